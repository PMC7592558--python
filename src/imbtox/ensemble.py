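"""Bagged ensemble with per-bootstrap rebalancing.

For each of N base learners: draw a stratified bootstrap of the training set
(same size and class counts as the input, sampled with replacement within
each class), rebalance it with the configured resampler (identity for plain
bagging), tune the base learner by stratified five-fold cross-validated grid
search on the rebalanced subset, and refit on all of it.  Prediction counts
the learners' votes (ties go to the inactive class) and averages their
active-class probabilities for the ranking/calibration metrics.

The base learner is a random forest behind a minimal fit/predict-probability
contract and is pluggable, so other classifiers can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from ._seed import derive_seed
from .data_prep import FeatureMatrix
from .metrics import full_panel
from .resampling import ResampledSet, ResamplingConfig, resample

__all__ = [
    "EnsembleConfig",
    "FittedEnsemble",
    "PredictionResult",
    "DEFAULT_GRID",
    "stratified_bootstrap",
    "fit_ensemble",
    "predict",
    "sweep_n_estimators",
]

#: default base-learner grid: small on purpose — the contract is per-learner
#: grid search, not a specific grid
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 300],
    "max_features": ["sqrt", "log2"],
    "min_samples_leaf": [1, 3],
}


def _default_base_learner(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(random_state=seed, n_jobs=1)


@dataclass(frozen=True)
class EnsembleConfig:
    n_estimators: int = 30
    resampling: ResamplingConfig = field(
        default_factory=lambda: ResamplingConfig(method="smoteenn")
    )
    grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    cv_folds: int = 5
    cv_scoring: str = "f1"
    seed: int = 0
    base_learner_factory: Callable[[int], object] = _default_base_learner

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.grid:
            raise ValueError("grid must be nonempty")


@dataclass
class FittedEnsemble:
    learners: list
    config: EnsembleConfig
    n_features: int
    training_fingerprint: str
    removed_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.learners) != self.config.n_estimators:
            raise ValueError("learner count must equal n_estimators")

    def save(self, path) -> None:
        """Persist the fitted ensemble (config + learners) to a versioned archive."""
        import pickle

        payload = {"format_version": 1, "model": self}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FittedEnsemble":
        import pickle

        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != 1:
            raise ValueError("unrecognized model archive version")
        return payload["model"]


@dataclass
class PredictionResult:
    labels: np.ndarray
    prob_active: np.ndarray
    vote_fraction: np.ndarray


def stratified_bootstrap(fm: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Bootstrap with replacement within each class: exact class counts kept."""
    rng = np.random.default_rng(seed)
    idx_parts = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(fm.labels == cls)
        if cls_idx.size == 0:
            raise ValueError("both classes must be present")
        idx_parts.append(rng.choice(cls_idx, size=cls_idx.size, replace=True))
    return fm.subset(np.concatenate(idx_parts))


def _grid_combos(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]


def _fit_one(rs: ResampledSet, cfg: EnsembleConfig, seed: int):
    """Grid-search the base learner on the rebalanced subset, refit on all of it."""
    base = cfg.base_learner_factory(seed)
    combos = _grid_combos(cfg.grid)
    if len(combos) == 1:
        learner = clone(base).set_params(**combos[0])
        learner.fit(rs.values, rs.labels)
        return learner
    n_min_class = int(np.bincount(rs.labels, minlength=2).min())
    folds = min(cfg.cv_folds, max(2, n_min_class))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        base, cfg.grid, scoring=cfg.cv_scoring, cv=cv, n_jobs=1, refit=True
    )
    search.fit(rs.values, rs.labels)
    return search.best_estimator_


def _train_hash(fm: FeatureMatrix) -> str:
    import hashlib

    h = hashlib.blake2b(digest_size=16)
    h.update(np.ascontiguousarray(fm.values).tobytes())
    h.update(np.ascontiguousarray(fm.labels).tobytes())
    return h.hexdigest()


def fit_ensemble(train: FeatureMatrix, cfg: EnsembleConfig) -> FittedEnsemble:
    """Fit the N rebalanced-bootstrap base learners (Algorithm-1-style loop).

    A bootstrap whose rebalanced subset degenerates to a single class is
    regenerated with the next derived seed, at most 10 retries.
    """
    learners = []
    removed = []
    for i in range(cfg.n_estimators):
        rs = None
        for attempt in range(10):
            boot_seed = derive_seed(cfg.seed, "bootstrap", i, attempt)
            S_i = stratified_bootstrap(train, boot_seed)
            r_cfg = replace(
                cfg.resampling, seed=derive_seed(cfg.seed, "resample", i, attempt)
            )
            candidate = resample(S_i, r_cfg)
            if len(np.unique(candidate.labels)) == 2:
                rs = candidate
                break
        if rs is None:
            raise RuntimeError(f"could not obtain a two-class subset for learner {i}")
        learners.append(_fit_one(rs, cfg, derive_seed(cfg.seed, "learner", i)))
        removed.append(rs.removed_count)
    return FittedEnsemble(
        learners=learners,
        config=cfg,
        n_features=train.p,
        training_fingerprint=_train_hash(train),
        removed_counts=removed,
    )


def _prob_active(learner, X: np.ndarray) -> np.ndarray:
    proba = learner.predict_proba(X)
    classes = list(learner.classes_)
    if 1 in classes:
        return proba[:, classes.index(1)]
    return np.zeros(X.shape[0])


def _aggregate(learners: Sequence, X: np.ndarray) -> PredictionResult:
    votes = np.zeros(X.shape[0])
    probs = np.zeros(X.shape[0])
    for lr in learners:
        votes += lr.predict(X)
        probs += _prob_active(lr, X)
    n = len(learners)
    vote_fraction = votes / n
    # strict majority of active votes; exact ties go to the inactive class
    labels = (vote_fraction > 0.5).astype(int)
    return PredictionResult(labels=labels, prob_active=probs / n, vote_fraction=vote_fraction)


def predict(model: FittedEnsemble, test: FeatureMatrix) -> PredictionResult:
    if test.p != model.n_features:
        raise ValueError(
            f"feature count mismatch: model has {model.n_features}, test has {test.p}"
        )
    return _aggregate(model.learners, test.values)


def sweep_n_estimators(
    train: FeatureMatrix,
    test: FeatureMatrix,
    cfg: EnsembleConfig,
    n_values: Sequence[int] = tuple(range(5, 101, 5)),
) -> pd.DataFrame:
    """Metric panel versus ensemble size N with shared learner seeds.

    Learner i's bootstrap and seeds depend only on (cfg.seed, i), so the
    ensemble of size N is exactly the first N learners of the largest fit:
    one fit at max(N), evaluated on every prefix — the comparisons across N
    are paired by construction.
    """
    if not n_values:
        raise ValueError("n_values must be nonempty")
    n_max = max(n_values)
    big = fit_ensemble(train, replace(cfg, n_estimators=n_max))
    rows = []
    for n in sorted(n_values):
        pred = _aggregate(big.learners[:n], test.values)
        panel = full_panel(test.labels, pred.labels, pred.prob_active)
        row = {"n_estimators": n}
        row.update(panel.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
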