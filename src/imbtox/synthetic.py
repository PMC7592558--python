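"""Synthetic imbalanced fingerprint assays.

Generates two-class binary feature matrices that mimic the class structure of
highly imbalanced qHTS toxicity screens: a large inactive majority drawn from
one sparse bit-activation profile and a small active minority drawn from a
mixture of a few tight "scaffold family" clusters whose signal bits can
overlap the majority profile to a controllable degree.  The geometry is chosen
so that the pathologies the resampling methods address are observable at desk
scale: with high overlap, interpolated synthetic minority points cross into
majority territory (the borderline noise that edited-nearest-neighbor
cleaning removes).

Defaults encode the study conditions used throughout the analysis: 1,200
compounds per assay, 512 fingerprint bits, 3 minority clusters, overlap 0.5,
1% bit-flip noise, and imbalance ratios spanning 5-70.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._seed import derive_seed
from .data_prep import FeatureMatrix

__all__ = [
    "SyntheticAssayConfig",
    "ConfusionFixture",
    "class_split",
    "generate_assay",
    "generate_suite",
    "generate_confusion_fixture",
    "DEFAULT_SUITE_IRS",
    "IR_SWEEP_IRS",
]

#: imbalance ratios of the default four-assay suite (headline comparisons)
DEFAULT_SUITE_IRS: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0)
#: imbalance ratios of the IR-sensitivity sweep
IR_SWEEP_IRS: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 70.0)

# mean bit density of the majority (inactive) activation profile; typical of
# hashed 1024-bit circular fingerprints
_MAJORITY_DENSITY_A, _MAJORITY_DENSITY_B = 0.8, 15.2  # Beta prior, mean ~0.05
# density range of the re-randomized per-cluster "pharmacophore" bit block;
# kept high so each cluster is tight: at zero overlap and zero noise the
# classes are then separable row-wise, the geometry the overlap dial assumes
_SIGNAL_LO, _SIGNAL_HI = 0.7, 1.0


@dataclass(frozen=True)
class SyntheticAssayConfig:
    """Generator settings for one synthetic assay.

    ``overlap`` interpolates each minority cluster's signal-block profile
    toward the majority profile: 0 gives fully separable classes, 1 makes the
    minority indistinguishable from the majority.
    """

    n_total: int = 1200
    ir: float = 10.0
    p: int = 512
    n_minority_clusters: int = 3
    bit_flip_noise: float = 0.01
    overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 20:
            raise ValueError("n_total must be >= 20")
        if self.ir < 1:
            raise ValueError("ir must be >= 1")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.n_minority_clusters < 1:
            raise ValueError("need at least one minority cluster")
        if not (0.0 <= self.bit_flip_noise <= 1.0 and 0.0 <= self.overlap <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_minority_clusters * max(1, self.p // 16) > self.p:
            raise ValueError("too many minority clusters for the feature count")


@dataclass(frozen=True)
class ConfusionFixture:
    """Score/label vectors engineered to yield exact confusion counts at 0.5."""

    y_true: np.ndarray
    y_score: np.ndarray
    intended_counts: tuple[int, int, int, int]  # (TP, FP, TN, FN)


def class_split(n_total: int, ir: float) -> tuple[int, int]:
    """Deterministic (n_inactive, n_active) split closest to the target IR.

    ``n_active = round(n_total / (ir + 1))`` floored at 1.
    """
    n_active = max(1, round(n_total / (ir + 1.0)))
    n_inactive = n_total - n_active
    if n_inactive < 1:
        raise ValueError("ir and n_total leave no majority rows")
    return n_inactive, n_active


def _profiles(cfg: SyntheticAssayConfig, rng: np.random.Generator):
    """Majority profile and per-cluster minority profiles (stream order fixed)."""
    majority = rng.beta(_MAJORITY_DENSITY_A, _MAJORITY_DENSITY_B, size=cfg.p)
    block = max(1, cfg.p // 16)
    clusters = []
    for c in range(cfg.n_minority_clusters):
        prof = majority.copy()
        lo = c * block
        signal = rng.uniform(_SIGNAL_LO, _SIGNAL_HI, size=block)
        prof[lo : lo + block] = (
            (1.0 - cfg.overlap) * signal + cfg.overlap * majority[lo : lo + block]
        )
        clusters.append(prof)
    return majority, clusters


def generate_assay(config: SyntheticAssayConfig) -> FeatureMatrix:
    """Draw one imbalanced binary assay; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_inactive, n_active = class_split(config.n_total, config.ir)
    majority, clusters = _profiles(config, rng)

    X_maj = (rng.random((n_inactive, config.p)) < majority).astype(float)
    assign = rng.integers(0, config.n_minority_clusters, size=n_active)
    X_min = np.empty((n_active, config.p))
    for i, c in enumerate(assign):
        X_min[i] = rng.random(config.p) < clusters[c]

    X = np.vstack([X_maj, X_min])
    y = np.concatenate([np.zeros(n_inactive, int), np.ones(n_active, int)])
    if config.bit_flip_noise > 0:
        flips = rng.random(X.shape) < config.bit_flip_noise
        X = np.abs(X - flips.astype(float))
    order = rng.permutation(config.n_total)
    return FeatureMatrix(
        X[order],
        y[order],
        [f"bit_{i}" for i in range(config.p)],
        assay_id=f"synthetic_ir{config.ir:g}",
    )


def generate_suite(
    ir_list: Sequence[float],
    base_config: SyntheticAssayConfig | None = None,
    *,
    test_fraction: float = 0.2,
) -> list[tuple[FeatureMatrix, FeatureMatrix]]:
    """One (train, test) pair per IR, split by stratified holdout.

    The holdout is stratified on the class label, so train and test realized
    IRs agree with the target up to one minority sample of rounding slack.
    """
    if not ir_list:
        raise ValueError("ir_list must be nonempty")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    base = base_config or SyntheticAssayConfig()
    pairs = []
    for ir in ir_list:
        cfg = replace(base, ir=float(ir), seed=derive_seed(base.seed, "assay", ir))
        fm = generate_assay(cfg)
        rng = np.random.default_rng(derive_seed(cfg.seed, "holdout"))
        test_idx: list[int] = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(fm.labels == cls)
            n_test = max(1, round(test_fraction * cls_idx.size))
            test_idx.extend(rng.choice(cls_idx, size=n_test, replace=False))
        test_mask = np.zeros(fm.n, bool)
        test_mask[np.asarray(test_idx)] = True
        train = fm.subset(np.flatnonzero(~test_mask))
        test = fm.subset(np.flatnonzero(test_mask))
        train.assay_id = test.assay_id = fm.assay_id
        pairs.append((train, test))
    return pairs


def generate_confusion_fixture(
    tp: int, fp: int, tn: int, fn: int, seed: int = 0
) -> ConfusionFixture:
    """Construct labels and scores whose 0.5-threshold confusion matrix is exact.

    Predicted-positive rows receive scores strictly above 0.5, predicted
    negatives strictly below; shuffling preserves the counts by construction.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + tn + fn
    if n < 1:
        raise ValueError("at least one count must be positive")
    rng = np.random.default_rng(seed)
    y_true = np.concatenate(
        [np.ones(tp, int), np.zeros(fp, int), np.zeros(tn, int), np.ones(fn, int)]
    )
    hi = rng.uniform(0.55, 0.95, size=tp + fp)
    lo = rng.uniform(0.05, 0.45, size=tn + fn)
    y_score = np.concatenate([hi, lo])
    order = rng.permutation(n)
    return ConfusionFixture(y_true[order], y_score[order], (tp, fp, tn, fn))
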