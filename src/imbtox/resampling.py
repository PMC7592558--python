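"""From-scratch resampling: RUS, SMOTE, ENN cleaning and SMOTEENN.

All four operate on a :class:`~imbtox.data_prep.FeatureMatrix` and return a
:class:`ResampledSet` carrying per-row provenance (original vs synthetic) and
the number of rows deleted by cleaning.

Distances are Euclidean on the raw feature values (no scaling).  Neighbor ties
at equal distance are broken by lowest row index; the search is exact chunked
brute force at every problem size, so tie behavior never depends on a backend
switch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data_prep import FeatureMatrix

__all__ = [
    "ResamplingConfig",
    "ResampledSet",
    "ORIGINAL",
    "SYNTHETIC",
    "nearest_neighbors",
    "random_undersample",
    "smote",
    "enn_clean",
    "smoteenn",
    "resample",
]

ORIGINAL, SYNTHETIC = 0, 1

_METHODS = ("none", "rus", "smote", "smoteenn")


@dataclass(frozen=True)
class ResamplingConfig:
    """Settings shared by the resamplers.

    ``target_ratio`` is the desired minority/majority ratio after rebalancing
    (1.0 = fully balanced).  ``k_enn`` is the neighbor count of the ENN vote;
    ``enn_scope`` selects whether cleaning may remove only synthetic rows (the
    default) or any row (the canonical SMOTEENN behavior).
    """

    method: str = "smoteenn"
    k_smote: int = 5
    k_enn: int = 3
    target_ratio: float = 1.0
    seed: int = 0
    enn_scope: str = "synthetic"  # "synthetic" | "all"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.k_smote < 1 or self.k_enn < 1:
            raise ValueError("neighbor counts must be >= 1")
        if not (0.0 < self.target_ratio <= 1.0):
            raise ValueError("target_ratio must lie in (0, 1]")
        if self.enn_scope not in ("synthetic", "all"):
            raise ValueError("enn_scope must be 'synthetic' or 'all'")


@dataclass
class ResampledSet:
    """Rebalanced training set with provenance flags."""

    values: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray  # ORIGINAL / SYNTHETIC per row
    removed_count: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=int)
        if not (len(self.values) == len(self.labels) == len(self.provenance)):
            raise ValueError("values, labels and provenance must align")

    @property
    def n(self) -> int:
        return len(self.labels)

    def class_counts(self) -> tuple[int, int]:
        """(n_majority_label_0, n_minority_label_1)."""
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    @classmethod
    def from_matrix(cls, fm: FeatureMatrix) -> "ResampledSet":
        return cls(fm.values.copy(), fm.labels.copy(), np.full(fm.n, ORIGINAL))

    def to_csv(self, path) -> None:
        """Write rows with label and provenance ('original'/'synthetic') columns."""
        import pandas as pd

        df = pd.DataFrame(self.values)
        df.insert(0, "provenance",
                  np.where(self.provenance == SYNTHETIC, "synthetic", "original"))
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------

def nearest_neighbors(
    X: np.ndarray,
    query: np.ndarray,
    k: int,
    *,
    exclude_self: bool = False,
    chunk: int = 1024,
) -> np.ndarray:
    """Indices of the k nearest rows of ``X`` for each query row.

    Squared Euclidean distances via the Gram-matrix expansion (exact for
    integer-valued data in float64); ties broken by lowest row index through a
    stable argsort.  ``exclude_self=True`` assumes ``query is X`` row-aligned.
    """
    X = np.asarray(X, float)
    Q = np.asarray(query, float)
    if k < 1 or k > X.shape[0] - (1 if exclude_self else 0):
        raise ValueError("k out of range for the reference set")
    x_sq = np.einsum("ij,ij->i", X, X)
    out = np.empty((Q.shape[0], k), dtype=int)
    for start in range(0, Q.shape[0], chunk):
        q = Q[start : start + chunk]
        d2 = x_sq[None, :] - 2.0 * (q @ X.T) + np.einsum("ij,ij->i", q, q)[:, None]
        np.maximum(d2, 0.0, out=d2)
        if exclude_self:
            rows = np.arange(start, start + q.shape[0])
            d2[np.arange(q.shape[0]), rows] = np.inf
        out[start : start + q.shape[0]] = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return out


# ---------------------------------------------------------------------------
# resamplers
# ---------------------------------------------------------------------------

def _split_classes(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    maj = np.flatnonzero(fm.labels == 0)
    mino = np.flatnonzero(fm.labels == 1)
    if maj.size == 0 or mino.size == 0:
        raise ValueError("both classes must be present")
    if mino.size > maj.size:  # labels say active is the majority: still treat
        warnings.warn("active class is not the minority; proceeding as labeled")
    return maj, mino


def random_undersample(fm: FeatureMatrix, cfg: ResamplingConfig) -> ResampledSet:
    """Keep all minority rows; subsample the majority without replacement.

    Target majority count is ``ceil(n_minority / target_ratio)``; if that
    exceeds the available majority rows, all are kept with a warning.
    """
    maj, mino = _split_classes(fm)
    rng = np.random.default_rng(cfg.seed)
    target = math.ceil(mino.size / cfg.target_ratio)
    if target >= maj.size:
        warnings.warn("target majority count exceeds available rows; keeping all")
        chosen = maj
    else:
        chosen = rng.choice(maj, size=target, replace=False)
    keep = np.sort(np.concatenate([chosen, mino]))
    return ResampledSet(
        fm.values[keep], fm.labels[keep], np.full(keep.size, ORIGINAL)
    )


def smote(fm: FeatureMatrix, cfg: ResamplingConfig) -> ResampledSet:
    """Interpolated minority oversampling.

    Each synthetic row is ``x + alpha * (x_nn - x)`` with ``x`` a minority row,
    ``x_nn`` one of its ``k_smote`` nearest minority neighbors (Euclidean) and
    ``alpha ~ Uniform(0, 1)``.  Rows are added until the minority/majority
    ratio reaches ``target_ratio``; originals pass through untouched.
    """
    maj, mino = _split_classes(fm)
    if mino.size < 2:
        raise ValueError("SMOTE requires at least two minority rows")
    k = cfg.k_smote
    if k > mino.size - 1:
        warnings.warn(
            f"k_smote={k} exceeds minority size - 1; clipped to {mino.size - 1}"
        )
        k = mino.size - 1

    n_target = round(cfg.target_ratio * maj.size)
    n_syn = max(0, n_target - mino.size)
    base_set = ResampledSet.from_matrix(fm)
    if n_syn == 0:
        return base_set

    X_min = fm.values[mino]
    nn = nearest_neighbors(X_min, X_min, k, exclude_self=True)
    rng = np.random.default_rng(cfg.seed)
    bases = rng.integers(0, mino.size, size=n_syn)
    picks = rng.integers(0, k, size=n_syn)
    alphas = rng.random(n_syn)
    neigh = nn[bases, picks]
    X_new = X_min[bases] + alphas[:, None] * (X_min[neigh] - X_min[bases])

    return ResampledSet(
        np.vstack([fm.values, X_new]),
        np.concatenate([fm.labels, np.ones(n_syn, int)]),
        np.concatenate([np.full(fm.n, ORIGINAL), np.full(n_syn, SYNTHETIC)]),
    )


def enn_clean(rs: ResampledSet, cfg: ResamplingConfig) -> ResampledSet:
    """Edited-nearest-neighbor cleaning of a (possibly augmented) set.

    Each row in the cleaning scope whose label disagrees with the majority
    label among its ``k_enn`` nearest neighbors (excluding itself, computed
    once against the full pre-cleaning set) is removed.  A tied vote (even k)
    leaves the row in place.  If cleaning would empty the minority class, the
    minority row nearest its class centroid is retained instead.
    """
    if cfg.k_enn >= rs.n:
        raise ValueError("k_enn must be smaller than the number of rows")
    scope = (
        np.flatnonzero(rs.provenance == SYNTHETIC)
        if cfg.enn_scope == "synthetic"
        else np.arange(rs.n)
    )
    if scope.size == 0:
        return ResampledSet(rs.values.copy(), rs.labels.copy(), rs.provenance.copy(),
                            removed_count=rs.removed_count)

    nn = nearest_neighbors(rs.values, rs.values, cfg.k_enn, exclude_self=True)
    votes_active = rs.labels[nn].sum(axis=1)
    majority_vote = np.where(
        2 * votes_active > cfg.k_enn, 1, np.where(2 * votes_active < cfg.k_enn, 0, -1)
    )
    inconsistent = (majority_vote != -1) & (majority_vote != rs.labels)
    remove = np.zeros(rs.n, bool)
    remove[scope] = inconsistent[scope]

    keep = ~remove
    if not (rs.labels[keep] == 1).any():
        warnings.warn("ENN removed every minority row; retaining centroid-nearest one")
        mino = np.flatnonzero(rs.labels == 1)
        centroid = rs.values[mino].mean(axis=0)
        d = np.linalg.norm(rs.values[mino] - centroid, axis=1)
        keep[mino[int(np.argmin(d))]] = True

    return ResampledSet(
        rs.values[keep],
        rs.labels[keep],
        rs.provenance[keep],
        removed_count=rs.removed_count + int((~keep).sum()),
    )


def smoteenn(fm: FeatureMatrix, cfg: ResamplingConfig) -> ResampledSet:
    """SMOTE followed by ENN cleaning; the result need not be balanced."""
    return enn_clean(smote(fm, cfg), cfg)


def resample(fm: FeatureMatrix, cfg: ResamplingConfig) -> ResampledSet:
    """Dispatch on ``cfg.method`` (``none`` is the identity)."""
    if cfg.method == "none":
        return ResampledSet.from_matrix(fm)
    if cfg.method == "rus":
        return random_undersample(fm, cfg)
    if cfg.method == "smote":
        return smote(fm, cfg)
    return smoteenn(fm, cfg)
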