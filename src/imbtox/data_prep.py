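"""Activity-data ingestion and feature hygiene.

Curation rules for quantitative high-throughput screening activity data:
duplicate compounds are merged to a single record carrying the majority
activity label (groups with an equal number of active and inactive outcomes
are dropped as ambiguous), zero-variance feature columns are removed, and
class imbalance is summarized as the inactive/active ratio (IR).

Featurization (RDKit descriptors, MACCS keys, Morgan/ECFP bits) and structure
standardization are delegated to RDKit behind :func:`featurize` /
:func:`standardize_structure`; every other operation in this module is
toolkit-free so the synthetic pipeline runs without a cheminformatics stack.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "ActivityTable",
    "FeatureMatrix",
    "ImbalanceProfile",
    "FeaturizationConfig",
    "merge_duplicates",
    "drop_zero_variance",
    "featurize",
    "compute_imbalance_profile",
    "standardize_structure",
    "read_smiles_file",
    "read_sdf",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One compound with a binary activity outcome (1 = active, 0 = inactive)."""

    compound_id: str
    label: int
    structure: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be nonempty")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class ActivityTable:
    """Curated per-assay record collection (post duplicate merging)."""

    assay_id: str
    records: tuple[CompoundRecord, ...]
    split: str = "training"

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "structure": [r.structure for r in self.records],
                "label": [r.label for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class FeatureMatrix:
    """n x p feature matrix with aligned binary labels.

    ``values`` holds binary fingerprint bits and/or continuous descriptors;
    downstream code treats it as a plain float array.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    assay_id: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("label count must match row count")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[idx],
            self.labels[idx],
            list(self.feature_names),
            self.assay_id,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, assay_id: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(float), labels, list(df.columns), assay_id)

    def to_sparse_text(self, path: str | Path) -> None:
        """Coordinate-format text dump (compact for sparse fingerprints).

        Header line ``n p assay_id``, then the labels, then one ``row col
        value`` triple per nonzero entry.
        """
        rows, cols = np.nonzero(self.values)
        lines = [f"{self.n} {self.p} {self.assay_id or '-'}"]
        lines.append(" ".join(str(l) for l in self.labels))
        lines += [
            f"{r} {c} {self.values[r, c]:g}" for r, c in zip(rows, cols)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_sparse_text(cls, path: str | Path) -> "FeatureMatrix":
        text = Path(path).read_text().splitlines()
        n, p, assay_id = text[0].split(maxsplit=2)
        n, p = int(n), int(p)
        assay_id = "" if assay_id == "-" else assay_id
        labels = np.array(text[1].split(), dtype=int)
        values = np.zeros((n, p))
        for line in text[2:]:
            if not line.strip():
                continue
            r, c, v = line.split()
            values[int(r), int(c)] = float(v)
        return cls(values, labels, assay_id=assay_id)


@dataclass(frozen=True)
class ImbalanceProfile:
    """Class counts and the imbalance ratio IR = n_inactive / n_active."""

    n_inactive: int
    n_active: int

    @property
    def ir(self) -> float:
        return self.n_inactive / self.n_active

    @property
    def ir_display(self) -> float:
        """IR rounded half-up to one decimal, matching tabular reporting."""
        return float(Decimal(self.ir).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# curation operations
# ---------------------------------------------------------------------------

def merge_duplicates(
    records: Iterable[CompoundRecord],
    *,
    key: str = "compound_id",
    assay_id: str = "",
    split: str = "training",
) -> ActivityTable:
    """Collapse duplicate compounds to a single majority-label record.

    Records are grouped by ``key`` (``"compound_id"`` for synthetic data or
    ``"structure"`` for standardized structures).  Each group keeps one record
    carrying its most frequent label; groups with an equal number of active
    and inactive outcomes are ambiguous and dropped entirely.  Idempotent.
    """
    if key not in ("compound_id", "structure"):
        raise ValueError(f"unknown duplicate key {key!r}")
    groups: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        kval = getattr(rec, key)
        if kval is None:
            raise ValueError(f"record {rec.compound_id!r} lacks duplicate key {key!r}")
        groups.setdefault(kval, []).append(rec)

    merged: list[CompoundRecord] = []
    n_ambiguous = 0
    for members in groups.values():
        counts = Counter(r.label for r in members)
        if counts[0] == counts[1]:
            n_ambiguous += 1
            continue
        majority = 1 if counts[1] > counts[0] else 0
        keeper = next(r for r in members if r.label == majority)
        merged.append(keeper)
    if n_ambiguous:
        logger.info("dropped %d ambiguous duplicate group(s)", n_ambiguous)
    return ActivityTable(assay_id=assay_id, records=tuple(merged), split=split)


def drop_zero_variance(fm: FeatureMatrix, *, rtol: float = 1e-12) -> FeatureMatrix:
    """Remove constant feature columns, preserving the order of the rest.

    Binary/integer-valued columns are tested by exact equality; continuous
    columns by a relative spread tolerance ``rtol``, so platform-level float
    jitter cannot resurrect a constant descriptor.
    """
    if fm.n < 1:
        raise ValueError("feature matrix must have at least one row")
    X = fm.values
    span = X.max(axis=0) - X.min(axis=0)
    is_integral = np.all(X == np.round(X), axis=0)
    scale = np.maximum(1.0, np.abs(X).max(axis=0))
    keep = np.where(is_integral, span > 0, span > rtol * scale)
    if not keep.any():
        raise ValueError("all feature columns are constant; no usable features")
    return FeatureMatrix(
        X[:, keep],
        fm.labels,
        [n for n, k in zip(fm.feature_names, keep) if k],
        fm.assay_id,
    )


def compute_imbalance_profile(labels: Sequence[int] | np.ndarray) -> ImbalanceProfile:
    """Exact class counts and IR (majority inactive / minority active)."""
    y = np.asarray(labels, dtype=int)
    n_active = int((y == 1).sum())
    n_inactive = int((y == 0).sum())
    if n_active == 0:
        raise ValueError("no active compounds: imbalance ratio undefined")
    return ImbalanceProfile(n_inactive=n_inactive, n_active=n_active)


# ---------------------------------------------------------------------------
# cheminformatics boundary (RDKit-delegated)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeaturizationConfig:
    """Which feature blocks to compute and their fingerprint settings."""

    use_descriptors: bool = True
    use_maccs: bool = True
    use_morgan: bool = True
    radius: int = 2
    n_bits: int = 1024


def _require_rdkit():
    try:
        from rdkit import Chem  # noqa: F401
    except ImportError as exc:  # pragma: no cover - rdkit present in CI env
        raise ImportError(
            "RDKit is required for structure handling; install the 'chem' extra"
        ) from exc


def standardize_structure(smiles: str) -> str | None:
    """Canonical SMILES of the largest uncharged fragment, or None if unparseable.

    Fragment splitting, salt/solvent removal and canonicalization are delegated
    to RDKit's standardizer; the returned string is the duplicate-merge key for
    real-data mode.
    """
    _require_rdkit()
    from rdkit import Chem
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        parent = rdMolStandardize.FragmentParent(mol)
        parent = rdMolStandardize.Uncharger().uncharge(parent)
    except Exception:  # standardizer failure: fall back to the parsed mol
        parent = mol
    return Chem.MolToSmiles(parent)


def featurize(table: ActivityTable, config: FeaturizationConfig | None = None) -> FeatureMatrix:
    """Concatenated descriptor / MACCS / Morgan feature blocks per record.

    Unparseable structures are skipped with a logged warning; the skip count is
    carried on the returned matrix.  Deterministic for fixed input.
    """
    _require_rdkit()
    from rdkit import Chem
    from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

    cfg = config or FeaturizationConfig()
    if not (cfg.use_descriptors or cfg.use_maccs or cfg.use_morgan):
        raise ValueError("at least one feature block must be enabled")

    morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=cfg.radius, fpSize=cfg.n_bits
    )
    desc_list = Descriptors.descList if cfg.use_descriptors else []

    rows: list[np.ndarray] = []
    labels: list[int] = []
    n_skipped = 0
    for rec in table.records:
        if rec.structure is None:
            n_skipped += 1
            logger.warning("record %s has no structure; skipped", rec.compound_id)
            continue
        mol = Chem.MolFromSmiles(rec.structure)
        if mol is None:
            n_skipped += 1
            logger.warning("unparseable structure for %s; skipped", rec.compound_id)
            continue
        blocks: list[np.ndarray] = []
        if cfg.use_descriptors:
            vals = []
            for _, fn in desc_list:
                try:
                    vals.append(float(fn(mol)))
                except Exception:
                    vals.append(np.nan)
            blocks.append(np.asarray(vals))
        if cfg.use_maccs:
            blocks.append(np.asarray(MACCSkeys.GenMACCSKeys(mol), dtype=float))
        if cfg.use_morgan:
            blocks.append(np.asarray(morgan_gen.GetFingerprint(mol), dtype=float))
        rows.append(np.concatenate(blocks))
        labels.append(rec.label)

    if not rows:
        raise ValueError("no featurizable records")
    names: list[str] = []
    if cfg.use_descriptors:
        names += [f"desc_{name}" for name, _ in desc_list]
    if cfg.use_maccs:
        names += [f"maccs_{i}" for i in range(167)]
    if cfg.use_morgan:
        names += [f"ecfp{2 * cfg.radius}_{i}" for i in range(cfg.n_bits)]
    X = np.vstack(rows)
    # descriptors can yield NaN for exotic structures; impute with column median
    if np.isnan(X).any():
        med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), med, X)
    fm = FeatureMatrix(X, np.asarray(labels), names, table.assay_id)
    fm.n_skipped = n_skipped
    return fm


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_smiles_file(
    path: str | Path, *, assay_id: str = "", split: str = "training"
) -> list[CompoundRecord]:
    """Read whitespace-separated ``SMILES  compound_id  label`` lines."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"malformed SMILES line: {line!r}")
        smiles, cid, label = parts[0], parts[1], int(parts[2])
        records.append(CompoundRecord(compound_id=cid, label=label, structure=smiles))
    return records


def read_sdf(
    path: str | Path,
    *,
    label_prop: str,
    id_prop: str | None = None,
) -> list[CompoundRecord]:
    """Read an SDF file, taking the binary label from property ``label_prop``.

    Records whose label is not 0/1 (inconclusive, not tested) are dropped, as
    are unparseable structures.
    """
    _require_rdkit()
    from rdkit import Chem

    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None or not mol.HasProp(label_prop):
            continue
        raw = mol.GetProp(label_prop).strip()
        if raw not in ("0", "1"):
            continue
        cid = (
            mol.GetProp(id_prop)
            if id_prop and mol.HasProp(id_prop)
            else (mol.GetProp("_Name") or f"mol{i}")
        )
        records.append(
            CompoundRecord(
                compound_id=str(cid) or f"mol{i}",
                label=int(raw),
                structure=Chem.MolToSmiles(mol),
            )
        )
    return records


def imbalance_table(profiles: dict[str, ImbalanceProfile]) -> pd.DataFrame:
    """Tabulate per-assay class counts and IR (exact and display-rounded)."""
    return pd.DataFrame(
        {
            "assay_id": list(profiles),
            "n_inactive": [p.n_inactive for p in profiles.values()],
            "n_active": [p.n_active for p in profiles.values()],
            "ir": [p.ir for p in profiles.values()],
            "ir_display": [p.ir_display for p in profiles.values()],
        }
    )
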