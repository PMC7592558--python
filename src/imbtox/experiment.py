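"""End-to-end study orchestration.

Runs the four hybrid methods (rf = plain bagging, rus = bagging + random
undersampling, smo = bagging + SMOTE, smn = bagging + SMOTEENN) per assay,
aggregates the nine-metric panels into method x dataset tables, performs the
aligned-rank / Bergmann-Hommel comparison per metric and the log2(IR)
correlation analysis, and exposes the two parameter sweeps (ensemble size N,
ENN neighbor count k).

The headline study conditions live in :data:`default_suite_config` /
:func:`default_suite`: four synthetic assays at imbalance ratios 5, 10, 20
and 40 with three overlapping minority clusters.  The desk-scale model
configuration (five ensemble members, a single-point 50-tree forest grid)
keeps a full replicated comparison tractable on one CPU while preserving the
per-bootstrap-rebalancing structure under study.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seed import derive_seed
from .data_prep import FeatureMatrix, compute_imbalance_profile
from .ensemble import EnsembleConfig, fit_ensemble, predict, sweep_n_estimators
from .metrics import LOWER_IS_BETTER, PANEL_METRICS, MetricPanel, full_panel
from .resampling import ResamplingConfig
from .stats_compare import (
    ComparisonResult,
    CorrelationResult,
    MetricTable,
    compare_methods,
    ir_correlation,
)
from .synthetic import (
    DEFAULT_SUITE_IRS,
    IR_SWEEP_IRS,
    SyntheticAssayConfig,
    generate_suite,
)

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "METHOD_RESAMPLING",
    "ExperimentConfig",
    "SuiteResult",
    "desk_scale_ensemble_config",
    "default_suite",
    "run_assay",
    "run_suite",
    "sweep_enn_k",
    "headline_f1_comparison",
    "ir_sweep_f1_correlations",
    "plateau_gap",
]

METHODS = ("rf", "rus", "smo", "smn")
METHOD_RESAMPLING = {"rf": "none", "rus": "rus", "smo": "smote", "smn": "smoteenn"}

#: desk-scale base-learner grid: one 50-tree forest configuration, so the
#: grid-search stage is a no-op refit and a replicated suite stays tractable
FAST_GRID: dict[str, list] = {"n_estimators": [50]}


@dataclass(frozen=True)
class ExperimentConfig:
    methods: tuple[str, ...] = METHODS
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods must be nonempty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class SuiteResult:
    panels: dict[tuple[str, str], MetricPanel]
    metric_tables: dict[str, MetricTable]
    comparisons: dict[str, ComparisonResult]
    ir_correlations: dict[tuple[str, str], CorrelationResult]
    manifest: dict


def desk_scale_ensemble_config(
    seed: int, method: str, n_estimators: int = 5, k_enn: int = 3
) -> EnsembleConfig:
    """Desk-scale ensemble configuration for one method and seed."""
    return EnsembleConfig(
        n_estimators=n_estimators,
        # the study runs use the canonical all-rows ENN scope (SMOTE followed
        # by edited-nearest-neighbor cleaning of the whole augmented set, as
        # in standard SMOTEENN implementations); the synthetic-only scope
        # remains the library default
        resampling=ResamplingConfig(
            method=METHOD_RESAMPLING[method], k_enn=k_enn, enn_scope="all"
        ),
        grid=dict(FAST_GRID),
        seed=seed,
    )


def default_suite(
    seed: int, irs: Sequence[float] = DEFAULT_SUITE_IRS
) -> list[tuple[FeatureMatrix, FeatureMatrix]]:
    """The default overlapping-cluster synthetic suite (one pair per IR)."""
    return generate_suite(irs, SyntheticAssayConfig(seed=seed))


def _test_hash(fm: FeatureMatrix) -> str:
    h = hashlib.blake2b(digest_size=16)
    h.update(np.ascontiguousarray(fm.values).tobytes())
    h.update(np.ascontiguousarray(fm.labels).tobytes())
    return h.hexdigest()


def run_assay(
    train: FeatureMatrix,
    test: FeatureMatrix,
    cfg: ExperimentConfig,
) -> dict[str, MetricPanel]:
    """Fit and evaluate every configured method on one train/test pair.

    The test split is hashed before fitting and verified afterwards: nothing
    from the test set may influence training.
    """
    if train.p != test.p:
        raise ValueError("train and test feature spaces must match")
    before = _test_hash(test)
    panels: dict[str, MetricPanel] = {}
    for method in cfg.methods:
        e_cfg = replace(
            cfg.ensemble,
            resampling=replace(
                cfg.ensemble.resampling, method=METHOD_RESAMPLING[method]
            ),
            seed=derive_seed(cfg.seed, train.assay_id, method),
        )
        try:
            model = fit_ensemble(train, e_cfg)
            pred = predict(model, test)
            panels[method] = full_panel(test.labels, pred.labels, pred.prob_active)
        except Exception:
            logger.exception("method %s failed on %s", method, train.assay_id)
            raise
    if _test_hash(test) != before:
        raise RuntimeError("test set was mutated during fitting")
    return panels


def _tables_from_panels(
    panels: dict[tuple[str, str], MetricPanel],
    methods: Sequence[str],
    datasets: Sequence[str],
) -> dict[str, MetricTable]:
    tables = {}
    for metric in PANEL_METRICS + ("average9",):
        values = np.array(
            [[getattr(panels[(m, d)], metric) for d in datasets] for m in methods]
        )
        tables[metric] = MetricTable(
            values,
            list(methods),
            list(datasets),
            higher_is_better=metric not in LOWER_IS_BETTER,
        )
    return tables


def run_suite(
    suite: Sequence[tuple[FeatureMatrix, FeatureMatrix]],
    cfg: ExperimentConfig,
) -> SuiteResult:
    """Per-assay runs, per-metric comparison and IR-correlation analysis.

    Writes metric tables, comparison summaries and a manifest (config, seeds,
    per-assay hashes) as CSV/JSON under ``cfg.output_dir`` when set.
    """
    if not suite:
        raise ValueError("suite must be nonempty")
    datasets = [train.assay_id for train, _ in suite]
    panels: dict[tuple[str, str], MetricPanel] = {}
    irs: dict[str, float] = {}
    for train, test in suite:
        irs[train.assay_id] = compute_imbalance_profile(test.labels).ir
        for method, panel in run_assay(train, test, cfg).items():
            panels[(method, train.assay_id)] = panel

    tables = _tables_from_panels(panels, cfg.methods, datasets)
    comparisons = {
        m: compare_methods(t) for m, t in tables.items() if len(cfg.methods) >= 2
    }
    ir_corrs: dict[tuple[str, str], CorrelationResult] = {}
    ir_vec = np.array([irs[d] for d in datasets])
    if len(datasets) >= 3 and np.ptp(np.log2(ir_vec)) > 0:
        for metric, table in tables.items():
            for mi, method in enumerate(cfg.methods):
                try:
                    ir_corrs[(metric, method)] = ir_correlation(
                        ir_vec, table.values[mi]
                    )
                except ValueError:
                    continue

    manifest = {
        "seed": cfg.seed,
        "methods": list(cfg.methods),
        "datasets": datasets,
        "test_irs": {d: irs[d] for d in datasets},
        "ensemble": {
            "n_estimators": cfg.ensemble.n_estimators,
            "grid": cfg.ensemble.grid,
            "cv_folds": cfg.ensemble.cv_folds,
            "cv_scoring": cfg.ensemble.cv_scoring,
            "resampling": asdict(cfg.ensemble.resampling),
        },
    }
    result = SuiteResult(panels, tables, comparisons, ir_corrs, manifest)
    if cfg.output_dir:
        _write_suite(result, cfg)
    return result


def _write_suite(result: SuiteResult, cfg: ExperimentConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (method, dataset), panel in result.panels.items():
        row = {"method": method, "dataset": dataset, "specificity": panel.specificity}
        row.update(panel.to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "metric_panels.csv", index=False)
    comp_rows = []
    for metric, comp in result.comparisons.items():
        comp_rows.append(
            {
                "metric": metric,
                "comparison": "omnibus",
                "statistic": comp.aligned_rank_statistic,
                "p": comp.omnibus_p,
            }
        )
        for a, b, raw, adj in comp.pairwise:
            comp_rows.append(
                {"metric": metric, "comparison": f"{a}_vs_{b}", "raw_p": raw, "p": adj}
            )
    pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)
    corr_rows = [
        {
            "metric": metric,
            "method": method,
            "cc": c.cc,
            "critical_value": c.critical_value,
            "significant": c.significant,
        }
        for (metric, method), c in result.ir_correlations.items()
    ]
    pd.DataFrame(corr_rows).to_csv(out / "ir_correlations.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def sweep_enn_k(
    train: FeatureMatrix,
    test: FeatureMatrix,
    cfg: ExperimentConfig,
    k_values: Sequence[int] = (1, 2, 3, 4, 5),
) -> pd.DataFrame:
    """SMN metric panel versus the ENN neighbor count k (shared seeds).

    Also reports the mean number of rows ENN removed per ensemble member,
    which is expected to grow with k (a stricter vote removes more).
    """
    rows = []
    for k in k_values:
        e_cfg = replace(
            cfg.ensemble,
            resampling=replace(cfg.ensemble.resampling, method="smoteenn", k_enn=k),
            seed=derive_seed(cfg.seed, train.assay_id, "smn"),
        )
        model = fit_ensemble(train, e_cfg)
        pred = predict(model, test)
        panel = full_panel(test.labels, pred.labels, pred.prob_active)
        row = {"k_enn": k, "mean_removed": float(np.mean(model.removed_counts))}
        row.update(panel.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# headline study computations (shared by the analysis drivers, the
# acceptance checks and the reproduction script)
# ---------------------------------------------------------------------------

def headline_f1_comparison(
    seed: int,
    n_seeds: int = 20,
    methods: tuple[str, str] = ("rf", "smn"),
    irs: Sequence[float] = DEFAULT_SUITE_IRS,
    n_estimators: int = 5,
) -> pd.DataFrame:
    """Per-seed suite-mean F1 for two methods on the default suite.

    Returns one row per replicate seed with a column per method; replicates
    are paired (same suites, same bootstrap substream structure).
    """
    rows = []
    for r in range(n_seeds):
        suite_seed = derive_seed(seed, "headline", r)
        suite = default_suite(suite_seed, irs)
        row: dict[str, float] = {"replicate": r}
        for method in methods:
            f1s = []
            for train, test in suite:
                e_cfg = desk_scale_ensemble_config(
                    derive_seed(suite_seed, train.assay_id, method),
                    method,
                    n_estimators=n_estimators,
                )
                model = fit_ensemble(train, e_cfg)
                pred = predict(model, test)
                f1s.append(full_panel(test.labels, pred.labels, pred.prob_active).f1)
            row[method] = float(np.mean(f1s))
        rows.append(row)
    return pd.DataFrame(rows)


def paired_sign_test(wins: int, n: int) -> float:
    """One-sided sign-test p-value for `wins` successes out of n pairs."""
    return float(stats.binomtest(wins, n, 0.5, alternative="greater").pvalue)


def ir_sweep_f1_correlations(
    seed: int,
    n_seeds: int = 10,
    irs: Sequence[float] = IR_SWEEP_IRS,
    methods: Sequence[str] = METHODS,
    n_estimators: int = 5,
) -> tuple[pd.DataFrame, dict[str, CorrelationResult]]:
    """F1 per (method, IR) averaged over seeds, plus log2(IR) correlations."""
    records = []
    for r in range(n_seeds):
        rep_seed = derive_seed(seed, "irsweep", r)
        suite = default_suite(rep_seed, irs)
        for (train, test), ir in zip(suite, irs):
            for method in methods:
                e_cfg = desk_scale_ensemble_config(
                    derive_seed(rep_seed, train.assay_id, method),
                    method,
                    n_estimators=n_estimators,
                )
                model = fit_ensemble(train, e_cfg)
                pred = predict(model, test)
                panel = full_panel(test.labels, pred.labels, pred.prob_active)
                records.append(
                    {"replicate": r, "ir": ir, "method": method, "f1": panel.f1}
                )
    df = pd.DataFrame(records)
    mean_f1 = df.groupby(["method", "ir"])["f1"].mean().reset_index()
    corrs = {}
    for method in methods:
        sub = mean_f1[mean_f1["method"] == method]
        corrs[method] = ir_correlation(sub["ir"].to_numpy(), sub["f1"].to_numpy())
    return df, corrs


def plateau_gap(
    seed: int,
    n_seeds: int = 3,
    n_small: int = 30,
    n_large: int = 100,
    method: str = "smn",
    ir: float = 10.0,
) -> tuple[float, pd.DataFrame]:
    """|F1(N=n_small) - F1(N=n_large)| on the default assay, paired seeds.

    Uses the prefix-ensemble evaluation, so the two ensemble sizes share
    every learner up to n_small; returns the mean absolute gap and the full
    sweep table.
    """
    gaps = []
    frames = []
    for r in range(n_seeds):
        rep_seed = derive_seed(seed, "plateau", r)
        (train, test), = default_suite(rep_seed, [ir])
        e_cfg = desk_scale_ensemble_config(
            derive_seed(rep_seed, train.assay_id, method), method
        )
        table = sweep_n_estimators(train, test, e_cfg, [n_small, n_large])
        table.insert(0, "replicate", r)
        frames.append(table)
        f1 = table.set_index("n_estimators")["f1"]
        gaps.append(abs(f1[n_small] - f1[n_large]))
    return float(np.mean(gaps)), pd.concat(frames, ignore_index=True)
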