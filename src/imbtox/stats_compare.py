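"""Nonparametric multi-method comparison and IR-correlation analysis.

Friedman aligned-rank omnibus test (values aligned by subtracting each
dataset's mean, then all n*k aligned observations ranked jointly with average
ranks on ties), pairwise z-statistics on mean aligned ranks with the
Bergmann-Hommel exhaustive-set p-value adjustment, plain average Friedman
ranks (1 = best per dataset), and the Pearson correlation between log2 of
the imbalance ratio and a performance metric with the closed-form two-tailed
critical value r* = t* / sqrt(t*^2 + df), df = n - 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "MetricTable",
    "ComparisonResult",
    "CorrelationResult",
    "friedman_aligned_ranks",
    "bergmann_hommel",
    "compare_methods",
    "average_friedman_ranks",
    "pearson_critical_value",
    "ir_correlation",
]


@dataclass
class MetricTable:
    """methods x datasets matrix of one evaluation metric."""

    values: np.ndarray
    method_names: list[str]
    dataset_names: list[str]
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        k, n = self.values.shape
        if k < 2 or n < 2:
            raise ValueError("need at least 2 methods and 2 datasets")
        if len(self.method_names) != k or len(self.dataset_names) != n:
            raise ValueError("name lists must match the matrix shape")
        if np.isnan(self.values).any():
            raise ValueError("metric table has missing cells")

    def oriented(self) -> np.ndarray:
        """Values with 'higher is better' orientation (lower-is-better negated)."""
        return self.values if self.higher_is_better else -self.values


@dataclass
class ComparisonResult:
    aligned_rank_statistic: float
    omnibus_p: float
    pairwise: list[tuple[str, str, float, float]]  # (a, b, raw_p, adjusted_p)
    avg_ranks: dict[str, float]
    degenerate: bool = False


@dataclass
class CorrelationResult:
    cc: float
    critical_value: float
    significant: bool
    p_value: float


# ---------------------------------------------------------------------------
# aligned ranks
# ---------------------------------------------------------------------------

def _aligned_rank_matrix(oriented: np.ndarray) -> np.ndarray:
    """Joint ranks (1..n*k, average on ties) of dataset-mean-aligned values."""
    aligned = oriented - oriented.mean(axis=0, keepdims=True)
    ranks = stats.rankdata(aligned, method="average")  # ranks the flat array
    return ranks.reshape(aligned.shape)


def friedman_aligned_ranks(table: MetricTable) -> ComparisonResult:
    """Aligned-rank chi-square omnibus test across methods.

    Statistic (Hodges-Lehmann construction):

        T = (k-1) [ sum_j Rhat_.j^2 - (k n^2 / 4)(k n + 1)^2 ]
            / ( k n (k n + 1)(2 k n + 1) / 6 - (1/k) sum_i Rhat_i.^2 )

    with Rhat_.j the aligned-rank sum of method j and Rhat_i. that of dataset
    i; T is referred to a chi-square with k - 1 degrees of freedom.  A table
    that is constant within every dataset is degenerate: T = 0, p = 1.
    """
    R = _aligned_rank_matrix(table.oriented())
    k, n = R.shape
    method_sums = R.sum(axis=1)
    dataset_sums = R.sum(axis=0)
    kn = k * n
    numerator = (method_sums**2).sum() - (k * n**2 / 4.0) * (kn + 1) ** 2
    denominator = kn * (kn + 1) * (2 * kn + 1) / 6.0 - (dataset_sums**2).sum() / k
    degenerate = denominator <= 1e-12 or numerator <= 1e-9
    statistic = 0.0 if degenerate else (k - 1) * numerator / denominator
    p = 1.0 if degenerate else float(stats.chi2.sf(statistic, k - 1))
    return ComparisonResult(
        aligned_rank_statistic=float(statistic),
        omnibus_p=p,
        pairwise=[],
        avg_ranks=dict(zip(table.method_names, average_friedman_ranks(table)[0])),
        degenerate=degenerate,
    )


def _pairwise_raw_p(table: MetricTable) -> list[tuple[str, str, float]]:
    """Two-sided normal p-values on differences of mean aligned ranks.

    Aligned ranks are uniform on 1..n*k under the null, so a single rank has
    variance ((nk)^2 - 1)/12 and the difference of two method means has
    standard error sqrt(((nk)^2 - 1)/(6 n)).
    """
    R = _aligned_rank_matrix(table.oriented())
    k, n = R.shape
    means = R.mean(axis=1)
    se = np.sqrt(((k * n) ** 2 - 1) / (6.0 * n))
    out = []
    for a, b in combinations(range(k), 2):
        z = (means[a] - means[b]) / se
        out.append(
            (table.method_names[a], table.method_names[b], float(2 * stats.norm.sf(abs(z))))
        )
    return out


# ---------------------------------------------------------------------------
# Bergmann-Hommel adjustment
# ---------------------------------------------------------------------------

def _partitions(items: tuple[int, ...]):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]


def exhaustive_sets(k: int) -> list[frozenset[tuple[int, int]]]:
    """Nonempty sets of pairwise hypotheses that can be exactly true together.

    Each partition of the k methods into equality groups induces the set of
    within-group pairs; the distinct nonempty such sets are the exhaustive
    sets of the Bergmann-Hommel procedure.
    """
    if k > 6:
        raise ValueError(
            "exhaustive-set enumeration is infeasible for k > 6; "
            "use a simpler correction (e.g. Holm)"
        )
    seen = set()
    for part in _partitions(tuple(range(k))):
        E = frozenset(
            (i, j) for block in part for i, j in combinations(sorted(block), 2)
        )
        if E:
            seen.add(E)
    return sorted(seen, key=lambda e: (len(e), sorted(e)))


def bergmann_hommel(raw_p: dict[tuple[int, int], float], k: int) -> dict[tuple[int, int], float]:
    """Adjusted p-values via the exhaustive-set (dynamic) procedure.

    APV for hypothesis h is min(1, max over exhaustive sets E containing h of
    |E| * min_{g in E} p_g), then made monotone in the raw p ordering.
    """
    pairs = list(combinations(range(k), 2))
    if set(raw_p) != set(pairs):
        raise ValueError("raw_p must cover every method pair (i < j)")
    sets_E = exhaustive_sets(k)
    v = {}
    for h in pairs:
        v[h] = max(
            len(E) * min(raw_p[g] for g in E) for E in sets_E if h in E
        )
    # enforce monotonicity: a hypothesis with smaller raw p never gets a
    # larger adjusted p than one with bigger raw p
    order = sorted(pairs, key=lambda h: raw_p[h])
    running = 0.0
    adjusted = {}
    for h in order:
        running = max(running, v[h])
        adjusted[h] = min(1.0, running)
    return adjusted


def compare_methods(table: MetricTable) -> ComparisonResult:
    """Omnibus aligned-rank test plus Bergmann-Hommel-adjusted pairwise tests."""
    res = friedman_aligned_ranks(table)
    raw = _pairwise_raw_p(table)
    idx = {name: i for i, name in enumerate(table.method_names)}
    raw_by_pair = {(idx[a], idx[b]): p for a, b, p in raw}
    adj = bergmann_hommel(raw_by_pair, len(table.method_names))
    res.pairwise = [
        (a, b, p, adj[(idx[a], idx[b])]) for a, b, p in raw
    ]
    return res


# ---------------------------------------------------------------------------
# average Friedman ranks and IR correlation
# ---------------------------------------------------------------------------

def average_friedman_ranks(table: MetricTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-method mean rank (1 = best per dataset; average ranks on ties)
    and its standard error across datasets."""
    oriented = table.oriented()
    k, n = oriented.shape
    ranks = np.empty_like(oriented)
    for j in range(n):
        ranks[:, j] = stats.rankdata(-oriented[:, j], method="average")
    means = ranks.mean(axis=1)
    ses = ranks.std(axis=1, ddof=1) / np.sqrt(n)
    return means, ses


def pearson_critical_value(alpha: float = 0.05, df: int = 10) -> float:
    """Two-tailed critical |r| at significance alpha: t*/sqrt(t*^2 + df)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_star / np.sqrt(t_star**2 + df))


def ir_correlation(ir_values, metric_values, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation of a metric against log2(IR) with significance flag."""
    ir = np.asarray(ir_values, float)
    m = np.asarray(metric_values, float)
    if ir.size != m.size or ir.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(ir <= 0):
        raise ValueError("imbalance ratios must be positive")
    x = np.log2(ir)
    if np.ptp(x) == 0 or np.ptp(m) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(x, m)
    crit = pearson_critical_value(alpha, df=ir.size - 2)
    return CorrelationResult(
        cc=float(r), critical_value=crit, significant=bool(abs(r) >= crit),
        p_value=float(p),
    )
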