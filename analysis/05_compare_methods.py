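#!/usr/bin/env python
"""Headline comparison: does SMOTEENN beat the plain bagged forest?

Twenty paired replicate suites; per replicate, the suite-mean F1 of the
SMOTEENN hybrid (smn) against the no-resampling baseline (rf), summarized
by a one-sided sign test.  Also reports average Friedman ranks of all four
methods on a single suite for the rank-based view of the same question.
"""

from pathlib import Path

from imbtox.ensemble import EnsembleConfig
from imbtox.experiment import (
    FAST_GRID,
    ExperimentConfig,
    default_suite,
    headline_f1_comparison,
    paired_sign_test,
    run_suite,
)
from imbtox.resampling import ResamplingConfig
from imbtox.stats_compare import average_friedman_ranks

OUT = Path("results/comparison")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    df = headline_f1_comparison(seed=SEED, n_seeds=20)
    df.to_csv(OUT / "paired_f1_per_replicate.csv", index=False)
    wins = int((df["smn"] > df["rf"]).sum())
    p = paired_sign_test(wins, len(df))
    print(f"suite-mean F1: smn={df['smn'].mean():.4f}  rf={df['rf'].mean():.4f}")
    print(f"smn beats rf in {wins}/{len(df)} replicates; one-sided sign test p={p:.2g}")

    cfg = ExperimentConfig(
        methods=("rf", "rus", "smo", "smn"),
        ensemble=EnsembleConfig(
            n_estimators=5,
            resampling=ResamplingConfig(method="none", enn_scope="all"),
            grid=dict(FAST_GRID),
        ),
        seed=SEED,
    )
    result = run_suite(default_suite(SEED), cfg)
    print("\naverage Friedman ranks (1 = best) per metric:")
    lines = []
    for metric in ("f1", "mcc", "auprc", "auroc", "balanced_accuracy"):
        table = result.metric_tables[metric]
        means, ses = average_friedman_ranks(table)
        cells = "  ".join(
            f"{m}={mu:.2f}±{se:.2f}" for m, mu, se in zip(table.method_names, means, ses)
        )
        lines.append(f"  {metric:18s} {cells}")
        print(lines[-1])
    (OUT / "friedman_ranks.txt").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
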