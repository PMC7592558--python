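#!/usr/bin/env python
"""Parameter sweeps: ensemble size N and the ENN neighbor count k.

The N sweep (5..100 in steps of 5, shared learner seeds via prefix
evaluation) looks for the performance plateau as the bagged ensemble grows;
the k sweep (1..5) probes how strict edited-nearest-neighbor cleaning should
be, reporting both the metric panel and the mean number of rows removed.
"""

from pathlib import Path

import pandas as pd

from imbtox._seed import derive_seed
from imbtox.ensemble import sweep_n_estimators
from imbtox.experiment import (
    ExperimentConfig,
    default_suite,
    desk_scale_ensemble_config,
    sweep_enn_k,
)

OUT = Path("results/sweeps")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ((train, test),) = default_suite(SEED, [10])

    n_cfg = desk_scale_ensemble_config(derive_seed(SEED, "nsweep"), "smn")
    n_table = sweep_n_estimators(train, test, n_cfg, list(range(5, 101, 5)))
    n_table.to_csv(OUT / "n_estimators_sweep.csv", index=False)
    f1 = n_table.set_index("n_estimators")["f1"]
    print("F1 vs ensemble size (SMOTEENN):")
    print(n_table[["n_estimators", "f1", "auroc", "mcc"]].to_string(index=False))
    print(f"\n|F1(N=30) - F1(N=100)| = {abs(f1[30] - f1[100]):.4f}")

    cfg = ExperimentConfig(
        methods=("smn",), ensemble=desk_scale_ensemble_config(0, "smn"), seed=SEED
    )
    k_table = sweep_enn_k(train, test, cfg, k_values=[1, 2, 3, 4, 5])
    k_table.to_csv(OUT / "enn_k_sweep.csv", index=False)
    print("\nSMOTEENN panel vs ENN k:")
    print(
        k_table[["k_enn", "f1", "auroc", "balanced_accuracy", "mean_removed"]]
        .to_string(index=False)
    )


if __name__ == "__main__":
    main()
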