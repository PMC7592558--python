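#!/usr/bin/env python
"""Generate the default synthetic assay suite and summarize its imbalance.

Emulates the class structure of a panel of imbalanced qHTS toxicity screens:
four assays at imbalance ratios 5, 10, 20 and 40, each with 1,200 compounds,
512 fingerprint bits, three overlapping minority clusters and a stratified
80/20 train/test holdout.  Writes the per-split class counts and imbalance
ratios plus the train/test matrices as CSV.
"""

from pathlib import Path

from imbtox.data_prep import compute_imbalance_profile, imbalance_table
from imbtox.experiment import default_suite

OUT = Path("results")
MATRIX_OUT = Path("scratch/suite")  # full matrices are bulky; keep them out
SEED = 1                            # of the curated results tree


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    MATRIX_OUT.mkdir(parents=True, exist_ok=True)
    suite = default_suite(SEED)
    profiles = {}
    for train, test in suite:
        profiles[f"{train.assay_id} (train)"] = compute_imbalance_profile(train.labels)
        profiles[f"{test.assay_id} (test)"] = compute_imbalance_profile(test.labels)
        train.to_csv(MATRIX_OUT / f"{train.assay_id}_train.csv")
        test.to_csv(MATRIX_OUT / f"{test.assay_id}_test.csv")
    table = imbalance_table(profiles)
    table.to_csv(OUT / "imbalance_profiles.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {len(suite)} train/test pairs under {MATRIX_OUT}/")


if __name__ == "__main__":
    main()
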