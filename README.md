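# imbtox

Imbalanced-learning pipeline for structure–activity (SAR) based binary
chemical toxicity classification.

Toxicity screens are lopsided: a handful of active compounds drown in
thousands of inactives, with imbalance ratios IR = n_inactive / n_active of
5–70.  A classifier trained naively on such data buys accuracy by ignoring
the active class.  `imbtox` implements and evaluates the standard
data-level remedies — random undersampling (RUS), SMOTE, and SMOTEENN
(SMOTE followed by edited-nearest-neighbor cleaning) — hybridized with a
bagged ensemble in which **every bootstrap is independently rebalanced**
before its base learner (a grid-searched random forest) is trained:

    for i = 1..N:
        S_i  = stratified bootstrap of the training set X
        S'_i = resample(S_i)          # identity | RUS | SMOTE | SMOTEENN
        f_i  = grid-searched forest fit on S'_i (5-fold stratified CV)
    prediction = majority vote of f_1..f_N   (probability = mean of theirs)

Evaluation uses a nine-metric panel built for imbalanced problems — recall,
precision, F1, balanced accuracy (BA), Matthews correlation coefficient
(MCC), Brier score (BS), AUROC, AUPRC and the sensitivity–specificity gap
(SSG) — plus the composite

    average9 = (F1 + MCC + AUROC + AUPRC + BA + Precision + Recall − BS − SSG) / 9.

Method comparison across datasets uses the Friedman aligned-rank test with
Bergmann–Hommel-adjusted pairwise contrasts, and IR sensitivity is the
Pearson correlation between log2(IR) and each metric against the
closed-form critical value r* = t*/√(t*² + df).

Everything runs end to end on a built-in synthetic generator that emulates
the class structure of imbalanced fingerprint screens (sparse majority
bit-profile, a few tight minority "scaffold" clusters, controllable overlap
and IR), so no external chemical data are required.  Real-data mode (SDF /
SMILES ingestion, RDKit standardization and featurization, duplicate
merging by canonical structure) is available behind the same interfaces.

## Worked example

The numbered drivers under `analysis/` reproduce the study narrative; each
writes its tables under `results/`.  Generating the default suite (four
assays, IR 5–40, 1,200 compounds each) and running the four methods:

```bash
python analysis/01_generate_suite.py
python analysis/02_run_methods.py
```

prints (seed 1):

```
F1 by method and assay:
  rf   0.769  0.308  0.167  0.000   mean=0.311
  rus  0.940  1.000  0.952  0.800   mean=0.923
  smo  0.750  0.087  0.167  0.000   mean=0.251
  smn  0.873  0.308  0.167  0.000   mean=0.337

omnibus aligned-rank p-values per metric:
  f1                 p=0.03304
  mcc                p=0.03304
  brier              p=0.03086
  balanced_accuracy  p=0.03013
  auroc              p=0.4113
```

Read: the assays are ordered by IR (5, 10, 20, 40).  Every method decays as
the imbalance grows; rebalancing the bootstraps helps — SMOTEENN (smn)
improves on the plain bagged forest (rf), SMOTE alone (smo) does not
(fractional synthetic fingerprints rarely move the vote threshold; the
cleaning step is what matters), and on this tight-cluster geometry
undersampling (rus) is strikingly effective.  The aligned-rank test calls
the method effect significant for the threshold metrics (p < 0.05) but not
for AUROC, which barely notices resampling.  `analysis/03`–`05` add the
ensemble-size and ENN-k sweeps, the IR-correlation analysis and the paired
20-replicate headline comparison.

## Layout

```
src/imbtox/        library: data_prep, synthetic, resampling, ensemble,
                   metrics, stats_compare, experiment
analysis/          numbered narrative drivers (01..05)
scripts/           acceptance.py
tests/             pytest suite incl. end-to-end acceptance checks
docs/methods.md    model, assumptions, parameter choices, limitations
```
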