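# Methods

## Problem setting

Quantitative high-throughput toxicity screens label each chemical as active
(toxic, the rare outcome) or inactive.  The imbalance ratio
IR = n_inactive / n_active routinely reaches 30–70, and a classifier trained
on such data maximizes accuracy by ignoring the active class — precisely the
class a toxicologist cares about.  This package studies one family of
remedies: rebalance each bootstrap of a bagged ensemble before training its
base learner, using random undersampling (RUS), synthetic minority
oversampling (SMOTE), or SMOTE followed by edited-nearest-neighbor cleaning
(SMOTEENN), and judge the result with a panel of metrics designed for
imbalanced problems.

## Pipeline

For a training set X and ensemble size N, each of the N members is built as:

1. **Stratified bootstrap** S_i: sample with replacement within each class,
   so S_i has exactly the class counts (and hence the IR) of X.
2. **Rebalancing** S'_i = resample(S_i): identity (plain bagging), RUS,
   SMOTE, or SMOTEENN, with target minority/majority ratio 1.
3. **Per-learner tuning**: grid search over the base-learner grid with
   stratified five-fold cross-validation on S'_i (scored by F1 on the active
   class), refit on all of S'_i.  The base learner is a random forest behind
   a minimal fit/predict-probability contract and is pluggable.
4. **Aggregation**: the ensemble label is the majority vote of the N
   learners (an exactly even vote goes to the inactive class — conservative
   toward the majority); the ensemble probability is the mean of the
   learners' active-class probabilities and feeds the Brier score, AUROC and
   AUPRC.  Vote labels feed the threshold metrics.

Cross-validation folds are drawn from the rebalanced subset S'_i, i.e. after
resampling; the untouched test split never enters any resampler or fit, and
the orchestrator hashes the test matrix before and after fitting to enforce
this.

All randomness flows from one integer seed through BLAKE2-derived
substreams tagged by (assay, method, member index), so any two methods run
on the same suite are paired replicate by replicate.

## Resamplers

* **RUS** keeps every minority row and draws
  ceil(n_minority / target_ratio) majority rows without replacement.
* **SMOTE** adds synthetic minority rows x_new = x + α(x_nn − x), with x a
  minority row, x_nn one of its k = 5 nearest minority neighbors by
  Euclidean distance, and α ~ Uniform(0, 1), until the target ratio is
  reached.  k = 5 is the original SMOTE convention; it is configurable.
* **ENN** computes each row's k = 3 nearest neighbors (excluding itself)
  once against the full pre-cleaning set and removes rows whose label loses
  the neighbor vote; a tied vote (possible for even k) keeps the row.  The
  default cleaning scope is the synthetic rows only; `enn_scope="all"`
  extends removal to every row, which is the behavior of the canonical
  SMOTEENN implementations, and is what the study drivers use — cleaning
  majority rows that sit inside minority territory is what actually moves
  the decision boundary.  If cleaning would empty the minority class, the
  minority row nearest its class centroid is retained and a warning issued.
* **SMOTEENN** is the composition ENN ∘ SMOTE with provenance preserved;
  its output is deliberately not guaranteed balanced.

Distances are computed on the raw feature values without scaling.  Neighbor
ties at equal distance are broken by lowest row index; the search is exact
(chunked Gram-matrix brute force, which is exact in float64 for
integer-valued fingerprints) at every problem size rather than switching to
an approximate spatial index — a backend switch could not guarantee the same
tie ordering, and no dataset in this study exceeds a few thousand rows.

## Metric panel

Nine metrics per method × dataset cell: recall, precision, F1, balanced
accuracy, MCC, Brier score, AUROC, AUPRC, and the sensitivity–specificity
gap SSG = |sensitivity − specificity|, composited as

    average9 = (F1 + MCC + AUROC + AUPRC + BA + precision + recall
                − Brier − SSG) / 9,

the two lower-is-better members entering with a minus sign.  Zero-denominator
conventions: precision = 0 when no positive prediction exists, F1 = 0 when
precision + recall = 0, MCC = 0 when any factor of its denominator is 0.
AUPRC is step-wise average precision (no linear interpolation, which is
optimistic); AUROC gives half credit to tied score pairs.  Accuracy and
specificity are computed but kept out of the headline panel (accuracy is
misleading under imbalance; specificity is near-saturated), specificity
being reported in the supplementary-style output.

## Statistical comparison

Method-versus-method comparison across datasets uses the Friedman
aligned-rank test: values are aligned by subtracting each dataset's mean
across methods, all n·k aligned values are ranked jointly (average ranks on
ties), and the chi-square statistic of the Hodges–Lehmann construction is
referred to k − 1 degrees of freedom.  Pairwise contrasts use the normal
z-statistic on differences of mean aligned ranks with
SE = sqrt(((nk)² − 1)/(6n)), adjusted by the Bergmann–Hommel exhaustive-set
procedure (feasible for k ≤ 6 methods; the adjusted values are clamped
monotone in the raw ordering).  Average Friedman ranks (1 = best per
dataset) summarize the same tables descriptively; Brier and SSG columns are
sign-flipped before ranking so rank 1 is uniformly best.

IR sensitivity is the Pearson correlation between log2(IR) and a metric,
flagged significant when |r| exceeds the closed-form two-tailed critical
value r* = t*/sqrt(t*² + df) with df = n − 2 (r* ≈ 0.5760 at α = 0.05,
df = 10).

## Synthetic data generator

The generator emulates the class structure of an imbalanced fingerprint
screen, not its chemistry.  The majority class draws each of p binary
features from a sparse activation profile (Beta prior with mean density
≈ 0.05, typical of hashed circular fingerprints).  The minority class is a
mixture over a small number of "scaffold family" clusters: each cluster
copies the majority profile and re-randomizes a disjoint signal block of
p/16 bits at density Uniform(0.7, 1.0) — high, so clusters are tight and the
classes are row-wise separable when overlap = 0.  The `overlap` dial
linearly interpolates the signal block back toward the majority profile
(overlap = 1 makes the classes indistinguishable; a nearest-centroid rule
then scores balanced accuracy ≈ 0.5, and at overlap = 0 it scores 1.0 —
both verified).  Independent bit flips with probability `bit_flip_noise`
are applied last.  Class sizes follow n_active = round(n_total/(IR + 1)),
floored at one, and the train/test split is a stratified 20% holdout, so
realized IRs match their targets to within one minority sample.

What the generator does *not* emulate: real feature correlation structure,
scaffold chemistry, activity cliffs tied to actual substructures, or
between-assay compound sharing.  Passing tests therefore demonstrate that
the pipeline recovers the *directional* phenomena (resampling helps;
performance decays with IR; cleaning strictness trades off threshold
metrics) on data with the right geometry — not that it reproduces any
particular screen's numbers.

## Study conditions and desk-scale choices

The default suite is four assays at IR ∈ {5, 10, 20, 40}, n = 1,200
compounds each, p = 512 bits, 3 minority clusters, overlap 0.5, 1% bit
noise; the IR-sensitivity sweep adds IR = 70 and averages over 10 replicate
suites; the headline SMOTEENN-vs-baseline comparison uses 20 paired
replicates.  Ensembles in the replicated studies use N = 5 members with a
single-point forest grid (50 trees) — the single-point grid makes the
grid-search stage a direct refit, keeping hundreds of ensemble fits
tractable on one CPU while preserving the per-bootstrap-rebalancing
structure under study; the per-learner grid-search contract itself is
exercised with multi-point grids elsewhere in the test suite.  The
ensemble-size plateau check fits 100 members once and evaluates prefix
ensembles, so N = 30 and N = 100 share their first 30 learners and the
comparison is exactly paired.

## Chemistry boundary

Real-data mode reads SDF and SMILES, standardizes structures (largest
uncharged fragment, canonical SMILES) via RDKit's standardizer, merges
duplicates by canonical structure with the majority activity label
(groups split evenly between active and inactive are dropped as ambiguous),
and featurizes with RDKit descriptors, MACCS keys and Morgan fingerprints
(radius 2, 1,024 bits) before zero-variance column removal.  Synthetic mode
needs none of this; every module downstream of featurization is
toolkit-free.

## Known limitations

* The aligned-rank pairwise z-statistic's normal reference treats aligned
  ranks as exchangeable across blocks; for very small n its p-values are
  approximate (the omnibus statistic is the standard construction).
* SMOTE on binary fingerprints produces fractional synthetic coordinates;
  trees can split between 0 and 1, so oversampling alone rarely moves the
  vote threshold — visible here as SMO ≈ RF, and the reason the cleaning
  step matters.
* Desk-scale ensembles (N = 5, 50-tree forests) trade variance for runtime;
  absolute metric values are noisier than a full-scale run, which is why
  the headline comparisons are paired and replicated.
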