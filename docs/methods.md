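# Methods

## The procedure

`itemreduce` addresses feature reduction for binary diagnostic
classification from ordinal instrument items (the motivating instruments
are the ADOS behavior observation and the ADI-R caregiver interview, with
ASD vs non-ASD as the label). The pipeline is deliberately simple and fully
determined by a master seed:

1. **Holdout.** A stratified 25% of subjects is set aside before anything
   else; all model building happens on the remaining 75%.
2. **Recoding.** Special codes 7/8 (peculiar/abnormal behavior, not
   severity) map to 0 and severity code 3 collapses into 2, per the
   instruments' manual conventions, so analysed codes are {0, 1, 2} or
   missing. Missing entries are never imputed; they enter the forests as a
   distinct sentinel category (−1), so every subject is used.
3. **Importance ranking.** A stratified 20-fold CV is laid over the
   training partition; run *i* trains a 400-tree random forest on all folds
   but fold *i* and scores each item by permutation importance: the mean
   decrease in held-fold accuracy over `n_permutations` (default 5)
   independent permutations of that item's column. Items are ranked within
   each run (ties broken by item id) and the aggregated hierarchy orders
   items by mean rank across runs, ties by mean importance, then item id —
   a total, deterministic order.
4. **Nested family.** For each prefix of the hierarchy a forest is
   evaluated by pooled out-of-fold scores under the same 20-fold CV (all
   prefix sizes share one fold assignment, so family members are compared
   on identical resampling). The positive-class score is the fraction of
   trees voting positive. Each model's threshold is fixed at the Youden
   optimum of its out-of-fold ROC and frozen. The **optimal model**
   maximizes `0.35·Â + 0.65·Ĉ` with Â the min-max-scaled AUC over the
   family and Ĉ the scaled simplicity (`Ĉ = 1` at the smallest prefix,
   `0` at the largest); ties go to the smaller model.
5. **Blind evaluation and minimal model.** Every family member is retrained
   on the full training partition and scored on the holdout at its frozen
   threshold. The **minimal model** is the smallest prefix whose
   correctness vector does not differ from the full model's by the
   uncorrected McNemar test (χ² = (b−c)²/(b+c), 1 df) at α = 0.05,
   scanning k upward. If none passes, the full model is flagged as its own
   minimal model.

## Statistical choices

- **McNemar without continuity correction.** The uncorrected χ²(1) tail
  reproduces standard printed (χ², p) anchor pairs exactly (e.g. 7.23 →
  0.007), which fixes the variant. Its small-sample companion is the
  *mid-p* exact binomial sign test — the two agree within 0.02 absolute for
  b + c ≥ 25, which the test suite verifies; the classic (non-mid-p) exact
  test is conservative relative to both. With b + c = 0 the convention is
  χ² = 0, p = 1. No multiple-testing correction is applied across the
  per-k comparisons; the scan is reported in full so readers can apply one.
- **Youden threshold.** Exhaustive search over midpoints between adjacent
  unique scores plus ±∞ sentinels; rule "positive when score ≥ t". Ties in
  J break toward higher specificity, then the higher threshold. With tied
  J on both flanks this prefers the stricter cut; flip the score sign if a
  sensitivity-first policy is wanted.
- **Accuracy.** "ACC" is balanced accuracy (mean of sensitivity and
  specificity) by default — robust to the ≈46/54 class split; plain
  accuracy is available via `plain_acc`.
- **Summary-statistic t-tests.** Pooled (Student) t by default, with
  `t = (m₂ − m₁)/SE` so t is negative when the first-listed (ASD) group
  scores higher, and Cohen's d = |m₁ − m₂| / pooled SD. A Welch option
  exists because heteroscedastic group pairs (very unequal SDs with unequal
  n) reproduce published t values better under Welch while printed dfs
  remain pooled; both variants are tested against raw-data oracles.
- **AUC** is the Mann–Whitney rank statistic (exact under ties), equivalent
  to pair counting; the brute-force pair counter serves as the test oracle,
  not the implementation.

## Randomness and reproducibility

One master seed drives everything. Substreams are derived by SHA-256
hashing of (seed, context labels), so results do not depend on the order in
which streams are consumed. Two consequences worth knowing:

- Permutation streams are keyed by *item id*, and forests are fitted
  internally on a canonical (lexicographic) column ordering, so the
  aggregated ranking is invariant to the column order of the input table —
  sklearn forests alone are not, because feature subsampling consumes RNG
  in column order.
- Pipeline output bundles are byte-identical across reruns with the same
  config and seed; the run log records every flag, seed and library
  version.

## The synthetic cohort generator

The generator defines the study conditions for all tests: two subsample
designs (28 module-3 or 31 module-4 observation items, optionally combined
with 37 interview algorithm items → 65/68), prevalence 0.46, 5% special
codes, 10% missingness, and seven planted informative items with latent
shifts δ = 2.0, 1.8, …, 0.8.

Model: item latent value `z = N(0,1) + δ·class`, discretized through
cutpoints placed so the negative class shows code mass ≈ {0: 50%, 1: 25%,
2: 15%, 3: 10%} (cutpoints Φ⁻¹(0.5), Φ⁻¹(0.75), Φ⁻¹(0.9); configurable
per item). A graded/probit generator was chosen over per-code multinomial
sampling because it yields a closed-form ground truth — the latent AUC of
a planted item is Φ(δ/√2) — against which oracle tests can check both the
generator and the metrics. Special codes are injected independently of
class (recoding them to 0 therefore adds class-independent noise, matching
their semantics of flagging peculiar behavior rather than severity), and
missingness is MCAR by default with an optional class-dependent stress
mode via custom specs.

What the generator does **not** emulate: real items are correlated within
domains (here they are conditionally independent given class), item
difficulty varies (one default cutpoint set), effects are monotone probit
shifts (no differential item functioning, no age/IQ structure), and
instrument-level missingness (subjects lacking the entire interview) is
only approximated by item-level MCAR unless `subset_on_adir` is used.
Passing the parameter-recovery suite therefore shows the *procedure* is
implemented correctly and can recover planted structure under realistic
noise — it does not certify clinical performance numbers, which depend on
the cohort. For the same reason the pipeline makes no attempt to reproduce
published performance tables from restricted clinical data.

## Problem sizes in tests and the acceptance script

The production defaults (20 runs × 400 trees, 20 folds) are what a study
run should use. The test and acceptance runs scale the forests to 100 trees
(and unit tests smaller still) on cohorts of n = 1500 (planted recovery)
and n = 2000 (null sanity): at these sizes ranking recovery and the
null-cohort behavior are already stable, and a full run completes in
minutes on one CPU. The null-cohort check builds only the k = 1 and k = n
family members, which is all its assertions need.

## Known limitations

- Prefix-only families: no combinatorial subset search, by design — the
  ranking defines the nesting.
- The importance hierarchy inherits random-forest biases (e.g. toward
  items with more observed levels); mean-rank aggregation tempers run-to-run
  noise but not systematic bias.
- The McNemar scan tests each k against the full model only; "minimal"
  means statistically indistinguishable *from the full model*, not from the
  optimal model.
- With very small validation sets the χ² approximation is rough below
  b + c ≈ 25 discordant pairs; the per-k (b, c) counts are exported so an
  exact test can be applied externally.
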