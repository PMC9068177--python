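# Methods

## The estimation problem

The input is a BCSC-dialect risk-factor frequency table: rows are distinct
combinations of 12 categorical risk factors (small integer codes, with 9
meaning "unknown" for every factor except age group, where 9 is the 75–79
band), a binary cancer outcome, and a `count` column giving the number of
mammography records sharing the combination. The goal is a classifier that
predicts the outcome for an individual factor profile, under two
constraints that shape every stage: the cancer class is rare (3.32% of
rows), and `count` must be honored as an observation frequency.

## Pipeline model

The pipeline runs in a fixed order: **normalize → balance → weight → train
→ evaluate**. Configurations that rearrange the order are rejected. The
stages:

**Normalization.** Each factor column is divided by its maximum, mapping
codes into [0, 1]. The default divisor is the observed per-column maximum
(`observed-max`), the literal reading of the rule; `code-max` (the schema
maximum) is offered because the observed maximum can change across
subsamples. The unknown code 9 is kept as a numeric category — it usually
*is* the maximum and maps to 1.0 — because the source procedure treats it
that way. A `recode_unknown` option remaps it to the factor's modal known
code instead; it is off by default. Trees with exact categorical splits are
invariant to any of these choices; they matter only for binary threshold
splits and for any downstream consumer of the matrix.

**Balancing** operates on rows, not count-weighted totals. Oversampling
duplicates every minority row to total multiplicity `dup_factor`
(default 5, giving a 14.64% minority share at the published class sizes:
9,305 × 5 = 46,525 of 317,880). Down-sampling retains
`round(majority_n / reduction_factor)` majority rows chosen uniformly at
random under a seed (default factor 3.524; the published table prints
77,000 retained where the quotient is 77,002, so an explicit
`majority_target` override exists to reproduce printed figures exactly).
The mixed strategy does both (published shares 17.10% / 82.90%).
Duplication copies rows rather than incrementing `count`, keeping the two
frequency mechanisms orthogonal; `fold_into_count` merges duplicates back
when a compact table is wanted.

**Weighting.** Two expert evidence streams are fused per factor i:

- questionnaire: `DOI_q(i) = 0.6 H_i + 0.4 M_i`, with H, M the High- and
  Medium-risk vote fractions of the physician questionnaire;
- reports: `DOI_r(i) = (0.9 Ess_i + 0.1 Sec_i) / 4`, with Ess, Sec the
  number of four clinical reports listing the factor as essential or
  secondary. A factor mentioned in no report (the last-mammogram factor)
  gets `DOI_r = 0`; this zero-fill is forced by the published fused values.
- fusion: `DOI_f = (DOI_q + DOI_r) / 2`, the unweighted arithmetic mean.
  The published fused table carries more digits than its printed inputs can
  produce (e.g. 0.65751 vs the computable 0.6575); the hidden precision is
  not guessed, and the golden tests assert agreement within 2×10⁻³.

The integer suggested training weight (STW) is read off descending
thresholds on `DOI_f`: ≥ 0.60 → 4, ≥ 0.44 → 3, ≥ 0.42 → 2, else 1. The
thresholds are configuration, not logic: the published weight column pins
the third cut into (0.4156, 0.42255] and these defaults reproduce the
column exactly. Weak-impact factors can additionally carry a down-scale in
(0, 1] (e.g. 0.2–0.5), multiplying the STW.

**How weights enter training.** Two modes are supported because the
original mechanism is not stated. `column` multiplies each normalized
factor column by `stw × downscale`; this is invisible to a tree that
splits exactly on category values (scale invariance is a tested property).
`gain-scale` — the default — multiplies each factor's split gain by its
weight during split selection, which *can* change the induced tree; it
biases the greedy search toward high-weight factors, most visibly deep in
the tree where per-node samples are small and empirical gains noisy.

**Tree induction.** A from-scratch greedy partitioner: each node splits on
the factor maximizing information gain, `IG = H(parent) − Σ (w_c/w) H(c)`
in bits (Gini is available), with multiway splits over all category values
of the chosen factor (binary threshold splits optional). Stopping: pure
node, depth limit, or no positive gain. Ties break toward the lowest
factor index, then the lowest split value, making fitting deterministic
for the `best` splitter; the `random` splitter picks a seeded random
positive-gain factor. `count` enters every entropy as an observation
weight; because counts are integers, weighted sums are exact and fitting
is *identical* to row expansion (a tested invariant, not an
approximation). Tunable hyperparameters: criterion, splitter, max depth —
grid-searched by stratified k-fold CV accuracy with ties broken toward
the smaller depth.

**Evaluation.** Count-weighted 2×2 confusion matrix; per class c treated
as positive, FNR = FN/(FN+TP) and FDR = FP/(FP+TP); accuracy is the
weighted trace fraction. The validation protocol is stratified 5-fold CV
(pooled out-of-fold predictions) by default, configurable to holdout or
resubstitution.

**Prediction tool.** A query of 12 codes (no count) is matched exactly
against a reference dataset; the counts of all matching rows are summed
(duplicate combinations can occur with either outcome label — summation
makes the lookup equivalent to row-expanded frequency), 1 if unseen. The
query is then normalized and weighted with the divisors stored at training
time and routed down the tree; the leaf's class frequencies are the
reported probabilities. The looked-up count is reported but does not enter
traversal: count is an observation frequency, not a predictor.

## Synthetic cohorts

The real BCSC extract is registration-gated, so the test bed is synthetic:

- codes drawn independently per factor from the published marginal
  percentages (only marginals are published; no joint structure, so real
  inter-factor correlation — e.g. menopause with age — is absent);
- outcome from a logistic model, logit = b + Σ w_i · z_i, where z_i is the
  code divided by the factor's largest *known* code and the unknown code
  contributes 0. Every factor's known categories thus span the same [0, 1]
  range, so the coefficient w_i is the factor's importance on a common
  scale. Default coefficients equal the STW values (agegrp 4; race, nrelbc,
  hrt 3; agefirst 2; others 1), making the expert weights a correct prior
  by construction;
- the intercept b is calibrated by bisection so the expected prevalence
  equals the 3.32% target (realized count-weighted prevalence is binomial
  around it; the ±10%-relative contract is comfortably met at n = 10⁵);
- identical (codes, label) rows are merged, multiplicities summed into
  `count`, so the aggregation mechanics of the real file are exercised.

What passing tests on this bed do and do not show: they validate the
pipeline's mechanics and the *directional* claims (a correct importance
prior does not hurt, and removing a high-importance factor costs more than
removing a low-importance one) under independence and a clean logistic
truth. They say nothing about the published headline accuracies on the
real data, which depend on the real joint distribution.

## Study sizes and numerical choices

- The synthetic-cohort studies use n = 10⁵ generated records per cohort,
  five cohorts (seeds 1–5), fivefold oversampling, and a depth-8
  information-gain tree under stratified 5-fold CV — large enough for the
  directional effects to dominate fold noise while keeping a full study in
  minutes on one core.
- When two CV accuracies are compared on the same data, fold assignment is
  shared (same seed), so the comparison is paired; a fixed allowance of
  one accuracy point (0.01) is used where a "no worse than noise" claim is
  asserted.
- Gain comparisons use an absolute tolerance of 10⁻¹² (gains are O(1)
  bits); a split is accepted only if its scaled gain exceeds that.
- Entropy treats 0·log 0 as 0 and guards underflow by dropping
  zero-probability classes after normalization.
- The prevalence calibration bisects the intercept on [−40, 40] to width
  10⁻¹², and fails loudly if the target is unreachable.
- Degenerate inputs have defined behavior: single-class balancing, empty
  fits, all-zero entropy weights, folds exceeding the minority size, and
  dropping every factor all raise typed errors.

## Known limitations

- On the synthetic cohorts the gain-scale prior is, by measurement,
  accuracy-neutral rather than beneficial: with 10⁴–10⁵ records the
  empirical gains already rank factors correctly, so multiplying them by a
  correct prior reorders little and paired CV differences stay within
  ±0.3 accuracy points with no stable sign (the cohort test suite computes
  exactly this comparison). The clearly positive results are the adjacent
  ones: removing a high-weight factor costs far more accuracy than removing
  a low-weight one, and down-weighting a no-effect factor is harmless.
  Whether prior weighting helps on the real joint distribution cannot be
  decided from independent-marginal synthetic data.

- Factor independence in the generator understates the redundancy between
  correlated real factors; ablation effects on real data would be damped
  by substitution among correlated factors.
- The multiway splitter fragments high-cardinality factors; the binary
  mode mitigates this but is not the default, matching the k-subset
  formulation of the gain criterion.
- The STW thresholds are reverse-engineered from a printed table of 12
  values; with new questionnaire data they should be re-examined rather
  than reused.
- `count` is trusted as given; no de-duplication across conflicting labels
  is attempted beyond the lookup-time summation.
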