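# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the test suite demonstrates.

## The MCCV ensemble

The classifier is an ensemble built by repeated random subsampling
(Monte-Carlo cross-validation). Unlike conventional MCCV, which uses the
repeated splits only to *estimate* generalisation error, every per-split
tuned model is retained as an ensemble member, and prediction aggregates all
of them. The rationale is variance reduction at small n: single 262-subject
training sets produce unstable small models (validation CER ≈ 0.28-0.35 per
split on study-condition cohorts), while the average of hundreds of their
probability outputs is a much smoother score.

Assumptions and consequences:

* members are exchangeable — splits are i.i.d. uniform partitions (a guard
  redraws the rare split that leaves a class empty; stratified splitting is
  available by flag);
* the aggregate score is a mean of member probabilities, not a calibrated
  probability; the decision threshold 0.5 is a design constant, not a fitted
  cutoff, and ties resolve to benign (strict ">");
* the across-split interval reported for validation AUC is mean ± 1.96 SD of
  the member AUCs. This is a *dispersion* interval describing split-to-split
  variability, not a standard error of the mean; it is labelled as such in
  all outputs.

A vote-fraction rule (share of members with probability > 0.5) is
implemented alongside the mean-probability rule; with members emitting hard
0/1 probabilities the two rules provably coincide at threshold 0.5 (a unit
test asserts this). Mean-probability is the default because the downstream
threshold semantics ("probability exceeded 0.5") and the continuous
probability distributions reported per group presuppose a continuous
aggregate.

### Tuning

Per split, hyperparameters are chosen by exhaustive grid search with
stratified 10-fold CV accuracy on the training portion (fold count drops to
the largest feasible k ≥ 2 for tiny classes). Ties break to the first grid
point in declaration order, so tuning is deterministic. Continuous features
are standardised inside every fold and in the final refit via a pipeline
scaler — fold statistics never leak.

Two grid scales exist. `paper` carries the full documented ranges (SVM cost
0.01-1000 on a log grid; GBM interaction depth 1-9, shrinkage
{0.01, 0.1, 0.2}, min node size {5, 10, 15, 20}, bag fraction
{0.5, 0.75, 1.0}, 10,000 trees; XGBoost eta {0.01, 0.1, 0.2}, depth 1-9, min
child weight 1-9, subsample/colsample {0.7, 0.8, 0.9, 1.0}). The random
forest and AdaBoost grids (trees {500}, mtry 1-5; learners {50, 100, 500},
learning rate {0.1, 0.5, 1.0}) and the kernel-specific SVM parameters
(gamma = "scale", degree 3, coef0 0) are reconstructions, marked as such —
the original tuning table for those families is not public. `desk` keeps
one to three values per knob (e.g. SVM cost {0.1, 1, 10}) so that a full
run — 100 splits, both feature sets — completes in minutes on one CPU; the
package's own checks run at desk scale and state their split counts below.

### SVM probabilities

SVMs emit margins, not probabilities. Member probabilities for the four SVM
kernels come from explicit Platt scaling: a one-dimensional logistic
regression fitted to the training-set decision values. This is
deterministic, fast, and monotone in the margin (so member AUC is identical
to margin AUC); the default L2 regularisation (C = 1) keeps the sigmoid
finite on separable fits. Tree-family members use their native
`predict_proba`.

## missForest-style imputation

WBC and platelet are jointly missing for a fixed subset of benign subjects.
Within every MCCV split an iterative random-forest imputer is fitted on the
training portion only: missing cells start at training-column medians, then
variables are revisited in increasing-missingness order, each regressed on
all others with a 100-tree forest (30 at desk scale) and re-predicted. The
sweep difference criterion — sum of squared changes of the imputed values
normalised by their sum of squares — is tracked, and iteration stops the
first time it increases (the previous sweep's values are kept) or at 10
sweeps.

Two deliberate choices:

* **Out-of-sample replay.** The forests of every accepted sweep are stored,
  and held-out rows are imputed by replaying them in the same visit order
  from the same median initialisation. Nothing is refit on validation or
  test rows; transforming the training rows reproduces the fit-time
  imputations bit for bit (asserted by test). Re-fitting on pooled data
  would leak validation information into preprocessing.
* **Outcome exclusion.** The outcome label is not among the imputation
  predictors. Using it would propagate label information into imputed
  covariates of validation rows. Both choices are conservative defaults; the
  imputer accepts arbitrary predictor frames if a user wants otherwise.

Forest predictions are averages of observed leaf values, so imputations
cannot leave the observed training range (asserted by test).

## Synthetic cohorts

Only group-wise summary statistics of the motivating study population are
public, so the generator reproduces exactly that structure: 228 cancer /
170 benign-healthy subjects; per-group feature distributions fitted by least
squares to the published quartile triples; WBC and platelet jointly missing
for round(33/170 × n_benign) randomly chosen benign subjects (missingness is
group-dependent by construction — MNAR-by-group, exactly as observed, not
MCAR); subgroup labels (BI-RADS 0-6, stage 0-4, ER/HER2 subtype, density
B-D, each with an explicit NA category) drawn from the published frequency
tables conditional on outcome.

Distribution families:

* **Counts (CK18, MGB): negative binomial**, the standard overdispersed
  model for non-negative integer counts. Quartile targets may be
  non-integer (the benign MGB Q1 is an interpolated 1.25), so the fit uses a
  continuous quantile that linearly interpolates the CDF within each lattice
  point's probability mass, centred so that the continuous value k
  corresponds to the middle of P(X = k); the objective is minimised over a
  bounded (mean 0.5-20) × (dispersion 0.1-50) grid and polished by
  Nelder-Mead, never trusting the polish past the grid optimum.
* **Continuous features (age, WBC, platelet): three-parameter shifted
  log-normal**, reflected for left-skewed triples and truncated to the
  feature's support (age 18-100 years; blood counts > 0) by CDF inversion.
  Three parameters against three targets make the fit exact. A symmetric
  two-parameter family cannot represent these targets: the benign age triple
  (34, 46.5, 54) has quartile-gap ratio 1.67, beyond even a skew-normal's
  maximum (~1.34), and the best truncated normal leaves the median 1.8 years
  off. A plain truncated normal remains available as a family for
  symmetric-ish features.
* An optional Gaussian copula correlates CK18 and MGB within subject
  (default 0 — no joint structure is published).

What the generator does **not** emulate: any dependence between continuous
features and subgroup labels (labels are drawn independently given outcome),
between-feature correlation beyond the optional CTC copula, measurement
error in CTC counting, or longitudinal structure. Consequently, passing
tests demonstrate that the *pipeline* behaves correctly under the published
marginal structure — they say nothing about real-cohort effect sizes.
One known gap is quantified: the published quartiles under-determine the
CK18 distributions, and the quartile-faithful negative-binomial fits imply a
stochastic-superiority of only θ ≈ 0.59 between groups, so two-group CK18
comparisons at n = 398 reach p < 0.05 in ~86% of seeds rather than the
near-certainty the original data showed (p < 0.001 there). Age and MGB
separations are robust.

## Diagnostics

AUC is the Mann-Whitney statistic via midranks (ties ½). The analytic CI
uses DeLong's placement-value variance estimator (cross-checked against the
pROC reference implementation); the resampling CI is a percentile interval
over 2000 within-class (stratified) bootstrap replicates. Both are emitted
and labelled; intervals are truncated to [0, 1]. Confusion ratios with zero
denominators are NA, never 0. Display rounding is half-up to two decimals;
raw values are always retained in the JSON reports. The WMW
probability-distribution test uses the exact null for small tie-free
samples and the continuity-corrected asymptotic otherwise; the two-sample
KS test uses the asymptotic distribution. Threshold sweeps run over
0.30-0.80 in steps of 0.05.

Subgroup reports exclude NA-labelled rows (counting them), pool BI-RADS 3
and 4 on request, and report outcome prevalence (detection rate) per level.
The per-subject BI-RADS score is taken as given in the cohort table; when
assembling tables from multi-modality imaging the caller should supply the
maximum score across modalities.

## Gating

CTC identification on candidate-event tables applies, per event: DAPI
positivity, CD45 negativity, non-multilobed nucleus, diameter within
8-40 µm (both bounds inclusive — the published range states no open/closed
convention), round-or-oval shape, and the slide's marker (CK18 on slide 1,
MGB on slide 2). Pan-CK on slide 2 is recorded but not required by default;
a strict flag adds it. Excluded events are attributed to the *first*
failing rule in the fixed order DAPI → CD45 → multilobed → diameter →
shape → marker, making exclusion tallies deterministic. Per-channel counts
are independent tallies (each sample is split across two slides, so no
cross-slide deduplication is possible). The upstream imaging/AI confidence
scoring is out of scope; a numeric `score` column is accepted and ignored.

## Determinism and problem sizes

Every random draw derives from one master seed: MC split k is seeded by the
pair (seed, k) and is regenerable in isolation, so parallel execution
(joblib over splits) cannot change results; the imputer and learner seeds
of split k derive from (seed, k, ·). Two end-to-end runs with one seed
produce byte-identical CSVs (asserted by test).

The package's own checks choose desk-scale sizes: ensembles of 5-50 members
in unit tests, 12-40 in the end-to-end and acceptance runs, 15-20 per seed
in the permutation-null (20 seeds) and separated-cohort recovery (10 seeds)
properties, and n = 10,000 per group for generator-fidelity quantile
recovery. These sizes make the full suite a minutes-scale run while leaving
the assertions' statistical margins intact; the `paper` scale tag restores
the original design (1000 splits, full grids, 10,000-tree GBM) for users
who want it.

## Known limitations

* No probability calibration (Platt/isotonic on the aggregate) and no
  decision-curve analysis.
* The real cohort's headline test-set results cannot be reproduced — only
  the structure of the analysis and every metric whose inputs are published.
* Family comparison at desk scale on study-condition synthetic cohorts
  yields near-ties among SVM variants and GBM, as the original comparison
  did; selection among near-ties is governed by the configurable
  exclude/prefer ladder rather than re-derived.
* Categorical imputation is unsupported (the study's missingness is
  continuous-only).
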