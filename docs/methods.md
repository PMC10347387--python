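# Methods

## The screening problem and the economic statistic

The package benchmarks binary classifiers that decide which type 2
diabetes patients should receive an HbA1c test. The outcome is poor
glycemic control, defined as HbA1c strictly above 7.0%; a value of exactly
7.0 is negative (the controlled group is "HbA1c ≤ 7.0"). Model quality is
summarized by Model Benefit (MB): the cost of testing everyone (TC = N·fee)
minus the model-guided cost (MC = tests ordered · fee + misses · miss-cost −
averted tests · fee). Defaults are fee = ¥73 and miss-cost = ¥786.77, the
per-patient excess cost of therapeutic inertia; both are configurable, and
currency arithmetic is exact decimal rounded to cents at report time.
Algebraically MB = 2·fee·TN − (miss_cost − fee)·FN, so MB rewards averted
tests and penalizes misses only — two models with equal TN and FN tie on MB
even if their TP/FP differ. The classification threshold defaults to 0.5
(ties predicted positive); `optimal_mb_threshold` can instead scan
training-partition scores for the MB-maximizing cutoff, which is then
applied frozen to the test partition.

## Synthetic cohort generator

The packaged catalog describes 55 candidate variables by their
class-conditional marginals: for continuous variables a mean ± SD with
plausibility bounds, for categorical variables per-class level frequencies
(stored as counts and normalized at load time; level order defines integer
codes 0, 1, ...). Cohorts are drawn by sampling the outcome label
Bernoulli(prevalence = 0.523 by default) and then each variable
independently given the class.

Continuous sampling preserves the catalog moments exactly. A truncated
normal is used whenever its two parameters can be solved (least squares on
the truncated mean/SD) to reproduce the target moments on the bounded
support; where that is infeasible — high coefficient-of-variation
variables on a nonnegative scale such as insulin doses or measurement
intervals, and the EQ-5D utility whose mean + SD sits exactly on the
upper-truncation boundary of [0, 1] — a scaled Beta distribution is
moment-matched in closed form. The distinction matters because the
pre-screening CV rule sits right at the printed moments for some variables
(EQ-5D: CV 0.111 against the 0.1 cutoff); a generator that let truncation
deflate the SD would remove variables that should survive.

Missingness is injected separately, missing-completely-at-random per
variable, with defaults of 5% on same-day FBG (X55) and waistline (X4) —
the fields a clinic measures rather than asks — and 0 elsewhere; the rates
are fully overridable and the outcome is never masked. The missingness RNG
stream is decoupled from the sampling stream so turning missingness on
does not change the sampled values.

What the generator deliberately does **not** model: inter-variable
correlation given the class (only marginals are available; variables are
conditionally independent), longitudinal structure, and
missing-not-at-random mechanisms. Consequently, passing tests demonstrate
that the pipeline machinery is correct and that class-conditional signal
is exploited, but not that real-data effect sizes are reproduced; in
particular, predictive imputation can barely beat mean imputation on these
cohorts because, given the class, no variable predicts another (see the
test suite's planted-companion design for where the advantage is real).

## Pre-screening

Three rules fire in order, each computed on the input table (no cascade),
each removal attributed to the first rule that fires: (1) missing fraction
> 0.90; (2) modal-value share among observed cells > 0.90; (3) coefficient
of variation sd/|mean| < 0.1, continuous columns only — a CV of integer
level codes is meaningless, and the rule would otherwise discard
frequency-coded categoricals arbitrarily. A zero-mean column is kept with
a warning. The operation is idempotent, and loosening any threshold never
removes more columns. On large cohorts from the packaged catalog the
removed set is exactly the 14 near-constant variables (nationality,
marital status, the complication indicators, glinides, thiazolidinediones,
GLP-1 receptor agonists, SGLT2 inhibitors, Chinese-medicine use), leaving
41 candidates.

## Missing-data methods

All imputers follow fit/transform semantics: statistics and models are fit
on the training partition only and applied frozen to the test partition.

- **SI** — continuous: column mean; categorical: median of observed
  integer codes, computed nearest-rank so the fill is always an observed
  code. (The median, not the mode, is deliberate: level codes are ordered.)
- **KNN** — distances are NaN-aware Euclidean on z-scored continuous plus
  one-hot categorical features; each missing cell takes the mean (or mode,
  with the smallest code winning ties) of the k = 5 nearest training rows
  observed in that column.
- **RF** — iterative per-column random forests (100 trees by default),
  initialized by SI, columns visited in increasing missing-count order, up
  to 10 sweeps or until the maximum standardized change drops below 1e-3;
  regression forests for continuous targets, classification forests for
  categorical. Transforming new data applies the stored final-sweep models
  for two sweeps after SI initialization.
- **OD (optimal deletion)** — instead of filling, delete rows and/or
  columns so the retained submatrix is complete, maximizing the retained
  cell count (rows × columns; pure row maximization would degenerately
  delete every incomplete column). Because complete columns are always
  kept, enumerating subsets of the incomplete columns (with a subset-sum
  sweep over row missingness bitmasks) is exhaustive and exactly optimal;
  it runs whenever at most 16 columns carry missing cells, which covers
  every benchmark configuration. Beyond that cap a greedy heuristic takes
  over: repeatedly delete the row or column with the largest missing count
  (ties toward columns, then lowest index), then restore anything deleted
  that is complete with respect to the retained set. The greedy variant is
  a genuine heuristic — on random 6×6 masks it attains the optimum in only
  about a third of cases, which is why the exact path is the default and
  `brute_force_deletion` exists as an independent oracle. Applied to a test
  partition, OD drops the training plan's columns and any test row that is
  still incomplete.

## Variable screening

LASSO (LA) and ElasticNet (EN) are penalized logistic fits on z-scored
continuous plus one-hot categorical features, with penalty strength chosen
from 10 log-spaced values by stratified 5-fold cross-validated AUC (EN
additionally tunes the mixing weight over {0.1, 0.5, 0.9}); a variable is
selected if any of its indicator columns has a nonzero coefficient, and EN
with mixing weight pinned to 1 reproduces LA exactly. Ridge (RD) never
zeroes coefficients, so it selects variables whose per-variable score (L2
norm of owned standardized coefficients) strictly exceeds the mean score;
an all-equal tie keeps everything, and the threshold quantile is
configurable. Boruta (BOR) shuffles a shadow copy of every feature each
iteration, fits a 500-tree random forest on real plus shadow features, and
counts a hit when a real feature out-ranks the best shadow; features are
confirmed/rejected by binomial tests against chance (α = 0.05,
Bonferroni-corrected across features, no confirmations before iteration
5), running up to 100 iterations, with leftover tentatives resolved by
comparing median importance to the median shadow maximum. One caveat
inherent to the all-relevant formulation: the strongest chance-correlated
feature of a finite noise design is data-conditionally relevant and is
occasionally confirmed; per-feature false confirmations stay near α but
per-dataset "zero false positives" cannot be guaranteed.

## Factorial grid

The cohort is split 8:2, stratified by outcome with the training size
exactly ⌊0.8·n⌋ and prevalence preserved within one patient (simple random
splitting would add avoidable MB variance at n ≈ 1000). For each
FBG flag (X55 kept or dropped), each imputer × selector pair produces a
training dataset and a consistently transformed test set, numbered in
alphabetical imputer-then-selector order. Six algorithms are tuned per
dataset by exhaustive grid search on stratified k-fold AUC (MB-based
selection is available via the threshold optimizer downstream): random
forest, logistic regression, MLP (both behind scaling/one-hot
preprocessing), XGBoost, LightGBM, and — for the categorical-boosting
slot — histogram gradient boosting with native categorical splits. Default
grids are anchored on the benchmark's winning hyperparameter values
(LGBM max_depth {1,3,5} × subsample {0.1,0.5,1.0}; CB iterations
{50,67,100,200}; RF trees {100,147,200}; XGB gamma {0,0.1} × depth {3,5} ×
subsample {0.7,1.0}; MLP activation/solver; LR C {0.01,0.1,1,10});
`fast_grids()` provides reduced axes for desk-scale runs. Tree learners
consume raw integer codes; per-cell failures are recorded in the output
records rather than raised. No test-partition row can influence
imputation, selection or tuning by construction, and the suite verifies
this by mutating test rows and asserting bit-identical trained models.

## Attributions

Per-prediction attributions are interventional Shapley values against a
background sample (default 64 rows): the payoff of a coalition is the mean
model output with coalition features from the explained row and the rest
from the background. Exact subset enumeration is used up to 10 features;
above that, permutation sampling (default 32 orderings) whose telescoping
marginal contributions keep local accuracy exact — baseline plus
attributions equals the model output to floating point for both
estimators. Models without probability outputs fall back to permutation
importance, flagged as such since those scores are not additive.

## Meta-analysis

Ranking sorts scored records by a chosen metric (default MB), ties broken
by AUC then record id. Meta-regression fits OLS of each metric on the
pipeline factors; method factors are integer-coded (SI=1, RF=2, KNN=3,
OD=4; BOR=1, EN=2, LA=3, RD=4) to yield one slope per factor, with one-hot
coding available; non-varying factors are dropped with a warning, and
coefficients, standard errors, p-values and R² are reported. The learning
curve re-trains a pinned model configuration on stratified subsamples of
the training partition at fractions 0.1–1.0 (10 repeats by default;
subsampling is without replacement, with a with-replacement switch),
evaluating AUC on the fixed test partition; at fraction 1.0 the subsample
is the whole partition, so the point is deterministic under a fixed model
seed. The flattening point is the smallest fraction after which every
successive mean-AUC increment is below the tolerance (default 0.005),
returned as 1.0 with a flag when the curve is still rising; it is
descriptive, not a formal power analysis.

## Problem sizes and numerical choices

The test suite runs the full 4 × 4 × 6 × 2-flag factorial (192 models) on
a 980-patient synthetic cohort with reduced hyperparameter grids, 3-fold
tuning, a 30-tree/3-sweep RF imputer and a 60-tree/25-iteration Boruta —
sizes chosen so the complete benchmark remains a single-machine,
few-minute computation while keeping every pipeline stage on its default
code path. Penalized selection uses saga with tolerance 1e-3 (up to 2000
iterations) on standardized features. The acceptance script's cohort size
of 100,000 makes the pre-screening statistics' Monte-Carlo error an order
of magnitude smaller than each rule's margin; the one deliberately tight
case is the any-complication indicator, whose dominant share (≈0.902)
exceeds the 0.90 cutoff by about two standard errors at that size, exactly
as tight as the underlying frequencies make it.

## Known limitations

- Marginal-only generation: no correlation given class, so multivariate
  structure (and the real advantage of predictive imputation) is absent.
- The MB statistic prices only tests and misses; no QALYs, discounting, or
  uncertainty in the cost inputs (a 1:1 RMB:DKK conversion underlies the
  default miss cost and is recorded as configuration metadata only).
- Single split: no nested cross-validation or bootstrap confidence
  intervals for the reported metrics.
- OD optimality is exact only up to 16 incomplete columns; beyond that the
  greedy fallback carries no guarantee.
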