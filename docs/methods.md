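# Methods

`valimpute` estimates the predictive performance — and the *added*
predictive performance — of binary-outcome logistic prediction models
developed on data with missing covariate values. It combines internal
validation (bootstrap, subsampling, K-fold cross-validation) with
multiple imputation by chained equations, and corrects the resulting
estimates for optimism. This note records the models, the defaults, the
numerical choices, and what the synthetic-data generator does and does
not emulate.

## Data-generating model

The simulation engine draws an outcome `y_i ~ Bernoulli(frac)` i.i.d.
and covariates from a multivariate normal with unit variances and
exchangeable correlation `rho` within each covariate set (baseline and
additional sets are mutually uncorrelated). A common mean shift
`delta_mu` is added (+`delta_mu`/2 to cases, −`delta_mu`/2 to controls)
to every covariate of a set, so the outcome implicitly follows a
logistic model with coefficients `gamma = Sigma^{-1} dmu`. The shift is
solved numerically (Brent root finding, tolerance 1e−12) from

```
auc_target = Phi( 1/2 * sqrt( dmu' Sigma^{-1} dmu ) ),
```

the relation conventionally used to parameterize the separation. For
the two-set (added performance) case the baseline shift is solved on
the baseline block alone for `auc0`, then the additional shift is
solved, holding the baseline shift fixed, so the joint vector attains
`auc0 + delta_auc`.

**Parameterization note.** Under the class-shift construction the
realized AUC of the optimal linear score is the standard binormal value
`Phi(delta / sqrt(2))` with `delta = sqrt(dmu' Sigma^{-1} dmu)`, which
*exceeds* the solving relation's `Phi(delta / 2)` whenever the effect is
non-null (e.g. a nominal 0.74 realizes about 0.819). We therefore treat
`auc_target` as an effect-size label, not as the achievable AUC, and —
like every comparison in the package — evaluate estimates against
empirically computed truth (below), never against the nominal value.
Tests of the generator assert the mathematically correct realized AUC.

## Missingness mechanisms

Missingness is imposed per covariate on the covariates only (never the
outcome), by one of:

* **MCAR** — cells drawn uniformly at random.
* **MAR** — the masking probability of covariate `j` is
  `logistic(b0_j + b1_j * M_{i,j-1} + b2_j * x_{i,k_j} + 2 * y_i)`,
  where `M_{i,j-1}` is the realized missingness of the previous
  covariate (`b1_j` a fair ±1 coin for `j > 1`, 0 for the first),
  `x_{i,k_j}` a partner covariate chosen uniformly among the others
  (`b2_j = 2` for `j > 1`, dropped for the first covariate and when
  `p = 1`), and the outcome coefficient is fixed at 2. Covariates are
  processed in index order so the lagged mask is always defined.
* **MARblock** — covariates are assigned uniformly to three blocks; all
  covariates of a block share one partner covariate outside the block
  with coefficient 10 (plus the outcome term), producing blockwise-
  correlated missingness. If the random assignment leaves no covariate
  outside a block, one member is moved to the next block so a partner
  exists. Intercepts are re-solved per covariate after block
  assignment.

Each intercept `b0_j` is solved (bracketed Brent, 1e−12) so the *mean*
model probability equals the target proportion `miss`. Exactness: per
covariate, exactly `round(n * miss)` distinct cells (round half to
even) are masked, sampled without replacement with probabilities
proportional to the model probabilities. Sampling distinct cells
guarantees the advertised proportion exactly, which a multinomial draw
with replacement cannot. A configuration that would leave fewer than
two observed values in a covariate is rejected.

## Imputation

MICE with predictive mean matching, type-1 matching:

1. Per incomplete variable, the transformation (raw, natural log, cube
   root, square root; log/sqrt only where the domain allows) maximizing
   the Shapiro–Wilk statistic on the *observed* values is chosen once,
   before chaining. The chain runs on the transformed scale; because
   PMM donates observed values, the final inverse transform is
   lossless.
2. Initial fill: random draws from each variable's observed values.
3. Sweeps visit incomplete variables by increasing missingness count
   (ties by column index). Each variable is regressed on all other
   covariates (current working values) plus the outcome iff the
   strategy includes it. Coefficients: least squares; residual variance
   drawn from its scaled inverse-chi-square posterior; coefficient draw
   normal around the fit. Observed rows are scored with the
   point-estimate coefficients, missing rows with the drawn
   coefficients, and each missing entry copies the observed value of
   one donor drawn uniformly from the 5 closest predictions (donor ties
   broken by row index via a stable sort). Collinear normal equations
   fall back to a small ridge with a warning.

Defaults: `M = 5` imputations, 5 sweeps, 5 donors. With a single
incomplete variable one sweep is exact (the variable's own working
values never enter its predictor set), so further sweeps are elided.
Estimates across imputations are pooled by Rubin's rules: mean point
estimate; total variance = mean within-imputation variance +
(1 + 1/M) × between-imputation variance.

## Validation strategies and estimators

Resampling plans: bootstrap (`BS`, n draws with replacement, out-of-bag
complement as test set; a degenerate draw with empty complement is
redrawn), subsampling (`SS`, round(0.632 n) distinct training indices),
and simple/repeated K-fold CV (random permutation, contiguous chunks,
fold sizes within 1). No outcome stratification; splits are simple
random. Degenerate splits (single-class training outcome, or a test set
on which a measure is undefined) are skipped and counted; more than
20 % skipped is a hard error.

With `apparent` the fit-and-evaluate-on-original value, `oob` the mean
fit-on-resample/evaluate-on-test value, and resample-apparent and
resample-on-original averages analogous, the combiners are:

* ordinary optimism correction: `apparent − (traintrain − trainorig)`;
* 0.632: `0.368 apparent + 0.632 oob`;
* 0.632+: `(1−w) apparent + w oob`, `w = 0.632/(1 − 0.368 R)`,
  `R = (oob − apparent)/(noinfo − apparent)` clipped to [0, 1] so `w`
  stays in [0.632, 1]. The clip follows the original 0.632+
  construction; no truncation of `oob` at the no-information value is
  applied. No-information values: 0.5 for AUC, 0 for the added
  measures, and a 1000-permutation average for the Brier score.
  The calibration intercept/slope have no no-information value;
  they are reported as apparent and out-of-bag values only.
* CV strategies report the plain CV estimate (mean test performance per
  repetition, then across repetitions).

Estimators are applied to the averages pooled across all B×M
resample×imputation sets, not per split.

## Combining validation with imputation

* **Val-MI**: splits are drawn from the incomplete data; per split, the
  training part and the test part are imputed separately, each as a
  self-contained data set with the outcome included; train-imputation m
  is paired with test-imputation m (M pairs, not the M×M cross).
  Apparent performance averages fit-and-evaluate over M imputations of
  the full data. The ordinary optimism correction additionally needs an
  evaluate-on-original term, which on incomplete data we take on the
  m-th full-data imputed copy (the same copies defining apparent
  performance); the recommended 0.632+ estimate does not use this term.
* **MI-Val / MI(-y)-Val**: the full data are imputed M times (with /
  without the outcome); one shared resampling plan is applied to every
  completed copy, giving B×M sets. Sharing the plan across copies (the
  figure-level reading of "B·M sets") also makes every strategy
  collapse bit-identically to complete-data validation when the data
  have no missing values, which the test suite asserts.
* **MI / MI(-y)**: Rubin-pooled apparent performance, no validation.

Seed handling: one seed is split into named child streams (plan,
imputation, apparent-imputation, permutations) via NumPy's
`SeedSequence.spawn`, so every stage is independently reproducible and
the plan stream is shared across strategies.

## Confidence intervals

The modified percentile procedure centres a bootstrap interval of the
apparent performance at the 0.632+ estimate: with
`w_bm = theta(BS(b,m),BS(b,m)) − theta(Orig,Orig)` across the B×M sets
and `xi_q` the empirical quantiles of the `w_bm`, the 1−alpha interval
is `[theta_0.632+ − xi_{1−alpha/2}, theta_0.632+ − xi_{alpha/2}]`
(alpha = 0.05 by default; a warning is issued below 40 resamples).
Recommended settings: Val-MI with B=100, M=1; MI(-y)-Val with M=100,
B=1. For the no-validation strategies an analytic interval for the
(change in) AUC uses DeLong's placement-value variance per completed
copy, Rubin-pooled, with a normal approximation.

The sign convention of the interval follows the modified form as
printed in its source (both bounds subtract a quantile); for w
distributions symmetric about zero it coincides with the plain
percentile interval.

## Evaluation design

"True" performance of a configuration is the average of fitting the
logistic model on a fresh complete data set of the configured size and
evaluating on an independent complete data set of `n_test = 10,000` by
default (experiments at reduced scale use smaller test sets, stated per
experiment). Bias, variance and MSE of replicate estimates are taken
against this truth. The type-1/power experiment counts the fraction of
simulations whose CI lies entirely above the null value. The
variability experiment re-runs a strategy with fresh resampling/
imputation seeds and reports the run-to-run SD per (B, M); the SD of a
B-resample estimate follows `SD(theta_B) = SD(theta_1)/sqrt(B)`, which
the tests confirm at B ∈ {1, 4, 16} (observed ratios ≈ 2.1 and ≈ 4.0
against the theoretical 2 and 4 at the test's problem size). The
future-missingness experiment fits on complete data, imposes MCAR
missingness of increasing degree on a large independent test set,
imputes it *without* the outcome (mimicking application-stage data),
and reports the average measure over imputations; imputation uses the
test set alone as its basis.

## Problem sizes used in the shipped checks

The test suite and the acceptance script use desk-scale sizes chosen to
keep Monte-Carlo error well below the asserted margins: the CI
calibration check uses 200 simulated data sets of n=200 (binomial SE
≈ 1.5 percentage points around the nominal 5 %); the bias-ordering
check uses 100 replicates at n=200, p=10, MAR 25 % missingness with
B=10, M=5 (the variability plateau for simulation work); the
variability-law check uses 10 data sets × 10 runs at n=100, p=2.
Experiment functions accept larger replicate counts (the simulation
default is 250) for full-scale runs.

## Known limitations

* Only continuous covariates and logistic models; no survival
  outcomes, censoring, or time-dependent discrimination.
* No missingness in the outcome; MAR models are the specific logistic
  forms above, not arbitrary mechanisms, and real-data missingness
  patterns (beyond the block mechanism) are not mimicked.
* The generator's Gaussian, exchangeable-correlation covariates carry
  no skewness, outliers, nonlinearity or interactions — passing tests
  show correctness of the estimators under these conditions, not
  robustness of imputation models on messy real data (the
  transformation search only matters for non-Gaussian inputs and is
  exercised directly in unit tests).
* No variable selection or tuning inside the validation loop; the
  estimators assume the same model-fitting recipe on every resample.
* Percentile CIs assume the resample-apparent deviations track the
  sampling variability of the estimate; with very small B×M the
  quantiles are unstable (hence the 40-resample warning).
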