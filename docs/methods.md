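# Methods

## Problem

`lassoval` builds lasso-penalised linear prediction models on data completed
by multiple imputation, and estimates how optimistic their apparent
performance is.  The motivating setting is clinical prognosis: a continuous
patient-reported outcome, a few dozen candidate predictors, missing
covariate values, and a model that must generalise beyond the development
cohort.  The lasso shrinks coefficients and sets some exactly to zero, which
helps prediction and parsimony — but the penalty is tuned to the data at
hand, so the apparent mean squared error (MSE) is still optimistic, and the
model still needs internal validation.

## Model fitting

The fitted model minimises

    (1/2n) * sum_i (y_i - b0 - x_i' b)^2  +  lam * ||b||_1

with covariates standardised to unit (population) variance internally and an
unpenalised intercept; coefficients are reported back on the original scale.
The `1/2n` scaling matches the glmnet family of software, so penalty
magnitudes are comparable across sample sizes.  The path solver is a
Gram-based cyclic coordinate descent (numba-compiled) with warm starts down
a descending penalty grid; at p = 20 a full 40-value path costs tens of
microseconds, which is what makes the nested bootstrap experiments below
tractable on one core.  Its solutions are verified in the test suite against
scikit-learn's `Lasso` and against an independent convex-programming oracle
(bound-constrained positive/negative-part QP solved by L-BFGS-B) to 1e-6 in
objective value.

**Penalty grid.** The top of the grid is `lambda_max = max_j |x~_j'(y -
ybar)|/n`, the smallest penalty that zeroes every slope; the grid is
log-spaced over three decades below it, 40 values by default.

**Tuning.** For each penalty, models are fit on bootstrap resamples (with
replacement, same size; 100 by default) and scored by MSE on the rows each
resample left out (out-of-bag).  The same resamples are reused across the
whole grid, which removes between-penalty Monte-Carlo noise from the
profile.  The *best* penalty minimises the mean bootstrap MSE (ties break
toward the stronger penalty); the *tolerance* penalty is the strongest
penalty whose mean MSE is within 3% of that minimum — a deliberate trade of
a little accuracy for a sparser model.  Scoring on the full original sample
instead of out-of-bag is available (`scoring="original"`); it systematically
favours weaker penalties (the resample overlaps the scoring set) and is not
the default because the out-of-bag variant reproduces the selection
behaviour and penalty magnitudes this design is known for.

**Pooling over imputations.** With M completed data sets the penalty is
tuned and the model fit separately per set, and the final model averages
intercept and coefficient vectors element-wise, zeros included: a covariate
retained in only one of M = 10 sets keeps a tenth of its value.  Per-set
tuning shares one bootstrap index stream (indices depend only on the seed
and n), so M identical copies pool to exactly the single-set fit — a useful
degenerate-case identity that the tests assert.

## Performance and calibration

Discrimination is the MSE; for a pooled model the apparent MSE is the
average of its MSE over the M completed sets.  Calibration regresses the
observed outcome on the linear predictor, `y = a_LP + b_LP * LP`; slope
`b_LP` = 1 means perfect calibration, and `b_LP` > 1 — the typical lasso
outcome — means the predictions are over-shrunk.  A decile table of mean
predicted vs mean observed outcome is flagged against a ±0.5 band (a
minimal clinically important difference on the outcome scale).
Recalibration multiplies every slope by a uniform shrinkage factor s and
re-estimates the intercept by mean-matching (the OLS intercept with the
slope fixed at 1 on the rescaled predictor), averaged over the completed
sets.  Recalibrating with s equal to the fitted calibration slope restores
slope 1 on the same data to numerical precision.

## Internal validation

Expected optimism is estimated by the optimism bootstrap: repeat the entire
model-building process (grid, tuning, per-set fits, pooling) inside each of
B bootstrap resamples, record `apparent*` (the resampled model on its own
bootstrap data), `test*` (the same model on the original data), and
`optimism* = apparent* - test*`; the corrected performance is the original
apparent MSE minus the mean of the B optimism values.  The shrinkage factor
s is the mean over bootstraps of the slope from regressing the original
outcome on the bootstrap model's linear predictor.

With multiply imputed data the resampling step is ambiguous, and four
approaches are implemented:

1. one shared row-index vector applied to all M sets (samples differ only by
   imputed values);
2. an independent index vector per set;
3. resample one chosen set, exactly the no-missing-data procedure;
4. resample the *incomplete* data and re-impute M times inside every
   bootstrap, validating the imputation step itself.

Approach 2 averages M models built on effectively different subject sets,
which produces an artificially robust pooled model and collapses the
optimism estimate toward zero — the implementation reproduces this failure
mode, including on M identical copies of complete data.  Approach 4 is the
most faithful replay of the pipeline and the most expensive; its within-boot
imputation count defaults to the outer M.

Seed layout (stable, relied on by tests): the master seed opens a
`SeedSequence`; children serve the original fit and the bootstrap loop; each
bootstrap spawns, in order, the index draw, the model-building stream, and
the re-imputation stream.  With a single completed set, approaches 1-3
coincide bit-for-bit with the standalone no-MI procedure under the same
seed.

## Multiple imputation

Chained equations with the conventions: predictive mean matching for
continuous columns, logistic draws for binary columns, all other columns —
including the outcome — as predictors.  Each imputation runs on its own
substream, starts missing cells at random draws from the observed values,
and sweeps incomplete columns in order of increasing missingness for 5
cycles (configurable; the procedure stabilises quickly at these
missingness levels).  Linear sub-models are made approximately proper by
drawing the residual variance from its scaled inverse chi-square
distribution and the coefficients from the implied normal; PMM then matches
each perturbed prediction to the k = 5 observed cases with closest
unperturbed predictions and copies one donor's observed value, so imputed
continuous values always live on the observed support.  Logistic sub-models
are fit by a ridge-stabilised IRLS Newton solver (near-MLE at the default
tiny ridge; the ridge escalates under separation, with a warning, and the
parameter draw is then skipped); the fit matches a reference GLM to ~1e-4
on well-conditioned data.  An optional filter drops rows whose outcome was
itself imputed, for analyses where imputed outcomes would only add noise;
it is inert in the simulation study, where outcomes are complete.

## The synthetic cohort generator

The generator emulates a prognosis-like cohort: 20 standard-normal latent
covariates with eight nonzero pairwise correlations (e.g. R(1,5) = 0.72,
R(4,12) = -0.82, R(19,20) = 0.65); covariates 1-10 dichotomised — X1, X2,
X6, X7 at the 50th percentile, X3, X4, X8, X9 at the 30th, X5, X10 at the
20th; outcome `Y = 1.14 + X'b + eps` with `eps ~ N(0, 1.74)` (irreducible
MSE 3.0276) and ten truly nonzero coefficients (covariates 6-10 and 16-20,
|b| between 0.46 and 1.59).  Missingness is MCAR per cell: 20% on X2, X7,
X12, X17 and 50% on X3, X8, X13, X18; the outcome is never missing.

Two design points were genuinely open and were fixed as follows.
Dichotomisation uses the theoretical N(0,1) quantile rather than the
per-sample percentile, so training and external data share the same cut and
the generator is deterministic in distribution; and an indicator is 1 when
the latent value lies strictly above the threshold (the direction only
relabels the intercept).  "Percent missing" is read as independent per-cell
Bernoulli deletion at the stated rate.

What the generator does *not* emulate: real cohorts have
missing-at-random (not MCAR) structure, longitudinal covariates, skewed and
bounded outcomes, and imputation models that are misspecified in unknown
ways.  Passing tests on this generator show the estimators behave as
designed under a known truth; they do not certify behaviour under MAR
violations or model misspecification.

## Simulation experiments

Each replicate draws a training cohort (n = 250 or 1000), builds the best
and tolerance models (in the with-missing setting after M = 10 imputations),
and records apparent MSE, external MSE on a fresh complete cohort of the
same size, their difference (external optimism — the gold standard), the
internal optimism estimate per approach, calibration slope, shrinkage
factors, and per-covariate selection counts.  Selection summaries report
per-covariate frequencies and the rate of recovering all ten relevant
covariates simultaneously (in the with-missing setting a covariate counts as
selected when retained in at least half the imputed sets).  Summary tables
give the mean and empirical 2.5th/97.5th percentiles (linear interpolation
between order statistics) per quantity.

Full scale is 1000 replicates with 100/100 bootstraps and a 40-value grid.
The bundled desk-scale preset — and the problem sizes used by
`scripts/acceptance.py` and the statistical tests (200 no-missing and
36-100 with-missing replicates, 20-value grid, 20-30 bootstraps, m = 3-10)
— reduces those counts; all reductions are recorded in the run metadata.
One reduction deliberately not made: the near-zero-optimism behaviour of
approach 2 is an averaging-across-sets effect that scales with 1/M, so that
experiment keeps the full M = 10.

## Numerical choices and degenerate inputs

* Coordinate descent converges on a max-coefficient-change threshold of
  1e-12 (standardised scale); tested to 1e-6 objective agreement with the
  QP oracle.
* Zero-variance covariates keep coefficient 0; a constant outcome yields an
  intercept-only model; a constant linear predictor makes the calibration
  slope undefined and raises.
* Argmin ties in tuning break toward the stronger penalty; decile edges are
  sample quantiles with ties joining the lower bin.
* Out-of-bag scoring falls back to the full sample in the (vanishingly
  rare) event a resample covers every row.
* Non-finite bootstrap calibration slopes are excluded from s with a
  warning; an all-non-finite set raises.
* CSVs are written with `%.17g` and read with round-trip float parsing, so
  a write/read cycle is bit-exact.

## Known limitations

* MCAR only; no MAR/MNAR mechanisms, no multilevel imputation models for
  longitudinal covariates, and no ordinal-outcome variant.
* No group-lasso penalty for forcing a common selection across imputed
  sets; selection variability across sets is reported, not removed.
* The optimism bootstrap here is Harrell's simple variant; no .632+ or
  cross-validation alternatives.
* Significance testing between validation approaches is out of scope; the
  simulation reports means and percentile intervals only.
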