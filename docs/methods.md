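# Methods

## The problem

A clinical prediction model is derived in one setting and applied in
another, and the *same* predictor is often measured by different
procedures in the two settings — different devices, protocols, raters or
definitions.  `predhet` quantifies what such **measurement heterogeneity**
does to out-of-sample performance of an unpenalized logistic prediction
model, isolating it from the usual suspects (overfitting, case-mix shift):
derivation and validation samples are always drawn from the identical
population, at sample sizes where overfitting is negligible, and only the
measurement process differs.

## Measurement model and taxonomy

An exact measurement X and a pragmatic measurement W of the same predictor
are linked by the general linear measurement model, with parameters that
may depend on case status Y:

    W | Y=y = psi_y + theta_y * X + eps_y,   eps_y ~ N(0, sigma2_eps,y)

* **random (classical) error**: psi = 0, theta = 1, class-independent —
  W is mean-unbiased but noisy;
* **systematic error**: psi != 0 and/or theta != 1, identical for cases
  and noncases;
* **differential error**: any parameter differs between cases and
  noncases (e.g. recall bias, or closer scrutiny of suspected cases).

`MeasurementSpec` stores the six parameters (noise as *variances*);
`classify_spec` implements the taxonomy.  Error draws are independent
across predictors and observations; noise that scales with X, categorical
predictors and misclassification are out of scope.

## Data-generating mechanisms

Single-predictor population: `logit P(Y=1|X) = log(4) * X`, `X ~ N(0,1)`.
The intercept is 0, so the event rate is 50% (~1000 events per n = 2000
sample) and the concordance of X with Y is ~0.80.  Two-predictor
populations use equicorrelated standard-normal predictors with
rho in {0, 0.5, 0.9} and coefficients (2.3, 2.3) for rho <= 0.5,
(2.1, 2.1) for rho = 0.9, keeping discrimination comparable across rho.

## The transport experiment

Per replication: draw a derivation sample (n = 2000), apply the
derivation-setting measurement model, fit `logit(y) = alpha + beta' w` by
maximum likelihood; draw an independent validation sample from the same
population, apply the validation-setting measurement model, and evaluate
the **transported** linear predictor `lp = alpha_D + beta_D' w_V`.
Recorded measures:

* **c-statistic** — empirical concordance (ties half credit; equals ROC
  area), in-sample and at validation.  The binormal closed form
  `Phi((m1-m0)/sqrt(v1+v0))` and the induced change under a measurement
  model are available in `performance` for analytic reasoning.
* **calibration slope b** — from the ML recalibration fit
  `logit(y_V) = a + b*lp`; b < 1 means predictions too extreme
  (overfitting-like), b > 1 too moderate.
* **calibration-in-the-large** — intercept of an intercept-only logistic
  fit with lp as offset (a | b=1); negative when risk is systematically
  overestimated.  Stored on the logit scale; reports display it x10.
* **Brier score** with its exact pointwise decomposition
  `(y-p)^2 = (y-p)(1-2p) + p(1-p)` into calibration and refinement terms.

A model refit on the validation measurements (the *re-estimated* model)
is weakly calibrated by construction — slope 1, zero calibration term —
whatever the amount of measurement error; miscalibration at validation is
therefore a signature of *heterogeneity across settings*, not of error
per se.  `run_large_sample` reproduces this contrast at N = 10^6 for the
three transport settings (exact→pragmatic, re-estimated,
pragmatic→exact).

## Scenario grid

Full factorial over the validation measurement factors psi_V in
{0, 0.25}, theta_V in {0.5, 1, 2} and the noise levels sigma_eps(V),
sigma_eps(D) in {0.5, 1, 2}, with psi_D = 0, theta_D = 1 (derivation
measurements always follow the random-error model).  **The noise factor
levels are standard deviations**; they are squared into the
`MeasurementSpec` variances (0.25, 1, 4).  This yields 54 single-predictor
scenarios, 162 two-predictor scenarios with both predictors heterogeneous
(54 x 3 values of rho), 162 with one predictor measured consistently
across settings, and 54 differential-error scenarios: 432 in total.

The differential family crosses case-specific noise SDs
sigma_eps1(D), sigma_eps1(V) in {0.5, 1, 2} with psi_V and theta_V, at a
noncase noise SD fixed at 1.0 in both settings.  Its four headline cells
(psi_V = 0, theta_V = 1, one of sigma_eps1 in {0.5, 2} with the other
setting nondifferential) are exposed as named presets
(`differential_preset`).

Defaults: n = 2000 per sample, 10 000 replications per scenario for full
runs.  The bundled tests and the acceptance script use 1000 replications
per scenario, which keeps a full verification run under a few minutes on
one CPU while the Monte Carlo standard error of every summarised quantity
stays an order of magnitude below the differences of interest (e.g.
SE ~ 0.0004 for a mean c-statistic).

### Pooled overview rows

The single-predictor overview table groups the 54 cells into three blocks
by the ordering of derivation and validation noise
(sigma_D < sigma_V, equal, sigma_D > sigma_V).  Each displayed row pools
the three (sigma_D, sigma_V) pairs of its block: the row value is the
mean over pairs of the per-pair summary statistic (mean for c, CITL and
Brier; median for the slope) and the parenthesised spread is the
across-pair SD.  This is also the convention used for the reference
values reproduced in `tests/test_acceptance.py` and
`scripts/acceptance.py`.

## Aggregation and summaries

Within a scenario the slope is summarised by its **median** across
replications (its distribution is right-skewed, strongly so when the
validation measurements are much cleaner than the derivation ones); the
c-statistic, CITL and Brier score by their **means**; all with
across-replication SDs.  Replications whose ML fit or recalibration fit
fails to converge (separation) are excluded and counted, never redrawn —
redrawing would bias extreme-scenario summaries.  At n = 2000 with ~1000
events, exclusions do not occur in practice.

## Numerical choices

* Logistic fits use a damped Newton iteration (IRLS) on the full
  likelihood: at most 100 iterations, convergence when the relative
  log-likelihood change falls below 1e-10 (score equations then hold to
  well below 1e-8), step-halving to keep the iteration monotone.
  Separation is detected (fitted probabilities at the 0/1 boundary
  matching the outcomes) and flagged as non-convergence rather than
  raised.  The fit is cross-checked against `statsmodels.Logit` to 1e-6
  in the test suite.
* CITL uses a one-dimensional Newton iteration on the intercept with the
  linear predictor as a fixed offset (tolerance 1e-12).
* Ties in the concordance statistic receive half credit via mid-ranks,
  matching the ROC-area definition.
* Calibration curves use quantile bins (deciles by default) instead of a
  loess smoother: reproducible, parameter-free, and sufficient for
  diagnosing the slope patterns; bins that collapse under tied
  predictions are merged with a warning.
* Randomness: one root seed per scenario; per-replication generators are
  spawned from it (`numpy` `SeedSequence`), so any single replication can
  be reproduced in isolation and summaries are independent of execution
  order.

## What the generator does and does not emulate

The synthetic cohorts realise exactly the stated populations: normal
predictors, a correctly specified logistic outcome model, measurement
error that is linear, additive, normal and independent across predictors.
Real validation studies additionally face case-mix shift, model
misspecification, finite-sample overfitting, skewed or categorical
predictors and correlated error structures — none of which are simulated
here.  Passing tests therefore certify the measurement-heterogeneity
mechanism in isolation, not the full behaviour of any particular applied
validation study.

## Known limitations

* The binormal AUC formula is an approximation: under a logistic DGM the
  within-class predictor distributions are not exactly normal, so it
  overestimates the empirical concordance slightly (e.g. ~0.74 vs ~0.71
  at noise variance 1); the simulation pipeline always uses the empirical
  c-statistic.
* Performance is summarised per scenario; no confidence intervals are
  attached to single-validation metrics.
* Measurement-error *correction* methods are out of scope; the package
  quantifies the problem, it does not fix it.
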