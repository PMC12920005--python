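# Methods

## Setup and estimands

Observed data are i.i.d. draws of O = (W, A, Y): baseline covariates W,
a continuous exposure A, and an outcome Y. A binarization region 𝒜 (a
finite union of intervals with explicit open/closed endpoints) defines
T = 1{A ∈ 𝒜}. The package's convention for a single cut-off c is the
left-closed region [c, ∞), so an observation exactly at the cut-off is
treated; users who need the opposite convention (e.g. "within 1 km"
coded as untreated, boundary included) can pass explicit endpoint tags.

Binarization is given causal content through two truncation modified
treatment policies. Policy Ã₁ replaces the conditional exposure law by
its renormalization onto 𝒜:

    p̃₁(a | w) = 1{a ∈ 𝒜} p(a | w) / π(w),   π(w) = Pr(A ∈ 𝒜 | W = w),

and Ã₀ renormalizes onto 𝒜ᶜ. These are the unique policies confined to
their regions that preserve relative self-selection — the ratio
p(a|w)/p(a′|w) for any two allowed exposure values. Under

- positivity: 0 < π(w) < 1 for all w in the support of W, and
- conditional exchangeability: Y_a ⫫ A | W,

the binarized ATE equals the two-policy contrast,
ψ_BATE = E[Y_Ã₁] − E[Y_Ã₀] = E[μ(1, W)] − E[μ(0, W)] with
μ(t, w) = E[Y | T=t, W=w], and the attributable effect of binarization
is ψ_CAB(t) = E[Y_Ãₜ] − E[Y] = E[μ(t, W)] − E[Y]. The CAB needs only
the one-way positivity bound for its own direction (π(w) > 0 for t=1,
π(w) < 1 for t=0). Identification requires nothing about the density of
A beyond the distribution of T, which is why the estimators consume
only (W, T, Y); the `mtp` module exists for interpretation and
visualization and is deliberately unreachable from the estimators.

## Estimators

Let π̂(w) and μ̂(t, w) denote fitted nuisances, n the sample size, and
Ȳ the sample mean outcome.

- **Regression plug-in**: ψ̂ = mean[μ̂(1,W)] − mean[μ̂(0,W)] (BATE) or
  mean[μ̂(t,W)] − Ȳ (CAB).
- **IPW**: Horvitz–Thompson arm means mean[1{T=t} Y / π̂ₜ(W)] with
  π̂₁ = π̂, π̂₀ = 1 − π̂, or (default) Hajek arm means with weights
  normalized to sum to one within the arm. Hajek is the default because
  it is invariant to outcome location shifts, matching the CAB's
  differencing structure.
- **AIPW**: the one-step estimator, e.g. for CAB(1) the mean of
  T/π̂(W)·(Y − μ̂(1,W)) + μ̂(1,W) − Y. Doubly robust: consistent if
  either nuisance is.
- **TMLE**: Y is affinely rescaled to [0, 1] using the sample range
  widened by a relative guard band of 1e-6 (so in-range predictions stay
  strictly inside (0, 1) without distorting exact fits); each arm's
  outcome regression is fluctuated on the logit scale with the clever
  covariate 1{T=t}/π̂ₜ(W). The fluctuation coefficient solves the score
  equation Σ Hᵢ (Yᵢˢ − expit(logit μ̂ˢ + ε Hᵢ)) = 0, which is strictly
  monotone in ε and solved by bracketed root finding (xtol 1e-14); at
  the solution the empirical mean of the efficient influence curve is
  zero by construction. The E[Y] component of the CAB needs no
  targeting — its efficient estimator is the sample mean. A
  non-convergent fluctuation (separation-like degeneracy) falls back to
  AIPW with a warning.

The targeting is done **per arm** (ε₁ for μ(1,·), ε₀ for μ(0,·)) rather
than with a single shared coefficient. Both variants solve the EIF
equation; the per-arm form was chosen so that the algebraic identity
ψ_BATE = ψ_CAB(1) − ψ_CAB(0) holds *exactly* for TMLE, as it does for
the other three estimators (the Ȳ terms cancel). That identity, the
exact sign flip under region complementation, and the collapse of all
four estimators onto the brute-force stratified estimator under
saturated nuisances are enforced by tests at 1e-10.

## Variance and intervals

AIPW and TMLE report influence-curve SEs: the sample SD of the centered
per-unit EIF values over √n. These variance estimators are **not**
doubly robust — they are consistent only when both nuisances are — and
every report carries that caveat. For the regression plug-in the EIF is
evaluated at the fitted outcome model together with an internally fitted
default propensity (a documented approximation; the plug-in itself never
uses π̂). IPW uses the standard HT/Hajek linearization ICs treating π̂
as known, which is conservative when the propensity is estimated. The
nonparametric bootstrap (resample rows, re-fit nuisances, re-estimate;
percentile CI; failed replicates dropped and counted, >10% dropped is an
error) is the principled alternative for any method. Wald intervals use
normal quantiles.

Positivity is enforced per estimand before any weighting: BATE requires
all fitted propensities strictly inside (0, 1) (tolerance 1e-8); CAB(t)
requires only the t-side bound. Separation in logistic fits warns and
continues so the diagnostics, not the fitting routine, decide usability.
A mathematically empty region (π below 1e-12 in the law machinery) is a
distinct `PositivityError` — undefined conditioning rather than a
finite-sample overlap problem.

## Nuisance defaults

The default outcome spec includes the T×W interaction ("saturated"),
making the model genuinely saturated for discrete covariates; the
default propensity is logistic regression of T on W. Additive,
treatment-only, stratum (empirical proportions), marginal, patsy-formula
and plug-in learner specs are available. Cross-fitting is not
implemented: the parametric defaults are Donsker, and the benchmark
study does not use flexible learners. Missing data are rejected, never
imputed — imputation would silently change the estimand. Categorical
covariates are one-hot encoded at load time with the encoding recorded.

## Benchmark DGP and the replicate study

The synthetic generator draws

    W ~ Bernoulli(0.5),  A | W ~ Normal(5 + 2W, 1),
    Y = A³ + sin(A) + 100·W + Normal(0, 1),  T = 1{A ≥ 6},

a setting with strong confounding (W shifts both the exposure location
and the outcome level) and a smooth nonlinear dose-response. True values
are computed by adaptive quadrature (absolute tolerance 1e-10) of
E[a³ + sin a] under the truncated, complement-truncated, and untruncated
exposure laws per stratum:

    ψ_BATE = 202.2985,  ψ_CAB(1) = 89.9585,  ψ_CAB(0) = −112.3400.

A 10⁷-draw Monte Carlo oracle agrees within Monte Carlo error (tested).
The replicate study draws 5,000 samples at n ∈ {150, 300, 500},
binarizes at the cut-off, fits the saturated outcome model and logistic
propensity once per replicate, and evaluates every requested estimator
and estimand on the shared fits. Replicate RNG substreams are keyed by
(master seed, sample size, replicate index), so results are invariant to
the set of methods requested and to evaluation order. Summaries report
the replicate mean, the mean estimated SD, the empirical SD across
replicates, and raw and relative bias against the quadrature truth
(formula stated in the CSV header). These sizes run in about a minute on
one CPU; TMLE can be added as a fourth method.

What the generator emulates — confounded selection into the treated
region, nonlinear outcome surfaces, exact overlap — and what it does
not: continuous or high-dimensional covariates (the saturated default
is only saturated for discrete W), heteroscedastic or heavy-tailed
noise, measurement error in A, and informative missingness. Passing the
study therefore demonstrates correctness of the estimators and their
sampling behavior under ideal parametric nuisances, not robustness to
real-data model misspecification beyond the single-nuisance
misspecification checks in the test suite (outcome model without the
interaction, or propensity collapsed to the marginal rate, at n = 10⁵).

## Numerical choices and edge cases

- Continuous-law normalizers integrate the density over the region
  clipped to the law's integration range (location-scale laws default to
  mean ± 10 SD), quadrature tolerances 1e-12.
- Region endpoints are honored exactly; complements flip open/closed
  tags so membership is a partition of the real line.
- A constant outcome yields zero contrasts and zero SEs for every
  method; a constant treatment degenerates the propensity with a
  warning, and a CAB(t) request when all units already have T = t
  returns exactly 0, flagged as degenerate rather than raised.
- Propensity clipping is available but off by default; clipped counts
  are reported in the overlap diagnostics.

## Known limitations

Binary treatments only (no multi-level coarsening); single time point;
no effect modification / CATE machinery; no density-based estimation for
general MTPs (shift interventions are out of scope by design); IC-based
SEs for regression and IPW are approximations as documented above, with
the bootstrap as the recommended alternative when they matter.
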