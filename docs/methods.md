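# Methods

This note documents the model, the conventions the implementation fixes
where the underlying study design leaves choices open, and what the
synthetic-data tests do and do not establish.

## Model and likelihood

The outcome model is a linear mixed growth curve on cohort-sequential
data: a person-level intercept, linear age slope and (fixed-only)
orthogonalised quadratic age slope, each regressed on birth cohort
(linear, calendar years), education (years), sex (0 = male, 1 = female)
and their two- and three-way interactions, plus a main effect of sample
membership in the intercept block only (a proxy for test-retest
experience — two persons of the same age and cohort in different samples
differ only in testing history).  That yields 25 fixed effects; the
random part is a bivariate normal person-level intercept/linear-slope
deviation (SDs σ_u0, σ_u1, correlation ρ) plus an occasion-level residual
σ_e.  Identification rests on the usual no-period-effects assumption of
age-cohort models, and missingness is assumed ignorable (observed rows
enter the likelihood; nothing is imputed or deleted listwise).

The random effects are integrated out analytically: for person *i* with
k_i observed occasions, y_i ~ N(X_i γ, Z_i Σ_u Z_i' + σ_e² I) with
Z_i = (1, age_lin).  The implementation evaluates this with the Woodbury
identity and the matrix determinant lemma, batched over persons grouped
by k_i, and is verified against (a) a dense per-person reference
implementation and (b) 2-D Gauss-Hermite quadrature over (u0, u1) on a
small fixture (agreement ≤ 1e-6; 201 nodes per dimension are needed
because the per-person likelihood is much narrower than the
random-effects prior that supplies the quadrature weight).

## Priors

Normal(50, 20) on the intercept (T-score scale), Normal(0, 3) on every
other regression coefficient, half-Cauchy(0, 10) on σ_u0, σ_u1 and σ_e,
LKJ(1) — flat — on ρ.  The residual-scale prior is an assumption: the
source protocol specifies half-Cauchy(0, 10) for the random-effect scales
and we apply the same family to σ_e.  The focal education-by-slope
coefficient optionally receives a Normal(0, σ) prior; σ ranges over
{1, 2, 4} × |literature base effect| (0.002 visuospatial, 0.004 semantic,
0.017 episodic memory, T-units of annual change per year of education),
which simultaneously serves as the prior-sensitivity analysis.

## Sampler

Sampling exploits partial conjugacy.  Each scan:

1. draws the 25 regression coefficients exactly from their multivariate
   normal conditional posterior given the variance components (GLS
   precision plus diagonal prior precision, Cholesky solve);
2. updates the variance block (log σ_u0, log σ_u1, atanh ρ, log σ_e) with
   5 adaptive random-walk Metropolis sub-steps; the Jacobians of the
   unconstrained reparameterisation are included, so the invariant
   distribution is exactly the constrained-space posterior.

The proposal covariance follows a Haario-style empirical-covariance
recursion with a Robbins-Monro global scale tuned toward 30% acceptance;
adaptation runs during warmup only and is frozen afterwards, so the
post-warmup chain is a valid Markov chain for the exact target.  Defaults
mirror the analysis protocol: 4 chains × 2,000 post-warmup draws with an
equal warmup ("2,000 samples" is read as post-warmup draws).  Chains are
initialised from a ridge fit with per-chain overdispersed jitter.
Convergence is monitored with the split-chain Gelman-Rubin R̂ (threshold
1.01); degenerate chains with zero total variance return R̂ = 1.0 by
convention rather than 0/0.  Marginal summaries: posterior mean, MAP as
the mode of a Gaussian KDE (Silverman bandwidth, 512-point grid over the
draw range), and the 95% highest-density interval as the shortest
contiguous interval of the pooled sorted draws.

With no data the sampler reproduces the prior (the coefficient draw is
then an exact prior draw; the variance block targets the prior density),
which the tests use as a distributional check.

## Savage-Dickey Bayes factors

BF01 is the marginal posterior density of the focal coefficient at zero
divided by its prior density at zero, valid only when the posterior was
sampled under that same focal prior — the code enforces the match via fit
metadata and refits the model once per prior width (prior re-weighting of
a single fit is deliberately not the default).  The headline density
estimator is the Silverman-bandwidth Gaussian KDE on the pooled chains; a
moment-matched normal approximation is always computed alongside and a
discrepancy above 25% triggers a warning.  Pointwise KDE estimates carry
both smoothing bias and MC noise of a few percent at 10^4–10^5 draws;
the conjugate-model validation therefore uses 2.4 × 10^5 pooled draws,
where the ratio agrees with the closed form to well within 5%.

## Synthetic cohort generator

The generator emulates the motivating design: 5-year birth-cohort bands
(midpoints 1909–1959), two samples entering at consecutive waves (S1 at
wave 0, S3 at wave 1), five waves at 5-year spacing (1989–2009), ~100
persons per sample × cohort cell, 54% female, education drawn once per
person from a rounded truncated Normal(10.2, 3) (the education SD is a
realistic placeholder; the source reports only the mean), and monotone
MCAR dropout with a configurable per-wave hazard (default 0.15; dropout
after entry follows a geometric survival curve).  Age is integer
test-year minus birth-year; an optional ±2-year jitter flag exists and is
off by default.  Outcomes are produced by the Level-1/Level-2 model above
with configurable truth; the default truth profiles are the published MAP
estimates of the three outcomes, with episodic memory as the default.

Two conventions matter for interpreting recovered parameters:

* **Orthogonal quadratic scale.**  The quadratic age term is the raw
  residual of centred-age² after projection on {1, age_lin} over all
  retained person-period rows pooled, not rescaled.  Whether the original
  analysis rescaled its quadratic term is unknown; under the raw
  convention, quadratic coefficients of the published magnitude produce
  synthetic cross-sections substantially wider than 10 T-units.
* **Re-standardisation.**  Preparation T-standardises outcomes against
  the first measurement occasion, an affine map that transforms the
  generating truth exactly: every coefficient and SD scales by
  b = 10/baseline-SD, the intercept also shifts, ρ is unchanged
  (`rescale_truth`).  All recovery and coverage checks compare posteriors
  against this exactly transformed truth, so the generator/preparation
  round-trip is bit-exact for noise-free data even under dropout (the
  generator computes its covariate basis on the rows it actually emits,
  and preparation with `recompute_centers_from_data=True` rebuilds the
  identical basis).

What the generator does *not* emulate: non-ignorable (outcome-dependent)
dropout is available only as an optional robustness device and is off by
default; practice/retest effects beyond a sample main effect; floor and
ceiling effects, integer score supports, and measurement non-invariance
of the real tests; period effects.  Passing tests therefore demonstrate
that the estimation and testing machinery is correct and calibrated under
the model's own assumptions — not that those assumptions hold in any real
cohort.

## Preparation conventions

Exclusions, applied per person in fixed order with each person counted
once: (a) excluded birth bands (defaults: earliest 1908–1910 and latest
1958–1960 cells), (b) education missing at every wave, (c) derived
education above 25 years, (d) below the minimum (default 6 years, a proxy
for "less than compulsory schooling", configurable).  Person-level
education is the maximum self-report across waves.  T-standardisation
uses the population SD (ddof = 0) of the first occasion; the choice is
arbitrary but fixed so tests can be exact.  Centering constants default
to the published values (62.9 / 1933 / 10.2) and can be recomputed from
the data at hand, which is the right choice for arbitrary synthetic
designs.  Sample coding: S1 → 0, S3 → 1.

## Problem sizes and numerical choices

The validation suite runs at desk scale: recovery, power and geometry
checks use 400 synthetic persons (4 cohorts × 2 samples × 50, ~1,450
observations after 10% dropout), the replicated null-direction runs use
240 persons, and replicate fits use 4 × 500 draws while the headline
convergence fit uses the full 4 × 2,000 protocol.  Interval-coverage
calibration is assessed over 20 replicates × 25 fixed effects.  Numerical
tie-breaks: zero-variance draw vectors short-circuit MAP/HDI to the
degenerate point; a non-positive-definite implied covariance raises with
diagnostics in the reference likelihood and yields log-density −inf in
the sampler; HDI mass and KDE conventions are as above.

## Known limitations

* The variance block mixes by random-walk Metropolis; near-boundary
  scale parameters (σ_u1 close to zero) have heavy log-scale tails and
  need the full 2,000-draw protocol for R̂ < 1.01 — short exploratory
  fits may show R̂ ≈ 1.02 on σ_u1 without invalidating the fixed-effect
  summaries.
* One refit per prior width makes the sensitivity analysis cost scale
  with the grid size.
* Bayes factors are computed for the focal education-by-slope parameter
  only; the cohort-by-education interaction is reported by interval
  estimation, and no WAIC/LOO model comparison is provided.
* The KDE density-at-zero estimator has a few-percent bias/noise floor;
  the normal approximation is reported alongside as a diagnostic.
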