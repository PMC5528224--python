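# Methods

This note documents the models, estimators, numerical choices and
known limitations of `selstrength`.

## Selection models and the RSS

Models are linear predictors over *terms*: transformed covariates
(identity, natural log, square) and pairwise products of transformed
covariates (e.g. `log(dist)*forest`). Two link forms are supported:

- **Exponential RSF** `w(x) = exp(Σ βᵢ tᵢ(h))`. Under used-available
  sampling the intercept (normalising constant) is non-identifiable; it
  is carried when present but never enters `evaluate_w` or any RSS.
- **Logistic RSPF** `w(x) = expit(β₀ + Σ βᵢ tᵢ(h))`, an absolute
  selection probability; the intercept is a real parameter and is
  required.

`log_rss(model, x1, x2) = ln w(x1) − ln w(x2)` is defined for both
forms (computed via `log_expit` for the logistic form for stability).
The argument order reads "selection for x1 relative to x2". For the
exponential form it reduces exactly to the difference of linear
predictors, which makes it independent of any intercept; the identity
`log_rss(x1,x2) + log_rss(x2,x3) = log_rss(x1,x3)` holds to floating
point (tests assert 1e-10 absolute).

The seven closed forms in `closed_form_log_rss` are algebraic
consequences of the exponential linear predictor (linear, interaction,
quadratic, quadratic+interaction, log, log+interaction, log–log). They
are rejected for logistic models, where they do not hold. Log cases
require positive covariate values at both locations and express the RSS
through the *ratio* of habitat values.

## Estimators

All three estimators report SEs from the inverse observed information,
Wald `z = estimate/SE`, two-sided normal p-values (unadjusted), the
maximised log-likelihood and `AIC = 2k − 2ℓ` with `k` the number of
estimated parameters.

**Used-available binomial GLM** (`fit_rsf_logistic`). The standard
computational trick: a binomial GLM with logistic link, fitted by IRLS
(statsmodels), of the used indicator on the expanded design matrix.
The slopes are consistent for the exponential-RSF coefficients because
the used and available samples differ by an exponential tilt, which is
exactly a linear log density ratio; the intercept absorbs the sampling
fractions and is flagged non-identifiable and excluded from the
parameter table. The coefficients are *not* interpreted as odds ratios:
they are log-RSS per unit of habitat. Rank deficiency is detected with
a pivoted QR on the normalised design and reported with the offending
term names; standardised coefficients exceeding 15 in absolute value
set a quasi-separation warning flag (beyond that bound the binomial
likelihood is flat to machine precision).

**Weighted-distribution maximum likelihood** (`fit_weighted_ml`). The
availability points are treated as an i.i.d. sample from the
availability distribution and the used points as draws tilted by the
selection function, giving

    ℓ(θ) = Σ_used ln w(xᵢ) − n_used · ln( mean_avail w(xⱼ) ).

For the exponential form the intercept cancels and is not estimated;
for the logistic RSPF the intercept is identifiable through the
saturation of the expit. Optimisation is quasi-Newton (L-BFGS-B) from
zero with the analytic gradient; the availability term is computed with
`logsumexp` (exponential) or `log_expit`/`expit` (logistic), which
keeps the objective and gradient finite without explicit clipping of
the linear predictor. The observed information is obtained by central
finite differences of the analytic gradient (step `1e-5·(1+|θᵢ|)`).
AIC values from two such fits on the same data are mutually comparable;
this is the package's only cross-family comparison (exponential RSF vs
logistic RSPF).

**Conditional logistic regression** (`fit_conditional_logistic`). For
stratified (case-control / step-selection) data with exactly one used
row per stratum, Newton–Raphson with step-halving maximises
`Σ_s [η_used − ln Σ_{j∈s} exp(ηⱼ)]` (no intercept; it cancels within
strata). Convergence: relative log-likelihood change < 1e-10 or
gradient ∞-norm < 1e-8, at most 100 iterations; the log-likelihood path
is recorded and is non-decreasing by construction. Covariates with no
within-stratum variation are rejected before iteration with an
"inestimable" error. The implementation is cross-checked in the test
suite against statsmodels' `ConditionalLogit` and against brute-force
grid search.

## Average-effect and preference curves

The average-effect construction: evaluate the fitted `w` at every
available location, pair it with the focal covariate's value there, and
smooth the scatter with a Nadaraya–Watson regression over an equally
spaced grid spanning the observed focal range. The result is the
average fitted selection weight at each focal value, averaged over the
availability distribution of the other covariates — a *probability of
use* (absolute for the logistic RSPF, relative for the exponential RSF,
marked by the curve's `relative` flag), not a probability of selection.
Because availability enters the average, the curve changes when the
study area changes even at fixed coefficients; the test suite asserts
this contrast explicitly.

Smoothing follows the `ksmooth` convention so curves are comparable
with that smoother: kernels are scaled so their quartiles sit at
±0.25·bandwidth (normal kernel sd = 0.3706506·bandwidth; box kernel
half-width 0.5·bandwidth). Defaults: normal kernel, bandwidth
0.2 × focal range, 100 grid points with endpoints included. Grid points
with an empty box-kernel window return NaN with a warning, never a
silent zero. A running-quantile statistic (`statistic="quantile"`,
sliding window of one bandwidth) provides percentile-effect curves.

Confidence bands are nonparametric bootstrap percentile envelopes over
availability rows (default), or optionally draws of the coefficient
vector from the fit's asymptotic normal (`method="beta"`, requires a
`FitResult`). Percentile envelopes are clamped so
`lower ≤ estimate ≤ upper` holds at every grid point. Bands are
pointwise, not simultaneous.

Preference curves impose a uniform availability distribution on
resource *types*: each model covariate gets a uniform grid over a
user-supplied range (full factorial when the grid has ≤ 1e6 points,
otherwise a seeded uniform Monte Carlo sample), making use and
selection coincide; a single-covariate preference curve therefore
reproduces the selection function itself up to smoothing bias.

## Rasters, RSS maps and utilization distributions

Rasters are ESRI ASCII grids (row 0 at top, row-major, NODATA held as
NaN in memory and round-tripped bitwise through the writer).
`rss_map` evaluates `RSS(pixel, reference)` for exponential models;
the conventional habitat-selection map is the special case of an
all-zero reference, and a "typical" reference (per-layer median)
rescales the whole map by one constant. For maps derived from
conditional-logistic fits the pixel value is the RSS of a step ending
at that pixel relative to an identical step ending at the reference
pixel — less intuitive than the unconditional map, and noted here
rather than enforced in code.

Movement is a first-order Markov chain on active pixels:
`P(i→j) ∝ w(xⱼ)·φ(d_ij)` for centre-to-centre Euclidean distance
`d_ij` within the kernel radius (uniform or exponential-decay disc),
zero beyond; self-transitions are included (d=0), which guarantees
aperiodicity. The kernel is truncated at the raster edge — no
wrapping — as the simplest defensible boundary convention. Explicit
transition matrices are guarded at 10,000 active pixels; beyond that
`monte_carlo_ud` is the intended route. `stationary_distribution`
checks strong connectivity, then power-iterates from uniform until the
∞-norm change is below 1e-12. `monte_carlo_ud` simulates seeded
trajectories and returns post-burn-in visit frequencies; on small
rasters it is tested against the exact stationary distribution (total
variation < 0.02 at 200,000 steps). Higher-order movement (velocity
autocorrelation) is explicitly unsupported.

## Synthetic data

The generators emulate a telemetry study design of roughly 5,700 used
and 13,700 available points with two covariates — a habitat-suitability
index in (0,1) and distance to road in km, truncated at 3 — plus their
interaction. Ground-truth coefficient sets of the magnitude reported in
elk road-avoidance analyses are provided (`elk_rsf_truth`,
`elk_rspf_truth`) for recovery experiments.

Two study-area recipes:

- `hypothetical_study_area`: suitability ~ Uniform(0,1) and road
  distance ~ Exponential(mean 1 km) truncated at 3 km, independent.
  The truncated exponential is sampled by inversion,
  `h = −μ·ln(1 − u·(1 − e^(−upper/μ)))`; its analytic mean
  (0.8428 for μ=1, upper 3) anchors the generator tests.
- `roadside_study_area`: availability concentrated near roads (road
  distance ~ truncated Exponential, mean 0.6 km) with suitability
  improving away from the road (`suitability = u^(1/(1+d))`, mean
  rising from 0.5 at the road to 0.8 at 3 km). The positive
  suitability–distance association emulates a disturbed roadside
  landscape; it is what makes average-effect curves steeper in road
  distance here than in the hypothetical area at identical
  coefficients. With independent covariates the curve shape would not
  depend on the availability marginal of the focal covariate at all, so
  some cross-covariate dependence is required to exhibit the contrast.

Used points are generated according to each form's semantics:
weighted resampling proportional to `w` for the exponential RSF
(relative semantics), Bernoulli thinning at probability `expit(η)` for
the logistic RSPF (absolute semantics). For recovery experiments the
used points are drawn from a separate 50,000-point draw of the same
availability distribution (the `pool` argument) rather than from the
13,652 availability rows themselves, so used rows are not literal
duplicates of available rows; this mirrors real telemetry, where animal
locations are not a subset of the availability sample.

Step-selection tracks are simulated on rasters with the same
`w·φ` transition rule; case-control tables sample available steps from
the movement kernel φ alone (selection-free), keeping the conditional
likelihood correctly specified. Available steps are drawn from the
stated kernel rather than from the empirical step-length distribution,
which keeps the generator self-contained.

What the generators do *not* emulate: spatial autocorrelation of
covariates, multi-animal dependence, observation error or irregular fix
intervals, and any functional response of selection to availability.
Passing recovery tests therefore demonstrates estimator correctness
under a correctly specified model, not robustness to these real-data
features.

## Problem sizes and tolerances used in the checks

Closed-form/oracle agreement is asserted to 1e-10 absolute over 10,000
random models per case. Recovery experiments use 100 replicates at the
full design size (5,686/13,652) and require all parameters within 3
estimated SEs in ≥ 95 of them; the AIC-direction experiment uses 50
replicates. Toy-table fitter checks agree with brute-force grid or
simplex maximisation to 1e-3 (1e-6 where the oracle is polished). The
Monte Carlo UD check uses a 5×5 raster and 200,000 steps against the
exact steady state. Identity checks use 1e-10–1e-12 absolute
tolerances.

## Known limitations

- No mixed-effects or random-coefficient selection models, no robust /
  clustered SEs, no model selection beyond AIC reporting.
- No spline/GAM smoothers and no simultaneous confidence bands for
  effect curves.
- No GeoTIFF or projection support; rasters are plain ASCII grids.
- Movement kernels are fixed and user-supplied; estimating the
  movement kernel jointly with selection (integrated step-selection)
  is out of scope.
- Cross-family AIC comparisons are only meaningful between two
  `fit_weighted_ml` fits on the same data, and the package only
  performs them there.
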