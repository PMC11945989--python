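# Methods

## Model

The daily outcome count `Y_t` is modelled on the log scale as

    ln Y_t = μ + λ(t) + S(t) + Σ_{j=1..p} g_j(Σ_{τ=0..L_j} θ_{j,τ} X_{j,t−τ}) + ε_t,

with Gaussian errors ε_t. The components and their identification:

- **Baseline μ.** Expectation of the log count on the default day with zero
  cumulative effects. Identification requires fixing the location of each
  g_j; we centre every fitted g_j to mean zero over the used sample each
  sweep and absorb the offset into μ. (The alternative g_j(0) = 0 would tie
  the location to an unobserved zero-exposure point.)
- **Weekly effect S(t).** Six indicator coefficients α₁..α₆; the default
  day (Friday by default) carries exactly zero. Non-default days are
  indexed in week order starting the day after the default day
  (Saturday..Thursday); the mapping is a convention and configurable.
- **Growth curve λ(t).** Zero up to the intervention window's start,
  `ξ1 + ξ3/(1 + exp(−ξ2(τ − ξ4)))` from its end, with τ = days since the
  window's end. Counting τ from the window's end (rather than the series
  origin) keeps ξ4 on an interpretable "days after reopening" scale. Rows
  strictly inside the open window are excluded from fitting entirely, as is
  any row whose lag history would cross the window or the series start, so
  no lag window straddles the excluded period.
- **Cumulative effects.** Lag weights θ_j lie on the *ordered simplex*
  {θ ≥ 0, non-increasing, Σθ = 1}: the sum constraint identifies the scale
  of g_j, the ordering encodes that more recent exposure never matters less.
  The ordering/non-negativity/sum constraints apply to every covariate;
  monotonicity (non-decreasing g_j) applies only to pollutant-like
  covariates — weather curves (humidity, temperature) are typically
  U-shaped and are left unconstrained.

## Estimation

**Index transform.** For a block with lag order d the index v = θᵀX is
mapped to u = F_d(v) ∈ [0, 1], where F_d is the CDF of the symmetric
Beta{(d+1)/2, (d+1)/2} law rescaled to [−a, a], computed with the
regularized incomplete beta function. The scale a is the 95th percentile
(nearest-rank) of the per-row sup norms max(|X_t|, …, |X_{t−L}|); it
depends on the block only, not on θ. Index values beyond ±a (possible
since a is a percentile, not a maximum) are clamped to the boundary.

**Spline.** Cubic B-splines (order 4) with N = max(⌊n^{1/5.5}⌋, 5)
interior knots placed at the j/(N+1) nearest-rank quantiles of the
transformed index, so each inter-knot segment holds roughly equal sample
mass. Duplicate or boundary-coincident knots (heavy ties) are collapsed
with a logged warning. A non-decreasing curve is imposed through
non-decreasing spline coefficients — a sufficient condition — estimated by
exact restricted least squares: coefficients are reparametrised as a level
plus non-negative increments, the level is profiled out (the basis is a
partition of unity, so the level column is constant) and the increments
solved by NNLS. Unconstrained blocks use ordinary least squares with a
tiny-ridge fallback (1e−8 on the normal equations, logged) for
rank-deficient designs caused by clamping ties.

**Weights.** Given the spline, θ is updated by projected gradient descent:
the analytic gradient of the residual sum of squares flows through the
fixed spline and the transform's density, the step is halved (Armijo-style,
up to 30 times from 1/‖grad‖) and the candidate is projected onto the
ordered simplex. Projection is exact: for a fixed sum-constraint
multiplier the solution is the clipped decreasing isotonic regression
(PAVA) of the shifted point, and the multiplier is found by bisection.
After every accepted θ step the knots are refreshed (the index
distribution changed) and the spline refitted; a candidate is accepted
only if the fully refreshed RSS decreases, so the block objective is
monotone non-increasing. Inner θ iterations are capped at 50 per call;
relative-RSS tolerance 1e−6.

**Backfitting.** Phase one fits (μ, α, ξ) by least squares on the log
outcome, then initialises the blocks sequentially on partial residuals.
Phase two cycles: (i) refit the parametric part on the outcome minus all
cumulative effects — ξ1, ξ3 enter linearly given (ξ2, ξ4), so the linear
part is profiled by OLS and (ξ2, ξ4) found by a multi-start grid plus
Nelder–Mead refinement, warm-started from the previous iterate;
(ii) re-estimate each block on the partial residuals of all other
components, warm-started from its previous weights. Because every step is
a coordinate-descent refit against the current partial residuals (the
previous component value is always feasible for the refit), the overall
RSS is monotone non-increasing across cycles; convergence is declared at
relative RSS change < 1e−6 (cap 100 cycles). When no post-window rows
exist, or the logistic shift adds nothing over the weekly-only fit, ξ is
fixed at zero effect with a warning. Counts of zero are rejected at load
time (the log transform requires positive counts); an optional +0.5
offset is available but off by default.

## Lag selection

AIC at fixed sample size reduces to log MSE + 2m/n with
m = 1 + 6 + 4 + Σ_j L_j (constant, weekly, growth curve, free weights per
block after the sum constraint; spline coefficient counts are fixed across
lag candidates and cancel). The search scans a common lag over the grid
{1, 1+l, …, K} (defaults l = 10, K = 200), then refines one coordinate at
a time over ±d windows (default d = 5) until a full cycle changes nothing.
All candidate fits share one row sample trimmed by the global bound K so
their AICs are comparable; ties break toward smaller lags; repeated lag
vectors are memoised. Search fits use reduced iteration caps (12 backfit
cycles) — AIC ranking stabilises long before full convergence — and the
selected model is refit at full settings on the maximal usable sample.

## Bootstrap

Residual i.i.d. bootstrap on the log scale: ε* resampled with replacement
from the fitted residuals, Y* = fitted + ε*, and the model refit with the
lags held at the point estimate, warm-started from the point fit
(15-cycle cap). A moving-block variant is available behind a flag for
autocorrelated residuals, off by default. Bounds are percentile-method
nearest-rank quantiles, reported with the draw standard deviations; curve
bands are pointwise on a fixed index grid (simultaneous bands are not
implemented). Replicates whose refit fails are dropped and counted; more
than 20% dropped is an error. All intervals are deterministic given the
seed.

## Synthetic data

The generator emulates the structure the model assumes: pollutant-like
exposures are lognormal AR(1) series (marginal mean/SD matched, lag-1
correlation ρ), weather-like exposures Gaussian AR(1) clipped at a small
positive floor; lag weights decay geometrically (ratio 0.6) renormalised
onto the ordered simplex; pollutant effect curves saturate
(amplitude·(1 − e^{−v/scale}), levelling after moderate cumulative
exposure) while the weather curve is a quadratic U; weekly effects are
0.07–0.24, the growth curve (−0.6, 0.01, 0.75, 200) and μ = 4.6 echo the
scale of published estimates for this model class; noise is Gaussian on
the log scale (default sd 0.05) and counts are the rounded exponential
(rounding adds mild heteroscedasticity; a flag disables it for
exact-recovery tests). The default study has n = 1500 days, two
pollutant-like and one weather-like covariate with true lags (6, 4, 3),
and a 107-day excluded window at 45% of the series. Every component
series, the centring offsets and the realised noise are stored so each
estimation stage can be scored against truth.

What the generator does *not* emulate: seasonal cycles and long-term
trends, covariate cross-correlation (real pollutants co-vary strongly),
measurement error in exposures, overdispersed or autocorrelated count
noise, and missing data. Passing recovery tests therefore demonstrates
correctness of the estimator under its own assumptions, not robustness to
real-data violations of them.

## Problem sizes and numerical behaviour

Tests and the acceptance script use the default n = 1500 study for
recovery (20 replicates), n = 600–800 single/double-block studies for
descent and lag-search checks (search grid l = 2, K = 20, d = 3), and an
n = 400 single-block study for bootstrap coverage (B = 200, 50 outer
replicates) — sizes chosen to exercise every code path at desk scale.

A known approximation floor: with the knot rule fixing N = 5 at these
sample sizes, a noise-free fit of the default study converges to MSE
≈ 6e−4 rather than machine zero. Two mechanisms, both inherent to the
method's primitives, set this floor. First, index values beyond the 95th
percentile scale a are clamped to u = 1, so all exposure variation in the
top tail maps to a single spline value; for a weather curve that keeps
rising quadratically in the tail this leaves an irreducible residual on
the clamped rows. Second, near u = 1 the inverse Beta transform has
unbounded derivative (its density vanishes at the boundary), so the
composite g∘F⁻¹ has unbounded curvature there and a cubic spline with few
knots cannot track it exactly. Saturating (pollutant-like) curves are
immune to both effects — their noiseless approximation error is ~1e−7 —
so the floor is driven entirely by the U-shaped weather block.

Other numerical choices: nearest-rank (type-1) empirical quantiles are
used everywhere a percentile is needed (index scale, knot placement,
bootstrap bounds); AIC ties break toward smaller lags; the lag search's
fixed trimming keeps n constant across candidates; all randomness flows
from a single root seed split deterministically per component.

## Limitations

- Gaussian least squares on log counts, not a count likelihood
  (Poisson/negative-binomial are out of scope).
- The lag search is a local coordinate descent; it is not guaranteed to
  find the global AIC optimum on the lag lattice.
- Bootstrap bands are pointwise percentile intervals; no asymptotic
  standard errors.
- Within each backfitting sweep, blocks are iterated to their own
  tolerance; single-step block updates would also converge and can be
  cheaper, but the per-sweep order of updates then matters more.
- No seasonal terms, interactions, or variable selection.
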