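# Methods

## The movement model

Whale movement is modelled as a continuous-time correlated random walk
(CTCRW): per planar coordinate, velocity follows an Ornstein–Uhlenbeck
process, dv = −β v dt + σ dW, and position is its integral.  β (h⁻¹)
controls how quickly velocity decorrelates and σ (km h⁻³ᐟ²) the overall
velocity variability.  Because the transition density between any two
times has a closed form, the model handles irregular Argos sampling
without interpolation.  Observed fixes are the true position plus
bivariate Gaussian error whose covariance comes from the Argos error
ellipse: with semi-major M, semi-minor m (metres) and orientation c
(degrees clockwise from north),

    var_east  = (M² sin²c + m² cos²c) / 2
    var_north = (M² cos²c + m² sin²c) / 2
    cov       = (M² − m²) sin c cos c / 2

(the covariance of a point drawn with uniform angle on the ellipse).
Tags without transmitted ellipses receive the per-location-class mean
ellipse of tags that do transmit them.

Behavioral variation enters by letting the parameters vary per sampling
interval as lognormal random variables with covariate-linked means:

    log σ_t ~ Normal(A0 + A·X_t, ε₁)
    log β_t ~ Normal(B0 + B·X_t, ε₂),  ε₂ fixed at 0.01

where X_t holds standardized environmental covariates attributed, by
default, to the relocation at which the interval ends (configurable to
interval start).  ε₂ is pinned because it is empirically tiny and poorly
identified.  Two fallbacks mirror how the model degrades gracefully:
if no covariate effect on β_t is Wald-significant at 0.05 the model is
refit with a single scalar β, and if that scalar estimate exceeds 4 on
the log scale it is refit with log β fixed at 4 — β above e⁴ implies a
persistence time 3/β below ~0.05 h, i.e. movement that is effectively
uncorrelated at the sampling resolution, where β is no longer
identifiable from above.

Derived quantities: persistence p_t = 3/β_t (hours), and the long-term
velocity ν_t = √π σ_t / (2√β_t), the mean of the stationary speed
distribution (speed is Rayleigh with scale σ/√(2β)).  ν_t indexes the
continuum from area-restricted search (ARS; slow, weakly persistent) to
transit.  Post-hoc behavioral states are quadrants of (σ_t, p_t)
relative to their medians pooled across individuals; ties count as
"below", so identical values classify as ARS.  Lognormal
back-transforms use the median (exp of the linear predictor), not the
mean; at ε₂ = 0.01 the distinction is negligible for β and documented
for σ.

## Likelihood and the Laplace approximation

For fixed latent parameters the model is linear-Gaussian, so the state
integral is exact.  `kalman_loglik` evaluates it with a classic Kalman
recursion; the fitting machinery evaluates the same quantity as a single
banded Gaussian–Markov solve (the joint density of states and
observations is quadratic in the states with a block-tridiagonal
precision), and the two routes are tested to agree to numerical
round-off.

The marginal likelihood over the latent vector u = (log σ_t[, log β_t])
is approximated by Laplace:

    −log L(θ) ≈ g(u*) + ½ log det H_g(u*) − (dim u / 2) log 2π

with g(u) = −log p(z|u) − log p(u|θ) (exact in the states) and u* its
minimizer.  Three structural results keep every evaluation O(n):

* g itself is one banded solve;
* ∇g is exact via Fisher's identity — the conditional expectation of the
  joint-density gradient under the smoothed state posterior, computed
  from one RTS pass extended with lag-one and lag-two covariances;
* H_g equals the Schur complement of the joint (states + latents) banded
  Hessian plus the curvature of the state log-determinant term.  That
  correction's entries decay geometrically with time lag; lags 0 and 1
  are computed analytically from the smoothed covariances and added to
  the band (validated against dense finite differences; the discarded
  lag-2 terms change the log-determinant by ≲0.01 nats on tracks of
  realistic length).

The mode is found by a damped Newton iteration using the corrected band
for directions, warm-started across outer evaluations, with convergence
declared when the implied latent displacement falls below ~1e-8.  On a
3-interval toy the resulting marginal agrees with full Gauss–Hermite
quadrature over the 6-dimensional latent vector to ~0.02%.

Numerical choices: initial position prior is diffuse (1e6 km²; exposed
as a parameter because comparisons against dense reference computations
are conditioning-limited at that scale and prefer 1e4 km²); initial
velocity prior is the stationary distribution at the first interval's
prior means; observation covariances receive a 1e-6 km² ridge so
degenerate ellipses stay invertible; local transition-matrix derivatives
use complex-step differentiation (machine precision), and only the
latent-latent Hessian blocks use central differences.  The sequential
filter/smoother pass is JIT-compiled with numba when available, with an
identical pure-numpy fallback.

## Fitting

Stage 1 maximizes the constant-parameter likelihood over (log σ, log β)
by Nelder–Mead and smooths the track to estimate true locations.
Covariates are extracted there as 3-km-radius means (twice the nominal
error of the best Argos classes), standardized — per track by default,
or with the raster stack's global constants — and missing values become
0, the standardized mean.  Stage 2 minimizes the Laplace marginal NLL
over (A0, A, log ε₁, B0, B) with L-BFGS-B; finite-difference steps
(1e-3) and stopping tolerances are set above the inner solver's noise
floor.

Standard errors come from the curvature of the outer objective,
estimated by a least-squares quadratic fit over a symmetric two-scale
stencil (axis points at 0.05 and 0.15, cross points at 0.10, relative
to parameter magnitude; the stencil is widened once if the fitted
curvature is not positive definite, and SEs are flagged unavailable if
it still is not).  The wide stencil is deliberate: the Laplace marginal
can develop narrow kinks where the profile Hessian of the latent field
approaches singularity (the optimizer is attracted to such
near-degenerate configurations because the log-determinant term dips
there), and a small-step finite difference at such a point reports the
cusp's spurious curvature rather than the likelihood basin's.  The
quadratic fit measures the basin, which is the quantity Wald intervals
are built from; p-values are Wald.

## Spatial layers

* ν prediction: per 1-km cell, covariates are standardized with the
  fit's constants and pushed through the fitted response; missing
  covariates use the standardized mean; land stays masked.  Only
  individuals with more than 200 locations (strict) enter the
  cross-individual mean, since shorter tracks give unstable response
  curves.
* Aggregation to the 8-km analysis grid is the block mean of unmasked
  1-km cells.
* Vessel density VD_i: per month, for each day with data, the unique
  vessels whose straight-line interpolated path crosses cell i are
  counted (Amanatides–Woo grid traversal; configurable to
  fix-containment only); the day-sum is divided by that month's number
  of days with data, and monthly layers are averaged.
* Encounter layers: RPEW_i = N_i (1/ν_i) / Σ N_i (1/ν_i);
  RPVEW_i normalizes the product of the whale (Pw), residence-time (Pt)
  and vessel (Pv) probability fields.  All normalizations run over
  valid (unmasked) cells; masked cells are excluded from sums, zeros are
  kept.
* Overlap: layers are min-max rescaled to [0, 1], normalized to sum to
  one, and compared with Schoener's D = 1 − ½Σ|p−q| and Warren's
  I = 1 − ½Σ(√p−√q)².  The formula-level functions are exposed
  separately because the rescale step is a no-op exactly when layer
  minima are zero.

## Covariate layers

DAHCC (distance to areas of high spring chlorophyll-a concentration):
cells at or above the 95th percentile of the spring chlorophyll
distribution form the source set; every marine cell takes
log(d + cell/2), the half-cell floor keeping the log finite on the
source set.  A raster distance transform replaces polygon construction;
they agree at cell resolution.  Thermal gradients: the SST field is
median-filtered (3×3 by default) to suppress impulse noise, then the
gradient magnitude is taken by central differences (one-sided at edges),
in °C km⁻¹.  Covariate pairs with |r| ≥ 0.5 are flagged before entering
a model.

## The synthetic world

The generator emulates a summering baleen whale on a 200 × 200 km
coastal domain.  Defaults: n = 500 fixes at 1 h ± 30% spacing; σ
intercept A0 = 1.0 and β intercept B0 = 0.8 on the log scale, giving a
long-term velocity around 1.6 km/h and persistence ≈ 1.4 h (consistent
with predominantly foraging-type movement); ε₁ = 0.3; slopes
(0.6, 0.1, −0.4) on (log-DAHCC, SST, thermal gradient) when all three
covariates are active — velocity rises away from the productive patch
and falls on strong fronts; a mixed Argos class distribution from class
3 (250 m) to class B (8 km) with uniform ellipse orientations.
Covariate rasters are smooth by construction (a Gaussian chlorophyll
patch seeding the DAHCC layer; an SST ramp with ~20-km-scale
anomalies), vessels are correlated random walks with an optional
corridor attractor, and the density surface is a sum of Gaussian bumps.

What the generator does not emulate: coastline geometry and land
masking of real fjords, Argos class-quality serial correlation, tidal
and advective currents, data gaps from duty cycling, and
migration-onset behavior.  Passing tests therefore demonstrate that the
estimation machinery is correct and calibrated under the model's own
assumptions, not that the model is adequate for any particular real
data set.

The parameter-recovery study (50 replicates, n = 500, one active
covariate on σ with slope 0.5, scalar β) runs the full production path:
simulate, stage-1 smooth, extract covariates from the rasters at
smoothed positions, standardize with the stack constants, fit, and
compare the slope against truth using the fit's own Wald intervals.
Problem sizes throughout (n = 500 tracks, 10⁴-step stationary runs,
10⁶-draw Monte-Carlo checks, 16³ × 6³ quadrature nodes) were chosen so
the whole validation suite completes comfortably on a single CPU.

## Known limitations

* The Laplace marginal is an approximation; its accuracy is verified on
  small cases against quadrature but not bounded in general.
* Per-interval latent parameters indexed at interval end are a
  convention; the model is agnostic and the alternative is one flag
  away.
* The planar projection is spherical azimuthal-equidistant per track;
  tracks spanning more than ~1000 km from their centroid trigger a
  distortion warning rather than a reprojection.
* Vessel "crossing" assumes straight-line movement between consecutive
  fixes; sparse vessel pings understate the traversed area.
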