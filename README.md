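# movescape

Movement-ecology toolkit for satellite-tracked marine megafauna: a
fast-fitting continuous-time correlated random walk (CTCRW) whose
movement parameters respond to environmental covariates, and the
spatial risk layers built on top of it — long-term-velocity prediction
surfaces, relative encounter-probability maps, and overlap statistics
against vessel traffic.  It is written for analysts working with
Argos-quality telemetry (blue whales off northern Chilean Patagonia are
the motivating system) who want behaviorally informed priority areas
and ship-strike risk screening from tracking data, gridded
oceanographic covariates, a density surface, and vessel position
reports.

## The model

Velocity follows an Ornstein–Uhlenbeck process per coordinate,
dv = −β v dt + σ dW, with position its integral; observed fixes carry
bivariate Gaussian error derived from each fix's Argos error ellipse.
Per sampling interval the parameters are lognormal latent variables
linked to standardized covariates X_t:

    log σ_t ~ Normal(A0 + A·X_t, ε₁)        (velocity variability)
    log β_t ~ Normal(B0 + B·X_t, ε₂ = 0.01) (velocity autocorrelation)

Fitting is single-step maximum marginal likelihood: the kinematic
states are integrated exactly (the model is linear-Gaussian given the
latents) and the latent parameter vector by a Laplace approximation
over a block-banded joint Hessian, so a 500-fix track fits in seconds.
If no covariate moves β_t significantly the model falls back to a
single scalar β, and a scalar estimate above 4 (log scale) is pinned at
4, flagging movement that decorrelates faster than the sampling
resolves.  Derived behavioral quantities are the persistence
p_t = 3/β_t, the long-term velocity ν_t = √π σ_t/(2√β_t) (mean
stationary speed; the area-restricted-search ↔ transit axis), and
post-hoc quadrant states relative to pooled medians of σ_t and p_t.

Risk layers on a shared 8-km grid combine an external density surface
N_i, the predicted ν_i, and per-fleet vessel density VD_i:

    RPEW_i  = N_i (1/ν_i) / Σ N_i (1/ν_i)
    RPVEW_i ∝ Pw_i · Pt_i · Pv_i   (whale, residence-time, vessel fields)

with overlap between layers summarized by Schoener's D and Warren's I.

## Worked example

Simulate a 500-fix track whose σ responds to an SST-like field
(true log-scale parameters: intercepts A0 = 1.0, B0 = 0.8, SST slope
0.5, ε₁ = 0.3), then refit it end to end — smoothing, 3-km covariate
extraction, marginal-likelihood fit:

```python
from movescape import (SimConfig, MovementParams, simulate_track,
                       make_covariate_stack, fit, FitConfig,
                       behavior_series, classify_states)

config = SimConfig(seed=100, n_locations=500,
                   params=MovementParams(A0=1.0, A=(0.5,), eps1=0.3,
                                         B0=0.8, B=None),
                   covariates=("sst",))
stack = make_covariate_stack(config)
truth, track = simulate_track(config, stack)
fitted = fit(track, stack, FitConfig(covariates_on_beta=False,
                                     standardize="stack"))
print(fitted.report())
```

```
Covariate-driven CTCRW fit (log scale); log L = -2142.050
beta mode: scalar
parameter  estimate     se  p_value
       A0    1.1633 0.3114   0.0002
   A[sst]    0.6243 0.1814   0.0006
 log_eps1   -1.2526 0.3539   0.0004
       B0    0.9004 0.3164   0.0044
```

Every generating parameter is recovered within its Wald interval: the
whale moves faster in warmer water (positive, significant SST effect on
log σ), and the derived series give a mean long-term velocity of
1.33 km/h with a median persistence of 1.22 h — foraging-type movement.
`classify_states([behavior_series(fitted)])` labels each interval
ars / transit / mixed relative to the pooled medians, and
`predict_nu_raster` + `rpvew` turn a fitted model, a density surface
and vessel records into encounter-probability maps.

A command-line interface wraps the common paths:

```
movescape simulate --seed 1 --out-dir sim/
movescape fit --tracks sim/tracks.csv --sst sim/sst.asc --out-dir fits/
movescape risk --density sim/density.asc --nu nu.asc \
               --vessels sim/vessels.csv --fleet aquaculture
```

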