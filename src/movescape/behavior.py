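"""Derived behavioral quantities.

From the fitted per-interval (sigma_t, beta_t) the package derives the
persistence time scale p_t = 3 / beta_t (hours), the long-term velocity
nu_t = sqrt(pi) sigma_t / (2 sqrt(beta_t)) — the expected speed under the
stationary velocity distribution, a proxy for the area-restricted-search
(ARS) vs transit continuum — post-hoc four-quadrant behavioral states
relative to pooled medians, covariate prediction curves, and spatial nu
prediction rasters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import CovariateStack
from .ctcrw import FittedCTCRW
from .raster import GridRaster

__all__ = [
    "BehaviorSeries",
    "long_term_velocity",
    "behavior_series",
    "classify_states",
    "prediction_curve",
    "predict_nu_raster",
    "average_nu_rasters",
]

QUADRANTS = (
    "ars",  # low sigma, low persistence
    "transit",  # high sigma, high persistence
    "low_sigma_high_persistence",
    "high_sigma_low_persistence",
)


def long_term_velocity(sigma, beta):
    """Long-term velocity nu = sqrt(pi) * sigma / (2 sqrt(beta)).

    This is the mean of the stationary speed distribution (speed is
    Rayleigh with scale sigma / sqrt(2 beta)); km/h for sigma in
    km h^-3/2 and beta in 1/h.
    """
    sigma = np.asarray(sigma, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if (sigma <= 0).any() or (beta <= 0).any():
        raise ValueError("sigma and beta must be strictly positive")
    out = np.sqrt(np.pi) * sigma / (2.0 * np.sqrt(beta))
    return float(out) if out.ndim == 0 else out


@dataclass
class BehaviorSeries:
    """Per-interval behavioral quantities for one individual."""

    animal_id: str
    sigma: np.ndarray  # km h^-3/2
    beta: np.ndarray  # 1/h
    quadrant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma.shape != self.beta.shape:
            raise ValueError("sigma and beta must have matching lengths")

    @property
    def persistence(self) -> np.ndarray:
        """p_t = 3 / beta_t, hours."""
        return 3.0 / self.beta

    @property
    def nu(self) -> np.ndarray:
        return long_term_velocity(self.sigma, self.beta)

    def __len__(self) -> int:
        return len(self.sigma)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "sigma": self.sigma,
                "beta": self.beta,
                "persistence_h": self.persistence,
                "nu_kmh": self.nu,
            }
        )
        if self.quadrant is not None:
            df["quadrant"] = self.quadrant
        return df


def behavior_series(fitted: FittedCTCRW, animal_id: str | None = None) -> BehaviorSeries:
    """Per-interval behavioral series from a fitted model's latent mode."""
    aid = animal_id or (fitted.track.animal_id if fitted.track is not None else "?")
    return BehaviorSeries(
        animal_id=aid,
        sigma=np.exp(fitted.latent.log_sigma),
        beta=np.exp(fitted.latent.log_beta),
    )


def classify_states(series: list[BehaviorSeries]) -> list[BehaviorSeries]:
    """Label each relocation by its quadrant relative to pooled medians.

    Medians of sigma_t and persistence p_t are taken across all
    relocations of all individuals.  Values at or below the median count
    as "below" (the documented tie rule), so low sigma and low persistence
    is ARS and high/high is transit.
    """
    if not series:
        raise ValueError("no behavior series supplied")
    all_sigma = np.concatenate([s.sigma for s in series])
    if all_sigma.size == 0:
        raise ValueError("behavior series are empty")
    all_p = np.concatenate([s.persistence for s in series])
    med_sigma = float(np.median(all_sigma))
    med_p = float(np.median(all_p))

    out = []
    for s in series:
        low_s = s.sigma <= med_sigma
        low_p = s.persistence <= med_p
        quad = np.where(
            low_s & low_p,
            "ars",
            np.where(
                ~low_s & ~low_p,
                "transit",
                np.where(low_s, "low_sigma_high_persistence", "high_sigma_low_persistence"),
            ),
        )
        out.append(BehaviorSeries(animal_id=s.animal_id, sigma=s.sigma, beta=s.beta, quadrant=quad))
    return out


def _response(fitted: FittedCTCRW, x: np.ndarray, covariate: str):
    """(sigma, beta) along a grid of one standardized covariate, others at 0."""
    if covariate not in fitted.covariate_names:
        raise KeyError(
            f"unknown covariate {covariate!r}; fitted covariates are {fitted.covariate_names}"
        )
    j = fitted.covariate_names.index(covariate)
    params = fitted.params
    sigma = np.exp(params.A0 + params.A[j] * x)
    if params.beta_mode == "latent":
        beta = np.exp(params.B0 + params.B[j] * x)
    else:
        beta = np.full_like(x, np.exp(params.B0))
    return sigma, beta


def prediction_curve(fitted: FittedCTCRW, covariate: str, grid: np.ndarray) -> pd.DataFrame:
    """Expected nu response as one standardized covariate varies.

    The named covariate runs over ``grid`` while all others are held at 0
    (their standardized mean); the lognormal back-transform uses the
    median (exp of the linear predictor).
    """
    x = np.asarray(grid, dtype=float)
    sigma, beta = _response(fitted, x, covariate)
    return pd.DataFrame(
        {"x": x, "sigma": sigma, "beta": beta, "nu": long_term_velocity(sigma, beta)}
    )


def predict_nu_raster(
    fitted: FittedCTCRW,
    stack: CovariateStack,
    template: GridRaster,
    when=None,
) -> GridRaster:
    """Predicted long-term velocity nu per cell of ``template``.

    Cell covariates are standardized with the fit's constants; cells with
    a missing covariate use 0 (the standardized mean).  Masked template
    cells stay masked.
    """
    if not fitted.standardization:
        raise ValueError(
            "fit carries no standardization constants; refit with covariate extraction"
        )
    params = fitted.params
    nr, nc = template.shape
    xs, ys = template.cell_centers()
    log_sigma = np.full((nr, nc), params.A0)
    log_beta = np.full((nr, nc), params.B0)
    for j, name in enumerate(fitted.covariate_names):
        layer = stack.layers[name]
        ras = layer if isinstance(layer, GridRaster) else layer[when]
        mean, sd = fitted.standardization[name]
        vals = ras.sample(
            np.repeat(xs[None, :], nr, axis=0).ravel(),
            np.repeat(ys[:, None], nc, axis=1).ravel(),
        ).reshape(nr, nc)
        zed = (vals - mean) / sd
        zed[~np.isfinite(zed)] = 0.0
        log_sigma = log_sigma + params.A[j] * zed
        if params.beta_mode == "latent":
            log_beta = log_beta + params.B[j] * zed
    nu = long_term_velocity(np.exp(log_sigma), np.exp(log_beta))
    nu[~np.isfinite(template.values)] = np.nan
    return template.copy_with(nu)


def average_nu_rasters(
    rasters: list[GridRaster],
    locations_per_individual: list[int],
    min_locations: int = 200,
) -> GridRaster:
    """Cell-wise mean nu over individuals with more than ``min_locations`` fixes.

    Individuals with ``min_locations`` or fewer locations are excluded
    (strict inequality: exactly 200 locations does not qualify).
    """
    if len(rasters) != len(locations_per_individual):
        raise ValueError("one location count per raster is required")
    keep = [r for r, nloc in zip(rasters, locations_per_individual) if nloc > min_locations]
    if not keep:
        raise ValueError(
            f"no individual has more than {min_locations} locations; nothing to average"
        )
    ref = keep[0]
    for r in keep[1:]:
        if r.shape != ref.shape or r.cell_size != ref.cell_size:
            raise ValueError("nu rasters are not on aligned grids")
    stacked = np.stack([r.values for r in keep])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
    return ref.copy_with(mean)
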