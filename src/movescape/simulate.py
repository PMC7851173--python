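"""Synthetic data generation for every pipeline input.

Generates covariate-driven CTCRW whale tracks corrupted by Argos
error-ellipse noise, smooth covariate rasters with known structure,
correlated-random-walk vessel tracks, and a whale density surface, so the
whole pipeline is testable end to end without any external data.

Defaults emulate a summering baleen whale on a 200 x 200 km coastal
domain: hourly-ish irregular fixes, long-term speeds of a few km/h,
persistence around 1.4 h, and a mixed-quality Argos class distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._laplace import trans_blocks
from .covariates import CovariateStack, build_dahcc, thermal_gradient
from .ctcrw import MovementParams, ellipse_to_covariance
from .raster import GridRaster
from .tracks import ArgosRelocation, ArgosTrack, AzimuthalEquidistant, VesselRecord

__all__ = [
    "SimConfig",
    "make_covariate_stack",
    "make_density_surface",
    "simulate_track",
    "simulate_vessels",
    "write_tracks_csv",
    "write_vessels_csv",
]

# Argos location-class mixture: weight, semi-major (m), semi-minor (m)
DEFAULT_ELLIPSE_MIX: dict[str, tuple[float, float, float]] = {
    "3": (0.10, 250.0, 150.0),
    "2": (0.15, 500.0, 300.0),
    "1": (0.20, 1200.0, 600.0),
    "0": (0.15, 3000.0, 1500.0),
    "A": (0.20, 4000.0, 2000.0),
    "B": (0.20, 8000.0, 4000.0),
}


def _default_params() -> MovementParams:
    # sigma ~ e^1 km h^-3/2 and beta ~ e^0.8 /h give nu ~ 1.6 km/h and
    # persistence ~ 1.35 h; sigma rises away from the productive patch and
    # falls on strong fronts
    return MovementParams(
        A0=1.0, A=(0.6, 0.1, -0.4), eps1=0.3, B0=0.8, B=None, eps2=0.01
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic world; the seed fixes everything."""

    seed: int = 0
    n_locations: int = 500
    mean_dt_hours: float = 1.0
    dt_jitter: float = 0.3  # dt ~ mean * U(1 - j, 1 + j)
    params: MovementParams = field(default_factory=_default_params)
    covariates: tuple[str, ...] = ("log_dahcc", "sst", "thermal_gradient")
    ellipse_mix: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ELLIPSE_MIX)
    )
    extent_km: float = 200.0
    covariate_cell_km: float = 2.0
    center_lonlat: tuple[float, float] = (-73.5, -43.5)
    n_vessels: int = 20
    n_days: int = 10
    fleet: str = "aquaculture"
    vessel_speed_kmh: float = 15.0
    corridor: bool = False
    start_time: str = "2019-03-01T00:00:00+00:00"

    def __post_init__(self) -> None:
        if self.mean_dt_hours <= 0:
            raise ValueError("mean_dt_hours must be positive")
        if not (0 <= self.dt_jitter < 1):
            raise ValueError("dt_jitter must be in [0, 1)")
        if len(np.atleast_1d(self.params.A)) != len(self.covariates):
            raise ValueError("params.A must have one slope per configured covariate")

    @property
    def projection(self) -> AzimuthalEquidistant:
        return AzimuthalEquidistant(lon0=self.center_lonlat[0], lat0=self.center_lonlat[1])


def _smooth_field(rng, shape, scale_cells: float, amplitude: float) -> np.ndarray:
    """Smooth random field from heavily low-passed white noise."""
    from scipy import ndimage

    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scale_cells, mode="nearest")
    sd = smooth.std()
    return amplitude * smooth / sd if sd > 0 else smooth


def make_covariate_stack(config: SimConfig) -> CovariateStack:
    """Covariate rasters with known ground truth.

    Chlorophyll is a Gaussian bump (the "high concentration" patch seeds
    the DAHCC distance layer); SST is a north-south ramp plus smooth
    anomalies, from which the thermal-gradient layer is derived.
    """
    rng = np.random.default_rng([config.seed, 1])
    half = config.extent_km / 2.0
    n = int(round(config.extent_km / config.covariate_cell_km))
    xs = -half + (np.arange(n) + 0.5) * config.covariate_cell_km
    ys = half - (np.arange(n) + 0.5) * config.covariate_cell_km
    X, Y = np.meshgrid(xs, ys)

    def _grid(values):
        return GridRaster(
            values=values,
            x_origin=-half,
            y_origin=-half,
            cell_size=config.covariate_cell_km,
            crs_tag="aeqd-km",
        )

    layers: dict[str, GridRaster] = {}
    need_sst = "sst" in config.covariates or "thermal_gradient" in config.covariates
    if "log_dahcc" in config.covariates:
        cx, cy = rng.uniform(-half * 0.5, half * 0.5, size=2)
        chl = 0.5 + 6.0 * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 15.0**2))
        chl += np.abs(_smooth_field(rng, (n, n), scale_cells=6, amplitude=0.2))
        layers["log_dahcc"] = build_dahcc(_grid(chl), percentile=95.0)
    if need_sst:
        sst = 12.0 - 0.015 * Y + _smooth_field(rng, (n, n), scale_cells=10, amplitude=1.2)
        if "sst" in config.covariates:
            layers["sst"] = _grid(sst)
        if "thermal_gradient" in config.covariates:
            layers["thermal_gradient"] = thermal_gradient(_grid(sst), median_window=3)
    stack = CovariateStack(layers={name: layers[name] for name in config.covariates})
    stack.compute_standardization()
    return stack


def make_density_surface(config: SimConfig, cell_km: float = 8.0) -> GridRaster:
    """Whale density surface N_i (animals per cell) on an 8-km grid."""
    rng = np.random.default_rng([config.seed, 2])
    half = config.extent_km / 2.0
    n = int(round(config.extent_km / cell_km))
    xs = -half + (np.arange(n) + 0.5) * cell_km
    ys = half - (np.arange(n) + 0.5) * cell_km
    X, Y = np.meshgrid(xs, ys)
    dens = np.full((n, n), 0.05)
    for _ in range(3):
        cx, cy = rng.uniform(-half * 0.7, half * 0.7, size=2)
        amp = rng.uniform(0.5, 2.0)
        width = rng.uniform(15.0, 35.0)
        dens += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * width**2))
    return GridRaster(values=dens, x_origin=-half, y_origin=-half, cell_size=cell_km)


def _standardized_at(stack: CovariateStack, names, x: float, y: float) -> np.ndarray:
    out = np.empty(len(names))
    for j, name in enumerate(names):
        ras = stack.layers[name]
        v = float(ras.sample(x, y)[0])
        mean, sd = stack.standardization[name]
        z = (v - mean) / sd
        out[j] = z if np.isfinite(z) else 0.0
    return out


def simulate_track(
    config: SimConfig, stack: CovariateStack | None = None
) -> tuple[pd.DataFrame, ArgosTrack]:
    """Simulate one covariate-driven CTCRW track with Argos ellipse noise.

    At each irregular step the covariates are read at the current true
    position, log sigma_t and log beta_t are drawn from their Normals
    (beta stays deterministic when the model carries no beta covariates),
    the kinematic state advances by the exact transition law, and the
    observed fix adds bivariate normal noise from a randomly drawn
    location-class error ellipse.  Returns (truth table, observed track).
    """
    rng = np.random.default_rng([config.seed, 0])
    if stack is None:
        stack = make_covariate_stack(config)
    params = config.params
    n = config.n_locations
    m = n - 1
    dts = config.mean_dt_hours * rng.uniform(
        1.0 - config.dt_jitter, 1.0 + config.dt_jitter, size=m
    )
    half = config.extent_km / 2.0
    names = list(config.covariates)
    A = np.atleast_1d(params.A)
    B = np.atleast_1d(params.B) if params.B is not None else None

    x0 = _standardized_at(stack, names, 0.0, 0.0)
    mu1_0 = params.A0 + A @ x0
    mu2_0 = params.B0 + (B @ x0 if B is not None else 0.0)
    v_sd0 = np.sqrt(np.exp(2 * mu1_0 - mu2_0) / 2.0)
    state = np.array([0.0, rng.normal(0, v_sd0), 0.0, rng.normal(0, v_sd0)])

    truth = np.empty((n, 4))
    truth[0] = state
    Xrows = np.empty((m, len(names)))
    log_sigma = np.empty(m)
    log_beta = np.empty(m)
    reflected = False
    for t in range(m):
        xcov = _standardized_at(stack, names, state[0], state[2])
        Xrows[t] = xcov
        ls = rng.normal(params.A0 + A @ xcov, params.eps1)
        if params.beta_fixed_flag:
            lb = params.beta_fixed_value
        elif B is not None:
            lb = rng.normal(params.B0 + B @ xcov, params.eps2)
        else:
            lb = params.B0
        log_sigma[t] = ls
        log_beta[t] = lb
        F2, Q2 = trans_blocks(ls, lb, dts[t])
        L = np.linalg.cholesky(Q2)
        for sl in (slice(0, 2), slice(2, 4)):
            state[sl] = F2 @ state[sl] + L @ rng.standard_normal(2)
        for pos_i, vel_i in ((0, 1), (2, 3)):
            if abs(state[pos_i]) > half:
                state[pos_i] = np.sign(state[pos_i]) * (2 * half - abs(state[pos_i]))
                state[vel_i] = -state[vel_i]
                reflected = True
        truth[t + 1] = state
    if reflected:
        warnings.warn("simulated track hit the domain boundary; reflected", stacklevel=2)

    # observations: ellipse class mixture
    classes = list(config.ellipse_mix)
    weights = np.array([config.ellipse_mix[c][0] for c in classes], dtype=float)
    weights /= weights.sum()
    drawn = rng.choice(len(classes), size=n, p=weights)
    obs = np.empty((n, 2))
    ellipses = np.empty((n, 3))
    for i in range(n):
        cls = classes[drawn[i]]
        _, smaj, smin = config.ellipse_mix[cls]
        orient = rng.uniform(0.0, 180.0)
        ellipses[i] = (smaj, smin, orient)
        cov = ellipse_to_covariance(smaj, smin, orient).as_matrix()
        Lc = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
        obs[i] = truth[i, [0, 2]] + Lc @ rng.standard_normal(2)

    proj = config.projection
    t0 = pd.Timestamp(config.start_time)
    seconds = np.round(np.concatenate([[0.0], np.cumsum(dts)]) * 3600.0)
    times = t0 + pd.to_timedelta(seconds, unit="s")
    lon, lat = proj.inverse(obs[:, 0], obs[:, 1])
    relocs = [
        ArgosRelocation(
            timestamp=times[i].to_pydatetime(),
            lon=float(lon[i]),
            lat=float(lat[i]),
            location_class=classes[drawn[i]],
            ellipse_semi_major=float(ellipses[i, 0]),
            ellipse_semi_minor=float(ellipses[i, 1]),
            ellipse_orientation=float(ellipses[i, 2]),
        )
        for i in range(n)
    ]
    track = ArgosTrack(
        animal_id=f"sim-{config.seed}",
        relocations=relocs,
        projected_xy=obs,
        projection=proj,
    )

    truth_df = pd.DataFrame(
        {
            "timestamp": times,
            "x_km": truth[:, 0],
            "vx_kmh": truth[:, 1],
            "y_km": truth[:, 2],
            "vy_kmh": truth[:, 3],
            "log_sigma": np.concatenate([[np.nan], log_sigma]),
            "log_beta": np.concatenate([[np.nan], log_beta]),
        }
    )
    for j, name in enumerate(names):
        truth_df[f"z_{name}"] = np.concatenate([[np.nan], Xrows[:, j]])
    return truth_df, track


def simulate_vessels(config: SimConfig) -> list[VesselRecord]:
    """Correlated-random-walk vessel tracks sampled hourly over several days.

    With ``corridor=True`` vessels are drawn toward the east-west line
    y = 0, concentrating traffic in a known high-density band.
    """
    rng = np.random.default_rng([config.seed, 3])
    proj = config.projection
    half = config.extent_km / 2.0
    t0 = pd.Timestamp(config.start_time)
    records: list[VesselRecord] = []
    for v in range(config.n_vessels):
        pos = rng.uniform(-half * 0.9, half * 0.9, size=2)
        vel = rng.normal(0, config.vessel_speed_kmh / 2.0, size=2)
        for day in range(config.n_days):
            for hour in range(24):
                vel = 0.8 * vel + rng.normal(0, config.vessel_speed_kmh / 3.0, size=2)
                if config.corridor:
                    vel[1] -= 0.2 * pos[1]  # pull toward y = 0
                pos = pos + vel * 1.0
                pos = np.clip(pos, -half * 0.99, half * 0.99)
                lon, lat = proj.inverse(pos[0], pos[1])
                records.append(
                    VesselRecord(
                        vessel_id=f"v{v:03d}",
                        fleet=config.fleet,
                        timestamp=(t0 + pd.Timedelta(days=day, hours=hour)).to_pydatetime(),
                        lon=float(lon),
                        lat=float(lat),
                    )
                )
    return records


def write_tracks_csv(tracks: list[ArgosTrack], path) -> None:
    """Write tracks in the dialect read_argos_table consumes."""
    frames = [t.to_frame().drop(columns=["x_km", "y_km"], errors="ignore") for t in tracks]
    df = pd.concat(frames, ignore_index=True)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    df.to_csv(path, index=False)


def write_vessels_csv(records: list[VesselRecord], path) -> None:
    """Write vessel records in the dialect read_vessel_table consumes."""
    df = pd.DataFrame(
        {
            "vessel_id": [r.vessel_id for r in records],
            "fleet": [r.fleet for r in records],
            "timestamp": [
                pd.Timestamp(r.timestamp).strftime("%Y-%m-%dT%H:%M:%S%z") for r in records
            ],
            "lon": [r.lon for r in records],
            "lat": [r.lat for r in records],
        }
    )
    df.to_csv(path, index=False)
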