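"""Continuous-time correlated random walk with covariate-driven parameters.

The movement process is an integrated Ornstein-Uhlenbeck velocity model:
per coordinate, dv = -beta v dt + sigma dW and position integrates the
velocity.  ``beta`` (1/h) controls how quickly velocity decorrelates and
``sigma`` (km h^-3/2) the overall velocity variability.  Observed fixes
carry elliptical Argos error.  Per-interval ``log sigma_t`` and
``log beta_t`` are lognormal random variables whose means are linear in
standardized environmental covariates:

    log sigma_t ~ Normal(A0 + A X_t, eps_1)
    log beta_t  ~ Normal(B0 + B X_t, eps_2),   eps_2 fixed at 0.01

Fitting is two-stage: a constant-parameter fit recovers the true path for
covariate extraction, then the covariate model is estimated by maximizing
the Laplace-approximated marginal likelihood.  Fallbacks: if no covariate
effect on beta_t is significant the model is refit with a single scalar
beta; if that estimate exceeds 4 (log scale), log beta is fixed at 4,
flagging overall poorly autocorrelated movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._laplace import (
    LOG2PI,
    JointCTCRW,
    kalman_rts_pass,
    plugin_kalman_nll,
    trans_blocks,
)
from .covariates import CovariateStack, standardize_and_fill
from .tracks import ArgosTrack

__all__ = [
    "EllipseCovariance",
    "MovementParams",
    "LatentStates",
    "FittedCTCRW",
    "FitConfig",
    "ellipse_to_covariance",
    "ctcrw_transition",
    "kalman_loglik",
    "laplace_marginal_nll",
    "fit",
    "smooth_states",
]

_R_JITTER_KM2 = 1e-6  # ridge keeping degenerate ellipses invertible


@dataclass(frozen=True)
class EllipseCovariance:
    """Bivariate observation-error covariance derived from an Argos ellipse."""

    var_x: float  # km^2, east
    var_y: float  # km^2, north
    cov_xy: float  # km^2

    def __post_init__(self) -> None:
        if self.var_x < 0 or self.var_y < 0:
            raise ValueError("variances must be non-negative")
        if self.var_x * self.var_y < self.cov_xy**2 - 1e-12:
            raise ValueError("ellipse covariance is not positive semi-definite")

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.var_x, self.cov_xy], [self.cov_xy, self.var_y]])


def ellipse_to_covariance(
    semi_major: float, semi_minor: float, orientation: float
) -> EllipseCovariance:
    """Observation covariance (km^2) from an Argos error ellipse.

    Parameters
    ----------
    semi_major, semi_minor
        Ellipse axes in metres, ``semi_major >= semi_minor >= 0``.
    orientation
        Degrees clockwise from north of the semi-major axis.

    The covariance is that of a point drawn with uniform angle on the
    ellipse: with M, m the axes and c the orientation,
    ``var_x = (M^2 sin^2 c + m^2 cos^2 c) / 2`` (east),
    ``var_y = (M^2 cos^2 c + m^2 sin^2 c) / 2`` (north),
    ``cov_xy = (M^2 - m^2) sin c cos c / 2``.
    """
    if semi_minor > semi_major:
        raise ValueError("semi_minor must not exceed semi_major")
    if semi_minor < 0:
        raise ValueError("ellipse axes must be non-negative")
    c = np.radians(orientation)
    M2 = (semi_major / 1000.0) ** 2  # m -> km
    m2 = (semi_minor / 1000.0) ** 2
    sin, cos = np.sin(c), np.cos(c)
    return EllipseCovariance(
        var_x=float((M2 * sin**2 + m2 * cos**2) / 2.0),
        var_y=float((M2 * cos**2 + m2 * sin**2) / 2.0),
        cov_xy=float((M2 - m2) / 2.0 * sin * cos),
    )


def ctcrw_transition(beta: float, sigma: float, dt: float):
    """Transition matrix and process covariance for state (x, vx, y, vy).

    Closed forms of the integrated OU process over a step of ``dt`` hours:
    E[v'] = e^(-b dt) v,  E[x'] = x + v (1 - e^(-b dt)) / b, with the x and
    y blocks independent and identical.
    """
    if beta <= 0 or sigma <= 0 or dt <= 0:
        raise ValueError("beta, sigma and dt must all be strictly positive")
    F2, Q2 = trans_blocks(np.log(sigma), np.log(beta), float(dt))
    F = np.zeros((4, 4))
    Q = np.zeros((4, 4))
    F[0:2, 0:2] = F2
    F[2:4, 2:4] = F2
    Q[0:2, 0:2] = Q2
    Q[2:4, 2:4] = Q2
    return F, Q


# --------------------------------------------------------------------------- data prep
def _track_data(track: ArgosTrack, obs_cov=None):
    """(z, dt, R) arrays for a projected track."""
    if track.projected_xy is None:
        raise ValueError("track must be projected before model fitting (see project_track)")
    z = np.asarray(track.projected_xy, dtype=float)
    dt = track.dt_hours()
    if (dt <= 0).any():
        raise ValueError("track timestamps must be strictly increasing")
    n = len(z)
    R = np.empty((n, 2, 2))
    if obs_cov is not None:
        for i, c in enumerate(obs_cov):
            R[i] = c.as_matrix() if isinstance(c, EllipseCovariance) else np.asarray(c)
    else:
        ell = track.ellipses()
        if np.isnan(ell).any():
            raise ValueError(
                "track has relocations without error ellipses; impute them first"
            )
        for i in range(n):
            R[i] = ellipse_to_covariance(*ell[i]).as_matrix()
    R[:, 0, 0] += _R_JITTER_KM2
    R[:, 1, 1] += _R_JITTER_KM2
    return z, dt, R


def _expand(values, m: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        arr = np.full(m, float(arr))
    if arr.shape != (m,):
        raise ValueError(f"{name} must be scalar or have one entry per interval ({m})")
    if (arr <= 0).any():
        raise ValueError(f"{name} must be strictly positive")
    return arr


# --------------------------------------------------------------------------- Kalman
def kalman_loglik(
    track: ArgosTrack,
    sigma,
    beta,
    obs_cov=None,
    init_velocity_var: float | None = None,
    pos_var0: float = 1.0e6,
) -> float:
    """Exact Gaussian log-likelihood of a track under plug-in parameters.

    Parameters
    ----------
    track
        Projected track with error ellipses (or explicit ``obs_cov``).
    sigma, beta
        Scalars or per-interval arrays (length n - 1).
    obs_cov
        Optional per-relocation :class:`EllipseCovariance` (or 2x2 arrays)
        overriding the track's ellipses.
    init_velocity_var
        Initial velocity variance; defaults to the stationary variance
        ``sigma_1^2 / (2 beta_1)`` of the first interval.
    pos_var0
        Diffuse initial position variance (km^2) around the first fix.
        The default is effectively flat; comparisons against dense
        reference computations may prefer a smaller (better-conditioned)
        but still diffuse value.
    """
    z, dt, R = _track_data(track, obs_cov)
    m = len(dt)
    sigma = _expand(sigma, m, "sigma")
    beta = _expand(beta, m, "beta")
    nll = kalman_rts_pass(
        z, dt, R, sigma, beta, pos_var0=pos_var0, v0var=init_velocity_var
    )[0]
    return -nll


def _rts_smooth(z, dt, R, sigma, beta, init_velocity_var=None):
    """Rauch-Tung-Striebel smoother at plug-in per-interval parameters."""
    nll, ms, Ps, _, _, mf, Pf = kalman_rts_pass(z, dt, R, sigma, beta, v0var=init_velocity_var)
    return -nll, ms, Ps, mf, Pf


# --------------------------------------------------------------------------- types
@dataclass
class MovementParams:
    """Regression parameters of the covariate-driven CTCRW (log scale)."""

    A0: float
    A: np.ndarray
    eps1: float
    B0: float
    B: np.ndarray | None = None
    eps2: float = 0.01
    beta_fixed_flag: bool = False
    beta_fixed_value: float = 4.0  # log scale

    def __post_init__(self) -> None:
        self.A = np.atleast_1d(np.asarray(self.A, dtype=float))
        if self.B is not None:
            self.B = np.atleast_1d(np.asarray(self.B, dtype=float))
        if self.eps1 < 0:
            raise ValueError("eps1 must be non-negative")
        if self.beta_fixed_flag:
            self.B0 = self.beta_fixed_value
            self.B = None

    @property
    def beta_mode(self) -> str:
        if self.beta_fixed_flag:
            return "fixed"
        return "scalar" if self.B is None else "latent"


@dataclass
class LatentStates:
    """Posterior latent quantities at observation times."""

    positions: np.ndarray  # (n, 2) km
    velocities: np.ndarray  # (n, 2) km/h
    position_se: np.ndarray
    velocity_se: np.ndarray
    log_sigma: np.ndarray  # (n - 1,) per interval
    log_beta: np.ndarray
    log_sigma_se: np.ndarray | None = None
    log_beta_se: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        n = len(self.positions)
        df = pd.DataFrame(
            {
                "x_km": self.positions[:, 0],
                "y_km": self.positions[:, 1],
                "vx_kmh": self.velocities[:, 0],
                "vy_kmh": self.velocities[:, 1],
                "x_se": self.position_se[:, 0],
                "y_se": self.position_se[:, 1],
                "vx_se": self.velocity_se[:, 0],
                "vy_se": self.velocity_se[:, 1],
            }
        )
        # interval-end attribution: parameters of the interval ending at t
        df["log_sigma"] = np.concatenate([[np.nan], self.log_sigma])
        df["log_beta"] = np.concatenate([[np.nan], self.log_beta])
        return df


@dataclass
class FitConfig:
    """Options controlling :func:`fit`."""

    covariates_on_beta: bool = True
    significance: float = 0.05  # Wald threshold for the beta-reduction rule
    beta_fix_threshold: float = 4.0  # log scale
    eps2: float = 0.01
    radius_km: float = 3.0
    standardize: str = "track"  # "track" | "stack"
    attribution: str = "interval-end"  # or "interval-start"
    eps1_init: float = 0.1
    outer_maxiter: int = 200


@dataclass
class FittedCTCRW:
    """Result of a covariate-driven CTCRW fit for one track."""

    params: MovementParams
    param_names: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    latent: LatentStates
    log_likelihood: float
    convergence: dict
    covariate_names: list[str]
    standardization: dict[str, tuple[float, float]]
    X: np.ndarray
    stage1: dict
    track: ArgosTrack = field(repr=False, default=None)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": self.estimates,
                "se": self.std_errors,
                "p_value": self.p_values,
            }
        )

    def report(self) -> str:
        """Structured text report of coefficients, SEs and p-values."""
        lines = [
            f"Covariate-driven CTCRW fit (log scale); log L = {self.log_likelihood:.3f}",
            f"beta mode: {self.params.beta_mode}"
            + (
                f" (log beta fixed at {self.params.beta_fixed_value})"
                if self.params.beta_fixed_flag
                else ""
            ),
            self.coefficient_table().to_string(index=False, float_format="%.4f"),
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------- marginal NLL
def _joint_for(track_or_data, X, params: MovementParams, eps2=None):
    if isinstance(track_or_data, ArgosTrack):
        z, dt, R = _track_data(track_or_data)
    else:
        z, dt, R = track_or_data
    mode = params.beta_mode
    return JointCTCRW(
        z=z,
        dt=dt,
        R=R,
        X_sigma=X,
        X_beta=X if mode == "latent" else None,
        beta_mode=mode,
        eps2=params.eps2 if eps2 is None else eps2,
        beta_fixed_logvalue=params.beta_fixed_value,
    )


def _pack_theta(params: MovementParams) -> np.ndarray:
    theta = [params.A0, *np.atleast_1d(params.A), np.log(max(params.eps1, 1e-12))]
    if params.beta_mode == "latent":
        theta += [params.B0, *np.atleast_1d(params.B)]
    elif params.beta_mode == "scalar":
        theta += [params.B0]
    return np.asarray(theta, dtype=float)


def laplace_marginal_nll(track: ArgosTrack, X: np.ndarray, params: MovementParams) -> float:
    """Negative log marginal likelihood, latent parameters integrated by Laplace.

    ``X`` holds one row of standardized covariates per interval (n - 1
    rows).  The same design matrix drives both log sigma_t and (when the
    model retains it) log beta_t.
    """
    joint = _joint_for(track, X, params)
    return joint.marginal_nll(_pack_theta(params))


# --------------------------------------------------------------------------- fitting
def _stage1_constant_fit(z, dt, R):
    """Maximum-likelihood constant-parameter CTCRW (scalar log sigma, log beta)."""
    speeds = np.linalg.norm(np.diff(z, axis=0), axis=1) / dt
    vbar = max(float(np.mean(speeds)), 1e-3)
    beta0 = 1.0 / max(float(np.mean(dt)), 1e-2)
    sigma0 = max(vbar * 2.0 * np.sqrt(beta0) / np.sqrt(np.pi), 1e-3)

    def nll2(pair):
        if np.abs(pair).max() > 30:
            return 1e12
        try:
            return plugin_kalman_nll(z, dt, R, pair[0], pair[1])
        except (RuntimeError, np.linalg.LinAlgError):
            return 1e12

    res = optimize.minimize(
        nll2,
        np.array([np.log(sigma0), np.log(beta0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
    )
    log_sigma, log_beta = res.x
    return {
        "log_sigma": float(log_sigma),
        "log_beta": float(log_beta),
        "nll": float(res.fun),
        "converged": bool(res.success),
    }


def _optimize_marginal(joint: JointCTCRW, theta0, maxiter=200):
    cache = {}

    def obj(theta):
        key = tuple(np.round(theta, 12))
        if key not in cache:
            try:
                cache[key] = joint.marginal_nll(theta)
            except (RuntimeError, np.linalg.LinAlgError):
                cache[key] = 1e12
        return cache[key]

    # FD step and stopping tolerances must sit above the inner solver's
    # noise floor (~1e-5 in the objective), or the line search thrashes
    res = optimize.minimize(
        obj,
        np.asarray(theta0, dtype=float),
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 3e-8, "gtol": 0.03, "eps": 1e-3},
        jac=None,
    )
    # polish with a short simplex run if line-search stalled early
    if not res.success and res.nit < 3:
        res = optimize.minimize(
            obj, res.x, method="Nelder-Mead", options={"maxfev": 400}
        )
    return res, obj


def _outer_hessian(obj, theta, scale=0.05):
    """Curvature of the outer objective by least-squares quadratic fit.

    A two-scale symmetric stencil (axis points at 1x and 3x the base
    step, cross points at 2x) is fit with a full quadratic by least
    squares.  This measures the curvature of the likelihood basin and is
    robust to the narrow kinks the Laplace approximation can introduce
    near latent-degeneracy boundaries, where a small-step finite
    difference would report spuriously extreme curvature.
    """
    p = len(theta)
    h = scale * np.maximum(1.0, np.abs(theta))
    points = [np.zeros(p)]
    for i in range(p):
        for step in (1.0, -1.0, 3.0, -3.0):
            d = np.zeros(p)
            d[i] = step * h[i]
            points.append(d)
    for i in range(p):
        for j in range(i + 1, p):
            for si, sj in ((2, 2), (2, -2), (-2, 2), (-2, -2)):
                d = np.zeros(p)
                d[i] = si * h[i]
                d[j] = sj * h[j]
                points.append(d)
    D = np.array(points)
    y = np.array([obj(theta + d) for d in D])
    ok = np.isfinite(y) & (y < 1e11)
    D, y = D[ok], y[ok]
    # design: 1, d_i, d_i^2 / 2, d_i d_j
    cols = [np.ones(len(D))]
    for i in range(p):
        cols.append(D[:, i])
    quad_idx = []
    for i in range(p):
        for j in range(i, p):
            quad_idx.append((i, j))
            if i == j:
                cols.append(0.5 * D[:, i] ** 2)
            else:
                cols.append(D[:, i] * D[:, j])
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    H = np.zeros((p, p))
    for c, (i, j) in zip(coef[1 + p :], quad_idx):
        H[i, j] = c
        H[j, i] = c
    return H


def _wald(estimates, ses):
    with np.errstate(divide="ignore", invalid="ignore"):
        zscores = np.where(ses > 0, estimates / ses, np.inf)
    return 2.0 * stats.norm.sf(np.abs(zscores))


def _fit_one_mode(z, dt, R, X, beta_mode, theta0, config: FitConfig):
    joint = JointCTCRW(
        z=z,
        dt=dt,
        R=R,
        X_sigma=X,
        X_beta=X if beta_mode == "latent" else None,
        beta_mode=beta_mode,
        eps2=config.eps2,
        beta_fixed_logvalue=config.beta_fix_threshold,
    )
    res, obj = _optimize_marginal(joint, theta0, maxiter=config.outer_maxiter)
    ses = np.full(len(res.x), np.nan)
    se_ok = False
    for scale in (0.05, 0.12):  # widen the stencil if curvature comes out non-PD
        H = _outer_hessian(obj, res.x, scale=scale)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            continue
        diag = np.diag(cov)
        if (diag > 0).all():
            ses = np.sqrt(diag)
            se_ok = True
            break
        ses = np.sqrt(np.where(diag > 0, diag, np.nan))
    return joint, res, ses, se_ok


def _theta_to_params(theta, names, beta_mode, config: FitConfig, p: int) -> MovementParams:
    A0 = theta[0]
    A = theta[1 : 1 + p]
    eps1 = float(np.exp(theta[1 + p]))
    if beta_mode == "latent":
        return MovementParams(A0=A0, A=A, eps1=eps1, B0=theta[2 + p], B=theta[3 + p :], eps2=config.eps2)
    if beta_mode == "scalar":
        return MovementParams(A0=A0, A=A, eps1=eps1, B0=theta[2 + p], B=None, eps2=config.eps2)
    return MovementParams(
        A0=A0,
        A=A,
        eps1=eps1,
        B0=config.beta_fix_threshold,
        B=None,
        eps2=config.eps2,
        beta_fixed_flag=True,
        beta_fixed_value=config.beta_fix_threshold,
    )


def fit(
    track: ArgosTrack,
    stack: CovariateStack | None = None,
    config: FitConfig | None = None,
    X: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    when=None,
) -> FittedCTCRW:
    """Two-stage fit of the covariate-driven CTCRW to one track.

    Stage 1 fits a constant-parameter CTCRW by maximum likelihood and
    smooths it to estimate true locations.  Covariates are extracted at
    those locations (3-km-radius means), standardized, and the covariate
    model is fit by minimizing the Laplace marginal NLL over
    (A0, A, eps_1, B0, B) with eps_2 = 0.01 fixed.  If no covariate effect
    on beta_t reaches the significance threshold the model is refit with a
    single scalar beta; if that estimate exceeds 4 (log scale) it is refit
    with log beta fixed at 4.

    Either ``stack`` (extraction from rasters) or an explicit per-interval
    design matrix ``X`` of standardized covariates must be given.
    """
    config = config or FitConfig()
    z, dt, R = _track_data(track)
    m = len(dt)

    stage1 = _stage1_constant_fit(z, dt, R)
    s1_sigma = np.exp(stage1["log_sigma"])
    s1_beta = np.exp(stage1["log_beta"])
    _, ms, Ps, _, _ = _rts_smooth(z, dt, R, np.full(m, s1_sigma), np.full(m, s1_beta))
    smoothed_xy = ms[:, [0, 2]]

    standardization: dict[str, tuple[float, float]] = {}
    if X is None:
        if stack is None:
            raise ValueError("either a covariate stack or an explicit design matrix is required")
        raw = stack.extract(smoothed_xy, when=when, radius=config.radius_km)
        stats_source = None
        if config.standardize == "stack":
            if not stack.standardization:
                stack.compute_standardization()
            stats_source = stack.standardization
        X_full, standardization = standardize_and_fill(raw, stats_source)
        covariate_names = list(raw.columns)
        # parameter-to-interval attribution: covariates at the interval's
        # ending relocation by default
        X = X_full[1:] if config.attribution == "interval-end" else X_full[:-1]
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != m:
            raise ValueError(f"X must have one row per interval ({m})")
        covariate_names = covariate_names or [f"x{i + 1}" for i in range(X.shape[1])]
    p = X.shape[1]

    theta0 = np.concatenate(
        [
            [stage1["log_sigma"]],
            np.zeros(p),
            [np.log(config.eps1_init)],
            [stage1["log_beta"]],
            np.zeros(p) if config.covariates_on_beta else [],
        ]
    )
    beta_mode = "latent" if config.covariates_on_beta and p > 0 else "scalar"
    if not config.covariates_on_beta:
        theta0 = theta0[: 3 + p]

    joint, res, ses, se_ok = _fit_one_mode(z, dt, R, X, beta_mode, theta0, config)
    pvals = _wald(res.x, ses)

    reduction_applied = False
    if beta_mode == "latent":
        slope_idx = np.arange(3 + p, 3 + 2 * p)
        if not (pvals[slope_idx] < config.significance).any():
            reduction_applied = True
            beta_mode = "scalar"
            theta0 = np.concatenate([res.x[: 2 + p], [res.x[2 + p]]])
            joint, res, ses, se_ok = _fit_one_mode(z, dt, R, X, beta_mode, theta0, config)
            pvals = _wald(res.x, ses)

    fixed_applied = False
    if beta_mode == "scalar" and res.x[2 + p] > config.beta_fix_threshold:
        fixed_applied = True
        beta_mode = "fixed"
        theta0 = res.x[: 2 + p]
        joint, res, ses, se_ok = _fit_one_mode(z, dt, R, X, beta_mode, theta0, config)
        pvals = _wald(res.x, ses)

    params = _theta_to_params(res.x, joint.theta_names(), beta_mode, config, p)
    joint._warm = None  # final states must not depend on optimizer probe order
    details = joint.mode_details(res.x)
    u = details["u"]
    u_sd = details["u_sd"]
    log_sigma = u[:, 0]
    if beta_mode == "latent":
        log_beta = u[:, 1]
        log_beta_se = u_sd[:, 1]
    else:
        log_beta = np.full(m, params.B0)
        log_beta_se = None

    latent = LatentStates(
        positions=details["s"][:, [0, 2]],
        velocities=details["s"][:, [1, 3]],
        position_se=details["s_sd"][:, [0, 2]],
        velocity_se=details["s_sd"][:, [1, 3]],
        log_sigma=log_sigma,
        log_beta=log_beta,
        log_sigma_se=u_sd[:, 0],
        log_beta_se=log_beta_se,
    )

    # pretty parameter names using the covariate labels
    names = []
    for nm in joint.theta_names():
        if nm.startswith("A") and nm != "A0":
            names.append(f"A[{covariate_names[int(nm[1:]) - 1]}]")
        elif nm.startswith("B") and nm != "B0":
            names.append(f"B[{covariate_names[int(nm[1:]) - 1]}]")
        else:
            names.append(nm)

    return FittedCTCRW(
        params=params,
        param_names=names,
        estimates=res.x.copy(),
        std_errors=ses,
        p_values=pvals,
        latent=latent,
        log_likelihood=-float(res.fun),
        convergence={
            "status": int(res.status) if hasattr(res, "status") else 0,
            "success": bool(res.success),
            "n_outer_evals": int(res.nfev),
            "beta_reduced_to_scalar": reduction_applied,
            "beta_fixed": fixed_applied,
            "se_available": se_ok,
        },
        covariate_names=list(covariate_names),
        standardization=standardization,
        X=X,
        stage1=stage1,
        track=track,
    )


def smooth_states(fitted: FittedCTCRW) -> LatentStates:
    """Rauch-Tung-Striebel smoothed states at the fitted latent mode.

    Positions and velocities are re-smoothed with the per-interval
    (sigma_t, beta_t) plugged in at their Laplace mode, which coincides
    with the joint posterior mode used during fitting.
    """
    track = fitted.track
    z, dt, R = _track_data(track)
    sigma = np.exp(fitted.latent.log_sigma)
    beta = np.exp(fitted.latent.log_beta)
    mu1 = fitted.params.A0 + fitted.X @ fitted.params.A
    if fitted.params.beta_mode == "latent":
        mu2 = fitted.params.B0 + fitted.X @ fitted.params.B
    else:
        mu2 = np.full(len(dt), fitted.params.B0)
    v0 = float(np.exp(2.0 * mu1[0] - mu2[0]) / 2.0)
    loglik, ms, Ps, _, _ = _rts_smooth(z, dt, R, sigma, beta, init_velocity_var=v0)
    se = np.sqrt(np.maximum(np.diagonal(Ps, axis1=1, axis2=2), 0.0))
    return LatentStates(
        positions=ms[:, [0, 2]],
        velocities=ms[:, [1, 3]],
        position_se=se[:, [0, 2]],
        velocity_se=se[:, [1, 3]],
        log_sigma=fitted.latent.log_sigma,
        log_beta=fitted.latent.log_beta,
        log_sigma_se=fitted.latent.log_sigma_se,
        log_beta_se=fitted.latent.log_beta_se,
    )
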