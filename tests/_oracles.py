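"""Independent oracles used by the test suite and the acceptance script.

These deliberately avoid the package's banded/sequential filtering code
paths: the track likelihood is evaluated as a dense multivariate normal
built directly from the transition and observation equations, and the
latent-parameter marginal is integrated by Gauss-Hermite product
quadrature over the full latent vector.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp

from movescape._laplace import trans_blocks


def dense_track_loglik(z, dt, R, log_sigma, log_beta, v0var, pos_var0=1.0e6):
    """log p(z | per-interval parameters), batched over leading axis.

    Builds the joint Gaussian of all observed positions explicitly: the
    initial state is N((z_0x, 0, z_0y, 0), diag(pos_var0, v0var, ...)),
    states propagate by the closed-form transition, and each fix adds its
    elliptical error.  ``log_sigma``/``log_beta`` have shape (B, m).
    """
    log_sigma = np.atleast_2d(np.asarray(log_sigma, dtype=float))
    log_beta = np.atleast_2d(np.asarray(log_beta, dtype=float))
    B, m = log_sigma.shape
    n = m + 1
    F2, Q2 = trans_blocks(log_sigma, log_beta, np.asarray(dt, dtype=float)[None, :])
    # per-coordinate state covariance recursion plus cross-time terms
    P = np.zeros((B, n, 2, 2))
    P[:, 0] = np.array([[pos_var0, 0.0], [0.0, v0var]])
    Phi = np.zeros((B, n, n, 2, 2))  # state-transition products: time i -> j
    Phi[:, np.arange(n), np.arange(n)] = np.eye(2)
    for t in range(1, n):
        P[:, t] = F2[:, t - 1] @ P[:, t - 1] @ np.swapaxes(F2[:, t - 1], -1, -2) + Q2[:, t - 1]
        for i in range(t):
            Phi[:, i, t] = F2[:, t - 1] @ Phi[:, i, t - 1]
    C = np.zeros((B, n, n))  # position covariances per coordinate
    for i in range(n):
        for j in range(i, n):
            Cov = P[:, i] @ np.swapaxes(Phi[:, i, j], -1, -2)
            C[:, i, j] = Cov[:, 0, 0]
            C[:, j, i] = Cov[:, 0, 0]
    S = np.zeros((B, 2 * n, 2 * n))  # observation order: x_0..x_{n-1}, y_0..y_{n-1}
    S[:, :n, :n] = C
    S[:, n:, n:] = C
    for t in range(n):
        S[:, t, t] += R[t, 0, 0]
        S[:, n + t, n + t] += R[t, 1, 1]
        S[:, t, n + t] += R[t, 0, 1]
        S[:, n + t, t] += R[t, 0, 1]
    mean = np.concatenate([np.full(n, z[0, 0]), np.full(n, z[0, 1])])
    obs = np.concatenate([z[:, 0], z[:, 1]])
    d = obs - mean
    L = np.linalg.cholesky(S)
    alpha = np.linalg.solve(L, np.broadcast_to(d, (B, 2 * n))[..., None])[..., 0]
    quad = np.sum(alpha**2, axis=1)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    return -0.5 * quad - 0.5 * logdet - n * np.log(2.0 * np.pi)


def quadrature_marginal_nll(
    z, dt, R, mu1, eps1, mu2, eps2, n_sigma=16, n_beta=6, chunk=40_000
):
    """Marginal NLL by Gauss-Hermite product quadrature over all latents.

    Integrates log sigma_t ~ N(mu1_t, eps1) and log beta_t ~ N(mu2_t,
    eps2) exactly to quadrature precision; the per-node track likelihood
    is the dense multivariate normal above.  Feasible for a handful of
    intervals only.
    """
    m = len(dt)
    xs, ws = hermegauss(n_sigma)  # sum w f(x) ~ int f(x) e^(-x^2/2) dx
    xb, wb = hermegauss(n_beta)
    grids = [mu1[t] + eps1 * xs for t in range(m)] + [mu2[t] + eps2 * xb for t in range(m)]
    logws = [np.log(ws) - 0.5 * np.log(2 * np.pi)] * m + [
        np.log(wb) - 0.5 * np.log(2 * np.pi)
    ] * m
    mesh = np.meshgrid(*grids, indexing="ij")
    wmesh = np.meshgrid(*logws, indexing="ij")
    U = np.stack([g.ravel() for g in mesh], axis=1)
    LW = np.sum([w.ravel() for w in wmesh], axis=0)
    v0var = float(np.exp(2 * mu1[0] - mu2[0]) / 2.0)
    parts = []
    for s in range(0, len(U), chunk):
        ls = U[s : s + chunk, :m]
        lb = U[s : s + chunk, m:]
        ll = dense_track_loglik(z, dt, R, ls, lb, v0var)
        parts.append(ll + LW[s : s + chunk])
    return -float(logsumexp(np.concatenate(parts)))


def exact_ou_moments(beta, sigma, dt, n_sim, rng, n_substeps=64):
    """Sample moments of the integrated-OU transition via fine substepping.

    Composes many exact small steps, which is itself exact, so the sample
    mean/covariance of the terminal (position, velocity) converge to the
    closed-form transition moments.
    """
    sub_dt = dt / n_substeps
    F2, Q2 = trans_blocks(np.log(sigma), np.log(beta), sub_dt)
    F2 = np.asarray(F2, dtype=float)
    L = np.linalg.cholesky(np.asarray(Q2, dtype=float))
    state = np.zeros((n_sim, 2))
    state[:, 1] = 1.0  # deterministic start v = 1, x = 0
    for _ in range(n_substeps):
        state = state @ F2.T + rng.standard_normal((n_sim, 2)) @ L.T
    return state.mean(axis=0), np.cov(state.T)


def ellipse_mc_covariance(semi_major, semi_minor, orientation_deg, n, rng):
    """Sample covariance of points drawn uniformly-angled on an ellipse (m^2)."""
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    c = np.radians(orientation_deg)
    a_hat = np.array([np.sin(c), np.cos(c)])  # (east, north) of the major axis
    b_hat = np.array([np.cos(c), -np.sin(c)])
    pts = (
        semi_major * np.cos(phi)[:, None] * a_hat[None, :]
        + semi_minor * np.sin(phi)[:, None] * b_hat[None, :]
    )
    return np.cov(pts.T, bias=True)
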