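"""Batched weighted least-squares fitting of cumulative-Gaussian curves.

Neurometric curves map headings to choice probabilities through
``P(h) = Phi((h - mu) / sigma)``.  Bootstrap reliability screens and
sliding-window analyses refit this two-parameter curve tens of thousands of
times, so the solver is a vectorized Levenberg-Marquardt iteration over a
whole batch of problems at once (probit-regression initialization, damping
adapted per problem).  Parameters are ``mu`` and ``log sigma`` so that
``sigma > 0`` is structural.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["fit_cum_gauss_batch", "fit_cum_gauss"]

# Convergence envelope: fits escaping these bounds are flagged unreliable.
MU_MAX_DEG = 90.0
SIGMA_MIN_DEG = 0.05
SIGMA_MAX_DEG = 150.0

# Internal clipping box (wider than the convergence envelope so estimates can
# wander out and be flagged rather than sticking at the boundary).
_MU_BOX = 500.0
_LOG_SIGMA_BOX = (np.log(1e-3), np.log(1e4))


def _probit_init(h: np.ndarray, p: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted linear regression in probit space -> (mu0, sigma0) per batch row."""
    y = ndtri(np.clip(p, 0.01, 0.99))  # (B, H)
    sw = w.sum(axis=1, keepdims=True)
    hb = (w * h).sum(axis=1, keepdims=True) / sw
    yb = (w * y).sum(axis=1, keepdims=True) / sw
    cov = (w * (h - hb) * (y - yb)).sum(axis=1)
    var = (w * (h - hb) ** 2).sum(axis=1)
    slope = cov / np.maximum(var, 1e-12)
    # slope = 1/sigma; flat or inverted rows start wide and centered
    sigma0 = np.where(slope > 1e-3, 1.0 / np.maximum(slope, 1e-3), 50.0)
    mu0 = np.where(slope > 1e-3, hb[:, 0] - yb[:, 0] * sigma0, 0.0)
    return mu0, np.clip(sigma0, 0.5, 200.0)


def fit_cum_gauss_batch(
    headings: np.ndarray,
    p: np.ndarray,
    weights: np.ndarray | None = None,
    n_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``P = Phi((h - mu)/sigma)`` to each row of ``p`` by weighted least squares.

    Parameters
    ----------
    headings:
        Shape ``(H,)`` stimulus values shared by all batch rows.
    p:
        Shape ``(B, H)`` observed probabilities in [0, 1].
    weights:
        Shape ``(H,)`` or ``(B, H)`` nonnegative weights (e.g. trials per
        heading).  Uniform if omitted.

    Returns
    -------
    mu, sigma, converged:
        Arrays of shape ``(B,)``; ``converged`` is False where the optimum
        escaped the reliability envelope (|mu| > 90 deg or sigma outside
        [0.05, 150] deg) or the input was degenerate.
    """
    h = np.asarray(headings, dtype=float)
    p = np.atleast_2d(np.asarray(p, dtype=float))
    B, H = p.shape
    if h.shape != (H,):
        raise ValueError("headings must have shape (H,) matching p columns")
    if weights is None:
        w = np.ones((B, H))
    else:
        w = np.asarray(weights, dtype=float)
        w = np.broadcast_to(w, (B, H)).copy()
    w = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-12)

    mu, sigma = _probit_init(h, p, w)
    s = np.log(sigma)

    def cost(mu_, s_):
        f = ndtr((h[None, :] - mu_[:, None]) / np.exp(s_)[:, None])
        return (w * (f - p) ** 2).sum(axis=1)

    lam = np.full(B, 1e-3)
    c = cost(mu, s)
    inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)
    for _ in range(n_iter):
        sig = np.exp(s)[:, None]
        u = (h[None, :] - mu[:, None]) / sig
        f = ndtr(u)
        phi = inv_sqrt2pi * np.exp(-0.5 * u * u)
        r = f - p
        # Jacobian wrt (mu, s): df/dmu = -phi/sigma ; df/ds = -phi*u
        j_mu = -phi / sig
        j_s = -phi * u
        a11 = (w * j_mu * j_mu).sum(axis=1)
        a12 = (w * j_mu * j_s).sum(axis=1)
        a22 = (w * j_s * j_s).sum(axis=1)
        g1 = (w * j_mu * r).sum(axis=1)
        g2 = (w * j_s * r).sum(axis=1)
        d11 = a11 * (1.0 + lam) + 1e-12
        d22 = a22 * (1.0 + lam) + 1e-12
        det = d11 * d22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dmu = -(d22 * g1 - a12 * g2) / det
        ds = -(d11 * g2 - a12 * g1) / det
        mu_new = np.clip(mu + dmu, -_MU_BOX, _MU_BOX)
        s_new = np.clip(s + ds, *_LOG_SIGMA_BOX)
        c_new = cost(mu_new, s_new)
        better = c_new < c
        mu = np.where(better, mu_new, mu)
        s = np.where(better, s_new, s)
        c = np.where(better, c_new, c)
        lam = np.where(better, np.maximum(lam / 3.0, 1e-8), np.minimum(lam * 10.0, 1e8))

    sigma = np.exp(s)
    converged = (
        np.isfinite(c)
        & (np.abs(mu) <= MU_MAX_DEG)
        & (sigma >= SIGMA_MIN_DEG)
        & (sigma <= SIGMA_MAX_DEG)
    )
    return mu, sigma, converged


def fit_cum_gauss(
    headings: np.ndarray, p: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float, bool]:
    """Single-curve convenience wrapper around :func:`fit_cum_gauss_batch`."""
    mu, sigma, ok = fit_cum_gauss_batch(headings, np.asarray(p)[None, :], weights)
    return float(mu[0]), float(sigma[0]), bool(ok[0])
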