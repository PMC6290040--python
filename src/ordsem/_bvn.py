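"""Standard bivariate normal CDF via Owen's T function.

Owen (1956): for standard normal (X, Y) with correlation rho,

    P(X <= h, Y <= k) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta,

with a_h = (k - rho h)/(h sqrt(1-rho^2)), a_k symmetric, and beta = 1/2
when h k < 0 or h k = 0 with h + k < 0, else 0.  scipy's ``owens_t`` is
vectorized, which makes this far faster per rectangle-probability batch
than generic multivariate-normal quadrature; the generic scipy CDF serves
as the oracle in tests.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "bvn_pdf", "cell_probs", "cell_prob_derivs"]

_EPS = 1e-13


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal, vectorized in h, k."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if abs(rho) >= 1.0 - 1e-12:
        # degenerate: Y = +-X
        if rho > 0:
            return ndtr(np.minimum(h, k))
        return np.clip(ndtr(h) + ndtr(k) - 1.0, 0.0, None)
    # nudge exact zeros off the removable singularity of a_h, a_k
    hs = np.where(np.abs(h) < _EPS, _EPS, h)
    ks = np.where(np.abs(k) < _EPS, _EPS, k)
    denom = np.sqrt(1.0 - rho * rho)
    ah = (ks - rho * hs) / (hs * denom)
    ak = (hs - rho * ks) / (ks * denom)
    beta = np.where(
        (hs * ks < 0) | ((hs * ks == 0) & (hs + ks < 0)), 0.5, 0.0
    )
    val = 0.5 * (ndtr(hs) + ndtr(ks)) - owens_t(hs, ah) - owens_t(ks, ak) - beta
    return np.clip(val, 0.0, 1.0)


def bvn_pdf(h, k, rho: float):
    """Standard bivariate normal density at (h, k); zero at infinite points."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    om = 1.0 - rho * rho
    with np.errstate(invalid="ignore", over="ignore"):
        expo = -(h * h - 2.0 * rho * h * k + k * k) / (2.0 * om)
        out = np.exp(expo) / (2.0 * np.pi * np.sqrt(om))
    return np.where(np.isfinite(h) & np.isfinite(k), np.nan_to_num(out), 0.0)


def _cdf_grid(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """CDF at the full threshold grid, thresholds extended by -inf/+inf."""
    gx = np.concatenate(([-np.inf], tau_x, [np.inf]))
    gy = np.concatenate(([-np.inf], tau_y, [np.inf]))
    F = np.zeros((gx.size, gy.size))
    # interior
    H, K = np.meshgrid(gx[1:-1], gy[1:-1], indexing="ij")
    F[1:-1, 1:-1] = bvn_cdf(H, K, rho)
    F[-1, 1:-1] = ndtr(gy[1:-1])  # h = +inf
    F[1:-1, -1] = ndtr(gx[1:-1])  # k = +inf
    F[-1, -1] = 1.0
    return F


def cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """(Kx x Ky) rectangle probabilities of the categorized bivariate normal."""
    F = _cdf_grid(np.asarray(tau_x, float), np.asarray(tau_y, float), rho)
    return np.diff(np.diff(F, axis=0), axis=1)


def cell_prob_derivs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """d cell_probs / d rho via Plackett's identity (density at the corners)."""
    gx = np.concatenate(([-np.inf], np.asarray(tau_x, float), [np.inf]))
    gy = np.concatenate(([-np.inf], np.asarray(tau_y, float), [np.inf]))
    H, K = np.meshgrid(gx, gy, indexing="ij")
    D = bvn_pdf(H, K, rho)
    return np.diff(np.diff(D, axis=0), axis=1)
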