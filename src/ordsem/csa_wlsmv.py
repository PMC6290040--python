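"""Two-step ordinal estimation: thresholds, polychoric correlations, DWLS.

Step one estimates each variable's thresholds from its univariate margin
(normal quantiles of cumulative proportions).  Step two estimates each
pair's polychoric correlation by maximizing the bivariate-normal
multinomial likelihood of the contingency table with thresholds held fixed
(Olsson's two-step method).  The structural model is then fitted to the
polychoric correlations by diagonally weighted least squares,

    F_DWLS = [s - sigma(theta)]' Omega_D^{-1} [s - sigma(theta)],

where Omega_D holds delta-method estimates of the asymptotic variances of
the sample statistics.  The delta parameterization is used: latent
responses have unit variance, thresholds are free parameters fitted at
their first-stage values (so only the correlation part carries model
structure), and the implied latent-response correlation matrix has unit
diagonal with structural residual variances solved for standardized
latent variables.

Convergence accounting: a replication is recorded as improper when the
assembled polychoric correlation matrix is not positive definite or the
fitted solution implies a negative uniqueness or residual variance (the
non-positive-definite-matrix notion of a Heywood case), and as
non-converged when a polychoric estimate sits at the correlation bound,
a weight is non-finite, or the optimizer fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._bvn import cell_probs, cell_prob_derivs
from .model import EDGES, LATENTS, ModelSpec, INDICATORS, _loading_pattern
from .ordinal import OrdinalDataset

__all__ = [
    "PolychoricSummary",
    "DwlsFit",
    "CsaDwls",
    "estimate_thresholds",
    "polychoric_pair",
    "polychoric_summary",
    "asy_diag",
    "implied_polychoric_structure",
    "fit_dwls",
]

_LAT_IDX = {name: k for k, name in enumerate(LATENTS)}
_RHO_BOUND = 0.999
#: Boundary below which a variance ratio or latent-correlation eigenvalue
#: counts as collapsed onto an inadmissible solution.
_BOUNDARY = 5e-3

#: Unordered indicator pairs in row-major order of the upper triangle.
PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(20), 2))


@dataclass
class PolychoricSummary:
    """First-stage sample statistics and bookkeeping.

    ``thresholds`` is one strictly-increasing array per variable (length
    may fall below K-1 when unobserved extreme categories were collapsed);
    ``rho`` holds the 190 pairwise polychoric estimates in ``PAIRS`` order.
    """

    thresholds: list[np.ndarray]
    rho: np.ndarray
    collapsed: list[int]
    boundary_pairs: list[int]

    def corr_matrix(self) -> np.ndarray:
        R = np.eye(20)
        for p, (i, j) in enumerate(PAIRS):
            R[i, j] = R[j, i] = self.rho[p]
        return R

    @property
    def vector(self) -> np.ndarray:
        """Thresholds (variable-major) followed by correlations."""
        return np.concatenate([*self.thresholds, self.rho])


def estimate_thresholds(column: np.ndarray, K: int) -> tuple[np.ndarray, bool]:
    """Normal-quantile thresholds from the univariate margin.

    Empty categories are collapsed into their neighbor (thresholds are
    placed only at boundaries between observed categories).  Returns the
    threshold vector and a flag marking whether any collapsing happened.
    """
    counts = np.bincount(column.astype(int), minlength=K + 1)[1:]
    observed = np.flatnonzero(counts)
    if observed.size < 2:
        raise ValueError("fewer than two observed categories")
    n = counts.sum()
    cum = np.cumsum(counts[observed])[:-1] / n
    tau = stats.norm.ppf(cum)
    return tau, bool(observed.size < K)


def _recode(column: np.ndarray) -> np.ndarray:
    """Codes 0..m-1 over observed categories (collapsing preserved order)."""
    _, inv = np.unique(column, return_inverse=True)
    return inv


def _pair_negloglik(rho: float, table: np.ndarray, tau_x, tau_y) -> float:
    p = np.clip(cell_probs(tau_x, tau_y, rho), 1e-12, None)
    return -float(np.sum(table * np.log(p)))


def polychoric_pair(table: np.ndarray, tau_x: np.ndarray, tau_y: np.ndarray) -> tuple[float, bool]:
    """Two-step polychoric correlation for one contingency table.

    Maximizes the bivariate-normal multinomial likelihood over rho with the
    thresholds fixed.  Returns (rho_hat, at_bound flag).
    """
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == table.sum()) or np.any(table.sum(axis=1) == table.sum()):
        raise ValueError("all mass in a single row or column")
    res = optimize.minimize_scalar(
        _pair_negloglik,
        args=(table, tau_x, tau_y),
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-7},
    )
    rho = float(res.x)
    return rho, bool(abs(rho) >= _RHO_BOUND - 1e-4)


def polychoric_summary(data: OrdinalDataset) -> PolychoricSummary:
    """Thresholds and all 190 pairwise polychoric correlations."""
    X = data.values
    K = data.category_count
    thresholds, collapsed = [], []
    codes = np.empty_like(X)
    for j in range(20):
        tau, flagged = estimate_thresholds(X[:, j], K)
        thresholds.append(tau)
        codes[:, j] = _recode(X[:, j])
        if flagged:
            collapsed.append(j)
    m = [t.size + 1 for t in thresholds]
    rho = np.empty(len(PAIRS))
    boundary = []
    for p, (i, j) in enumerate(PAIRS):
        table = np.zeros((m[i], m[j]))
        np.add.at(table, (codes[:, i], codes[:, j]), 1.0)
        rho[p], at_bound = polychoric_pair(table, thresholds[i], thresholds[j])
        if at_bound:
            boundary.append(p)
    return PolychoricSummary(thresholds, rho, collapsed, boundary)


def asy_diag(data: OrdinalDataset, summary: PolychoricSummary) -> np.ndarray:
    """Delta-method asymptotic variances aligned with ``summary.vector``.

    Thresholds: Var(tau_k) = c_k (1 - c_k) / (n phi(tau_k)^2) with c_k the
    cumulative proportion.  Correlations: inverse Fisher information for
    rho with thresholds treated as known, 1 / (n sum (dp/drho)^2 / p).
    """
    n = data.n
    out = []
    for tau in summary.thresholds:
        c = stats.norm.cdf(tau)
        out.append(c * (1.0 - c) / (n * stats.norm.pdf(tau) ** 2))
    info = np.empty(len(PAIRS))
    for p, (i, j) in enumerate(PAIRS):
        ti, tj = summary.thresholds[i], summary.thresholds[j]
        probs = np.clip(cell_probs(ti, tj, summary.rho[p]), 1e-12, None)
        dp = cell_prob_derivs(ti, tj, summary.rho[p])
        info[p] = float(np.sum(dp * dp / probs))
    out.append(1.0 / (n * info))
    return np.concatenate(out)


def _latent_cov_free(paths: dict[str, float], phi: float):
    """Standardized latent covariance; residual variances may go negative."""
    A = np.zeros((5, 5))
    for edge, value in paths.items():
        t, s = EDGES[edge]
        A[_LAT_IDX[t], _LAT_IDX[s]] = value
    cov = np.zeros((5, 5))
    cov[:2, :2] = [[1.0, phi], [phi, 1.0]]
    psi = np.empty(3)
    for j in range(2, 5):
        a = A[j, :j]
        cov[j, :j] = cov[:j, :j] @ a
        cov[:j, j] = cov[j, :j]
        psi[j - 2] = 1.0 - float(a @ cov[:j, :j] @ a)
        cov[j, j] = 1.0
    return cov, psi


class _DwlsParamMap:
    """theta = [loadings (20) | paths | atanh(phi)] on the correlation scale."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.edges = tuple(spec.path_edges)
        self.size = 20 + len(self.edges) + 1
        self.pattern = _loading_pattern()

    def start(self) -> np.ndarray:
        x = np.zeros(self.size)
        x[:20] = 0.7
        return x

    def unpack(self, x: np.ndarray):
        lam = x[:20]
        paths = dict(zip(self.edges, x[20:-1]))
        phi = float(np.tanh(x[-1]))
        return lam, paths, phi


def implied_polychoric_structure(theta: np.ndarray, spec: ModelSpec, pmap=None) -> np.ndarray:
    """Model-implied correlations in PAIRS order (delta parameterization)."""
    pmap = pmap or _DwlsParamMap(spec)
    lam_vals, paths, phi = pmap.unpack(np.asarray(theta, float))
    lam = np.zeros((20, 5))
    lam[pmap.pattern] = lam_vals
    lat, _ = _latent_cov_free(paths, phi)
    R = lam @ lat @ lam.T
    iu = np.triu_indices(20, k=1)
    return R[iu]


class DwlsFit:
    """DWLS estimation result on the latent-response correlation scale."""

    def __init__(self, theta_hat, pmap, fdwls_value, iterations, converged, improper, reason=""):
        self.theta_hat = theta_hat
        self._pmap = pmap
        self.fdwls_value = fdwls_value
        self.iterations = iterations
        self.converged = converged
        self.improper = improper
        self.reason = reason

    @property
    def spec(self) -> ModelSpec:
        return self._pmap.spec

    def estimates(self) -> dict[str, float]:
        lam, paths, phi = self._pmap.unpack(self.theta_hat)
        out = {f"lam_{name}": float(v) for name, v in zip(INDICATORS, lam)}
        out.update({e: float(v) for e, v in paths.items()})
        out["phi"] = phi
        return out


def fit_dwls(
    rho: np.ndarray,
    weights: np.ndarray,
    spec: ModelSpec,
    max_fun: int = 10_000,
) -> DwlsFit:
    """Minimize F_DWLS over loadings, paths and phi.

    ``rho`` are the 190 sample polychoric correlations in PAIRS order and
    ``weights`` the matching diagonal entries of Omega_D (any positive
    rescaling leaves the minimizer unchanged).  Thresholds drop out of the
    criterion because they are free parameters fitted at their first-stage
    values.
    """
    pmap = _DwlsParamMap(spec)
    w_inv = 1.0 / np.asarray(weights, float)

    def objective(x: np.ndarray) -> float:
        resid = rho - implied_polychoric_structure(x, spec, pmap)
        return float(resid @ (w_inv * resid))

    res = optimize.minimize(
        objective,
        pmap.start(),
        method="L-BFGS-B",
        options={"maxfun": max_fun, "maxiter": max_fun, "ftol": 1e-14, "gtol": 1e-8},
    )
    lam, paths, phi = pmap.unpack(res.x)
    lat, psi = _latent_cov_free(paths, phi)
    improper = bool(
        np.any(1.0 - lam**2 <= 0)
        or np.any(psi <= 0)
        or np.linalg.eigvalsh(lat)[0] <= _BOUNDARY
    )
    return DwlsFit(res.x, pmap, float(res.fun), int(res.nit), bool(res.success), improper, res.message)


class CsaDwls(BaseEstimator):
    """Scikit-learn style WLSMV point estimator (two-step + DWLS).

    Fitted attributes: ``estimates_`` (standardized, or None), ``fdwls_``,
    ``converged_``, ``improper_``, ``status_``, ``summary_``.
    """

    def __init__(self, spec: ModelSpec | None = None, max_fun: int = 10_000):
        self.spec = spec
        self.max_fun = max_fun

    def fit(self, X: OrdinalDataset, y=None):
        spec = self.spec if self.spec is not None else ModelSpec()
        try:
            summary = polychoric_summary(X)
        except ValueError:
            self._mark("degenerate")
            return self
        self.summary_ = summary
        if summary.boundary_pairs:
            self._mark("nonconverged", reason="polychoric estimate at bound")
            return self
        if np.linalg.eigvalsh(summary.corr_matrix())[0] <= 0:
            self._mark("improper", reason="polychoric correlation matrix not PD")
            return self
        w = asy_diag(X, summary)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            self._mark("nonconverged", reason="non-finite weights")
            return self
        rho_w = w[-len(PAIRS):]
        res = fit_dwls(summary.rho, rho_w, spec, max_fun=self.max_fun)
        self.fdwls_ = res.fdwls_value
        self.n_iter_ = res.iterations
        self.converged_ = res.converged and not res.improper
        self.improper_ = res.improper
        self.reason_ = res.reason
        if res.converged and not res.improper:
            self.status_ = "converged"
            self.estimates_ = res.estimates()
        else:
            self.status_ = "improper" if res.improper else "nonconverged"
            self.estimates_ = None
        return self

    def _mark(self, status: str, reason: str = "") -> None:
        self.status_ = status
        self.reason_ = reason or status
        self.estimates_ = None
        self.converged_ = False
        self.improper_ = status == "improper"
        self.fdwls_ = np.nan
        self.n_iter_ = 0
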