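"""Covariance structure analysis by normal-theory maximum likelihood.

The ordinal codes are treated as continuous: the input is their Pearson
covariance matrix S and the discrepancy minimized is

    F_ML = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - r,

where Sigma(theta) is the implied covariance of the five-factor model
(exogenous factor variances fixed at 1 for identification, endogenous
structural residual variances free).  Variance parameters are carried on a
log scale inside the optimizer and the exogenous correlation on an atanh
scale, so every iterate yields a proper covariance algebra; improper
(Heywood) solutions show up as variance estimates collapsing onto the zero
boundary and are flagged after the fit.

A replication is recorded as non-converged when the optimizer fails, when
the sample size does not exceed the free-parameter count of the mean-and-
covariance model (20 intercepts + 20 loadings + paths + phi + 3 residual
variances + 20 uniquenesses), or when the solution is improper; such
replications are excluded from recovery metrics, mirroring the convergence
accounting of standard SEM software.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .model import EDGES, LATENTS, ModelSpec, INDICATORS, _loading_pattern
from .ordinal import OrdinalDataset

__all__ = [
    "MlFit",
    "CsaMl",
    "sample_cov",
    "implied_cov",
    "fml",
    "fit_ml",
    "detect_improper",
    "standardize_solution",
]

_LAT_IDX = {name: k for k, name in enumerate(LATENTS)}

#: Relative boundary below which a variance estimate counts as collapsed.
_BOUNDARY = 5e-3


def sample_cov(data: OrdinalDataset | np.ndarray) -> np.ndarray:
    """Pearson covariance (denominator n-1) of the integer codes."""
    X = data.values if isinstance(data, OrdinalDataset) else np.asarray(data)
    X = X.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need n >= 2")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("degenerate indicator: constant column")
    return np.cov(X, rowvar=False, ddof=1)


class _MlParamMap:
    """Vector <-> structured parameter bookkeeping for one ModelSpec."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.edges = tuple(spec.path_edges)
        self.n_load = 20
        self.n_path = len(self.edges)
        # layout: loadings | paths | atanh(phi) | log(psi) x3 | log(theta) x20
        self.size = self.n_load + self.n_path + 1 + 3 + 20
        self.pattern = _loading_pattern()

    def start(self, S: np.ndarray) -> np.ndarray:
        d = np.diag(S)
        x = np.zeros(self.size)
        x[: self.n_load] = 0.5 * np.sqrt(d)
        # paths, atanh(phi) start at 0; psi at log(1)=0
        x[self.n_load + self.n_path + 1 + 3 :] = np.log(0.75 * d)
        return x

    def unpack(self, x: np.ndarray):
        k = self.n_load
        lam_vals = x[:k]
        paths = dict(zip(self.edges, x[k : k + self.n_path]))
        k += self.n_path
        phi = float(np.tanh(x[k]))
        psi = np.exp(x[k + 1 : k + 4])
        theta_u = np.exp(x[k + 4 :])
        return lam_vals, paths, phi, psi, theta_u


def _latent_cov(paths: dict[str, float], phi: float, psi: np.ndarray) -> np.ndarray:
    """Latent covariance for raw (unstandardized) structural parameters."""
    A = np.zeros((5, 5))
    for edge, value in paths.items():
        t, s = EDGES[edge]
        A[_LAT_IDX[t], _LAT_IDX[s]] = value
    cov_u = np.zeros((5, 5))
    cov_u[:2, :2] = [[1.0, phi], [phi, 1.0]]
    cov_u[2:, 2:] = np.diag(psi)
    inv = np.linalg.solve(np.eye(5) - A, np.eye(5))
    return inv @ cov_u @ inv.T


def implied_cov(theta: np.ndarray, spec: ModelSpec, pmap: _MlParamMap | None = None) -> np.ndarray:
    """Model-implied 20x20 covariance Sigma(theta)."""
    pmap = pmap or _MlParamMap(spec)
    lam_vals, paths, phi, psi, theta_u = pmap.unpack(np.asarray(theta, float))
    lam = np.zeros((20, 5))
    lam[pmap.pattern] = lam_vals
    lat = _latent_cov(paths, phi, psi)
    sigma = lam @ lat @ lam.T
    sigma[np.diag_indices(20)] += theta_u
    return sigma


def _fml_grad(S: np.ndarray, x: np.ndarray, spec: ModelSpec, pmap: "_MlParamMap") -> np.ndarray:
    """Analytic gradient of F_ML on the transformed parameter scale.

    Uses dF = tr[Sigma^-1 (Sigma - S) Sigma^-1 dSigma] with the chain rule
    through Sigma = Lambda G Lambda' + diag(theta_u),
    G = (I-A)^-1 blockdiag(Phi, diag(psi)) (I-A)^-T.
    """
    lam_vals, paths, phi, psi, theta_u = pmap.unpack(x)
    lam = np.zeros((20, 5))
    lam[pmap.pattern] = lam_vals
    A = np.zeros((5, 5))
    for edge, value in paths.items():
        t, s = EDGES[edge]
        A[_LAT_IDX[t], _LAT_IDX[s]] = value
    cov_u = np.zeros((5, 5))
    cov_u[:2, :2] = [[1.0, phi], [phi, 1.0]]
    cov_u[2:, 2:] = np.diag(psi)
    E = np.linalg.solve(np.eye(5) - A, np.eye(5))
    G = E @ cov_u @ E.T
    sigma = lam @ G @ lam.T
    sigma[np.diag_indices(20)] += theta_u
    sig_inv = np.linalg.solve(sigma, np.eye(20))
    M = sig_inv - sig_inv @ S @ sig_inv  # dF = tr(M dSigma)

    grad = np.empty(pmap.size)
    MLG = M @ lam @ G  # 20 x 5
    for idx, (j, d) in enumerate(zip(*np.where(pmap.pattern))):
        grad[idx] = 2.0 * MLG[j, d]
    N1 = lam.T @ M @ lam  # 5 x 5, symmetric
    GNE = G @ N1 @ E  # for dA
    k = pmap.n_load
    for i, edge in enumerate(pmap.edges):
        t, s = EDGES[edge]
        grad[k + i] = 2.0 * GNE[_LAT_IDX[s], _LAT_IDX[t]]
    ENE = E.T @ N1 @ E
    grad[k + pmap.n_path] = 2.0 * ENE[0, 1] * (1.0 - phi * phi)  # atanh chain
    for j in range(3):
        grad[k + pmap.n_path + 1 + j] = ENE[2 + j, 2 + j] * psi[j]  # log chain
    grad[k + pmap.n_path + 4 :] = np.diag(M) * theta_u  # log chain
    return grad


def fml(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy; zero iff Sigma == S."""
    r = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise np.linalg.LinAlgError("F_ML requires positive definite matrices")
    return float(logdet_m + np.trace(np.linalg.solve(Sigma, S)) - logdet_s - r)


class MlFit:
    """ML estimation result with convergence and admissibility diagnostics."""

    def __init__(self, theta_hat, pmap, fml_value, iterations, converged, improper, reason=""):
        self.theta_hat = theta_hat
        self._pmap = pmap
        self.fml_value = fml_value
        self.iterations = iterations
        self.converged = converged
        self.improper = improper
        self.reason = reason

    @property
    def spec(self) -> ModelSpec:
        return self._pmap.spec

    def natural_params(self):
        return self._pmap.unpack(self.theta_hat)


def _free_param_count(spec: ModelSpec) -> int:
    """Free parameters of the mean-and-covariance model (intercepts included)."""
    return 20 + 20 + len(spec.path_edges) + 1 + 3 + 20


def fit_ml(
    S: np.ndarray,
    spec: ModelSpec,
    n: int,
    max_fun: int = 10_000,
    gtol: float = 1e-6,
) -> MlFit:
    """Quasi-Newton minimization of F_ML from deterministic start values."""
    pmap = _MlParamMap(spec)
    if n <= _free_param_count(spec):
        return MlFit(None, pmap, np.nan, 0, False, False, reason="parameters exceed sample size")
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return MlFit(None, pmap, np.nan, 0, False, False, reason="sample covariance not PD")

    def objective(x: np.ndarray):
        try:
            value = fml(S, implied_cov(x, spec, pmap))
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(pmap.size)
        return value, _fml_grad(S, x, spec, pmap)

    res = optimize.minimize(
        objective,
        pmap.start(S),
        jac=True,
        method="L-BFGS-B",
        options={"maxfun": max_fun, "ftol": 1e-13, "gtol": gtol, "maxiter": max_fun},
    )
    converged = bool(res.success)
    fit = MlFit(res.x, pmap, float(res.fun), int(res.nit), converged, False, reason=res.message)
    fit.improper = detect_improper(fit, diag_s=np.diag(S))
    return fit


def detect_improper(fit: MlFit, diag_s: np.ndarray | None = None) -> bool:
    """Heywood screen: non-positive (or boundary-collapsed) variances or a
    non-PD implied latent covariance.

    Variance ratios are taken on the standardized scale (uniqueness over
    implied indicator variance, structural residual over implied latent
    variance), which is invariant to the scale indeterminacy of the raw
    endogenous-factor parameterization.
    """
    if fit.theta_hat is None:
        return False
    lam_vals, paths, phi, psi, theta_u = fit.natural_params()
    lat = _latent_cov(paths, phi, psi)
    sd = np.sqrt(np.diag(lat))
    # raw-scale lat is PD by construction; a (near-)singular latent
    # correlation is the boundary image of a non-PD latent covariance
    if np.linalg.eigvalsh(lat / np.outer(sd, sd))[0] <= _BOUNDARY:
        return True
    lam = np.zeros((20, 5))
    lam[fit._pmap.pattern] = lam_vals
    sigma_diag = np.einsum("jd,de,je->j", lam, lat, lam) + theta_u
    if np.any(theta_u <= _BOUNDARY * sigma_diag):
        return True
    return bool(np.any(psi <= _BOUNDARY * np.diag(lat)[2:]))


def standardize_solution(fit: MlFit) -> dict[str, float]:
    """Completely standardized estimates keyed like the truth table."""
    if not fit.converged:
        raise ValueError("cannot standardize a non-converged fit")
    lam_vals, paths, phi, psi, theta_u = fit.natural_params()
    lat = _latent_cov(paths, phi, psi)
    sd_lat = np.sqrt(np.diag(lat))
    pat = _loading_pattern()
    lam = np.zeros((20, 5))
    lam[pat] = lam_vals
    sigma = lam @ lat @ lam.T
    sigma[np.diag_indices(20)] += theta_u
    sd_ind = np.sqrt(np.diag(sigma))
    out: dict[str, float] = {}
    for j, name in enumerate(INDICATORS):
        d = int(np.flatnonzero(pat[j])[0])
        out[f"lam_{name}"] = float(lam_vals[j] * sd_lat[d] / sd_ind[j])
    for edge in fit.spec.path_edges:
        t, s = EDGES[edge]
        out[edge] = float(paths[edge] * sd_lat[_LAT_IDX[s]] / sd_lat[_LAT_IDX[t]])
    lat_corr = lat / np.outer(sd_lat, sd_lat)
    out["phi"] = float(lat_corr[0, 1])
    return out


class CsaMl(BaseEstimator):
    """Scikit-learn style ML engine operating on raw ordinal data.

    ``fit`` computes the Pearson covariance of the codes and minimizes
    F_ML.  Fitted attributes: ``estimates_`` (standardized, or None),
    ``fml_``, ``converged_``, ``improper_``, ``n_iter_``, ``status_``.
    """

    def __init__(self, spec: ModelSpec | None = None, max_fun: int = 10_000, gtol: float = 1e-6):
        self.spec = spec
        self.max_fun = max_fun
        self.gtol = gtol

    def fit(self, X, y=None):
        spec = self.spec if self.spec is not None else ModelSpec()
        n = X.n if isinstance(X, OrdinalDataset) else np.asarray(X).shape[0]
        try:
            S = sample_cov(X)
        except ValueError:
            self._mark("degenerate")
            return self
        res = fit_ml(S, spec, n, max_fun=self.max_fun, gtol=self.gtol)
        self.fml_ = res.fml_value
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        self.improper_ = res.improper
        self.reason_ = res.reason
        if res.converged and not res.improper:
            self.status_ = "converged"
            self.estimates_ = standardize_solution(res)
        else:
            self.status_ = "improper" if res.improper else "nonconverged"
            self.estimates_ = None
        return self

    def _mark(self, status: str) -> None:
        self.status_ = status
        self.estimates_ = None
        self.converged_ = False
        self.improper_ = False
        self.fml_ = np.nan
        self.n_iter_ = 0
        self.reason_ = status
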