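"""Generalized structured component analysis estimated by alternating least squares.

GSCA treats each latent variable as an exact weighted composite of its
indicators, gamma = W z.  With V = [I; W] and A = [C; B] stacked from the
loading matrix C and the path matrix B, the model reads V z = A W z + e and
the estimator minimizes the global least-squares criterion

    phi = sum_i || V z_i - A W z_i ||^2

subject to each component having unit sample variance.  The ALS algorithm
alternates (i) ordinary least-squares updates of the free rows of A for
fixed W with (ii) per-component constrained least-squares updates of W for
fixed A.  On the unit-variance sphere the quadratic term of each component
subproblem is constant, so rescaling the unconstrained least-squares
solution yields the exact constrained minimizer and the criterion can never
increase.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .model import EDGES, LATENTS, ModelSpec, INDICATORS
from .ordinal import OrdinalDataset, standardize_columns

__all__ = ["GscaModel", "GscaFit", "GscaAls", "init_weights", "update_A", "update_W", "fit_gsca", "gsca_estimates"]


class GscaModel:
    """Fixed incidence patterns (W, C, B) derived from a ModelSpec."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.n_ind, self.n_comp = spec.loading_pattern.shape
        self.w_pattern = spec.loading_pattern.T.copy()  # comp x ind
        self.c_pattern = spec.loading_pattern.copy()  # ind x comp
        idx = {name: k for k, name in enumerate(LATENTS)}
        self.b_pattern = np.zeros((self.n_comp, self.n_comp), dtype=bool)
        for edge in spec.path_edges:
            tgt, src = EDGES[edge]
            self.b_pattern[idx[tgt], idx[src]] = True
        self.edge_index = {
            edge: (idx[EDGES[edge][0]], idx[EDGES[edge][1]]) for edge in spec.path_edges
        }


class GscaFit:
    """Result container: estimates, criterion trace and convergence status."""

    def __init__(self, W, C, B, trace, converged):
        self.weight_estimates = W
        self.loading_estimates = C
        self.path_estimates = B
        self.criterion_trace = trace
        self.criterion_value = trace[-1]
        self.iterations = len(trace) - 1
        self.converged = converged


def _criterion(Z: np.ndarray, W: np.ndarray, C: np.ndarray, B: np.ndarray) -> float:
    G = Z @ W.T  # component scores, n x 5
    meas = Z - G @ C.T
    struct = G - G @ B.T
    return float(np.sum(meas**2) + np.sum(struct**2))


def init_weights(model: GscaModel, Z: np.ndarray) -> np.ndarray:
    """Equal weights per block, scaled so each component has unit variance."""
    n = Z.shape[0]
    W = np.zeros((model.n_comp, model.n_ind))
    for d in range(model.n_comp):
        mask = model.w_pattern[d]
        w = mask.astype(float)
        score = Z @ w
        ss = float(score @ score)
        if ss <= 0:
            raise ValueError(f"component {d} has zero variance under equal weights")
        W[d] = w * np.sqrt(n / ss)
    return W


def update_A(W: np.ndarray, Z: np.ndarray, model: GscaModel, C: np.ndarray, B: np.ndarray):
    """Least-squares update of all free rows of A = [C; B] for fixed W.

    Each indicator regresses on its own component; each endogenous
    component regresses on the components entering its equation.  Returns
    new (C, B); fixed-zero entries are untouched.
    """
    G = Z @ W.T
    C = C.copy()
    B = B.copy()
    for j in range(model.n_ind):
        d = int(np.flatnonzero(model.c_pattern[j])[0])
        g = G[:, d]
        C[j, d] = float(g @ Z[:, j]) / float(g @ g)
    for d in range(model.n_comp):
        pred = np.flatnonzero(model.b_pattern[d])
        if pred.size == 0:
            continue
        Gp = G[:, pred]
        coef, *_ = np.linalg.lstsq(Gp, G[:, d], rcond=None)
        B[d, pred] = coef
    return C, B


def update_W(A_C: np.ndarray, A_B: np.ndarray, Z: np.ndarray, model: GscaModel, W: np.ndarray) -> np.ndarray:
    """Per-component constrained least-squares update of W for fixed A.

    For component d, collecting every criterion term in which gamma_d
    appears gives phi(w_d) = sum_m || t_m - alpha_m Z w_d ||^2 with the
    constraint ||Z w_d||^2 = N.  On that sphere the quadratic term is
    constant, so the minimizer is the projection of b = sum_m alpha_m t_m
    onto the span of the block's indicators, rescaled to the sphere.
    Components are updated Gauss-Seidel style (later components see the
    earlier updates).
    """
    n = Z.shape[0]
    W = W.copy()
    C, B = A_C, A_B
    for d in range(model.n_comp):
        G = Z @ W.T
        free = np.flatnonzero(model.w_pattern[d])
        Zf = Z[:, free]
        # b = sum over terms of alpha_m * t_m
        b = np.zeros(n)
        # measurement terms: indicators of block d, t = z_j, alpha = C[j, d]
        for j in free:
            b += C[j, d] * Z[:, j]
        # structural target term (gamma_d as response), alpha = 1
        others = [j for j in range(model.n_comp) if j != d]
        b += G[:, others] @ B[d, others]
        # structural predictor terms (gamma_d predicts gamma_k), alpha = B[k, d]
        for k in others:
            if B[k, d] != 0.0:
                resid_wo_d = G[:, k] - G[:, others] @ B[k, others]
                b += B[k, d] * resid_wo_d
        v, *_ = np.linalg.lstsq(Zf, b, rcond=None)
        score = Zf @ v
        ss = float(score @ score)
        if ss <= 1e-12:
            raise np.linalg.LinAlgError(f"singular weight subproblem for component {d}")
        w = np.zeros(model.n_ind)
        w[free] = v * np.sqrt(n / ss)
        W[d] = w
    return W


def fit_gsca(
    Z: np.ndarray | OrdinalDataset,
    spec: ModelSpec,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GscaFit:
    """Alternate A- and W-updates until the relative drop in phi < tol.

    ``Z`` may be an OrdinalDataset (standardized internally) or an
    already-standardized matrix.  Singular subproblems are reported as
    ``converged=False`` rather than raised.
    """
    if isinstance(Z, OrdinalDataset):
        Z = standardize_columns(Z)
    model = GscaModel(spec)
    W = init_weights(model, Z)
    C = np.zeros((model.n_ind, model.n_comp))
    B = np.zeros((model.n_comp, model.n_comp))
    trace = [_criterion(Z, W, C, B)]
    converged = False
    try:
        for _ in range(max_iter):
            C, B = update_A(W, Z, model, C, B)
            W = update_W(C, B, Z, model, W)
            trace.append(_criterion(Z, W, C, B))
            prev, cur = trace[-2], trace[-1]
            if prev - cur < tol * max(prev, 1.0):
                converged = True
                break
    except np.linalg.LinAlgError:
        converged = False
    W, C, B = _fix_signs(Z, model, W, C, B)
    return GscaFit(W, C, B, trace, converged)


def _fix_signs(Z, model, W, C, B):
    """Resolve component sign indeterminacy.

    Each component is flipped, if needed, so that it correlates positively
    with the first indicator of its block; C columns and B rows/columns
    flip along.
    """
    signs = np.ones(model.n_comp)
    for d in range(model.n_comp):
        first = int(np.flatnonzero(model.w_pattern[d])[0])
        score = Z @ W[d]
        if float(score @ Z[:, first]) < 0:
            signs[d] = -1.0
    S = np.diag(signs)
    return S @ W, C @ S, S @ B @ S


def gsca_estimates(fit: GscaFit, spec: ModelSpec) -> dict[str, float]:
    """Loadings and paths keyed like the population truth table.

    ``phi`` is reported as the correlation between the two exogenous
    component scores' model-side proxy: with standardized components it is
    not a fitted parameter of A, so it is taken from the fitted weights at
    scoring time by callers that need it; here only C/B entries are mapped.
    """
    if not fit.converged:
        raise ValueError("estimates requested from a non-converged GSCA fit")
    model = GscaModel(spec)
    out: dict[str, float] = {}
    for j, name in enumerate(INDICATORS):
        d = int(np.flatnonzero(model.c_pattern[j])[0])
        out[f"lam_{name}"] = float(fit.loading_estimates[j, d])
    for edge, (t, s) in model.edge_index.items():
        out[edge] = float(fit.path_estimates[t, s])
    return out


class GscaAls(BaseEstimator):
    """Scikit-learn style wrapper around the GSCA-ALS fit.

    Parameters
    ----------
    spec : ModelSpec
        Structural layout to fit (correct or misspecified).
    tol, max_iter : float, int
        ALS stopping rule: relative drop of the least-squares criterion.

    Attributes (after ``fit``)
    --------------------------
    weights_, loadings_, paths_ : ndarray
        Estimated W (5x20), C (20x5) and B (5x5) matrices.
    phi_ : float
        Sample correlation of the two exogenous component scores.
    estimates_ : dict
        Named standardized estimates keyed like the truth table.
    criterion_, n_iter_, converged_ : fit diagnostics.
    """

    def __init__(self, spec: ModelSpec | None = None, tol: float = 1e-6, max_iter: int = 500):
        self.spec = spec
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        spec = self.spec if self.spec is not None else ModelSpec()
        Z = standardize_columns(X)
        res = fit_gsca(Z, spec, tol=self.tol, max_iter=self.max_iter)
        self.weights_ = res.weight_estimates
        self.loadings_ = res.loading_estimates
        self.paths_ = res.path_estimates
        self.criterion_ = res.criterion_value
        self.criterion_trace_ = res.criterion_trace
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        G = Z @ self.weights_.T
        self.phi_ = float(np.corrcoef(G[:, 0], G[:, 1])[0, 1])
        if res.converged:
            est = gsca_estimates(res, spec)
            est["phi"] = self.phi_
            self.estimates_ = est
        else:
            self.estimates_ = None
        return self

    def transform(self, X):
        """Component scores for (column-standardized) data X."""
        return standardize_columns(X) @ self.weights_.T
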