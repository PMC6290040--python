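"""Population structural equation model with five latent variables.

The data-generating model has two correlated exogenous latent variables
(``xi1``, ``xi2``) and three endogenous ones (``eta1``, ``eta2``, ``eta3``)
connected by nine directed paths: six gamma paths (exogenous source) and
three beta paths (endogenous source), plus a single exogenous correlation
``phi``.  Each latent variable carries four indicators with standardized
loadings 0.8, 0.7, 0.6 and 0.5, so the full measurement model has 20
indicators.  All latent variables and indicators are standardized: the
structural residual variances are solved so that every latent variable has
unit variance, and each indicator's uniqueness is one minus its squared
loading.

The structural misspecification studied here removes the four weakest
directed paths (``gamma22``, ``gamma31``, ``gamma32``, ``beta31``) from the
fitted model while leaving the measurement model intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LATENTS",
    "LATENT_ROLES",
    "EDGES",
    "OMITTED_EDGES",
    "INDICATORS",
    "DEFAULT_PATHS",
    "DEFAULT_PHI",
    "LOADING_BLOCK",
    "ModelSpec",
    "PopulationParams",
    "build_population_model",
    "misspecify",
    "implied_latent_cov",
    "implied_indicator_cov",
    "truth_table",
]

#: Latent variables in canonical order (exogenous first).
LATENTS: tuple[str, ...] = ("xi1", "xi2", "eta1", "eta2", "eta3")

LATENT_ROLES: dict[str, str] = {
    "xi1": "exogenous",
    "xi2": "exogenous",
    "eta1": "endogenous",
    "eta2": "endogenous",
    "eta3": "endogenous",
}

#: Directed structural edges, name -> (target, source).  ``gammaIJ`` points
#: from exogenous ``xiJ`` to endogenous ``etaI``; ``betaIJ`` from ``etaJ``
#: to ``etaI``.
EDGES: dict[str, tuple[str, str]] = {
    "gamma11": ("eta1", "xi1"),
    "gamma12": ("eta1", "xi2"),
    "gamma21": ("eta2", "xi1"),
    "gamma22": ("eta2", "xi2"),
    "gamma31": ("eta3", "xi1"),
    "gamma32": ("eta3", "xi2"),
    "beta21": ("eta2", "eta1"),
    "beta31": ("eta3", "eta1"),
    "beta32": ("eta3", "eta2"),
}

#: The four weakest paths, dropped under structural misspecification.
OMITTED_EDGES: tuple[str, ...] = ("gamma22", "gamma31", "gamma32", "beta31")

#: Indicator names; indicators 4d..4d+3 load on latent d.
INDICATORS: tuple[str, ...] = tuple(f"i{j + 1}" for j in range(20))

#: Standardized loadings within each latent block, strongest first.
LOADING_BLOCK: tuple[float, ...] = (0.8, 0.7, 0.6, 0.5)

#: Default true path coefficients; the four omitted edges are the weakest.
DEFAULT_PATHS: dict[str, float] = {
    "gamma11": 0.6,
    "gamma12": 0.5,
    "gamma21": 0.4,
    "gamma22": 0.2,
    "gamma31": 0.1,
    "gamma32": 0.1,
    "beta21": 0.4,
    "beta31": 0.1,
    "beta32": 0.3,
}

DEFAULT_PHI: float = 0.3


def _loading_pattern() -> np.ndarray:
    pat = np.zeros((20, 5), dtype=bool)
    for d in range(5):
        pat[4 * d : 4 * d + 4, d] = True
    return pat


@dataclass(frozen=True)
class ModelSpec:
    """Structure (not values) of the five-latent model.

    Attributes
    ----------
    path_edges : tuple of str
        Names of the directed edges present in the structural model.
    misspecified : bool
        True once the four weakest paths have been removed.
    """

    latent_count: int = 5
    latent_roles: dict[str, str] = field(default_factory=lambda: dict(LATENT_ROLES))
    loading_pattern: np.ndarray = field(default_factory=_loading_pattern)
    path_edges: tuple[str, ...] = tuple(EDGES)
    exo_correlation: bool = True
    misspecified: bool = False

    def __post_init__(self) -> None:
        roles = list(self.latent_roles.values())
        if roles.count("exogenous") != 2 or roles.count("endogenous") != 3:
            raise ValueError("model requires 2 exogenous and 3 endogenous latents")
        pat = np.asarray(self.loading_pattern, dtype=bool)
        if pat.shape != (20, 5):
            raise ValueError("loading pattern must be 20x5")
        if not np.all(pat.sum(axis=1) == 1) or not np.all(pat.sum(axis=0) == 4):
            raise ValueError("each indicator loads on exactly one latent, 4 per block")
        unknown = set(self.path_edges) - set(EDGES)
        if unknown:
            raise ValueError(f"unknown structural edges: {sorted(unknown)}")

    @property
    def n_paths(self) -> int:
        return len(self.path_edges)

    def indicator_latent(self, j: int) -> int:
        """Column index of the latent on which indicator ``j`` loads."""
        return int(np.flatnonzero(self.loading_pattern[j])[0])


def misspecify(spec: ModelSpec) -> ModelSpec:
    """Drop the four weakest structural paths, leaving loadings untouched.

    Idempotent: an already-misspecified spec is returned unchanged.  A
    hand-edited spec from which only some of the four edges are missing is
    rejected, because the misspecification operator is defined relative to
    the full nine-edge structural model.
    """
    if spec.misspecified:
        return spec
    missing = [e for e in OMITTED_EDGES if e not in spec.path_edges]
    if missing:
        raise ValueError(f"edges to omit are absent from the spec: {missing}")
    kept = tuple(e for e in spec.path_edges if e not in OMITTED_EDGES)
    return replace(spec, path_edges=kept, misspecified=True)


@dataclass(frozen=True)
class PopulationParams:
    """True standardized parameter values of the population model."""

    loading_values: np.ndarray  # (20,)
    path_values: dict[str, float]
    phi: float
    structural_residual_variances: dict[str, float]  # per endogenous latent
    uniqueness: np.ndarray  # (20,), 1 - loading^2

    @property
    def psi(self) -> np.ndarray:
        return np.array(
            [self.structural_residual_variances[name]
             for name in LATENTS if LATENT_ROLES[name] == "endogenous"]
        )


def _path_matrix(path_values: dict[str, float]) -> np.ndarray:
    """5x5 coefficient matrix A with A[target, source] = path value."""
    idx = {name: k for k, name in enumerate(LATENTS)}
    A = np.zeros((5, 5))
    for edge, value in path_values.items():
        tgt, src = EDGES[edge]
        A[idx[tgt], idx[src]] = value
    return A


def _solve_latent_cov(path_values: dict[str, float], phi: float):
    """Latent covariance with residual variances solved for unit variances.

    Processes the endogenous latents in topological order (the directed
    graph among them is acyclic by construction) and sets each structural
    residual variance to one minus the variance explained by upstream
    latents.

    Returns
    -------
    cov : (5, 5) ndarray
    psi : dict mapping endogenous latent name -> residual variance
    """
    A = _path_matrix(path_values)
    cov = np.zeros((5, 5))
    cov[:2, :2] = np.array([[1.0, phi], [phi, 1.0]])
    psi: dict[str, float] = {}
    for j in range(2, 5):
        a = A[j, :j]
        cov[j, :j] = cov[:j, :j] @ a
        cov[:j, j] = cov[j, :j]
        explained = float(a @ cov[:j, :j] @ a)
        resid = 1.0 - explained
        if resid <= 0:
            raise ValueError(
                f"structural residual variance for {LATENTS[j]} is {resid:.4f} <= 0; "
                "configuration rejected"
            )
        psi[LATENTS[j]] = resid
        cov[j, j] = 1.0
    # positive definiteness of the assembled matrix
    if np.linalg.eigvalsh(cov)[0] <= 0:
        raise ValueError("implied latent covariance is not positive definite")
    return cov, psi


def build_population_model(config: dict | None = None) -> tuple[ModelSpec, PopulationParams]:
    """Construct the correctly specified population model.

    ``config`` may override ``paths`` (dict of the nine edge values),
    ``phi`` and ``loadings`` (the per-block loading quadruple).  Path
    values must lie in [0.1, 0.6] and the four omitted edges must carry
    the smallest absolute values among the nine paths.
    """
    config = config or {}
    paths = dict(DEFAULT_PATHS)
    paths.update(config.get("paths", {}))
    phi = float(config.get("phi", DEFAULT_PHI))
    block = tuple(config.get("loadings", LOADING_BLOCK))

    if set(paths) != set(EDGES):
        raise ValueError("config must supply exactly the nine structural edges")
    for edge, value in paths.items():
        if not (0.1 <= abs(value) <= 0.6):
            raise ValueError(f"path {edge}={value} outside the admissible range [0.1, 0.6]")
    weak_max = max(abs(paths[e]) for e in OMITTED_EDGES)
    kept_min = min(abs(paths[e]) for e in EDGES if e not in OMITTED_EDGES)
    if weak_max > kept_min:
        raise ValueError("the four omitted edges must be the weakest paths")
    if not (-1.0 < phi < 1.0):
        raise ValueError("phi must be a correlation in (-1, 1)")
    if len(block) != 4 or any(not (0 < b < 1) for b in block):
        raise ValueError("block loadings must be four values in (0, 1)")

    _, psi = _solve_latent_cov(paths, phi)
    loadings = np.tile(np.asarray(block, dtype=float), 5)
    params = PopulationParams(
        loading_values=loadings,
        path_values=paths,
        phi=phi,
        structural_residual_variances=psi,
        uniqueness=1.0 - loadings**2,
    )
    return ModelSpec(), params


def implied_latent_cov(params: PopulationParams) -> np.ndarray:
    """Model-implied 5x5 latent covariance (unit diagonal by construction)."""
    cov, _ = _solve_latent_cov(params.path_values, params.phi)
    return cov


def implied_indicator_cov(params: PopulationParams) -> np.ndarray:
    """Model-implied 20x20 indicator covariance on the standardized scale."""
    lat = implied_latent_cov(params)
    lam = np.zeros((20, 5))
    pat = _loading_pattern()
    lam[pat] = params.loading_values
    sigma = lam @ lat @ lam.T
    sigma[np.diag_indices(20)] += params.uniqueness
    return sigma


def truth_table(params: PopulationParams, spec: ModelSpec | None = None) -> dict[str, float]:
    """True standardized values keyed by the shared parameter names.

    When ``spec`` is misspecified, only the retained paths appear (the
    omitted paths are not parameters of the fitted model).
    """
    edges = spec.path_edges if spec is not None else tuple(EDGES)
    out = {f"lam_{name}": float(v) for name, v in zip(INDICATORS, params.loading_values)}
    for edge in edges:
        out[edge] = float(params.path_values[edge])
    out["phi"] = float(params.phi)
    return out
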