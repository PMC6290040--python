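"""Ordinal data generation: continuous factor draws and threshold discretization.

Continuous indicator data follow the common-factor model implied by the
population parameters (all marginals standard normal).  Each indicator is
then cut into K ordered categories at thresholds on the standard-normal
latent-response scale.  Two stored threshold shapes per K reproduce the
study conditions: a symmetric distribution (zero skewness, excess kurtosis
near -0.485) and an asymmetric one (skewness near -1.385, excess kurtosis
near 1.165).  Excess (Fisher) kurtosis is used throughout; ordinal codes
are scored 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .model import PopulationParams, implied_latent_cov, _loading_pattern

__all__ = [
    "ThresholdSet",
    "OrdinalDataset",
    "generate_continuous",
    "ordinal_moments",
    "solve_thresholds",
    "threshold_set",
    "discretize",
    "standardize_columns",
    "SYMMETRIC_TARGETS",
    "ASYMMETRIC_TARGETS",
]

#: Moment targets (skewness, excess kurtosis): midpoints of the study windows.
SYMMETRIC_TARGETS: tuple[float, float] = (0.0, -0.485)
ASYMMETRIC_TARGETS: tuple[float, float] = (-1.385, 1.165)


@dataclass(frozen=True)
class ThresholdSet:
    """K-1 strictly increasing cut-points on the latent-response scale."""

    category_count: int
    tau: tuple[float, ...]
    shape_label: str  # "symmetric" | "asymmetric"

    def __post_init__(self) -> None:
        K = self.category_count
        if not 2 <= K:
            raise ValueError("need at least two categories")
        if len(self.tau) != K - 1:
            raise ValueError("need K-1 thresholds")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def probabilities(self) -> np.ndarray:
        """Category probabilities p_k = Phi(tau_k) - Phi(tau_{k-1})."""
        return _category_probs(np.asarray(self.tau))


@dataclass(frozen=True)
class OrdinalDataset:
    """n x 20 matrix of ordinal codes in 1..K plus condition metadata."""

    values: np.ndarray
    category_count: int
    shape_label: str
    seed: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.shape[1] != 20:
            raise ValueError("ordinal data must be n x 20")
        if vals.min() < 1 or vals.max() > self.category_count:
            raise ValueError("codes must lie in 1..K")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _category_probs(tau: np.ndarray) -> np.ndarray:
    cdf = np.concatenate(([0.0], stats.norm.cdf(tau), [1.0]))
    return np.diff(cdf)


def _moments_from_probs(p: np.ndarray) -> tuple[float, float, float, float]:
    k = np.arange(1, p.size + 1, dtype=float)
    mean = float(p @ k)
    c = k - mean
    var = float(p @ c**2)
    skew = float(p @ c**3) / var**1.5
    exkurt = float(p @ c**4) / var**2 - 3.0
    return mean, var, skew, exkurt


def generate_continuous(
    params: PopulationParams, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw n rows of the 20 continuous indicators.

    Latent scores are drawn from the implied latent covariance and the
    indicators assembled as loading * latent + uniqueness noise, so every
    column has population mean 0 and variance 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lat_cov = implied_latent_cov(params)
    chol = np.linalg.cholesky(lat_cov)
    latent = rng.standard_normal((n, 5)) @ chol.T
    lam = np.zeros((20, 5))
    lam[_loading_pattern()] = params.loading_values
    noise = rng.standard_normal((n, 20)) * np.sqrt(params.uniqueness)
    return latent @ lam.T + noise


def ordinal_moments(thresholds: ThresholdSet) -> tuple[float, float, float, float]:
    """Analytic (mean, variance, skewness, excess kurtosis) of scores 1..K."""
    return _moments_from_probs(thresholds.probabilities)


def _tau_from_free(free: np.ndarray, K: int, symmetric: bool) -> np.ndarray:
    """Map unconstrained parameters to strictly increasing thresholds."""
    if symmetric:
        # free parameters are the positive half, log-spaced increments
        inc = np.exp(free) + 1e-9  # floor keeps ordering strict under underflow
        if K % 2 == 1:  # even number of thresholds, none at zero
            first = inc[0] / 2.0
            upper = first + np.concatenate(([0.0], np.cumsum(inc[1:])))
        else:  # odd count: middle threshold pinned at 0
            upper = np.cumsum(inc)
        tau = np.concatenate((-upper[::-1], [0.0] if K % 2 == 0 else [], upper))
        return tau
    start = free[0]
    inc = np.exp(free[1:]) + 1e-9
    return start + np.concatenate(([0.0], np.cumsum(inc)))


def _moment_residual(tau: np.ndarray, K: int, targets: tuple[float, float]) -> np.ndarray:
    _, _, skew, exkurt = _moments_from_probs(_category_probs(tau))
    return np.array([skew - targets[0], exkurt - targets[1]])


def solve_thresholds(
    K: int,
    target_skew: float,
    target_excess_kurtosis: float,
    shape_label: str,
) -> ThresholdSet:
    """Solve for thresholds whose scored distribution hits the moment targets.

    Symmetric requests enforce tau_j = -tau_{K-j} structurally (skewness is
    then exactly zero) and match only the kurtosis target.  A multistart
    least-squares search is used; residuals above 5e-3 on either matched
    moment raise an ``unattainable targets`` error.
    """
    symmetric = shape_label == "symmetric"
    if symmetric and target_skew != 0.0:
        raise ValueError("symmetric shape implies zero target skewness")
    n_free = (K - 1) // 2 if symmetric else K - 1
    targets = (target_skew, target_excess_kurtosis)

    # The moment constraints leave the thresholds underdetermined for K > 2;
    # among admissible sets we take the maximum-entropy one, which keeps
    # every category populated instead of collapsing some to zero mass.
    def neg_entropy(free: np.ndarray) -> float:
        tau = _tau_from_free(free, K, symmetric)
        p = np.clip(_category_probs(tau), 1e-300, None)
        return float(np.sum(p * np.log(p)))

    def constraint(free: np.ndarray) -> np.ndarray:
        res = _moment_residual(_tau_from_free(free, K, symmetric), K, targets)
        return res[1:] if symmetric else res

    best = None
    rng = np.random.default_rng(20_18)  # deterministic multistart
    starts = [np.zeros(n_free)] + [rng.normal(scale=0.7, size=n_free) for _ in range(24)]
    for x0 in starts:
        sol = optimize.minimize(
            neg_entropy,
            x0,
            method="SLSQP",
            bounds=[(-6.0, 6.0)] * n_free,
            constraints={"type": "eq", "fun": constraint},
            options={"maxiter": 400, "ftol": 1e-12},
        )
        feasible = np.max(np.abs(constraint(sol.x))) <= 5e-3
        if feasible and (best is None or sol.fun < best.fun):
            best = sol
    if best is None:
        raise ValueError(f"unattainable targets for K={K} ({shape_label})")
    tau = _tau_from_free(best.x, K, symmetric)
    if symmetric:
        tau = (tau - tau[::-1]) / 2.0  # exact symmetry against round-off
    return ThresholdSet(K, tuple(float(t) for t in tau), shape_label)


@lru_cache(maxsize=None)
def threshold_set(K: int, shape_label: str) -> ThresholdSet:
    """The stored study ThresholdSet for a (category count, shape) condition."""
    if shape_label == "symmetric":
        skew, kurt = SYMMETRIC_TARGETS
    elif shape_label == "asymmetric":
        skew, kurt = ASYMMETRIC_TARGETS
    else:
        raise ValueError(f"unknown shape label {shape_label!r}")
    return solve_thresholds(K, skew, kurt, shape_label)


def discretize(
    continuous: np.ndarray,
    thresholds: ThresholdSet,
    seed: int | None = None,
) -> OrdinalDataset:
    """Cut continuous values into codes 1..K (monotone in the input)."""
    tau = np.asarray(thresholds.tau)
    codes = 1 + np.searchsorted(tau, continuous, side="left").astype(np.int64)
    return OrdinalDataset(
        values=codes,
        category_count=thresholds.category_count,
        shape_label=thresholds.shape_label,
        seed=seed,
    )


def standardize_columns(data: OrdinalDataset | np.ndarray, ddof: int = 0) -> np.ndarray:
    """Column-wise z-scores (mean 0, variance 1 with the given ddof).

    Raises on a constant column ("degenerate indicator"): such a
    replication is flagged upstream rather than silently dropped.
    """
    X = data.values if isinstance(data, OrdinalDataset) else np.asarray(data)
    X = X.astype(float)
    sd = X.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"degenerate indicator: constant column(s) {bad.tolist()}")
    return (X - X.mean(axis=0)) / sd
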