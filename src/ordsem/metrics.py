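"""Parameter-recovery metrics: relative bias, relative RMSE, MAD and the
eta-squared ANOVA screen.

Per parameter k with truth theta_k and estimates theta_hat_kj over r
converged-and-proper replications:

    RB_k   = 100 * mean_j (theta_hat_kj - theta_k) / theta_k      [percent]
    RMSE_k = sqrt( mean_j ((theta_hat_kj - theta_k) / theta_k)^2 )

(the RMSE is the root of the mean squared *relative* deviation), averaged
separately over loadings and over path coefficients to give RB_a and
RMSE_a.  Within one replication the mean absolute difference

    MAD = mean_k | theta_hat_k - theta_k |

is the outcome of an ANOVA whose predictors are the simulation design
factors (plus the estimator) with interactions up to the maximum order.
Effects are screened by eta-squared.  Because a sequential decomposition
bounds the classical eta-squared sum by one while heavily reported
simulation effect sizes are customarily partial, the table carries both
eta^2 = SS_eff / SS_total and partial eta^2 = SS_eff / (SS_eff + SS_err).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "relative_bias",
    "relative_rmse",
    "average_by_type",
    "mad",
    "eta_squared",
    "recovery_table",
    "mad_table",
]


def _param_type(key: str) -> str:
    if key.startswith("lam_"):
        return "loading"
    if key.startswith(("gamma", "beta")):
        return "path"
    return "other"


def relative_bias(estimates: np.ndarray, truth: float) -> float:
    """Mean relative deviation from truth, in percent."""
    if truth == 0:
        raise ValueError("relative bias undefined for a zero truth")
    est = np.asarray(estimates, dtype=float)
    return float(np.mean((est - truth) / truth) * 100.0)


def relative_rmse(estimates: np.ndarray, truth: float) -> float:
    """Root mean squared relative deviation from truth."""
    if truth == 0:
        raise ValueError("relative RMSE undefined for a zero truth")
    est = np.asarray(estimates, dtype=float)
    return float(np.sqrt(np.mean(((est - truth) / truth) ** 2)))


def average_by_type(per_param: dict[str, float], param_type: str) -> float:
    """Arithmetic mean of a per-parameter metric over one parameter type."""
    vals = [v for k, v in per_param.items() if _param_type(k) == param_type]
    if not vals:
        raise ValueError(f"no parameters of type {param_type!r}")
    return float(np.mean(vals))


def mad(estimates: dict[str, float], truth: dict[str, float], keys=None) -> float:
    """Mean absolute difference over the given (or common-required) keys."""
    keys = list(keys) if keys is not None else list(estimates)
    missing = [k for k in keys if k not in estimates or k not in truth]
    if missing:
        raise KeyError(f"keys missing from estimates or truth: {missing}")
    diffs = [abs(estimates[k] - truth[k]) for k in keys]
    return float(np.mean(diffs))


def recovery_table(estimates: pd.DataFrame, truth: dict[str, float]) -> pd.DataFrame:
    """Per-condition RB_a / RMSE_a for loadings and paths.

    ``estimates`` is the long-format table with columns
    condition_id, estimator, replication, parameter, estimate
    already restricted to converged, proper replications.  ``truth`` maps
    parameter name -> population value (truths of fitted parameters only).
    """
    rows = []
    for (cond, estr), grp in estimates.groupby(["condition_id", "estimator"], sort=True):
        rb: dict[str, float] = {}
        rmse: dict[str, float] = {}
        for param, pg in grp.groupby("parameter"):
            if param not in truth or _param_type(param) == "other":
                continue
            rb[param] = relative_bias(pg["estimate"].to_numpy(), truth[param])
            rmse[param] = relative_rmse(pg["estimate"].to_numpy(), truth[param])
        rows.append(
            {
                "condition_id": cond,
                "estimator": estr,
                "n_replications": grp["replication"].nunique(),
                "rb_a_loadings": average_by_type(rb, "loading"),
                "rb_a_paths": average_by_type(rb, "path"),
                "rmse_a_loadings": average_by_type(rmse, "loading"),
                "rmse_a_paths": average_by_type(rmse, "path"),
            }
        )
    return pd.DataFrame(rows)


def mad_table(estimates: pd.DataFrame, truth: dict[str, float]) -> pd.DataFrame:
    """Replication-level MAD over loadings and over paths."""
    param_type = estimates["parameter"].map(_param_type)
    est = estimates.assign(param_type=param_type)
    est = est[est["param_type"] != "other"].copy()
    est["truth"] = est["parameter"].map(truth)
    est["absdiff"] = (est["estimate"] - est["truth"]).abs()
    out = (
        est.groupby(["condition_id", "estimator", "replication", "param_type"], sort=True)["absdiff"]
        .mean()
        .unstack("param_type")
        .rename(columns={"loading": "mad_loadings", "path": "mad_paths"})
        .reset_index()
    )
    return out


#: Sequential (type I) factor order for the unbalanced ANOVA.
FACTOR_ORDER = ("estimator", "misspecified", "shape", "categories", "n")


def eta_squared(
    mad_records: pd.DataFrame,
    outcome: str,
    factors: tuple[str, ...] = FACTOR_ORDER,
    max_interaction_order: int = 5,
) -> pd.DataFrame:
    """Sequential-SS ANOVA of replication-level MAD with eta-squared columns.

    ``mad_records`` must contain the outcome column and the design factor
    columns.  Effects up to ``max_interaction_order``-way interactions are
    entered in the documented order.  Returns a table with effect, sum_sq,
    df, eta_sq (share of total SS) and partial_eta_sq.
    """
    present = [f for f in factors if mad_records[f].nunique() > 1]
    if not present:
        raise ValueError("need at least one factor with two or more levels")
    data = mad_records.dropna(subset=[outcome]).copy()
    # main effects enter in the listed order, giving the documented
    # sequential decomposition; interactions up to the requested order
    order = min(max_interaction_order, len(present))
    base = " + ".join(f"C({f})" for f in present)
    formula = f"{outcome} ~ ({base}) ** {order}" if order > 1 else f"{outcome} ~ {base}"
    model = smf.ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    ss_total = float(anova["sum_sq"].sum())
    ss_err = float(anova.loc["Residual", "sum_sq"])
    out = anova.reset_index().rename(columns={"index": "effect"})
    out["eta_sq"] = out["sum_sq"] / ss_total
    out["partial_eta_sq"] = out["sum_sq"] / (out["sum_sq"] + ss_err)
    out.loc[out["effect"] == "Residual", ["eta_sq", "partial_eta_sq"]] = np.nan
    out["effect"] = (
        out["effect"]
        .str.replace(r"C\((\w+)\)", r"\1", regex=True)
        .str.replace(":", " x ")
    )
    return out[["effect", "sum_sq", "df", "eta_sq", "partial_eta_sq"]]
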