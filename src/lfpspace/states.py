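"""Coupling between spatial decay parameters and sleep state.

Joins per-epoch decay fits with staged states and band powers, then
quantifies the coupling: the fit-parameter ratio lambda/A (b/A for the
power law) against the gamma/delta band-power ratio, Pearson correlation
with analytic CI, Type-2 regression, per-state summaries of lambda and
the ratio, d-prime separation between states, coefficients of variation
with bootstrap CIs, and per-state kernel densities.

Both ratios are oriented so they are low in SWS and high in REM/awake
(SWS couples high initial values and short decay constants with
delta-dominant power), which is the direction under which their
correlation is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decay import Type2Result, type2_regression
from .spatial import inverse_fisher_z

__all__ = [
    "join_epochs",
    "add_ratios",
    "correlate_ratios",
    "dprime",
    "coefficient_of_variation",
    "state_densities",
    "state_parameter_summary",
]


def join_epochs(
    fits: pd.DataFrame,
    states: pd.DataFrame,
    powers: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, int]:
    """Inner-join per-epoch tables on the epoch index.

    ``powers`` may be omitted when the staging table already carries the
    band-power columns.  Returns (merged table, number of epochs
    excluded from the union).  Epochs with failed fits are dropped.
    """
    f = fits[~fits.get("failed", False)].copy() if "failed" in fits else fits.copy()
    merged = f.merge(states, on="epoch", how="inner")
    if powers is not None:
        merged = merged.merge(powers, on="epoch", how="inner")
    if merged.empty:
        raise ValueError("no epochs shared between fits and states")
    union = set(fits["epoch"]) | set(states["epoch"])
    if powers is not None:
        union |= set(powers["epoch"])
    excluded = len(union) - merged["epoch"].nunique()
    return merged, excluded


def add_ratios(table: pd.DataFrame, model: str = "exponential") -> pd.DataFrame:
    """Attach param_ratio and power_ratio columns.

    param_ratio = lambda/A (exponential) or b/A (power law);
    power_ratio = gamma power / delta power.
    """
    t = table[table["model"] == model].copy() if "model" in table else table.copy()
    if model == "exponential":
        t["param_ratio"] = t["lambda_um"] / t["A"]
    elif model == "powerlaw":
        t["param_ratio"] = t["b"] / t["A"]
    else:
        raise ValueError(f"no parameter ratio defined for model {model!r}")
    t["power_ratio"] = t["gamma_power"] / t["delta_power"]
    return t


@dataclass
class RatioCorrelation:
    r: float
    ci: tuple[float, float]
    n: int
    type2: Type2Result


def correlate_ratios(
    table: pd.DataFrame,
    x: str = "param_ratio",
    y: str = "power_ratio",
    n_boot: int = 1000,
    seed: int = 0,
) -> RatioCorrelation:
    """Pearson correlation between the two ratios with analytic CI.

    The CI comes from the Fisher method (z +/- 1.96/sqrt(n-3),
    back-transformed); the Type-2 slope and its bootstrap CI come from
    the standardized-major-axis regression.
    """
    xv = table[x].to_numpy(float)
    yv = table[y].to_numpy(float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    n = len(xv)
    if n < 4:
        raise ValueError("need at least 4 epochs")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance in a ratio series")
    r = float(np.corrcoef(xv, yv)[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.96 / np.sqrt(n - 3)
    ci = (float(inverse_fisher_z(z - half)), float(inverse_fisher_z(z + half)))
    t2 = type2_regression(xv, yv, n_boot=n_boot, seed=seed)
    return RatioCorrelation(r=r, ci=ci, n=n, type2=t2)


def dprime(group_a, group_b) -> float:
    """Separation index |mean_a - mean_b| / sqrt((var_a + var_b)/2).

    Variances use denominator n-1.  Two degenerate groups with equal
    means give 0; with different means the separation is infinite.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    num = abs(a.mean() - b.mean())
    pooled = np.sqrt((va + vb) / 2.0)
    if pooled == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / pooled)


def coefficient_of_variation(
    values, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """CV = SD/mean with a percentile bootstrap 95% CI.

    Defined only for positive-mean quantities; SD uses denominator n-1.
    """
    v = np.asarray(values, float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    if v.mean() <= 0:
        raise ValueError("CV undefined for non-positive mean")
    cv = float(v.std(ddof=1) / v.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(v)
    for i in range(n_boot):
        s = v[rng.integers(0, n, n)]
        m = s.mean()
        boots[i] = s.std(ddof=1) / m if m > 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return cv, (float(lo), float(hi))


def state_densities(
    table: pd.DataFrame,
    value: str = "param_ratio",
    state_col: str = "state",
    grid_points: int = 256,
) -> dict[str, dict]:
    """Per-state Gaussian-kernel densities on a shared grid.

    Silverman bandwidth; single-point states are flagged (delta-like,
    no density returned).  Densities integrate to ~1 on the grid.
    """
    vals = table[value].to_numpy(float)
    vals = vals[np.isfinite(vals)]
    lo, hi = vals.min(), vals.max()
    span = hi - lo or 1.0
    grid = np.linspace(lo - 0.2 * span, hi + 0.2 * span, grid_points)
    out = {}
    for state, grp in table.groupby(state_col):
        x = grp[value].to_numpy(float)
        x = x[np.isfinite(x)]
        entry = {"n": len(x), "grid": grid, "density": None, "degenerate": False}
        if len(x) < 2 or x.std() == 0:
            entry["degenerate"] = True
        else:
            kde = stats.gaussian_kde(x, bw_method="silverman")
            entry["density"] = kde(grid)
        out[str(state)] = entry
    return out


def state_parameter_summary(
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-state mean/SD of lambda and param_ratio, CV with CI, and n.

    States absent from the table are simply omitted.
    """
    rows = []
    for state, grp in table.groupby("state"):
        lam = grp["lambda_um"].to_numpy(float) if "lambda_um" in grp else None
        ratio = grp["param_ratio"].to_numpy(float)
        row = {"state": state, "n": len(grp)}
        if lam is not None:
            row["lambda_mean"] = lam.mean()
            row["lambda_sd"] = lam.std(ddof=1) if len(lam) > 1 else np.nan
        row["ratio_mean"] = ratio.mean()
        row["ratio_sd"] = ratio.std(ddof=1) if len(ratio) > 1 else np.nan
        if len(ratio) >= 3 and ratio.mean() > 0:
            cv, ci = coefficient_of_variation(ratio, n_boot=n_boot, seed=seed)
            row["ratio_cv"] = cv
            row["ratio_cv_lo"], row["ratio_cv_hi"] = ci
        rows.append(row)
    return pd.DataFrame(rows)
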