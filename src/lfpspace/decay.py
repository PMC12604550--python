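"""Parametric models of the correlation-by-distance function.

Each epoch's mean Fisher-z profile z(d) is fit with count-weighted
regression to one of four models:

* exponential  f(d) = A exp(-d / lambda)   (log-linearized WLS)
* power law    f(d) = A d^(-b)             (log-log WLS)
* gaussian     f(d) = A exp(-d^2 / (2 s^2)) + c   (nonlinear WLS)
* linear       f(d) = m d + c              (WLS)

A is the initial value (Fisher-z units at d = 0 for the exponential;
at d = 1 um for the power law); lambda is the spatial decay constant.
MSE is always evaluated in the original z domain so models with
different fitting domains are comparable.  The scatter of per-epoch
(A, lambda) pairs is summarized with a Type-2 (standardized major axis)
regression, which acknowledges variance in both coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spatial import DistanceCorrelationFunction

__all__ = [
    "DecayFit",
    "LAMBDA_CAP_UM",
    "fit_exponential",
    "fit_powerlaw",
    "fit_gaussian",
    "fit_linear",
    "exclude_low_count_bins",
    "fit_all_epochs",
    "compare_models",
    "type2_regression",
    "Type2Result",
]

#: lambda assigned to flat (non-decaying) profiles instead of infinity
LAMBDA_CAP_UM = 1e6


@dataclass
class DecayFit:
    model: str
    params: dict = field(default_factory=dict)
    mse: float = np.nan
    bins_used: int = 0
    weights: np.ndarray | None = None
    flat: bool = False
    converged: bool = True
    failed: bool = False

    @property
    def A(self) -> float:
        return self.params.get("A", np.nan)

    @property
    def lambda_um(self) -> float:
        return self.params.get("lambda_um", np.nan)

    @property
    def b(self) -> float:
        return self.params.get("b", np.nan)


def _usable(d, z, counts):
    """Keep finite, positive-z, counted bins; warn when z <= 0 drops."""
    d = np.asarray(d, float)
    z = np.asarray(z, float)
    w = np.asarray(counts, float)
    ok = np.isfinite(z) & (w > 0)
    nonpos = ok & (z <= 0)
    if nonpos.any():
        warnings.warn(
            f"dropping {int(nonpos.sum())} non-positive mean-z bins before "
            "log-domain fit",
            stacklevel=3,
        )
        ok &= z > 0
    return d[ok], z[ok], w[ok]


def _wls(x, y, w):
    """Weighted least squares line y = a + b x; returns (a, b)."""
    W = w / w.sum()
    xm = np.sum(W * x)
    ym = np.sum(W * y)
    sxx = np.sum(W * (x - xm) ** 2)
    if sxx == 0:
        return ym, 0.0
    b = np.sum(W * (x - xm) * (y - ym)) / sxx
    return ym - b * xm, b


def _z_mse(d, z, model_fn) -> float:
    return float(np.mean((z - model_fn(d)) ** 2))


def fit_exponential(d, z, counts) -> DecayFit:
    """Count-weighted log-linear fit of z(d) = A exp(-d/lambda).

    ln z is regressed on d with weights proportional to counts;
    A = exp(intercept), lambda = -1/slope.  Slopes >= -1e-9 indicate a
    flat profile: lambda is capped at :data:`LAMBDA_CAP_UM`, the flat
    flag is set, and A becomes the weighted geometric mean of z.
    """
    d, z, w = _usable(d, z, counts)
    if len(d) < 2:
        return DecayFit("exponential", failed=True)
    a, b = _wls(d, np.log(z), w)
    if b >= -1e-9:
        A = float(np.exp(np.sum(w * np.log(z)) / w.sum()))
        lam = LAMBDA_CAP_UM
        flat = True
    else:
        A = float(np.exp(a))
        lam = float(-1.0 / b)
        flat = False
    mse = _z_mse(d, z, lambda x: A * np.exp(-x / lam))
    return DecayFit(
        "exponential",
        {"A": A, "lambda_um": lam},
        mse=mse,
        bins_used=len(d),
        weights=w,
        flat=flat,
    )


def fit_powerlaw(d, z, counts) -> DecayFit:
    """Count-weighted log-log fit of z(d) = A d^(-b)."""
    d, z, w = _usable(d, z, counts)
    if len(d) < 2:
        return DecayFit("powerlaw", failed=True)
    if np.any(d <= 0):
        raise ValueError("power-law fit requires positive distances")
    a, slope = _wls(np.log(d), np.log(z), w)
    flat = slope >= -1e-12
    A = float(np.exp(a))
    b = float(-slope)
    mse = _z_mse(d, z, lambda x: A * x**(-b))
    return DecayFit(
        "powerlaw",
        {"A": A, "b": b},
        mse=mse,
        bins_used=len(d),
        weights=w,
        flat=flat,
    )


def fit_linear(d, z, counts) -> DecayFit:
    """Count-weighted straight-line fit z(d) = slope d + intercept."""
    d = np.asarray(d, float)
    z = np.asarray(z, float)
    w = np.asarray(counts, float)
    ok = np.isfinite(z) & (w > 0)
    d, z, w = d[ok], z[ok], w[ok]
    if len(d) < 2:
        return DecayFit("linear", failed=True)
    a, b = _wls(d, z, w)
    mse = _z_mse(d, z, lambda x: a + b * x)
    return DecayFit(
        "linear",
        {"intercept": a, "slope": b},
        mse=mse,
        bins_used=len(d),
        weights=w,
    )


def _gauss(d, A, sig, c):
    return A * np.exp(-(d**2) / (2 * sig**2)) + c


def fit_gaussian(d, z, counts, sigma_starts=(1000.0, 2000.0, 4000.0)) -> DecayFit:
    """Weighted nonlinear fit of z(d) = A exp(-d^2/(2 s^2)) + c.

    Multi-start over the width initializer; the best weighted-SSE
    candidate is kept even if the optimizer reports non-convergence
    (flagged via ``converged``).
    """
    d = np.asarray(d, float)
    z = np.asarray(z, float)
    w = np.asarray(counts, float)
    ok = np.isfinite(z) & (w > 0)
    d, z, w = d[ok], z[ok], w[ok]
    if len(d) < 3:
        return DecayFit("gaussian", failed=True)
    best = None
    converged = False
    A0 = float(z.max() - z.min()) or 1.0
    c0 = float(z.min())
    sig_err = 1.0 / np.sqrt(w / w.max())
    for s0 in sigma_starts:
        try:
            popt, _ = optimize.curve_fit(
                _gauss, d, z, p0=(A0, s0, c0), sigma=sig_err,
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            ok_fit = True
        except RuntimeError:
            ok_fit = False
            continue
        sse = float(np.sum(w * (z - _gauss(d, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
        converged = converged or ok_fit
    if best is None:
        return DecayFit("gaussian", failed=True, converged=False)
    A, sig, c = best[1]
    mse = _z_mse(d, z, lambda x: _gauss(x, A, sig, c))
    return DecayFit(
        "gaussian",
        {"A": float(A), "sigma_um": float(sig), "c": float(c)},
        mse=mse,
        bins_used=len(d),
        weights=w,
        converged=converged,
    )


_FITTERS = {
    "exponential": fit_exponential,
    "powerlaw": fit_powerlaw,
    "gaussian": fit_gaussian,
    "linear": fit_linear,
}


def exclude_low_count_bins(counts, threshold_frac: float = 0.2) -> np.ndarray:
    """Mask of bins to keep under the low-observation exclusion rule.

    A bin is dropped when its count is below ``threshold_frac`` times
    the mean count of the *other* bins (distant bins on an array have
    few electrode pairs and unreliable means).
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    c = np.asarray(counts, float)
    if len(c) < 2:
        return np.ones_like(c, dtype=bool)
    total = c.sum()
    loo_mean = (total - c) / (len(c) - 1)
    keep = c >= threshold_frac * loo_mean
    if not keep.any():
        raise ValueError("low-count rule removed every bin")
    return keep


def fit_all_epochs(
    fn: DistanceCorrelationFunction,
    models: tuple[str, ...] = ("exponential",),
    exclude_frac: float | None = None,
) -> pd.DataFrame:
    """Fit the requested models to every epoch's distance function.

    Returns a tidy frame with one row per (epoch, model), carrying the
    fitted parameters, z-domain MSE, and quality flags.
    """
    rows = []
    for row in range(fn.n_epochs):
        d = fn.bin_upper_um
        z = fn.mean_z[row]
        c = fn.counts[row].astype(float)
        if exclude_frac is not None:
            keep = exclude_low_count_bins(c, exclude_frac)
            d, z, c = d[keep], z[keep], c[keep]
        for model in models:
            fit = _FITTERS[model](d, z, c)
            rows.append(
                {
                    "epoch": int(fn.epoch_index[row]),
                    "model": model,
                    **{k: v for k, v in fit.params.items()},
                    "mse": fit.mse,
                    "bins_used": fit.bins_used,
                    "flat": fit.flat,
                    "converged": fit.converged,
                    "failed": fit.failed,
                }
            )
    return pd.DataFrame(rows)


def compare_models(fits: pd.DataFrame) -> dict:
    """Per-model MSE distributions with smoothed density summaries.

    Returns {model: {"mse", "mean", "density"}} where ``density`` is a
    Gaussian-kernel estimate (Silverman bandwidth) or None when the MSE
    values are degenerate (zero variance), in which case the
    distribution is a point mass at ``mean``.
    """
    out = {}
    for model, grp in fits[~fits["failed"]].groupby("model"):
        mse = grp["mse"].to_numpy(float)
        entry = {"mse": mse, "mean": float(mse.mean()), "density": None}
        if len(mse) >= 2 and mse.std() > 0:
            entry["density"] = stats.gaussian_kde(mse, bw_method="silverman")
        out[model] = entry
    return out


@dataclass
class Type2Result:
    slope: float
    intercept: float
    r: float
    ci_slope: tuple[float, float]
    boot_slopes: np.ndarray | None = None
    sign_undefined: bool = False


def type2_regression(
    x, y, n_boot: int = 1000, seed: int = 0
) -> Type2Result:
    """Standardized major axis (Type-2) regression with bootstrap CI.

    slope = sign(r) * sd(y)/sd(x); intercept through the means.  The CI
    is a percentile interval over ``n_boot`` case resamples.  SMA is
    scale-invariant, appropriate when both coordinates carry variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")

    def sma(xv, yv):
        r = np.corrcoef(xv, yv)[0, 1]
        s = np.sign(r) if r != 0 else 1.0
        slope = s * yv.std(ddof=1) / xv.std(ddof=1)
        return slope, yv.mean() - slope * xv.mean(), r

    slope, intercept, r = sma(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(x)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if xb.std() == 0 or yb.std() == 0:
            boots[i] = np.nan
            continue
        boots[i] = sma(xb, yb)[0]
    ci = tuple(np.nanpercentile(boots, [2.5, 97.5]))
    return Type2Result(
        slope=float(slope),
        intercept=float(intercept),
        r=float(r),
        ci_slope=(float(ci[0]), float(ci[1])),
        boot_slopes=boots,
        sign_undefined=bool(r == 0),
    )
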