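"""Fit decay models to every epoch's correlation-by-distance function.

Exponential f(d) = A exp(-d/lambda) is the workhorse; power-law,
Gaussian, and linear models are fit alongside for comparison.  The
scatter of per-epoch (A, lambda) is summarized by a Type-2
(standardized major axis) regression — the anticorrelation between
initial value and decay constant is the signature of state-dependent
spatial structure.
"""

import importlib
import json

import numpy as np
import pandas as pd

from lfpspace import decay
from lfpspace.spatial import DistanceCorrelationFunction

cfg = importlib.import_module("00_config")


def main():
    df = pd.read_csv(cfg.CORR_CSV)
    epochs = np.sort(df["epoch"].unique())
    d = np.sort(df["bin_upper_um"].unique())
    dcf = DistanceCorrelationFunction(
        bin_upper_um=d,
        mean_z=df.pivot(index="epoch", columns="bin_upper_um", values="mean_z")
        .loc[epochs, d].to_numpy(float),
        counts=df.pivot(index="epoch", columns="bin_upper_um", values="count")
        .loc[epochs, d].to_numpy(int),
        epoch_index=epochs,
    )
    fits = decay.fit_all_epochs(
        dcf, ("exponential", "powerlaw", "gaussian", "linear"), exclude_frac=0.2
    )
    fits.to_csv(cfg.FITS_CSV, index=False)

    cmp = decay.compare_models(fits)
    mse = pd.DataFrame(
        [{"model": m, "mean_mse": v["mean"], "n_epochs": len(v["mse"])}
         for m, v in sorted(cmp.items(), key=lambda kv: kv[1]["mean"])]
    )
    mse.to_csv(cfg.RESULTS / "model_mse_summary.csv", index=False)
    print("model comparison (z-domain MSE):")
    print(mse.round(5).to_string(index=False))

    exp = fits[(fits["model"] == "exponential") & ~fits["flat"]]
    t2 = decay.type2_regression(
        exp["A"].to_numpy(), exp["lambda_um"].to_numpy(), n_boot=1000, seed=cfg.SEED
    )
    out = {
        "slope_um_per_z": t2.slope,
        "intercept_um": t2.intercept,
        "pearson_r": t2.r,
        "ci95_slope": list(t2.ci_slope),
        "n_epochs": len(exp),
    }
    (cfg.RESULTS / "type2_regression.json").write_text(json.dumps(out, indent=2))
    print(
        f"\nType-2 (A, lambda) slope: {t2.slope:.0f} um per z-unit, "
        f"95% CI [{t2.ci_slope[0]:.0f}, {t2.ci_slope[1]:.0f}], r = {t2.r:.2f}"
    )
    print(f"mean A = {exp['A'].mean():.2f} z, mean lambda = {exp['lambda_um'].mean():.0f} um")


if __name__ == "__main__":
    main()
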