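"""Couple spatial decay parameters to sleep state.

Joins fits and states, then quantifies the link between the
fit-parameter ratio lambda/A and the gamma/delta power ratio: Pearson
correlation, Type-2 slope, per-state lambda summaries, d' separation
between SWS and REM/awake, and coefficients of variation with
bootstrap CIs.
"""

import importlib
import json

import pandas as pd

from lfpspace import states as st_mod

cfg = importlib.import_module("00_config")


def main():
    fits = pd.read_csv(cfg.FITS_CSV)
    staged = pd.read_csv(cfg.STATES_CSV, keep_default_na=False, na_values=[""])
    exp = fits[fits["model"] == "exponential"]
    merged, n_excluded = st_mod.join_epochs(exp, staged)
    merged = st_mod.add_ratios(merged)

    summary = st_mod.state_parameter_summary(merged, n_boot=1000, seed=cfg.SEED)
    summary.to_csv(cfg.RESULTS / "state_summary.csv", index=False)
    print(summary.round(3).to_string(index=False))

    rc = st_mod.correlate_ratios(merged, n_boot=1000, seed=cfg.SEED)
    by = {s: g["param_ratio"].to_numpy() for s, g in merged.groupby("state")}
    dp = st_mod.dprime(by["SWS"], by["REM_AWAKE"])
    out = {
        "n_epochs": int(merged["epoch"].nunique()),
        "n_excluded_from_join": n_excluded,
        "pearson_r_ratio": rc.r,
        "pearson_ci95": list(rc.ci),
        "type2_slope_ratio": rc.type2.slope,
        "type2_slope_ci95": list(rc.type2.ci_slope),
        "dprime_sws_rem_awake": dp,
    }
    (cfg.RESULTS / "state_coupling.json").write_text(json.dumps(out, indent=2))
    print(
        f"\nlambda/A vs gamma/delta: r = {rc.r:.3f} "
        f"[{rc.ci[0]:.3f}, {rc.ci[1]:.3f}], d'(SWS, REM/awake) = {dp:.2f}"
    )


if __name__ == "__main__":
    main()
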