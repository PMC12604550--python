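"""End-to-end session driver and artifact reporting."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decay, spatial, staging, states, threshold
from .layout import ArrayLayout, utah_array
from .preprocess import build_epoch_grid, make_virtual_lfp, zscore_channels
from .recording import Recording

logger = logging.getLogger("lfpspace")

__all__ = ["PipelineConfig", "run_pipeline", "run_sessions", "dropout_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with defaults matching the analysis regime."""

    epoch_s: float = 10.0
    bin_width_um: float = 600.0
    cutoff_hz: float = 250.0
    filter_order: int = 3
    fs_out: float = 1000.0
    delta_band: tuple[float, float] = (0.1, 4.0)
    gamma_band: tuple[float, float] = (30.0, 60.0)
    models: tuple[str, ...] = ("exponential", "powerlaw", "gaussian", "linear")
    exclude_low_count_frac: float | None = 0.2
    n_boot: int = 1000
    n_shuffles: int = 1000
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("delta_band", "gamma_band", "models"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_pipeline(
    rec: Recording,
    layout: ArrayLayout | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Preprocess -> correlate -> fit -> stage -> analyze one session.

    Returns a report dict with the per-epoch tables and summary
    statistics; CSV artifacts are written under ``out_dir`` when given,
    each stamped with the config hash and seed for provenance.
    """
    layout = layout or utah_array()
    config = config or PipelineConfig()

    rec_z = zscore_channels(rec)
    grid = build_epoch_grid(rec_z, config.epoch_s)
    n_invalid = int((~grid.valid).sum())
    logger.info("epochs: %d total, %d excluded by mask", grid.n_epochs, n_invalid)
    if len(grid.valid_epochs()) == 0:
        raise RuntimeError("pipeline aborted at epoching: no valid epochs")

    bins = spatial.DistanceBins(config.bin_width_um,
                                int(np.ceil(layout.max_distance_um / config.bin_width_um)))
    dcf = spatial.session_distance_function(rec_z, layout, grid, bins)
    fits = decay.fit_all_epochs(dcf, config.models, config.exclude_low_count_frac)

    vlfp = make_virtual_lfp(rec_z)
    bands = {"delta": config.delta_band, "gamma": config.gamma_band}
    staged = staging.stage_epochs(vlfp, rec_z.fs, grid, bands, seed=config.seed)

    exp_fits = fits[fits["model"] == "exponential"]
    merged, n_excluded = states.join_epochs(exp_fits, staged.table)
    merged = states.add_ratios(merged, model="exponential")
    summary = states.state_parameter_summary(
        merged, n_boot=config.n_boot, seed=config.seed
    )
    ratio_corr = states.correlate_ratios(
        merged, n_boot=config.n_boot, seed=config.seed
    )
    t2 = decay.type2_regression(
        exp_fits.loc[~exp_fits["flat"], "A"],
        exp_fits.loc[~exp_fits["flat"], "lambda_um"],
        n_boot=config.n_boot,
        seed=config.seed,
    )
    by_state = {s: g["param_ratio"].to_numpy() for s, g in merged.groupby("state")}
    dp = (
        states.dprime(by_state["SWS"], by_state["REM_AWAKE"])
        if "SWS" in by_state and "REM_AWAKE" in by_state
        and min(len(by_state["SWS"]), len(by_state["REM_AWAKE"])) >= 2
        else np.nan
    )

    report = {
        "config_hash": config.hash,
        "seed": config.seed,
        "n_epochs": grid.n_epochs,
        "n_epochs_invalid": n_invalid,
        "n_epochs_joined": int(merged["epoch"].nunique()),
        "n_epochs_excluded_join": n_excluded,
        "distance_function": dcf,
        "fits": fits,
        "staging": staged.table,
        "merged": merged,
        "state_summary": summary,
        "ratio_correlation": ratio_corr,
        "type2_A_lambda": t2,
        "dprime_sws_rem": dp,
        "model_comparison": {
            m: v["mean"] for m, v in decay.compare_models(fits).items()
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {"config": json.loads(config.to_json()), "config_hash": config.hash}
        (out_dir / "config.json").write_text(json.dumps(meta, indent=2))
        fits.to_csv(out_dir / "fits.csv", index=False)
        staged.table.to_csv(out_dir / "states.csv", index=False)
        merged.to_csv(out_dir / "merged.csv", index=False)
        summary.to_csv(out_dir / "state_summary.csv", index=False)
        corr_rows = pd.DataFrame(
            {
                "epoch": np.repeat(dcf.epoch_index, len(dcf.bin_upper_um)),
                "bin_upper_um": np.tile(dcf.bin_upper_um, dcf.n_epochs),
                "mean_z": dcf.mean_z.ravel(),
                "count": dcf.counts.ravel(),
            }
        )
        corr_rows.to_csv(out_dir / "correlations.csv", index=False)
    return report


def run_sessions(
    recs: list[Recording],
    layout: ArrayLayout | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    truth_sws: list[np.ndarray] | None = None,
) -> dict:
    """Run the pipeline per session; with >= 2 sessions also train the
    leave-one-out threshold classifier on the fitted initial values.

    ``truth_sws`` optionally supplies ground-truth SWS labels per
    session (as in simulation studies); otherwise the staged labels are
    the prediction target.
    """
    config = config or PipelineConfig()
    reports = []
    for i, rec in enumerate(recs):
        sub = Path(out_dir) / f"session{i:02d}" if out_dir else None
        reports.append(run_pipeline(rec, layout, config, sub))
    out = {"sessions": reports}
    if len(recs) >= 2:
        sessions = []
        for i, rep in enumerate(reports):
            merged = rep["merged"].sort_values("epoch")
            series = merged["A"].to_numpy(float)
            if truth_sws is not None:
                epochs = merged["epoch"].to_numpy(int)
                labels = np.asarray(truth_sws[i], bool)[epochs]
            else:
                labels = (merged["state"] == "SWS").to_numpy()
            sessions.append((series, labels))
        models = threshold.train_loo(sessions)
        classifier = []
        for (series, labels), model in zip(sessions, models):
            null = threshold.shuffle_null(
                series, labels, model, n_shuffles=config.n_shuffles,
                seed=config.seed,
            )
            perf = threshold.accuracy_precision(
                threshold.predict(series, model), labels
            )
            classifier.append({"model": model, "null": null, "performance": perf})
        out["classifier"] = classifier
    return out


def dropout_report(rec: Recording, epoch_s: float = 10.0) -> dict:
    """Characterize mask-invalid intervals.

    Returns dropout durations (s), dropouts per epoch, and
    inter-dropout intervals (s) as tables with their means.
    """
    invalid = ~rec.valid
    # run-length encode the invalid mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], invalid.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    durations = (ends - starts) / rec.fs
    inter = (starts[1:] - ends[:-1]) / rec.fs if len(starts) > 1 else np.array([])
    n_per = int(epoch_s * rec.fs)
    n_epochs = rec.n_samples // n_per
    per_epoch = np.zeros(n_epochs, dtype=int)
    for s in starts:
        ep = min(int(s // n_per), n_epochs - 1) if n_epochs else 0
        if n_epochs:
            per_epoch[ep] += 1
    return {
        "durations_s": pd.DataFrame({"duration_s": durations}),
        "per_epoch": pd.DataFrame({"epoch": np.arange(n_epochs), "count": per_epoch}),
        "inter_intervals_s": pd.DataFrame({"interval_s": inter}),
        "mean_duration_s": float(durations.mean()) if len(durations) else np.nan,
        "mean_inter_s": float(inter.mean()) if len(inter) else np.nan,
        "n_dropouts": int(len(starts)),
    }
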