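"""File formats: HDF5 recordings, JSON sidecars, CSV epoch tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .layout import ArrayLayout
from .recording import Recording
from .simulate import GeneratorParams, GroundTruth, StateParams

__all__ = [
    "save_recording",
    "load_recording",
    "layout_to_dict",
    "layout_from_dict",
    "params_to_dict",
    "params_from_dict",
    "save_ground_truth",
    "load_ground_truth",
]


def save_recording(
    path: str | Path,
    rec: Recording,
    layout: ArrayLayout | None = None,
    params: GeneratorParams | None = None,
) -> None:
    """Write /signal (float32), /mask, and attrs; JSON sidecar for
    layout/generator parameters when provided."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal.astype(np.float32))
        f.create_dataset("mask", data=rec.valid.astype(bool))
        f.attrs["fs"] = rec.fs
        f.attrs["channel_ids"] = np.asarray(rec.channel_ids)
        f.attrs["excluded_channels"] = sorted(rec.excluded_channels)
    sidecar = {}
    if layout is not None:
        sidecar["layout"] = layout_to_dict(layout)
    if params is not None:
        sidecar["params"] = params_to_dict(params)
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        rec = Recording(
            signal=f["signal"][...],
            fs=float(f.attrs["fs"]),
            channel_ids=np.asarray(f.attrs["channel_ids"]),
            valid=f["mask"][...],
            excluded_channels=set(int(c) for c in f.attrs["excluded_channels"]),
        )
    return rec


def load_sidecar(path: str | Path) -> dict:
    sidecar = Path(path).with_suffix(".json")
    return json.loads(sidecar.read_text()) if sidecar.exists() else {}


def layout_to_dict(layout: ArrayLayout) -> dict:
    return {
        "pitch_um": layout.pitch_um,
        "n_rows": layout.n_rows,
        "n_cols": layout.n_cols,
        "wired": layout.wired.astype(int).tolist(),
    }


def layout_from_dict(d: dict) -> ArrayLayout:
    return ArrayLayout(
        pitch_um=d["pitch_um"],
        n_rows=d["n_rows"],
        n_cols=d["n_cols"],
        wired=np.asarray(d["wired"], dtype=bool),
    )


def params_to_dict(params: GeneratorParams) -> dict:
    d = asdict(params)
    d["states"] = {k: asdict(v) for k, v in params.states.items()}
    return d


def params_from_dict(d: dict) -> GeneratorParams:
    d = dict(d)
    states = {
        k: StateParams(
            sigma_global=tuple(v["sigma_global"]),
            sigma_spatial=tuple(v["sigma_spatial"]),
            sigma_local=tuple(v["sigma_local"]),
            ell_um=v["ell_um"],
            ell_jitter_cv=v.get("ell_jitter_cv", 0.0),
        )
        for k, v in d.pop("states", {}).items()
    }
    d["band_edges"] = tuple(tuple(b) for b in d.get("band_edges", ((0.1, 4.0), (30.0, 60.0))))
    d["state_transition"] = tuple(tuple(r) for r in d.get(
        "state_transition", GeneratorParams().state_transition
    ))
    return GeneratorParams(states=states, **d)


def save_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    """Epoch table (index, start time, state, generative ell) as CSV."""
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(len(truth.states)),
            "t_start_s": np.arange(len(truth.states)) * truth.epoch_s,
            "state": truth.states,
            "ell_um": truth.ell_um,
        }
    )
    df.to_csv(path, index=False)


def load_ground_truth(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the NULL state label must survive as a string
    return pd.read_csv(path, keep_default_na=False, na_values=[""])
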