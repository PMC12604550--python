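"""Unsupervised sleep staging from virtual-LFP band power.

Every valid epoch gets two spectral features from the channel-average
virtual LFP: mean multitaper power in the slow-oscillation/delta band
(0.1-4 Hz) and in the gamma band (30-60 Hz).  Epochs are clustered into
three full-covariance Gaussian-mixture components on the standardized
log10 powers, and components are mapped to sleep states by their
delta-vs-gamma balance: the component with the largest
(mean delta - mean gamma) is slow-wave sleep (SWS), the smallest is
REM/awake, the remaining one is the null/transitional state.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss
from sklearn.mixture import GaussianMixture

from .preprocess import EpochGrid

__all__ = [
    "DEFAULT_BANDS",
    "multitaper_band_power",
    "cluster_states",
    "label_clusters",
    "stage_epochs",
]

DEFAULT_BANDS = {"delta": (0.1, 4.0), "gamma": (30.0, 60.0)}


@lru_cache(maxsize=8)
def _tapers(n: int, nw: float, k: int) -> np.ndarray:
    return dpss(n, nw, Kmax=k)


def multitaper_band_power(
    vlfp: np.ndarray,
    fs: float,
    grid: EpochGrid,
    bands: dict[str, tuple[float, float]] = DEFAULT_BANDS,
    nw: float = 3.0,
    k: int = 5,
) -> pd.DataFrame:
    """Mean multitaper spectral power per band per valid epoch.

    The one-sided PSD is averaged over ``k`` Slepian tapers
    (time-bandwidth product ``nw``); band power is the mean PSD over
    frequency bins with lo <= f <= hi (inclusive edges).  Raises when a
    band contains no resolvable frequency bin at the epoch length — the
    0.1 Hz lower delta edge needs epochs of at least 10 s at integer
    frequency resolution.
    """
    n = grid.n_samples_per_epoch
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = {}
    for name, (lo, hi) in bands.items():
        if hi >= fs / 2:
            raise ValueError(f"band {name} upper edge {hi} >= Nyquist")
        mask = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
        if not mask.any():
            raise ValueError(
                f"band {name} ({lo}-{hi} Hz) resolves no frequency bin at "
                f"epoch length {n / fs:g} s"
            )
        sel[name] = mask

    tapers = _tapers(n, nw, k)
    rows = []
    for ep in grid.valid_epochs():
        x = np.asarray(vlfp[grid.slice(ep)], float)
        x = x - x.mean()
        spec = np.fft.rfft(tapers * x[None, :], axis=1)
        psd = (np.abs(spec) ** 2).mean(axis=0) * (2.0 / fs)
        psd[0] /= 2.0
        if n % 2 == 0:
            psd[-1] /= 2.0
        row = {"epoch": int(ep), "t_start_s": grid.t_start_s(ep)}
        for name, mask in sel.items():
            row[f"{name}_power"] = float(psd[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _feature_matrix(powers: pd.DataFrame, bands=("delta", "gamma")) -> np.ndarray:
    """Standardized log10 band powers (epochs x bands)."""
    cols = [f"{b}_power" for b in bands]
    x = np.log10(powers[cols].to_numpy(float))
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate (zero-variance) band-power features")
    return (x - mu) / sd


def cluster_states(
    features: np.ndarray, k: int = 3, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Full-covariance Gaussian-mixture clustering.

    Returns (labels, posterior max per epoch).  ``seed`` fixes the
    initialization; ``n_init`` restarts guard against local optima.
    """
    features = np.asarray(features, float)
    if len(features) < k:
        raise ValueError("need at least k epochs to fit k components")
    if np.any(features.std(axis=0) == 0):
        raise ValueError("degenerate features")
    gmm = GaussianMixture(
        n_components=k, covariance_type="full", n_init=n_init, random_state=seed
    )
    labels = gmm.fit_predict(features)
    post = gmm.predict_proba(features).max(axis=1)
    return labels, post


def label_clusters(
    features: np.ndarray, labels: np.ndarray
) -> tuple[dict[int, str], bool]:
    """Map cluster ids to states by delta-vs-gamma balance.

    ``features`` must be the standardized (delta, gamma) matrix used for
    clustering.  Returns (mapping, tie_flag); ties in the ranking
    statistic are broken deterministically by cluster index.
    """
    ids = np.unique(labels)
    if len(ids) != 3:
        raise ValueError("expected exactly 3 clusters")
    stat = {}
    for c in ids:
        m = features[labels == c].mean(axis=0)
        stat[int(c)] = float(m[0] - m[1])  # delta minus gamma
    vals = sorted(stat.items(), key=lambda kv: (-kv[1], kv[0]))
    tie = len({round(v, 12) for _, v in vals}) < 3
    mapping = {vals[0][0]: "SWS", vals[1][0]: "NULL", vals[2][0]: "REM_AWAKE"}
    return mapping, tie


@dataclass
class StagingResult:
    table: pd.DataFrame  # epoch, t_start_s, powers, cluster, state, posterior_max
    mapping: dict[int, str]
    tie_flag: bool


def stage_epochs(
    vlfp: np.ndarray,
    fs: float,
    grid: EpochGrid,
    bands: dict[str, tuple[float, float]] = DEFAULT_BANDS,
    seed: int = 0,
    nw: float = 3.0,
    k_tapers: int = 5,
) -> StagingResult:
    """Full staging pipeline: band powers -> GMM -> state labels."""
    powers = multitaper_band_power(vlfp, fs, grid, bands, nw=nw, k=k_tapers)
    feats = _feature_matrix(powers, bands=tuple(bands))
    labels, post = cluster_states(feats, k=3, seed=seed)
    mapping, tie = label_clusters(feats, labels)
    table = powers.copy()
    table["cluster"] = labels
    table["state"] = [mapping[int(c)] for c in labels]
    table["posterior_max"] = post
    return StagingResult(table=table, mapping=mapping, tie_flag=tie)
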