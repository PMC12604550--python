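"""Distance-binned, Fisher-transformed pairwise correlation functions.

For every valid epoch a Pearson correlation matrix is computed on the
z-scored signals, each correlation is Fisher z-transformed
(z = atanh(r), variance-stabilizing), and the values are averaged into
600 um distance bins *per source electrode* (each row of the matrix).
Source-level bin means are then pooled into one array-level
correlation-by-distance function per epoch, weighting each source's
bin value by the number of electrode pairs that contributed to it —
sources near the array edge see fewer partners at a given distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy import signal as sps

from .layout import ArrayLayout, electrode_distances
from .preprocess import EpochGrid
from .recording import Recording

__all__ = [
    "DistanceBins",
    "DistanceCorrelationFunction",
    "fisher_z",
    "inverse_fisher_z",
    "epoch_correlation_matrix",
    "bin_by_distance",
    "array_average_function",
    "session_distance_function",
    "correlation_significance",
    "narrowband_distance_functions",
    "pooled_profile",
]

#: running count of |r| >= 1 values clipped before atanh
_n_clipped = 0

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class DistanceBins:
    """Half-open distance bins (lower, upper], labeled by upper edge."""

    width_um: float
    n_bins: int

    @property
    def edges(self) -> np.ndarray:
        return self.width_um * np.arange(self.n_bins + 1)

    @property
    def upper_um(self) -> np.ndarray:
        return self.edges[1:]

    @classmethod
    def for_layout(cls, layout: ArrayLayout, width_um: float = 600.0) -> "DistanceBins":
        return cls(width_um, int(np.ceil(layout.max_distance_um / width_um)))

    def index(self, d: np.ndarray) -> np.ndarray:
        """Bin index per distance; membership is (lower, upper]."""
        return np.digitize(d, self.edges, right=True) - 1


@dataclass
class DistanceCorrelationFunction:
    """Per-epoch array-level mean Fisher z per distance bin.

    ``mean_z`` and ``counts`` are (n_epochs, n_bins); bins with zero
    observations carry NaN mean and count 0.  ``epoch_index`` maps rows
    back to epoch numbers in the source grid.
    """

    bin_upper_um: np.ndarray
    mean_z: np.ndarray
    counts: np.ndarray
    epoch_index: np.ndarray
    n_samples_per_epoch: int = 0

    @property
    def n_epochs(self) -> int:
        return self.mean_z.shape[0]


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform, atanh(r); |r| >= 1 clipped to +/-(1 - 1e-7).

    Clipping guards against railed/duplicate channels producing exact
    +/-1; occurrences are tallied in a module counter.
    """
    global _n_clipped
    r = np.asarray(r, dtype=float)
    over = np.abs(r) >= 1.0
    if over.any():
        _n_clipped += int(over.sum())
        r = np.clip(r, -_CLIP, _CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    return np.tanh(z)


def epoch_correlation_matrix(
    rec: Recording, grid: EpochGrid, epoch: int
) -> np.ndarray:
    """Pearson correlation matrix of non-excluded channels in one epoch.

    Refuses invalid epochs: their samples must never enter statistics.
    """
    if not grid.valid[epoch]:
        raise ValueError(f"epoch {epoch} is invalid (artifact overlap)")
    keep = rec.included_channels()
    seg = rec.signal[keep, grid.slice(epoch)].astype(float)
    if seg.shape[1] < 2:
        raise ValueError("need at least 2 samples for a correlation")
    return np.corrcoef(seg)


def bin_by_distance(
    corr: np.ndarray, distances: np.ndarray, bins: DistanceBins
) -> tuple[np.ndarray, np.ndarray]:
    """Per-source binned mean Fisher z and pair counts.

    Returns (mean_z, counts), each (n_sources, n_bins).  For each source
    electrode the z values of its pairings are averaged within each
    distance bin; the diagonal is excluded.  Empty bins carry NaN/0.
    """
    n = corr.shape[0]
    if distances.shape != corr.shape:
        raise ValueError("correlation and distance matrices must align")
    z = fisher_z(corr)
    idx = bins.index(distances)
    off = ~np.eye(n, dtype=bool)

    sums = np.zeros((n, bins.n_bins))
    counts = np.zeros((n, bins.n_bins), dtype=int)
    src, tgt = np.nonzero(off)
    flat = src * bins.n_bins + idx[src, tgt]
    np.add.at(sums.ravel(), flat, z[src, tgt])
    np.add.at(counts.ravel(), flat, 1)
    with np.errstate(invalid="ignore"):
        mean_z = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean_z, counts


def array_average_function(
    per_source_z: np.ndarray, per_source_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pool source-level functions into one array-level function.

    Bin value = sum_e count_e * mean_z_e / sum_e count_e; bins empty for
    every source are marked missing (NaN, count 0).
    """
    counts = per_source_counts.sum(axis=0)
    weighted = np.where(per_source_counts > 0, per_source_z * per_source_counts, 0.0)
    with np.errstate(invalid="ignore"):
        mean_z = np.where(counts > 0, weighted.sum(axis=0) / np.maximum(counts, 1), np.nan)
    return mean_z, counts


def session_distance_function(
    rec: Recording,
    layout: ArrayLayout,
    grid: EpochGrid,
    bins: DistanceBins | None = None,
) -> DistanceCorrelationFunction:
    """Correlation-by-distance function for every valid epoch."""
    bins = bins or DistanceBins.for_layout(layout)
    dist_full = electrode_distances(layout)
    keep = rec.included_channels()
    dist = dist_full[np.ix_(keep, keep)]

    epochs = grid.valid_epochs()
    mean_z = np.full((len(epochs), bins.n_bins), np.nan)
    counts = np.zeros((len(epochs), bins.n_bins), dtype=int)
    for row, ep in enumerate(epochs):
        corr = epoch_correlation_matrix(rec, grid, ep)
        src_z, src_c = bin_by_distance(corr, dist, bins)
        mean_z[row], counts[row] = array_average_function(src_z, src_c)
    return DistanceCorrelationFunction(
        bin_upper_um=bins.upper_um,
        mean_z=mean_z,
        counts=counts,
        epoch_index=epochs,
        n_samples_per_epoch=grid.n_samples_per_epoch,
    )


def correlation_significance(
    z: float, n_samples: int
) -> tuple[tuple[float, float], bool]:
    """Analytic 95% CI for a Fisher z value and a greater-than-zero flag.

    CI = z +/- 1.96 / sqrt(n - 3).  Uses the nominal sample count; with
    autocorrelated signals the effective n is smaller, so the flag is
    anticonservative (documented caveat, matching the analytic
    approach).
    """
    if n_samples <= 3:
        raise ValueError("need more than 3 samples for the analytic CI")
    half = 1.96 / np.sqrt(n_samples - 3)
    lo, hi = z - half, z + half
    return (lo, hi), bool(lo > 0)


def bandpass_zerophase(
    signal: np.ndarray, lo: float, hi: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass via its squared-magnitude gain.

    Applies |H(f)|^2 (the forward-backward response of an order-``order``
    Butterworth band-pass) in the frequency domain.  Equivalent to
    filtfilt up to boundary handling (circular rather than reflected),
    and immune to the denormal slowdown sos filtering suffers at
    sub-hertz corners.
    """
    x = np.atleast_2d(np.asarray(signal, float))
    n = x.shape[-1]
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
    gain = np.abs(h) ** 2
    out = sfft.irfft(sfft.rfft(x, axis=-1) * gain, n, axis=-1)
    return out if signal.ndim > 1 else out[0]


def narrowband_distance_functions(
    rec: Recording,
    layout: ArrayLayout,
    grid: EpochGrid,
    bands: dict[str, tuple[float, float]],
    bins: DistanceBins | None = None,
    order: int = 4,
) -> dict[str, DistanceCorrelationFunction]:
    """Distance functions per frequency band.

    The recording is zero-phase band-pass filtered per band, then the
    full binning pipeline runs on the filtered signals.
    """
    out = {}
    for name, (lo, hi) in bands.items():
        if not (0 < lo < hi < rec.fs / 2):
            raise ValueError(f"band {name} ({lo}, {hi}) invalid for fs={rec.fs}")
        filt = bandpass_zerophase(rec.signal, lo, hi, rec.fs, order=order)
        sub = Recording(
            signal=filt,
            fs=rec.fs,
            channel_ids=rec.channel_ids,
            valid=rec.valid.copy(),
            excluded_channels=set(rec.excluded_channels),
        )
        out[name] = session_distance_function(sub, layout, grid, bins)
    return out


def pooled_profile(fn: DistanceCorrelationFunction) -> tuple[np.ndarray, np.ndarray]:
    """Pool a session's functions over epochs.

    Returns (mean z per bin, inverse-transformed correlation per bin),
    averaging epochs with equal weight (counts are identical across
    epochs for a fixed channel set).
    """
    finite = np.isfinite(fn.mean_z)
    sums = np.where(finite, fn.mean_z, 0.0).sum(axis=0)
    n = finite.sum(axis=0)
    mz = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return mz, inverse_fisher_z(mz)
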