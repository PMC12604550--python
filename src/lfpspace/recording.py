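"""In-memory container for a multichannel recording block."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    """A channels x samples signal block with validity bookkeeping.

    ``valid`` marks samples usable for analysis (False inside dropout or
    artifact intervals).  ``excluded_channels`` holds channel *indices*
    (row positions, not ids) removed from all downstream statistics,
    e.g. zero-variance/broken channels.
    """

    signal: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_ids: np.ndarray | None = None
    valid: np.ndarray | None = None
    excluded_channels: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal))
        n_ch, n_samp = self.signal.shape
        if self.channel_ids is None:
            self.channel_ids = np.arange(n_ch)
        else:
            self.channel_ids = np.asarray(self.channel_ids)
            if len(self.channel_ids) != n_ch:
                raise ValueError("channel_ids length mismatch")
        if self.valid is None:
            self.valid = np.ones(n_samp, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (n_samp,):
                raise ValueError("validity mask length mismatch")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def included_channels(self) -> np.ndarray:
        """Row indices of channels not excluded."""
        return np.array(
            [i for i in range(self.n_channels) if i not in self.excluded_channels],
            dtype=int,
        )
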