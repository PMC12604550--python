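"""Electrode-array geometry.

The recordings this package targets come from a planar Utah-style
microelectrode array: a regular grid of penetrating electrodes (default
10 x 10 at 400 um pitch) of which the four corner sites are not wired,
leaving 96 recording channels.  All spatial statistics downstream reduce
to the pairwise Euclidean distances between wired sites, so the layout
is the single source of truth for geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArrayLayout", "utah_array", "electrode_distances"]


@dataclass(frozen=True)
class ArrayLayout:
    """Geometry of a planar electrode grid.

    Parameters
    ----------
    pitch_um : float
        Inter-electrode spacing in micrometres.
    n_rows, n_cols : int
        Grid dimensions.
    wired : np.ndarray of bool, shape (n_rows, n_cols)
        True where a grid site carries a recording electrode.
    """

    pitch_um: float
    n_rows: int
    n_cols: int
    wired: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        wired = np.asarray(self.wired, dtype=bool)
        if wired.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"wired mask shape {wired.shape} does not match grid "
                f"({self.n_rows}, {self.n_cols})"
            )
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if wired.sum() < 2:
            raise ValueError("layout needs at least two wired electrodes")
        object.__setattr__(self, "wired", wired)

    @property
    def n_channels(self) -> int:
        return int(self.wired.sum())

    @property
    def channel_ids(self) -> np.ndarray:
        """Wired-site indices in row-major grid order."""
        return np.flatnonzero(self.wired.ravel())

    @property
    def positions(self) -> np.ndarray:
        """(n_channels, 2) electrode coordinates in micrometres."""
        rows, cols = np.nonzero(self.wired)
        return np.column_stack([cols, rows]).astype(float) * self.pitch_um

    @property
    def max_distance_um(self) -> float:
        return self.pitch_um * float(
            np.hypot(self.n_rows - 1, self.n_cols - 1)
        )


def utah_array(
    pitch_um: float = 400.0, n_rows: int = 10, n_cols: int = 10
) -> ArrayLayout:
    """Default 96-channel layout: full grid with unwired corners."""
    wired = np.ones((n_rows, n_cols), dtype=bool)
    for r in (0, n_rows - 1):
        for c in (0, n_cols - 1):
            wired[r, c] = False
    return ArrayLayout(pitch_um=pitch_um, n_rows=n_rows, n_cols=n_cols, wired=wired)


def grid_layout(
    n_rows: int, n_cols: int, pitch_um: float = 400.0
) -> ArrayLayout:
    """Fully wired rectangular grid (useful for small test arrays)."""
    wired = np.ones((n_rows, n_cols), dtype=bool)
    return ArrayLayout(pitch_um=pitch_um, n_rows=n_rows, n_cols=n_cols, wired=wired)


def electrode_distances(layout: ArrayLayout) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean distances (um).

    Raises
    ------
    ValueError
        If two wired electrodes share a position (degenerate layout).
    """
    pos = layout.positions
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(len(pos), dtype=bool)
    if np.any(dist[off] == 0.0):
        raise ValueError("duplicate electrode positions in layout")
    return dist
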