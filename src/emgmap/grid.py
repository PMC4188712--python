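"""Electrode-grid geometry.

The detection system is a rectangular grid of monopolar electrodes wrapped
around the forearm: columns run in the ulnar--radial (circumferential)
direction, rows in the proximal--distal direction.  Electrode positions are
1-based ``(x, y)`` pairs with ``x`` the column and ``y`` the row, and the
inter-electrode distance (IED) is the spatial unit of all map statistics:
adjacent electrodes are exactly 1 IED apart in grid coordinates.

The grid is treated as planar (no circumferential wrap), matching the flat
activity maps the analysis produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridLayout"]


@dataclass(frozen=True)
class GridLayout:
    """Rectangular electrode grid.

    Parameters
    ----------
    n_cols : int
        Number of circumferential (ulnar--radial) columns, ``x in [1, n_cols]``.
    n_rows : int
        Number of proximal--distal rows, ``y in [1, n_rows]``.
    ied_mm : float
        Centre-to-centre inter-electrode distance in millimetres.
    """

    n_cols: int = 14
    n_rows: int = 8
    ied_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one column and one row")
        if self.ied_mm <= 0:
            raise ValueError("inter-electrode distance must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_cols * self.n_rows

    def channel_index(self, x: int, y: int) -> int:
        """Flat channel index of electrode ``(x, y)`` (1-based coordinates)."""
        if not (1 <= x <= self.n_cols and 1 <= y <= self.n_rows):
            raise ValueError(f"electrode ({x}, {y}) outside grid")
        return (y - 1) * self.n_cols + (x - 1)

    def electrode_position(self, index: int) -> tuple[int, int]:
        """Inverse of :meth:`channel_index`."""
        if not 0 <= index < self.n_channels:
            raise ValueError("channel index out of range")
        return index % self.n_cols + 1, index // self.n_cols + 1

    def channel_coords(self) -> np.ndarray:
        """``(n_channels, 2)`` array of electrode ``(x, y)`` positions."""
        xs = np.arange(1, self.n_cols + 1)
        ys = np.arange(1, self.n_rows + 1)
        gx, gy = np.meshgrid(xs, ys)  # row-major: y varies slowly
        return np.column_stack([gx.ravel(), gy.ravel()]).astype(float)

    def neighbors(self, index: int) -> list[int]:
        """Flat indices of the 4-connected grid neighbours of a channel."""
        x, y = self.electrode_position(index)
        out = []
        for dx, dy in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nx, ny = x + dx, y + dy
            if 1 <= nx <= self.n_cols and 1 <= ny <= self.n_rows:
                out.append(self.channel_index(nx, ny))
        return out

    def to_grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape per-channel values into an ``(n_cols, n_rows)`` map.

        Element ``[x-1, y-1]`` of the result is the value of electrode (x, y).
        """
        values = np.asarray(values)
        if values.shape[0] != self.n_channels:
            raise ValueError("value vector does not match grid size")
        return values.reshape(self.n_rows, self.n_cols).T

    def from_grid(self, grid_values: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_grid`."""
        grid_values = np.asarray(grid_values)
        if grid_values.shape != (self.n_cols, self.n_rows):
            raise ValueError("map shape does not match grid")
        return grid_values.T.reshape(-1)
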