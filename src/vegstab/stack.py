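"""Core gridded data containers shared by every pipeline stage.

The internal grid convention is row-major with the origin at the top-left
cell corner and 0-based indices; cell centers are at ``x0 + (col + 0.5)*dx``
and ``y0 + (row + 0.5)*dy`` (``dy`` is negative for north-up grids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "RasterStack"]


@dataclass(frozen=True)
class GridSpec:
    """Affine georeferencing of a regular grid (no rotation)."""

    x0: float = 0.0
    y0: float = 0.0
    dx: float = 1.0
    dy: float = -1.0

    def cell_centers(self, n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays of shape (n_rows, n_cols)."""
        cols = np.arange(n_cols)
        rows = np.arange(n_rows)
        x = self.x0 + (cols + 0.5) * self.dx
        y = self.y0 + (rows + 0.5) * self.dy
        return np.broadcast_to(x, (n_rows, n_cols)).copy(), np.broadcast_to(
            y[:, None], (n_rows, n_cols)
        ).copy()

    def extent(self, n_rows: int, n_cols: int) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid footprint."""
        xs = sorted((self.x0, self.x0 + n_cols * self.dx))
        ys = sorted((self.y0, self.y0 + n_rows * self.dy))
        return xs[0], xs[1], ys[0], ys[1]

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "dx": self.dx, "dy": self.dy}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{k: float(d[k]) for k in ("x0", "y0", "dx", "dy")})


@dataclass
class RasterStack:
    """Annual raster time series of one variable.

    Attributes
    ----------
    data : float array, shape (n_years, n_rows, n_cols)
        Layer values; invalid cells hold NaN.
    years : int array, shape (n_years,)
        Calendar year label of each layer, ascending.
    mask : bool array, shape (n_rows, n_cols)
        True where the pixel is valid across the series.
    grid : GridSpec
        Georeferencing, carried unchanged through every stage.
    """

    data: np.ndarray
    years: np.ndarray
    mask: np.ndarray
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.years = np.asarray(self.years, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D (year, row, col), got {self.data.ndim}-D")
        if self.years.shape != (self.data.shape[0],):
            raise ValueError("one year label per layer required")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must match the spatial grid")
        if np.any(np.diff(self.years) < 0):
            raise ValueError("years must be sorted ascending")

    @property
    def n_years(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        return self.data[:, row, col]
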