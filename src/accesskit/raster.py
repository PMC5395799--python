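"""Rectangular raster grids: the substrate every layer in the toolkit shares.

Conventions used throughout the package:

* array indexing is ``(row, col)`` with row 0 at the *north* edge;
* map coordinates have y increasing northward, ``(origin_x, origin_y)`` is the
  map position of the *lower-left* corner of the grid;
* the centre of cell ``(row, col)`` is at
  ``origin + (col + 0.5, n_rows - row - 0.5) * cell_size``;
* nodata cells (default sentinel -9999) are excluded from every analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_NODATA = -9999.0

__all__ = ["RasterGrid", "CoRegistrationError", "DEFAULT_NODATA"]


class CoRegistrationError(ValueError):
    """Raised when rasters that must share a grid system do not."""


@dataclass
class RasterGrid:
    """A rectangular cell grid with cell size, origin and a nodata sentinel.

    Parameters
    ----------
    values
        2-D array, row-major with row 0 at the north edge.
    cell_size
        Cell edge length in metres (> 0).
    origin_x, origin_y
        Map coordinates of the lower-left corner.
    nodata
        Sentinel marking cells outside the analysis.
    """

    values: np.ndarray
    cell_size: float = 50.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got shape {self.values.shape}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid in map coordinates."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the centre of cell (row, col)."""
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing map point (x, y).

        Points exactly on the east/north boundary fall into the last cell so
        that every point of the closed extent maps to a valid index.
        """
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside grid extent {self.extent}")
        col = min(int((x - xmin) / self.cell_size), self.n_cols - 1)
        row = min(int((ymax - y) / self.cell_size), self.n_rows - 1)
        return row, col

    # -- nodata ----------------------------------------------------------

    def nodata_mask(self) -> np.ndarray:
        """Boolean mask of nodata cells."""
        return np.isclose(self.values, self.nodata) | ~np.isfinite(
            self.values.astype(float, copy=False)
        )

    # -- misc ------------------------------------------------------------

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's georeferencing with fresh values."""
        return RasterGrid(
            values=np.array(values),
            cell_size=self.cell_size,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            nodata=self.nodata,
        )

    def same_grid_system(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
        )

    def __eq__(self, other: object) -> bool:  # value equality incl. georef
        if not isinstance(other, RasterGrid):
            return NotImplemented
        return self.same_grid_system(other) and np.array_equal(
            self.values, other.values, equal_nan=True
        )


def check_coregistered(*grids: RasterGrid) -> None:
    """Raise :class:`CoRegistrationError` unless all grids share shape,
    cell size and origin. Every multi-layer operation calls this first."""
    if len(grids) < 2:
        return
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_grid_system(g):
            raise CoRegistrationError(
                "rasters are not co-registered: "
                f"{ref.shape}@{ref.cell_size}m({ref.origin_x},{ref.origin_y}) vs "
                f"{g.shape}@{g.cell_size}m({g.origin_x},{g.origin_y})"
            )
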