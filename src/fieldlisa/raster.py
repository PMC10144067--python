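"""Single-band elevation rasters on a planar metric grid.

The grid convention follows north-up imagery: row index increases
southward, column index increases eastward, and ``origin`` is the (x, y)
world coordinate of the grid's northwest corner.  All coordinates are in
meters of a local planar CRS.  Rasters are serialized as Esri ASCII grid
(.asc), a plain-text georeferenced format readable by GDAL/QGIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, OutOfExtentError, RasterAlignmentError

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A 2-D grid of elevations or heights in meters.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values in meters; row 0 is the northernmost row.
    cell_size : float
        Edge length of a square cell, meters per pixel.
    origin : (float, float)
        World (x, y) of the northwest corner of the grid.
    nodata : float
        Sentinel for missing cells.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = field(default=DEFAULT_NODATA)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise InvalidParameterError(f"cell_size must be > 0, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the outer cell edges."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of cell centers as (x of cols, y of rows)."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.cell_size
        return xs, ys

    def world_to_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing world point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        nrows, ncols = self.shape
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise OutOfExtentError(f"point ({x:.3f}, {y:.3f}) lies outside the raster extent {self.extent}")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        x_min, y_min, x_max, y_max = self.extent
        return x_min <= x < x_max and y_min < y <= y_max

    def sample(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); nodata becomes NaN."""
        row, col = self.world_to_index(x, y)
        v = self.values[row, col]
        return float("nan") if v == self.nodata else float(v)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return self.values != self.nodata

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_alignment(self, other: "Raster", what: str = "rasters") -> None:
        if not self.aligned_with(other):
            raise RasterAlignmentError(
                f"{what} are misaligned: shape {self.shape} vs {other.shape}, "
                f"cell {self.cell_size} vs {other.cell_size}, origin {self.origin} vs {other.origin}"
            )

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(np.asarray(values, dtype=float), self.cell_size, self.origin, self.nodata)

    # -- I/O --------------------------------------------------------------
    def write_ascii(self, path) -> None:
        """Write as an Esri ASCII grid (xllcorner/yllcorner reference the SW corner)."""
        nrows, ncols = self.shape
        x_min, y_min, _, _ = self.extent
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {x_min:.6f}\n"
            f"yllcorner {y_min:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {self.nodata:.1f}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.6f")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        cell = meta["cellsize"]
        nrows = int(meta["nrows"])
        origin = (meta["xllcorner"], meta["yllcorner"] + nrows * cell)
        return cls(values, cell, origin, meta.get("nodata_value", DEFAULT_NODATA))
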