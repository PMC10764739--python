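"""Minimal georeferenced raster container and TIFF I/O.

A :class:`Raster` is a 2-D array plus an affine north-up grid: the origin is
the outer corner of the top-left (north-west) cell and ``resolution`` is the
square cell size in metres.  Rasters are written as plain TIFF files with the
grid metadata stored as JSON in the TIFF description tag, so values round-trip
bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

NODATA = -9999.0


@dataclass
class GridSpec:
    """Regular north-up grid: ``x_origin, y_origin`` at the NW corner."""

    x_origin: float
    y_origin: float
    resolution: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.resolution**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, shape (n_rows, n_cols)."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.resolution
        ys = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each (x, y); raises if out of extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.resolution).astype(int)
        row = np.floor((self.y_origin - y) / self.resolution).astype(int)
        # points exactly on the far edge belong to the last cell
        col = np.where((x == self.x_origin + self.n_cols * self.resolution), self.n_cols - 1, col)
        row = np.where((y == self.y_origin - self.n_rows * self.resolution), self.n_rows - 1, row)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            pts = list(zip(np.atleast_1d(x)[np.atleast_1d(bad)], np.atleast_1d(y)[np.atleast_1d(bad)]))
            raise ValueError(f"points outside raster extent: {pts}")
        return row, col

    @classmethod
    def from_extent(cls, width_m: float, height_m: float, resolution: float,
                    x_origin: float = 0.0, y_origin: float | None = None) -> "GridSpec":
        n_cols = int(round(width_m / resolution))
        n_rows = int(round(height_m / resolution))
        if y_origin is None:
            y_origin = n_rows * resolution
        return cls(x_origin, y_origin, resolution, n_rows, n_cols)


@dataclass
class Raster:
    data: np.ndarray
    grid: GridSpec
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(f"data shape {self.data.shape} != grid shape {self.grid.shape}")

    def masked(self) -> np.ndarray:
        """Float copy with nodata replaced by NaN."""
        out = self.data.astype(float).copy()
        out[self.data == self.nodata] = np.nan
        return out

    def with_data(self, data: np.ndarray) -> "Raster":
        return replace(self, data=np.asarray(data))


def write_tif(path, raster: Raster) -> None:
    meta = {
        "x_origin": raster.grid.x_origin,
        "y_origin": raster.grid.y_origin,
        "resolution": raster.grid.resolution,
        "nodata": raster.nodata,
    }
    tifffile.imwrite(path, raster.data, description=json.dumps(meta))


def read_tif(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    grid = GridSpec(
        meta.get("x_origin", 0.0),
        meta.get("y_origin", float(data.shape[0])),
        meta.get("resolution", 1.0),
        data.shape[0],
        data.shape[1],
    )
    return Raster(data, grid, nodata=meta.get("nodata", NODATA))


@dataclass
class RasterStack:
    """Co-registered per-year grids for one field (year axis first)."""

    data: np.ndarray  # (n_years, n_rows, n_cols), NaN = missing
    grid: GridSpec
    years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3-D (years, rows, cols)")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("stack grid mismatch")
        if not self.years:
            self.years = list(range(1, self.data.shape[0] + 1))
        if len(self.years) != self.data.shape[0]:
            raise ValueError("years length mismatch")

    @property
    def n_years(self) -> int:
        return self.data.shape[0]
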