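"""Terrain covariates from elevation grids.

Slope and aspect use Horn's 3x3 kernel; depressions are removed with a
priority-flood fill; flow routing is single-direction D8 (each cell drains to
its steepest-descent neighbour, drops divided by centre distance).  Flow
accumulation is a cell count that includes the cell itself, so it is >= 1
everywhere and its log10 is always defined — convenient because upslope
contributing area is close to log-normal in gently rolling cropland and is
analysed on the log scale.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import GridSpec, Raster

ASPECT_NODATA = -1.0

# D8 neighbour offsets in row-major order (ties resolved to the first, i.e.
# lowest row-major index)
_D8_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_D8_DIST = np.array([np.hypot(dr, dc) for dr, dc in _D8_OFFSETS])


@dataclass
class TerrainRasters:
    elevation: Raster
    slope: Raster          # percent rise/run
    aspect: Raster         # degrees clockwise from north, downslope-facing
    flow_accumulation: Raster  # cell counts, >= 1
    log_flowacc: Raster    # log10 of the counts

    @property
    def grid(self) -> GridSpec:
        return self.elevation.grid


def slope_aspect(elev: np.ndarray, resolution: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn slope (%) and downslope aspect (deg CW from north) of an elevation grid.

    Edge cells use replicated-edge padding, which reduces to one-sided
    differences on the boundary.  Aspect is ``ASPECT_NODATA`` on flats.
    """
    z = np.asarray(elev, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    p = np.pad(z, 1, mode="edge")
    a = p[:-2, :-2]; b = p[:-2, 1:-1]; c = p[:-2, 2:]
    d = p[1:-1, :-2]; f = p[1:-1, 2:]
    g = p[2:, :-2]; h = p[2:, 1:-1]; i = p[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * resolution)   # east
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * resolution)   # north
    slope = 100.0 * np.hypot(dz_dx, dz_dy)
    # downslope unit direction is (-dz_dx, -dz_dy) in (east, north)
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    aspect[(dz_dx == 0) & (dz_dy == 0)] = ASPECT_NODATA
    return slope, aspect


def fill_depressions(elev: np.ndarray) -> np.ndarray:
    """Priority-flood depression fill.

    Raises every cell to the level of its lowest spill path to the grid
    boundary.  Output >= input everywhere; idempotent.  Flats created by the
    fill are left flat (resolved later during flow routing).
    """
    z = np.asarray(elev, dtype=float)
    nr, nc = z.shape
    filled = z.copy()
    visited = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(nr):
        for c in (range(nc) if r in (0, nr - 1) else (0, nc - 1)):
            heapq.heappush(heap, (filled[r, c], r, c))
            visited[r, c] = True
    while heap:
        level, r, c = heapq.heappop(heap)
        for dr, dc in _D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not visited[rr, cc]:
                visited[rr, cc] = True
                filled[rr, cc] = max(filled[rr, cc], level)
                heapq.heappush(heap, (filled[rr, cc], rr, cc))
    return filled


def _drainage_surface(filled: np.ndarray) -> np.ndarray:
    """Epsilon-drained copy of a filled DEM: every interior cell gains a
    strictly descending path to the boundary (flat resolution by gradient
    toward the lower edge)."""
    z = np.asarray(filled, dtype=float)
    nr, nc = z.shape
    out = z.copy()
    visited = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    order = 0
    for r in range(nr):
        for c in (range(nc) if r in (0, nr - 1) else (0, nc - 1)):
            heapq.heappush(heap, (out[r, c], order, r, c))
            order += 1
            visited[r, c] = True
    while heap:
        level, _, r, c = heapq.heappop(heap)
        for dr, dc in _D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not visited[rr, cc]:
                visited[rr, cc] = True
                if out[rr, cc] <= level:
                    out[rr, cc] = np.nextafter(level, np.inf)
                heapq.heappush(heap, (out[rr, cc], order, rr, cc))
                order += 1
    return out


OFFGRID = -1


def d8_flow_direction(filled: np.ndarray, _surf: np.ndarray | None = None) -> np.ndarray:
    """Index (0..7 into the row-major D8 offsets) of each cell's receiver;
    ``OFFGRID`` where flow leaves the grid.  Input must be depression-filled.
    """
    surf = _drainage_surface(filled) if _surf is None else _surf
    nr, nc = surf.shape
    padded = np.pad(surf, 1, mode="constant", constant_values=np.inf)
    drops = np.empty((8, nr, nc))
    for k, (dr, dc) in enumerate(_D8_OFFSETS):
        nb = padded[1 + dr:1 + dr + nr, 1 + dc:1 + dc + nc]
        drops[k] = (surf - nb) / _D8_DIST[k]
    best = np.argmax(drops, axis=0)  # first max wins -> lowest row-major index
    direction = best.astype(np.int8)
    no_lower = np.take_along_axis(drops, best[None], axis=0)[0] <= 0
    direction[no_lower] = OFFGRID  # boundary minima drain off-grid
    return direction


def d8_flow_accumulation(filled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """D8 flow direction and accumulation (cell counts, own cell included).

    Returns ``(direction, accumulation)``.  The sum of accumulation over cells
    draining off-grid equals the total cell count (conservation).
    """
    surf = _drainage_surface(np.asarray(filled, dtype=float))
    direction = d8_flow_direction(filled, _surf=surf)
    nr, nc = surf.shape
    acc = np.ones((nr, nc), dtype=np.int64)
    # process from high to low on the drainage surface so receivers are
    # visited after all their donors
    order = np.argsort(surf, axis=None, kind="stable")[::-1]
    rows, cols = np.unravel_index(order, surf.shape)
    for r, c in zip(rows, cols):
        k = direction[r, c]
        if k != OFFGRID:
            dr, dc = _D8_OFFSETS[k]
            acc[r + dr, c + dc] += acc[r, c]
    return direction, acc


def derive_terrain(elevation: Raster) -> TerrainRasters:
    """Full terrain product from an elevation raster."""
    elev = np.asarray(elevation.data, dtype=float)
    res = elevation.grid.resolution
    slope, aspect = slope_aspect(elev, res)
    filled = fill_depressions(elev)
    _, acc = d8_flow_accumulation(filled)
    g = elevation.grid
    return TerrainRasters(
        elevation=elevation,
        slope=Raster(slope, g),
        aspect=Raster(aspect, g, nodata=ASPECT_NODATA),
        flow_accumulation=Raster(acc.astype(float), g),
        log_flowacc=Raster(np.log10(acc.astype(float)), g),
    )


def sample_at_points(rasters: TerrainRasters, x, y) -> pd.DataFrame:
    """Nearest-cell terrain covariates at point locations.

    Raises ``ValueError`` listing any points outside the raster extent.
    """
    row, col = rasters.grid.index_of(np.asarray(x, float), np.asarray(y, float))
    return pd.DataFrame(
        {
            "x": np.atleast_1d(x).astype(float),
            "y": np.atleast_1d(y).astype(float),
            "elevation_m": rasters.elevation.data[row, col].astype(float),
            "slope_pct": rasters.slope.data[row, col].astype(float),
            "aspect_deg": rasters.aspect.data[row, col].astype(float),
            "flow_accumulation": rasters.flow_accumulation.data[row, col].astype(float),
            "log_flowacc": rasters.log_flowacc.data[row, col].astype(float),
        }
    )


def resample_to(raster: Raster, grid: GridSpec) -> Raster:
    """Nearest-neighbour resampling of a raster onto another grid."""
    xs, ys = grid.cell_centers()
    row, col = raster.grid.index_of(xs.ravel(), ys.ravel())
    data = raster.data[row, col].reshape(grid.shape)
    return Raster(data, grid, nodata=raster.nodata)
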