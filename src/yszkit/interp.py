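"""Interpolation of yield-monitor points to regular grids.

Harvester yield monitors emit semi-regular point observations; the zone
classifier needs co-registered per-year grids.  The workhorse here is
ordinary kriging with a spherical variogram fitted by weighted least squares
to the empirical semivariogram (Cressie weights), with inverse-distance
weighting as a fallback when variogram fitting is not possible.  Cells
outside the convex hull of the points (plus a 10 m margin) are left nodata
rather than extrapolated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint

from .raster import NODATA, GridSpec, Raster

log = logging.getLogger(__name__)

HULL_MARGIN_M = 10.0
MAX_NEIGHBORS = 64


@dataclass
class YieldPointSet:
    """Point yield observations for one field, possibly spanning years."""

    table: pd.DataFrame  # columns x, y, year, yield
    field_id: str = "field"
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        required = {"x", "y", "year", "yield"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"point table missing columns {sorted(missing)}")
        t = self.table
        if not np.all(np.isfinite(t[["x", "y"]].to_numpy(float))):
            raise ValueError("non-finite coordinates")
        if np.any(t["yield"].to_numpy(float) < 0):
            raise ValueError("negative yields")

    def year(self, year: int) -> pd.DataFrame:
        sub = self.table[self.table["year"] == year]
        if sub.empty:
            raise ValueError(f"no points for year {year}")
        return sub

    @property
    def years(self) -> list[int]:
        return sorted(self.table["year"].unique().tolist())


@dataclass
class VariogramModel:
    """Spherical semivariogram: nugget, sill (total), range (m)."""

    nugget: float
    sill: float
    range_m: float
    family: str = "spherical"
    constant_field: bool = False

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.sill < self.nugget or self.range_m <= 0:
            raise ValueError("require nugget >= 0, sill >= nugget, range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        hr = np.clip(h / self.range_m, 0.0, 1.0)
        gamma = self.nugget + psill * (1.5 * hr - 0.5 * hr**3)
        return np.where(h == 0.0, 0.0, gamma)


def _dedupe(xy: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average duplicate coordinates (exact ties) to avoid singular systems."""
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "z": z})
    g = df.groupby(["x", "y"], as_index=False, sort=False).mean()
    if len(g) < len(df):
        log.warning("averaged %d duplicate point locations", len(df) - len(g))
    return g[["x", "y"]].to_numpy(), g["z"].to_numpy()


def empirical_variogram(
    xy: np.ndarray, z: np.ndarray, n_lags: int = 15, max_dist: float | None = None
) -> pd.DataFrame:
    """Binned empirical semivariogram: lag centre, semivariance, pair count."""
    d = cdist(xy, xy)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    sv = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    if max_dist is None:
        max_dist = h.max() / 2.0
    keep = h <= max_dist
    h, sv = h[keep], sv[keep]
    edges = np.linspace(0, max_dist, n_lags + 1)
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_lags - 1)
    rows = []
    for j in range(n_lags):
        m = idx == j
        if m.sum() > 0:
            rows.append({"lag": h[m].mean(), "gamma": sv[m].mean(), "n_pairs": int(m.sum())})
    return pd.DataFrame(rows)


def fit_variogram(
    points: YieldPointSet, year: int, n_lags: int = 15
) -> VariogramModel:
    """WLS fit of a spherical model to a year's empirical semivariogram.

    Requires at least 10 points.  A constant field (zero variance) returns a
    zero-sill model flagged ``constant_field``.
    """
    sub = points.year(year)
    if len(sub) < 10:
        raise ValueError(f"need >= 10 points to fit a variogram, got {len(sub)}")
    xy, z = _dedupe(sub[["x", "y"]].to_numpy(float), sub["yield"].to_numpy(float))
    if np.ptp(z) == 0:
        return VariogramModel(0.0, 0.0, 1.0, constant_field=True)
    emp = empirical_variogram(xy, z, n_lags=n_lags)
    lags = emp["lag"].to_numpy()
    gam = emp["gamma"].to_numpy()
    npairs = emp["n_pairs"].to_numpy(float)

    def resid(theta):
        nugget, psill, rng = theta
        model = VariogramModel(nugget, nugget + psill, rng)(lags)
        return np.sqrt(npairs) * (gam - model) / np.maximum(model, 1e-12)

    z_var = z.var()
    x0 = [0.0, z_var, lags.max() / 2.0]
    res = least_squares(
        resid, x0,
        bounds=([0.0, 1e-12, 1e-6], [np.inf, np.inf, np.inf]),
        max_nfev=2000,
    )
    nugget, psill, rng = res.x
    return VariogramModel(float(nugget), float(nugget + psill), float(rng))


def _hull_mask(xy: np.ndarray, grid: GridSpec, margin: float = HULL_MARGIN_M) -> np.ndarray:
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull.buffer(margin)
    xs, ys = grid.cell_centers()
    return shapely.contains_xy(hull, xs.ravel(), ys.ravel()).reshape(grid.shape)


def kriging_weights(
    xy: np.ndarray, vgm: VariogramModel, target: np.ndarray
) -> tuple[np.ndarray, float]:
    """Ordinary-kriging weights and Lagrange multiplier for one target point.

    Solves the standard system with semivariances: ``[[G, 1], [1', 0]]``
    against ``[gamma(d_i0); 1]``.
    """
    n = len(xy)
    d = cdist(xy, xy)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = vgm(d)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = vgm(np.hypot(*(xy - target).T))
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    return sol[:n], float(sol[n])


def krige_to_grid(
    points: YieldPointSet,
    year: int,
    grid: GridSpec,
    vgm: VariogramModel,
    max_neighbors: int = MAX_NEIGHBORS,
) -> tuple[Raster, Raster]:
    """Ordinary kriging of one year's points onto a grid.

    Returns (estimate, kriging variance) rasters; cells outside the point
    hull (+10 m) are nodata.  With a zero-nugget model the estimate at a data
    location reproduces the observation.  Estimates more than 10% outside the
    observed data range are flagged with a logged warning (not clipped).
    """
    sub = points.year(year)
    xy, z = _dedupe(sub[["x", "y"]].to_numpy(float), sub["yield"].to_numpy(float))
    inside = _hull_mask(xy, grid)
    est = np.full(grid.shape, NODATA)
    var = np.full(grid.shape, NODATA)

    if vgm.constant_field or vgm.sill == 0 or np.ptp(z) == 0:
        est[inside] = z.mean()
        var[inside] = 0.0
        return Raster(est, grid), Raster(var, grid)

    xs, ys = grid.cell_centers()
    tree = cKDTree(xy)
    rows, cols = np.nonzero(inside)
    k = min(max_neighbors, len(xy))
    targets = np.column_stack([xs[rows, cols], ys[rows, cols]])
    _, nbr = tree.query(targets, k=k)
    nbr = np.atleast_2d(nbr)
    if nbr.shape[0] != len(targets):
        nbr = nbr.reshape(len(targets), -1)
    for i, (r, c) in enumerate(zip(rows, cols)):
        idx = np.atleast_1d(nbr[i])
        w, mu = kriging_weights(xy[idx], vgm, targets[i])
        est[r, c] = w @ z[idx]
        var[r, c] = max(0.0, float(w @ vgm(np.hypot(*(xy[idx] - targets[i]).T)) + mu))

    zmin, zmax = z.min(), z.max()
    span = zmax - zmin
    vals = est[inside]
    n_out = int(np.sum((vals < zmin - 0.1 * span) | (vals > zmax + 0.1 * span)))
    if n_out:
        log.warning("%d kriged cells exceed the data range by more than 10%%", n_out)
    return Raster(est, grid), Raster(var, grid)


def idw_to_grid(
    points: YieldPointSet, year: int, grid: GridSpec, power: float = 2.0
) -> Raster:
    """Inverse-distance-weighted interpolation; exact at data locations
    (snap tolerance: half a cell)."""
    sub = points.year(year)
    xy, z = _dedupe(sub[["x", "y"]].to_numpy(float), sub["yield"].to_numpy(float))
    inside = _hull_mask(xy, grid) if len(xy) >= 3 else np.ones(grid.shape, bool)
    xs, ys = grid.cell_centers()
    d = cdist(np.column_stack([xs.ravel(), ys.ravel()]), xy)
    snap = grid.resolution / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / d**power
        est = (w @ z) / w.sum(axis=1)  # inf weights resolved by snapping below
    nearest = d.argmin(axis=1)
    snapped = d[np.arange(len(d)), nearest] < snap
    est[snapped] = z[nearest[snapped]]
    est = est.reshape(grid.shape)
    est[~inside] = NODATA
    return Raster(est, grid)


# ---------------------------------------------------------------------------
# point I/O: CSV and GeoJSON

def read_points_csv(path, field_id: str = "field") -> YieldPointSet:
    return YieldPointSet(pd.read_csv(path), field_id=field_id)


def write_points_csv(path, points: YieldPointSet) -> None:
    points.table.to_csv(path, index=False)


def read_points_geojson(path, field_id: str = "field") -> YieldPointSet:
    with open(path) as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj["features"]:
        x, y = feat["geometry"]["coordinates"]
        props = feat.get("properties", {})
        rows.append({"x": x, "y": y, "year": props["year"], "yield": props["yield"]})
    return YieldPointSet(pd.DataFrame(rows), field_id=field_id)


def write_points_geojson(path, points: YieldPointSet) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
            "properties": {"year": int(row["year"]), "yield": float(row["yield"])},
        }
        for row in points.table.to_dict("records")
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
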