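"""Yield stability zone (YSZ) classification.

Each grid cell is classified from its multi-year relative yield — percent
deviation from the field mean of each year — into one of four zones:

* **US** (unstable): temporal SD of relative yield above the stability
  threshold (default 15 percentage points);
* **LS / MS / HS** (low / medium / high & stable): temporal mean relative
  yield below −10%, within ±10%, or above +10% (defaults).

Thresholds are strict inequalities, so boundary values fall to the
stable/medium side.  Relative NDVI stacks go through the identical code path
when yield monitor histories are unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import GridSpec, Raster, RasterStack

ZONE_CODES = {"nodata": 0, "LS": 1, "MS": 2, "HS": 3, "US": 4}
CODE_ZONES = {v: k for k, v in ZONE_CODES.items()}
ZONES = ("LS", "MS", "HS", "US")


@dataclass
class Thresholds:
    """Classification thresholds, in percent of field-year mean yield."""

    level_pct: float = 10.0
    stability_sd_pct: float = 15.0
    min_year_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.level_pct <= 0 or self.stability_sd_pct <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not 0 < self.min_year_fraction <= 1:
            raise ValueError("min_year_fraction must be in (0, 1]")


@dataclass
class YSZMap:
    zones: Raster           # uint8 codes per ZONE_CODES
    level: Raster           # mean relative yield, %
    stability: Raster       # temporal SD of relative yield, %
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def grid(self) -> GridSpec:
        return self.zones.grid

    def zone_mask(self, zone: str) -> np.ndarray:
        return self.zones.data == ZONE_CODES[zone]


def relative_yield(stack: RasterStack) -> RasterStack:
    """Per-year percent deviation from the field-year mean.

    r(i, t) = 100 * (y(i, t) - mean_i y(i, t)) / mean_i y(i, t), means taken
    over non-missing cells of year t.
    """
    if stack.n_years < 2:
        raise ValueError("at least 2 years required")
    data = stack.data
    rel = np.full_like(data, np.nan)
    for t in range(stack.n_years):
        year = data[t]
        if np.all(np.isnan(year)):
            raise ValueError(f"year {stack.years[t]} has no non-missing cells")
        ybar = np.nanmean(year)
        if ybar == 0:
            raise ValueError(f"degenerate year {stack.years[t]}: field mean is zero")
        rel[t] = 100.0 * (year - ybar) / ybar
    return RasterStack(rel, stack.grid, years=list(stack.years))


def classify(rel_stack: RasterStack, thresholds: Thresholds | None = None) -> YSZMap:
    """Classify a relative-yield stack into the four stability zones.

    Cells with fewer than ``min_year_fraction * n_years`` valid years (and
    never fewer than 2) become nodata.
    """
    th = thresholds or Thresholds()
    rel = rel_stack.data
    n_years = rel_stack.n_years
    valid = np.sum(~np.isnan(rel), axis=0)
    min_years = max(2, math.ceil(th.min_year_fraction * n_years))

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        level = np.nanmean(rel, axis=0)
        stability = np.nanstd(rel, axis=0, ddof=1)

    classified = valid >= min_years
    if not np.any(classified):
        raise ValueError("no cell has enough valid years to classify")

    zones = np.zeros(rel.shape[1:], dtype=np.uint8)
    us = classified & (stability > th.stability_sd_pct)
    ls = classified & ~us & (level < -th.level_pct)
    hs = classified & ~us & (level > th.level_pct)
    ms = classified & ~us & ~ls & ~hs
    zones[ls] = ZONE_CODES["LS"]
    zones[ms] = ZONE_CODES["MS"]
    zones[hs] = ZONE_CODES["HS"]
    zones[us] = ZONE_CODES["US"]

    level = np.where(classified, level, np.nan)
    stability = np.where(classified, stability, np.nan)
    g = rel_stack.grid
    return YSZMap(
        zones=Raster(zones, g, nodata=0),
        level=Raster(level, g, nodata=np.nan),
        stability=Raster(stability, g, nodata=np.nan),
        thresholds=th,
    )


def zone_areas(ysz: YSZMap, ndigits: int | None = None) -> pd.DataFrame:
    """Zone area summary: hectares and percent of classified area."""
    cell_ha = ysz.grid.cell_area_m2 / 1e4
    counts = {z: int(np.sum(ysz.zone_mask(z))) for z in ZONES}
    total_cells = sum(counts.values())
    rows = []
    for z in ZONES:
        area = counts[z] * cell_ha
        pct = 100.0 * counts[z] / total_cells if total_cells else 0.0
        if ndigits is not None:
            area, pct = round(area, ndigits), round(pct, ndigits)
        rows.append({"zone": z, "area_ha": area, "pct_of_classified": pct})
    return pd.DataFrame(rows)


def area_percent(area_ha: float, total_ha: float, ndigits: int = 0) -> float:
    """Percent of classified area for a published zone/total pair."""
    pct = round(100.0 * area_ha / total_ha, ndigits)
    return int(pct) if ndigits == 0 else pct


def design_samples(
    zones: Raster,
    cores_per_zone: int = 3,
    min_spacing_m: float = 20.0,
    edge_buffer_m: float = 10.0,
    seed: int = 0,
    max_tries: int = 50,
) -> pd.DataFrame:
    """Stratified random core locations: ``cores_per_zone`` cell centres per
    zone, uniform without replacement, at least ``min_spacing_m`` apart and
    ``edge_buffer_m`` in from the field boundary.  Deterministic per seed.

    Raises if a zone has too few eligible cells or spacing is infeasible.
    """
    if cores_per_zone == 0:
        return pd.DataFrame(columns=["zone", "core", "x", "y", "row", "col"])
    g = zones.grid
    xs, ys = g.cell_centers()
    buf_cells = int(np.ceil(edge_buffer_m / g.resolution))
    interior = np.zeros(g.shape, dtype=bool)
    if g.n_rows > 2 * buf_cells and g.n_cols > 2 * buf_cells:
        interior[buf_cells: g.n_rows - buf_cells, buf_cells: g.n_cols - buf_cells] = True
    rng = np.random.default_rng(seed)
    records = []
    for zone in ZONES:
        mask = (zones.data == ZONE_CODES[zone]) & interior
        rows, cols = np.nonzero(mask)
        if len(rows) < cores_per_zone:
            raise ValueError(
                f"zone {zone} has {len(rows)} eligible cells, need {cores_per_zone}"
            )
        placed: list[tuple[float, float, int, int]] = []
        for _ in range(max_tries):
            order = rng.permutation(len(rows))
            placed = []
            for idx in order:
                x, y = xs[rows[idx], cols[idx]], ys[rows[idx], cols[idx]]
                if all(np.hypot(x - px, y - py) >= min_spacing_m for px, py, *_ in placed):
                    placed.append((x, y, int(rows[idx]), int(cols[idx])))
                    if len(placed) == cores_per_zone:
                        break
            if len(placed) == cores_per_zone:
                break
        if len(placed) < cores_per_zone:
            raise ValueError(
                f"cannot place {cores_per_zone} cores in zone {zone} with "
                f"min_spacing_m={min_spacing_m}; relax the spacing or buffer"
            )
        for i, (x, y, r, c) in enumerate(placed, start=1):
            records.append({"zone": zone, "core": i, "x": x, "y": y, "row": r, "col": c})
    return pd.DataFrame(records)
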