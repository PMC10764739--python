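"""Synthetic multi-field studies with known ground truth.

The generator emulates the spatial and statistical structure of a
north-central US Midwest yield-stability study: ten commercial fields on a
regional texture/temperature gradient, four latent yield stability zones per
field tied to terrain (low-and-stable on steep cells, unstable where flow
accumulates), multi-year yield rasters whose relative-yield level and
temporal SD encode the zones, and stratified soil cores whose SOC and soil
health metrics differ between zones by configured amounts expressed in
within-field SD units.

Every stage is deterministic per seed; per-field seeds are derived from the
master seed and the field id (CRC32), so reordering the field list does not
change any field's data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import terrain as terrain_mod
from . import ysz as ysz_mod
from .raster import GridSpec, Raster, RasterStack, write_tif

ZONES = ysz_mod.ZONES

# Zone offsets of SOC from the field mean, in within-field SD units, for the
# 0-15 cm increment.  Derived from the target standardized differences
# HS-LS = 0.89, US-LS = 0.81, US-MS = 0.43, HS-MS = 0.51 (both pairs imply
# MS-LS = 0.38), centred to mean zero.
DEFAULT_SOC_OFFSETS = {"LS": -0.52, "MS": -0.14, "HS": 0.37, "US": 0.29}

# Zone means of terrain covariates used when sampled covariates are drawn
# synthetically (no terrain raster supplied).
DEFAULT_SLOPE_MEAN = {"LS": 2.3, "MS": 1.7, "HS": 1.3, "US": 0.9}       # %
DEFAULT_LOG_FLOWACC_MEAN = {"LS": 0.56, "MS": 0.61, "HS": 0.59, "US": 1.15}

# Zone area fractions of classified area (unstable / low / medium / high).
DEFAULT_ZONE_FRACTIONS = {"US": 0.18, "LS": 0.10, "MS": 0.60, "HS": 0.12}

# Field-mean and within-field SD of each soil health metric under default
# conditions (means typical of Midwest cropland panels).
METRIC_LEVELS = {
    "co2_burst": (80.0, 25.0),
    "sol_color": (1.6, 0.45),
    "slan": (150.0, 45.0),
    "wsa": (48.0, 12.0),
    "wsoc": (150.0, 45.0),
}


@dataclass
class FieldConfig:
    """One synthetic field: extent, climate, texture and management."""

    field_id: str
    width_m: float = 300.0
    height_m: float = 300.0
    resolution: float = 2.0
    n_years: int = 12
    mat: float = 10.0          # mean annual temperature, degC
    map_mm: float = 1000.0     # mean annual precipitation, mm
    clay_pct: float = 22.0
    silt_pct: float = 48.0
    sand_pct: float = 30.0
    tillage: bool = True
    cover_crop: bool = True
    n_rate: str = "uniform"    # "uniform" | "prescription"
    seed: int = 0
    # terrain shape
    tilt_pct: float = 1.5
    tilt_azimuth_deg: float = 135.0   # direction of ascent
    n_mounds: int = 8
    mound_height_m: float = 1.2
    mound_width_m: float = 50.0
    base_elevation_m: float = 250.0
    # yield process
    mean_yield: float = 10.0          # field-year mean level, t/ha
    year_cv: float = 0.15             # SD of field-year means around mean_yield

    def __post_init__(self) -> None:
        if self.width_m <= 0 or self.height_m <= 0 or self.resolution <= 0:
            raise ValueError("extent and resolution must be positive")
        if self.n_years < 2:
            raise ValueError("need at least 2 yield years")
        total = self.clay_pct + self.silt_pct + self.sand_pct
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"texture must sum to 100, got {total}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_extent(self.width_m, self.height_m, self.resolution)


@dataclass
class ZoneEffectProfile:
    """Zone-dependent structure of the soil panel, in field-SD units."""

    soc_offset_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SOC_OFFSETS))
    shs_offset_sd: dict[str, float] = field(
        default_factory=lambda: {z: 0.7 * v for z, v in DEFAULT_SOC_OFFSETS.items()}
    )
    slope_mean_pct: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SLOPE_MEAN))
    log_flowacc_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_FLOWACC_MEAN)
    )
    depth_amplification: float = 1.5
    noise_sd: float = 1.0            # within-zone noise, field-SD units
    core_noise_fraction: float = 0.5  # share of noise variance at core level
    field_sd_soc: float = 0.472       # within-field SD of SOC, % (0.42/0.89)
    # regional gradient of field-mean SOC (%): intercept + a*clay - b*MAT
    soc_intercept: float = 3.0
    soc_clay_coef: float = 0.12
    soc_mat_coef: float = 0.39
    regional_noise_sd: float = 0.25
    # additive shift of the HS-LS gap per management flag and depth increment
    management_shift: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.soc_offset_sd, self.shs_offset_sd):
            if set(m) != set(ZONES):
                raise ValueError("offsets must cover exactly the four zones")
            if not all(np.isfinite(v) for v in m.values()):
                raise ValueError("offsets must be finite")
        if self.depth_amplification < 0:
            raise ValueError("depth_amplification must be non-negative")

    def zone_offset(self, zone: str, depth_index: int, which: str = "soc") -> float:
        base = (self.soc_offset_sd if which == "soc" else self.shs_offset_sd)[zone]
        return base * (self.depth_amplification if depth_index == 1 else 1.0)


@dataclass
class SampleDesign:
    cores_per_zone: int = 3
    depth_splits: tuple[tuple[float, float], ...] = ((0.0, 15.0), (15.0, 30.0))
    min_spacing_m: float = 20.0
    edge_buffer_m: float = 10.0

    def __post_init__(self) -> None:
        if self.cores_per_zone < 0:
            raise ValueError("cores_per_zone must be >= 0")
        top = 0.0
        for a, b in self.depth_splits:
            if a != top or b <= a:
                raise ValueError("depth splits must be contiguous from 0 and increasing")
            top = b


def field_seed(master_seed: int, field_id: str) -> int:
    """Stable per-field seed below 2**31, independent of field-list order."""
    return (int(master_seed) * 2654435761 + zlib.crc32(field_id.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# terrain

def generate_terrain(config: FieldConfig, seed: int | None = None) -> Raster:
    """Smooth synthetic elevation: planar tilt plus random Gaussian
    mounds/depressions.  Reproducible for a fixed seed; no missing cells."""
    grid = config.grid
    rng = np.random.default_rng(config.seed if seed is None else seed)
    xs, ys = grid.cell_centers()
    az = np.radians(config.tilt_azimuth_deg)
    ux, uy = np.sin(az), np.cos(az)  # unit vector of ascent
    z = config.base_elevation_m + (config.tilt_pct / 100.0) * (xs * ux + ys * uy)
    for _ in range(config.n_mounds):
        cx = rng.uniform(0, config.width_m)
        cy = rng.uniform(0, config.height_m)
        height = rng.uniform(0.3, 1.0) * config.mound_height_m * rng.choice([-1.0, 1.0])
        width = rng.uniform(0.5, 1.5) * config.mound_width_m
        z = z + height * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * width**2))
    return Raster(z, grid)


def _smooth_standardize(arr: np.ndarray, sigma_cells: float) -> np.ndarray:
    s = gaussian_filter(np.asarray(arr, dtype=float), sigma=sigma_cells, mode="nearest")
    sd = s.std()
    return (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)


def latent_zone_grid(
    steepness: np.ndarray,
    wetness: np.ndarray,
    grid: GridSpec,
    fractions: dict[str, float] | None = None,
    smoothing_m: float = 20.0,
) -> Raster:
    """Contiguous latent zones from a steepness and a wetness surface.

    Unstable cells are the wettest (highest flow-accumulation) fraction;
    among the remaining stable cells the steepest become LS and the flattest
    HS, matching the observed topographic signatures of the zones.
    """
    frac = fractions or DEFAULT_ZONE_FRACTIONS
    sigma = smoothing_m / grid.resolution
    steep = _smooth_standardize(steepness, sigma)
    wet = _smooth_standardize(wetness, sigma)
    n = steep.size
    zones = np.zeros(grid.shape, dtype=np.uint8)

    wet_rank = wet.ravel().argsort().argsort().reshape(grid.shape) / (n - 1)
    us = wet_rank >= 1.0 - frac["US"]
    zones[us] = ysz_mod.ZONE_CODES["US"]

    stable = ~us
    steep_vals = steep[stable]
    order = steep_vals.argsort().argsort() / max(1, steep_vals.size - 1)
    stable_frac_ls = frac["LS"] / (1.0 - frac["US"])
    stable_frac_hs = frac["HS"] / (1.0 - frac["US"])
    labels = np.full(steep_vals.shape, ysz_mod.ZONE_CODES["MS"], dtype=np.uint8)
    labels[order >= 1.0 - stable_frac_ls] = ysz_mod.ZONE_CODES["LS"]
    labels[order <= stable_frac_hs] = ysz_mod.ZONE_CODES["HS"]
    zones[stable] = labels
    return Raster(zones, grid, nodata=0)


def true_zone_grid(
    config: FieldConfig,
    elevation: Raster | None = None,
    fractions: dict[str, float] | None = None,
    smoothing_m: float = 20.0,
    seed: int | None = None,
) -> Raster:
    """Latent zones for one field.

    With an elevation raster the steepness/wetness surfaces are the real
    Horn slope and D8 log flow accumulation; without one they are smoothed
    Gaussian random fields (cheap surrogate with the same patch geometry).
    """
    grid = config.grid
    if elevation is not None:
        tr = terrain_mod.derive_terrain(elevation)
        return latent_zone_grid(tr.slope.data, tr.log_flowacc.data, grid,
                                fractions, smoothing_m)
    rng = np.random.default_rng((config.seed if seed is None else seed) + 7)
    steep = rng.standard_normal(grid.shape)
    wet = rng.standard_normal(grid.shape)
    return latent_zone_grid(steep, wet, grid, fractions, smoothing_m)


# ---------------------------------------------------------------------------
# yield histories

def generate_yield_stack(
    config: FieldConfig,
    zones: Raster,
    seed: int | None = None,
    level_pct: float = 15.0,
    unstable_sd: float = 0.25,
    level_jitter_pct: float = 3.0,
    noise_sd: float = 0.05,
) -> RasterStack:
    """Multi-year yield rasters encoding the latent zones.

    yield(i, t) = Ybar_t * (1 + L(i)/100 + U(i) * w_t + eps), with L a level
    surface (-level_pct on LS cells, +level_pct on HS, ~0 elsewhere plus a
    smooth within-zone jitter), U the unstable indicator, w_t a zero-mean
    year shock rescaled to exactly ``unstable_sd`` sample SD, and eps white
    noise.  Set ``level_jitter_pct`` and ``noise_sd`` to 0 for noise-free
    stacks whose classification recovers the zones exactly.
    """
    if config.n_years < 2:
        raise ValueError("n_years must be >= 2")
    grid = config.grid
    if zones.grid.shape != grid.shape:
        raise ValueError("zone grid not co-registered with field grid")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 11)

    z = zones.data
    level = np.zeros(grid.shape)
    level[z == ysz_mod.ZONE_CODES["LS"]] = -level_pct
    level[z == ysz_mod.ZONE_CODES["HS"]] = level_pct
    if level_jitter_pct > 0:
        jitter = _smooth_standardize(rng.standard_normal(grid.shape),
                                     10.0 / grid.resolution)
        level = level + level_jitter_pct * jitter
    unstable = (z == ysz_mod.ZONE_CODES["US"]).astype(float)

    w = rng.standard_normal(config.n_years)
    w = (w - w.mean()) / w.std(ddof=1) * unstable_sd
    ybar = config.mean_yield * np.clip(
        1.0 + config.year_cv * rng.standard_normal(config.n_years), 0.2, None
    )
    data = np.empty((config.n_years,) + grid.shape)
    for t in range(config.n_years):
        eps = noise_sd * rng.standard_normal(grid.shape) if noise_sd > 0 else 0.0
        data[t] = ybar[t] * (1.0 + level / 100.0 + unstable * w[t] + eps)
    return RasterStack(data, grid)


# ---------------------------------------------------------------------------
# soil samples

def _field_mean_soc(config: FieldConfig, profile: ZoneEffectProfile,
                    rng: np.random.Generator) -> float:
    det = (
        profile.soc_intercept
        + profile.soc_clay_coef * config.clay_pct
        - profile.soc_mat_coef * config.mat
    )
    return max(0.1, det + profile.regional_noise_sd * rng.standard_normal())


def generate_soil_samples(
    zones: Raster,
    design: SampleDesign,
    profile: ZoneEffectProfile,
    config: FieldConfig,
    seed: int | None = None,
    terrain: terrain_mod.TerrainRasters | None = None,
) -> pd.DataFrame:
    """Stratified soil cores split by depth, as one long-format table.

    Per core location (``cores_per_zone`` per zone, spacing/buffer honoured)
    and depth split, SOC and the six soil health metrics are drawn as
    field_mean + zone_offset_sd * field_SD + noise; the deeper increment's
    offsets are multiplied by ``depth_amplification``.  Terrain covariates
    come from the supplied rasters, or are drawn around the profile's
    configured zone means when no terrain is given.
    """
    s = config.seed if seed is None else seed
    rng = np.random.default_rng(s + 23)
    locs = ysz_mod.design_samples(
        zones,
        cores_per_zone=design.cores_per_zone,
        min_spacing_m=design.min_spacing_m,
        edge_buffer_m=design.edge_buffer_m,
        seed=s + 31,
    )
    if locs.empty:
        return pd.DataFrame()

    mean_soc = _field_mean_soc(config, profile, rng)
    sd_soc = profile.field_sd_soc
    sigma_core = profile.noise_sd * np.sqrt(profile.core_noise_fraction)
    sigma_depth = profile.noise_sd * np.sqrt(1.0 - profile.core_noise_fraction)
    depth_mean_factor = (1.0, 0.7)  # deeper increment holds less SOC on average

    if terrain is not None:
        cov = terrain_mod.sample_at_points(terrain, locs["x"], locs["y"])

    rows = []
    for i, loc in enumerate(locs.to_dict("records")):
        zone = loc["zone"]
        core_id = f"{config.field_id}-{zone}-{loc['core']}"
        core_soc = sigma_core * rng.standard_normal()
        core_met = {m: sigma_core * rng.standard_normal() for m in METRIC_LEVELS}
        core_bd = rng.normal(0.0, 0.06)
        clay = config.clay_pct + rng.normal(0.0, 1.5)
        silt = config.silt_pct + rng.normal(0.0, 1.5)
        clay = float(np.clip(clay, 0.5, 95.0))
        silt = float(np.clip(silt, 0.5, 99.0 - clay))
        sand = 100.0 - clay - silt

        if terrain is not None:
            slope = float(cov["slope_pct"].iloc[i])
            aspect = float(cov["aspect_deg"].iloc[i])
            logfa = float(cov["log_flowacc"].iloc[i])
        else:
            slope = max(0.0, rng.normal(profile.slope_mean_pct[zone], 0.8))
            logfa = max(0.0, rng.normal(profile.log_flowacc_mean[zone], 0.3))
            aspect = rng.uniform(0.0, 360.0)

        for di, (top, bottom) in enumerate(design.depth_splits):
            off = profile.zone_offset(zone, di, "soc")
            off += _management_gap_shift(profile, config, zone, di)
            z_soc = off + core_soc + sigma_depth * rng.standard_normal()
            soc = max(0.01, mean_soc * depth_mean_factor[min(di, 1)] + z_soc * sd_soc)

            row = {
                "field_id": config.field_id,
                "zone": zone,
                "core_id": core_id,
                "x": loc["x"],
                "y": loc["y"],
                "depth_top_cm": top,
                "depth_bottom_cm": bottom,
                "soc_pct": soc,
                "bulk_density": float(np.clip(
                    1.40 - 0.08 * off + core_bd + rng.normal(0.0, 0.05), 0.8, 2.0)),
                "clay_pct": clay,
                "silt_pct": silt,
                "sand_pct": sand,
                "slope_pct": slope,
                "aspect_deg": aspect,
                "log_flowacc": logfa,
                "mat": config.mat,
                "map_mm": config.map_mm,
                "tillage": config.tillage,
                "cover_crop": config.cover_crop,
                "n_rate": config.n_rate,
            }
            off_m = profile.zone_offset(zone, di, "shs")
            for m, (mu, sd) in METRIC_LEVELS.items():
                val = mu * depth_mean_factor[min(di, 1)] + sd * (
                    off_m + core_met[m] + sigma_depth * rng.standard_normal()
                )
                row[m] = float(np.clip(val, 0.0, 100.0 if m == "wsa" else np.inf))
            row["mehlich_p"] = max(0.0, rng.normal(30.0, 10.0))
            row["mehlich_k"] = max(0.0, rng.normal(120.0, 30.0))
            row["ws_no3_n"] = max(0.0, rng.normal(10.0, 4.0))
            rows.append(row)
    return pd.DataFrame(rows)


def _management_gap_shift(profile: ZoneEffectProfile, config: FieldConfig,
                          zone: str, depth_index: int) -> float:
    """Half the configured HS-LS gap shift, signed by zone, for active flags."""
    if not profile.management_shift or zone not in ("HS", "LS"):
        return 0.0
    total = 0.0
    flags = {"no_till": not config.tillage, "cover_crop": config.cover_crop,
             "prescription_n": config.n_rate == "prescription"}
    for flag, shifts in profile.management_shift.items():
        if flags.get(flag, False):
            delta = shifts[min(depth_index, len(shifts) - 1)]
            total += delta / 2.0 if zone == "HS" else -delta / 2.0
    return total


# ---------------------------------------------------------------------------
# whole studies

@dataclass
class StudyConfig:
    fields: list[FieldConfig]
    profile: ZoneEffectProfile = field(default_factory=ZoneEffectProfile)
    design: SampleDesign = field(default_factory=SampleDesign)

    def __post_init__(self) -> None:
        ids = [f.field_id for f in self.fields]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate field_id in study")
        if len(ids) < 2:
            raise ValueError("a study needs at least 2 fields for regional statistics")


# Ten fields on the Michigan-Indiana-Illinois transect: MAP (mm), MAT (degC)
# and texture per field, with tillage / cover crop / N practice flags.
# Texture triples are renormalized to sum exactly to 100.
_DEFAULT_FIELDS = [
    # id,            map_mm, mat, clay, silt, sand, till, cover, n_rate
    ("SR",            929, 9.1, 20.8, 36.9, 42.3, True,  True,  "prescription"),
    ("ZC",            955, 9.1, 21.6, 35.3, 43.0, True,  True,  "prescription"),
    ("1-Cort",        938, 9.3, 15.0, 29.6, 55.4, True,  False, "prescription"),
    ("2-Well",        949, 9.3, 12.6, 25.6, 61.8, False, True,  "prescription"),
    ("F-79-2",       1024, 9.9,  9.3, 23.4, 67.3, False, True,  "uniform"),
    ("F-71",         1045, 10.1, 10.6, 26.9, 62.6, False, True,  "uniform"),
    ("Watt-East",    1042, 10.1, 30.4, 57.8, 11.7, False, True,  "prescription"),
    ("Micic-Stateline", 1017, 10.2, 27.4, 57.1, 15.5, False, True, "prescription"),
    ("Horn-South",   1000, 12.1, 29.0, 67.2,  3.8, True,  True,  "uniform"),
    ("South-Lane",   1000, 12.1, 29.3, 68.2,  2.5, True,  False, "uniform"),
]


def default_study_fields(seed: int = 0, **overrides) -> list[FieldConfig]:
    """The ten-field Midwest transect used as the default study conditions."""
    out = []
    for fid, mp, mt, clay, silt, sand, till, cover, nrate in _DEFAULT_FIELDS:
        total = clay + silt + sand
        out.append(
            FieldConfig(
                field_id=fid,
                map_mm=mp,
                mat=mt,
                clay_pct=round(clay * 100.0 / total, 6),
                silt_pct=round(silt * 100.0 / total, 6),
                sand_pct=round(100.0 - clay * 100.0 / total - silt * 100.0 / total, 6),
                tillage=till,
                cover_crop=cover,
                n_rate=nrate,
                seed=field_seed(seed, fid),
                **overrides,
            )
        )
    return out


def default_study(seed: int = 0, **overrides) -> StudyConfig:
    return StudyConfig(fields=default_study_fields(seed, **overrides))


def generate_field(
    config: FieldConfig,
    profile: ZoneEffectProfile,
    design: SampleDesign,
    mode: str = "full",
    zones_from: str = "classified",
) -> dict:
    """Run the generator for one field.

    mode="full" builds terrain, yield rasters and the classified zone map;
    mode="stats" skips terrain and yield simulation, drawing zones from cheap
    random fields and terrain covariates from the profile's zone means.
    Returns a dict with keys among elevation, terrain, stack, ysz, zones_true,
    zones_used, samples.
    """
    out: dict = {}
    if mode == "full":
        elevation = generate_terrain(config)
        tr = terrain_mod.derive_terrain(elevation)
        zones_true = latent_zone_grid(tr.slope.data, tr.log_flowacc.data, config.grid)
        stack = generate_yield_stack(config, zones_true)
        ysz_map = ysz_mod.classify(ysz_mod.relative_yield(stack))
        zones_used = zones_true if zones_from == "truth" else ysz_map.zones
        samples = generate_soil_samples(zones_used, design, profile, config, terrain=tr)
        out.update(elevation=elevation, terrain=tr, stack=stack, ysz=ysz_map,
                   zones_true=zones_true, zones_used=zones_used, samples=samples)
    elif mode == "stats":
        zones_true = true_zone_grid(config)
        samples = generate_soil_samples(zones_true, design, profile, config)
        out.update(zones_true=zones_true, zones_used=zones_true, samples=samples)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def generate_study(
    study: StudyConfig,
    seed: int,
    outdir: str | Path | None = None,
    mode: str = "full",
    zones_from: str = "classified",
) -> pd.DataFrame:
    """Generate every field of a study and return the combined sample table.

    With ``outdir`` set, per-field rasters (elevation, per-year yield, true
    zones) are written as TIFFs under one directory per field, and the study
    table as ``samples.csv`` at the root.
    """
    tables = []
    for cfg in study.fields:
        cfg = replace(cfg, seed=field_seed(seed, cfg.field_id))
        res = generate_field(cfg, study.profile, study.design, mode=mode,
                             zones_from=zones_from)
        tables.append(res["samples"])
        if outdir is not None and mode == "full":
            fdir = Path(outdir) / cfg.field_id
            fdir.mkdir(parents=True, exist_ok=True)
            write_tif(fdir / "elevation.tif", res["elevation"])
            write_tif(fdir / "zones_true.tif", res["zones_true"])
            write_tif(fdir / "zones_classified.tif", res["ysz"].zones)
            for t in range(res["stack"].n_years):
                write_tif(fdir / f"yield_year{t + 1:02d}.tif",
                          Raster(res["stack"].data[t], cfg.grid))
    table = pd.concat(tables, ignore_index=True)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(outdir) / "samples.csv", index=False)
    return table
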