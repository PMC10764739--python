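import numpy as np
import pandas as pd
import pytest

from yszkit import synth
from yszkit.raster import GridSpec, Raster, RasterStack


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec.from_extent(100, 100, 2)


@pytest.fixture
def small_field() -> synth.FieldConfig:
    return synth.FieldConfig(field_id="toy", width_m=200, height_m=200, seed=42)


@pytest.fixture
def default_profile() -> synth.ZoneEffectProfile:
    return synth.ZoneEffectProfile()


@pytest.fixture
def default_design() -> synth.SampleDesign:
    return synth.SampleDesign()


@pytest.fixture
def block_zone_raster() -> Raster:
    """A 40x40 grid split into four 20x20 quadrant zones LS/MS/HS/US."""
    from yszkit.ysz import ZONE_CODES

    z = np.zeros((40, 40), dtype=np.uint8)
    z[:20, :20] = ZONE_CODES["LS"]
    z[:20, 20:] = ZONE_CODES["MS"]
    z[20:, :20] = ZONE_CODES["HS"]
    z[20:, 20:] = ZONE_CODES["US"]
    return Raster(z, GridSpec.from_extent(80, 80, 2), nodata=0)


def make_stack(level: np.ndarray, sd: np.ndarray, n_years: int = 10,
               seed: int = 0) -> RasterStack:
    """Relative-yield stack (percent deviations) with prescribed per-cell
    level and exact temporal sample SD; feed directly to ``ysz.classify``."""
    rng = np.random.default_rng(seed)
    shocks = rng.standard_normal(n_years)
    shocks = (shocks - shocks.mean()) / shocks.std(ddof=1)
    grid = GridSpec.from_extent(level.shape[1] * 2, level.shape[0] * 2, 2)
    data = np.empty((n_years,) + level.shape)
    for t in range(n_years):
        data[t] = level + sd * shocks[t]
    return RasterStack(data, grid)


@pytest.fixture
def null_group_table() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    return pd.DataFrame({
        "zone": np.repeat(list("ABCD"), 30),
        "value": rng.standard_normal(120),
    })
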