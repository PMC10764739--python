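"""Solvita/Haney-style soil health and fertility scoring.

The soil health score (SHS) combines six equally weighted indicators —
CO2-burst respiration, Solvita colour (log optical density), Solvita labile
amino nitrogen (SLAN), water-stable aggregates (WSA, volume %), water-soluble
organic carbon (WSOC), and SOC (%) — each expressed as a ratio to a maximum
scaling value d and capped:

    SHS = 10 * sum_k min(x_k / d_k, cap)

With the default d = (250, 5.25, 400, 80, 400, 3.5) and cap 1 the score lies
in [0, 60].  The overall fertility score adds half a nutrient index:
OFS = NI/2 + SHS, where NI is the mean of capped P, K and available-N ratios
relative to crop-recommended values, as a percent.  Available N is
water-soluble NO3-N plus mineralisable N estimated linearly from the
CO2-burst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SHS_METRICS = ("co2_burst", "sol_color", "slan", "wsa", "wsoc", "soc_pct")

DEFAULT_D = {
    "co2_burst": 250.0,  # mg CO2-C / kg
    "sol_color": 5.25,   # log optical density
    "slan": 400.0,       # mg N / kg
    "wsa": 80.0,         # volume %
    "wsoc": 400.0,       # mg / kg
    "soc_pct": 3.5,      # %
}


@dataclass
class ScalingFactors:
    d: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_D))
    ratio_cap: float = 1.0

    def __post_init__(self) -> None:
        missing = set(SHS_METRICS) - set(self.d)
        if missing:
            raise ValueError(f"missing scaling factors for {sorted(missing)}")
        if any(v <= 0 for v in self.d.values()) or self.ratio_cap <= 0:
            raise ValueError("scaling factors and ratio cap must be positive")


@dataclass
class CropRecommendation:
    """Crop-need reference values for the nutrient index (mg/kg)."""

    rec_p: float = 50.0
    rec_k: float = 150.0
    rec_n: float = 25.0

    def __post_init__(self) -> None:
        if min(self.rec_p, self.rec_k, self.rec_n) <= 0:
            raise ValueError("recommendations must be positive")


def shs(panel, factors: ScalingFactors | None = None) -> float:
    """Soil health score of one sample.

    ``panel`` is a mapping (dict / Series / dataclass-like) with the six
    metric fields in :data:`SHS_METRICS`.
    """
    f = factors or ScalingFactors()
    total = 0.0
    for k in SHS_METRICS:
        x = float(panel[k] if not hasattr(panel, k) else getattr(panel, k))
        if np.isnan(x):
            return float("nan")
        if x < 0:
            raise ValueError(f"{k} must be non-negative, got {x}")
        total += min(x / f.d[k], f.ratio_cap)
    return 10.0 * total


def n_min_from_co2(co2_burst: float, coefficient: float = 0.1) -> float:
    """Mineralisable N (mg N/kg) estimated linearly from the CO2-burst."""
    if coefficient < 0:
        raise ValueError("coefficient must be non-negative")
    if co2_burst < 0:
        raise ValueError("co2_burst must be non-negative")
    return coefficient * co2_burst


def nutrient_index(
    mehlich_p: float,
    mehlich_k: float,
    ws_no3_n: float,
    n_min: float,
    rec: CropRecommendation | None = None,
) -> float:
    """Nutrient index (%): mean of capped P, K, available-N ratios x 100."""
    rec = rec or CropRecommendation()
    available_n = ws_no3_n + n_min
    ratios = [
        min(mehlich_p / rec.rec_p, 1.0),
        min(mehlich_k / rec.rec_k, 1.0),
        min(available_n / rec.rec_n, 1.0),
    ]
    return 100.0 * float(np.mean(ratios))


def ofs(ni: float, shs_value: float) -> float:
    """Overall fertility score: NI/2 + SHS."""
    return ni / 2.0 + shs_value


def score_table(
    table: pd.DataFrame,
    factors: ScalingFactors | None = None,
    rec: CropRecommendation | None = None,
    n_min_coefficient: float = 0.1,
) -> pd.DataFrame:
    """Append ``shs``, ``ni`` and ``ofs`` columns to a long-format sample table.

    Row count and order are preserved; rows with missing metrics get missing
    scores and a logged warning.  Raises on absent required columns.
    """
    f = factors or ScalingFactors()
    rec = rec or CropRecommendation()
    required = list(SHS_METRICS) + ["mehlich_p", "mehlich_k", "ws_no3_n"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    out = table.copy()
    metric = out[list(SHS_METRICS)].to_numpy(dtype=float)
    d = np.array([f.d[k] for k in SHS_METRICS])
    if np.any(metric[~np.isnan(metric)] < 0):
        raise ValueError("negative soil health metric in table")
    shs_col = 10.0 * np.minimum(metric / d, f.ratio_cap).sum(axis=1)

    n_min = n_min_coefficient * out["co2_burst"].to_numpy(dtype=float)
    avail_n = out["ws_no3_n"].to_numpy(dtype=float) + n_min
    ni_col = (100.0 / 3.0) * (
        np.minimum(out["mehlich_p"].to_numpy(dtype=float) / rec.rec_p, 1.0)
        + np.minimum(out["mehlich_k"].to_numpy(dtype=float) / rec.rec_k, 1.0)
        + np.minimum(avail_n / rec.rec_n, 1.0)
    )
    n_bad = int(np.isnan(shs_col).sum() + np.isnan(ni_col).sum())
    if n_bad:
        log.warning("%d rows have missing metrics; scores set to NaN", n_bad)
    out["shs"] = shs_col
    out["ni"] = ni_col
    out["ofs"] = ni_col / 2.0 + shs_col
    return out
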