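"""Biome and continental stock accounting, change rates and conversions.

Biomes (from an ecoregion-derived biome raster) are the spatial accounting
units: per-biome stock is the sum of AGBD x pixel area over the biome's
pixels (Mg -> Tg, 1 Tg = 1e6 Mg), and the continental total is the exact
sum of biome totals. Stock SD treats pixels as fully correlated within
blocks (default 10 x 10 pixels = 1 km) and independent between blocks:

    stock_sd = sqrt( sum_blocks ( sum_in-block sd * area )^2 )

Period net-change rates divide the stock difference between two endpoint
years by the period length, with a 95 % CI from the endpoint SDs in
quadrature; percentage rates are expressed against a reference stock
(conventionally the final-year continental stock). Weighted means combine
period rates with their durations as weights. Biomass converts to carbon
with a fraction of 0.5 by default (0.47 is the common alternative), and
map totals compare to FAO national statistics via
100 * (study - FAO) / FAO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomass_model import AGBDMap
from .grids import Grid2D

__all__ = [
    "PeriodEstimate",
    "biome_totals",
    "period_net_change",
    "weighted_mean_rate",
    "percent_rate",
    "biomass_to_carbon",
    "fao_percent_difference",
    "MG_PER_TG",
    "TG_PER_PG",
]

MG_PER_TG = 1e6
TG_PER_PG = 1e3


class LegendError(KeyError):
    """Biome code not present in the supplied legend."""


class GapError(ValueError):
    """A period endpoint falls in a year without data."""


@dataclass(frozen=True)
class PeriodEstimate:
    """Net AGB change rate for one scope and period.

    ``rate`` and ``ci95_halfwidth`` are in Tg/yr; ``percent_rate`` in %/yr
    relative to the reference stock used at construction.
    """

    scope: str
    t_start: int
    t_end: int
    rate: float
    ci95_halfwidth: float
    percent_rate: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


def biome_totals(agbd_map: AGBDMap, biome_map: Grid2D, pixel_area_ha: float = 1.0,
                 legend: dict[int, str] | None = None,
                 block_px: int = 10) -> pd.DataFrame:
    """Per-biome (and continental) biomass stock and SD in Tg.

    Returns a DataFrame indexed by biome code (plus row ``-1`` for the
    continental total) with columns ``name``, ``stock_tg``, ``stock_sd_tg``,
    ``n_pixels``.
    """
    agbd_map.agbd.require_same_geometry(biome_map)
    agbd = agbd_map.agbd.masked_values()
    sd = agbd_map.sd.masked_values()
    codes = np.unique(biome_map.values[biome_map.valid]).astype(int)
    if legend is not None:
        unknown = [int(c) for c in codes if int(c) not in legend]
        if unknown:
            raise LegendError(f"biome code(s) {unknown} missing from legend")

    def block_sd(mask: np.ndarray) -> float:
        # correlated within block, independent between blocks
        contrib = np.where(mask & np.isfinite(sd), sd, 0.0) * pixel_area_ha
        nrows, ncols = contrib.shape
        pr = (-nrows) % block_px
        pc = (-ncols) % block_px
        padded = np.pad(contrib, ((0, pr), (0, pc)))
        blocks = padded.reshape(padded.shape[0] // block_px, block_px,
                                padded.shape[1] // block_px, block_px).sum(axis=(1, 3))
        return float(np.sqrt(np.sum(blocks ** 2))) / MG_PER_TG

    rows = []
    for code in codes:
        sel = (biome_map.values.astype(int) == code) & biome_map.valid
        valid = sel & np.isfinite(agbd)
        stock = float(np.sum(agbd[valid]) * pixel_area_ha) / MG_PER_TG
        rows.append(dict(biome=int(code),
                         name=(legend or {}).get(int(code), str(int(code))),
                         stock_tg=stock, stock_sd_tg=block_sd(valid),
                         n_pixels=int(valid.sum())))
    df = pd.DataFrame(rows).set_index("biome")
    all_valid = biome_map.valid & np.isfinite(agbd)
    continental = dict(name="continental",
                       stock_tg=float(df["stock_tg"].sum()),
                       stock_sd_tg=block_sd(all_valid),
                       n_pixels=int(df["n_pixels"].sum()))
    df.loc[-1] = continental
    return df


def period_net_change(stocks_by_year: dict[int, float], sds_by_year: dict[int, float],
                      t_start: int, t_end: int, reference_stock: float,
                      scope: str = "continental") -> PeriodEstimate:
    """Average annual net change (Tg/yr) between two endpoint years."""
    for t in (t_start, t_end):
        if t not in stocks_by_year:
            raise GapError(f"no stock for endpoint year {t}")
    dt = t_end - t_start
    rate = (stocks_by_year[t_end] - stocks_by_year[t_start]) / dt
    ci = 1.96 * np.sqrt(sds_by_year.get(t_start, 0.0) ** 2
                        + sds_by_year.get(t_end, 0.0) ** 2) / dt
    return PeriodEstimate(scope=scope, t_start=t_start, t_end=t_end,
                          rate=float(rate), ci95_halfwidth=float(ci),
                          percent_rate=percent_rate(float(rate), reference_stock))


def weighted_mean_rate(components: list[tuple[float, float]]) -> float:
    """Duration-weighted mean of period rates: sum(rate*w) / sum(w)."""
    if not components:
        raise ValueError("no components")
    rates = np.array([r for r, _ in components], float)
    weights = np.array([w for _, w in components], float)
    if (weights <= 0).any():
        raise ValueError("weights must be positive")
    return float(np.sum(rates * weights) / np.sum(weights))


def percent_rate(rate: float, reference_stock: float) -> float:
    """Annual change rate as percent of a reference stock."""
    if reference_stock <= 0:
        raise ValueError("reference stock must be positive")
    return 100.0 * rate / reference_stock


def biomass_to_carbon(agb: float, carbon_fraction: float = 0.5) -> float:
    """Biomass -> carbon in the same unit (default fraction 0.5)."""
    if not 0.0 < carbon_fraction < 1.0:
        raise ValueError("carbon fraction must lie in (0, 1)")
    return carbon_fraction * agb


def fao_percent_difference(study_value: float, fao_value: float) -> float:
    """100 * (study - FAO) / FAO, the national-statistics comparison."""
    if fao_value <= 0:
        raise ValueError("FAO value must be positive")
    return 100.0 * (study_value - fao_value) / fao_value
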