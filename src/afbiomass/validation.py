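"""Map validation against field plots aggregated to 0.1-degree cells.

Field plots are first adjusted to the map year with a per-biome linear
growth increment (a simplified temporal harmonisation), then grouped into
cells of a fixed lattice; within a cell the reference value is the
area-weighted plot mean and the map value the mean of valid map pixels.
Cell geometry follows the global 0.1-degree graticule anchored at (0, 0),
half-open with the west and north edges inclusive; on the synthetic metric
grid the default cell size is 0.1 degree at the equator (11,132 m).

The metric suite is the map-validation standard: mean bias difference
(MBD), root mean square difference (RMSD), RMSD relative to the reference
mean, and R^2 (squared Pearson correlation by default; the
coefficient-of-determination form 1 - SSE/SST is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomass_model import AGBDMap
from .synthdata import ConfigurationError

__all__ = [
    "DEG01_CELL_SIZE_M",
    "ValidationMetrics",
    "adjust_plots",
    "aggregate_cells",
    "metrics",
]

#: 0.1 degree of longitude at the equator, in metres.
DEG01_CELL_SIZE_M = 11_132.0


def adjust_plots(plots: pd.DataFrame, map_year: int,
                 growth_rate: dict[int, float]) -> pd.DataFrame:
    """Shift plot AGBD to the map year with per-biome growth rates.

    adjusted = agbd + rate * (map_year - measurement_year), floored at 0;
    the applied adjustment is recorded per plot in ``adjustment``.
    """
    out = plots.copy()
    codes = set(out["biome"].astype(int))
    missing = sorted(codes - set(growth_rate))
    if missing:
        raise ConfigurationError(f"no growth rate for biome(s) {missing}")
    rate = out["biome"].astype(int).map(growth_rate).to_numpy(float)
    gap = map_year - out["measurement_year"].to_numpy(float)
    adjusted = np.maximum(out["agbd"].to_numpy(float) + rate * gap, 0.0)
    out["adjustment"] = adjusted - out["agbd"].to_numpy(float)
    out["agbd"] = adjusted
    return out


def aggregate_cells(agbd_map: AGBDMap, plots: pd.DataFrame,
                    cell_size_m: float = DEG01_CELL_SIZE_M) -> pd.DataFrame:
    """Aggregate plots and map to lattice cells; one row per populated cell.

    Columns: cell_id, n_plots, ref_mean (area-weighted), ref_sd, map_mean.
    Cells without plots or without valid map pixels are dropped. The cell
    convention is half-open: a coordinate on a cell edge belongs to the
    cell to its east/south (west and north edges inclusive).
    """
    grid = agbd_map.agbd
    x = plots["x"].to_numpy(float)
    y = plots["y"].to_numpy(float)
    # west edge inclusive (floor on x); north edge inclusive (half-open (south, north])
    ci = np.floor(x / cell_size_m).astype(int)
    cj = np.ceil(y / cell_size_m).astype(int) - 1

    vals = grid.masked_values()
    nrows, ncols = grid.shape
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    px, py = grid.xy(rr.ravel(), cc.ravel())
    pix_ci = np.floor(px / cell_size_m).astype(int)
    pix_cj = np.ceil(py / cell_size_m).astype(int) - 1
    pix_vals = vals.ravel()

    rows = []
    for (ii, jj), sub in plots.assign(_ci=ci, _cj=cj).groupby(["_ci", "_cj"]):
        in_cell = (pix_ci == ii) & (pix_cj == jj) & np.isfinite(pix_vals)
        if not in_cell.any():
            continue
        w = sub["area_ha"].to_numpy(float)
        ref = sub["agbd"].to_numpy(float)
        ref_mean = float(np.sum(w * ref) / np.sum(w))
        ref_sd = float(np.sqrt(np.sum((w * sub["agbd_sd"].to_numpy(float)) ** 2)) / np.sum(w)) \
            if "agbd_sd" in sub else np.nan
        rows.append(dict(cell_id=f"{ii}_{jj}", n_plots=len(sub),
                         ref_mean=ref_mean, ref_sd=ref_sd,
                         map_mean=float(np.nanmean(pix_vals[in_cell]))))
    return pd.DataFrame.from_records(
        rows, columns=["cell_id", "n_plots", "ref_mean", "ref_sd", "map_mean"])


@dataclass(frozen=True)
class ValidationMetrics:
    r2: float
    rmsd: float
    rel_rmsd_percent: float
    mbd: float
    r2_is_defined: bool = True
    r2_coefficient_of_determination: float = float("nan")


def metrics(pred, ref, r2_mode: str = "pearson") -> ValidationMetrics:
    """MBD, RMSD, relative RMSD (%) and R^2 for paired estimates.

    ``r2_mode``: 'pearson' (squared correlation, default) or 'cod'
    (1 - SSE/SST); both values are always reported.
    """
    p = np.asarray(pred, float)
    r = np.asarray(ref, float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("pred and ref must be equal-length and non-empty")
    diff = p - r
    mbd = float(diff.mean())
    rmsd = float(np.sqrt(np.mean(diff ** 2)))
    rel = float(100.0 * rmsd / r.mean()) if r.mean() != 0 else float("nan")
    sst = float(np.sum((r - r.mean()) ** 2))
    cod = 1.0 - float(np.sum(diff ** 2)) / sst if sst > 0 else float("nan")
    defined = p.std() > 0 and r.std() > 0
    pearson2 = float(np.corrcoef(p, r)[0, 1] ** 2) if defined else float("nan")
    r2 = pearson2 if r2_mode == "pearson" else cod
    return ValidationMetrics(r2=r2, rmsd=rmsd, rel_rmsd_percent=rel, mbd=mbd,
                             r2_is_defined=bool(defined),
                             r2_coefficient_of_determination=cod)
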