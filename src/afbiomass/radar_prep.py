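"""Radar scene normalization, predictor indices and annualized tree cover.

Annual L-band HH/HV mosaics carry large-scale artefacts, mostly from
moisture differences between acquisitions. Each annual scene is normalized
to a common multi-year baseline by matching local first and second moments
inside a circular moving window (default 100 pixels in diameter at 50 m,
~2,000 ha): for each polarisation

    out = (x - mu_t) / sigma_t * sigma_base + mu_base

where mu/sigma are the circular-window mean/SD of the current scene and of
the baseline mosaic (per-pixel mean of the 2007-2010 scenes). The implicit
assumption is that real vegetation change is smaller-scale than the window,
so window statistics carry only the artefact.

Two predictor indices are derived in linear power: the cross-polarisation
ratio CpR = HH/HV and the Radar Forest Degradation Index
RFDI = (HH - HV) / (HH + HV). Tree-cover annualization turns a base-year
percent-cover map plus an annual loss-year raster into per-year cover
layers: loss in the target year -> 0 % cover; loss in an earlier year ->
no-data (regrowth unknown); otherwise base cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .grids import Grid2D, GeoreferencingError, block_mean

__all__ = [
    "RadarScene",
    "TreeCoverSeries",
    "PredictorStack",
    "BaselineStats",
    "circular_window_stats",
    "compute_baseline",
    "normalize_scene",
    "compute_indices",
    "derive_annual_cover",
    "build_predictor_stacks",
]

RADAR_BANDS = ("hh", "hv", "cpr", "rfdi")
ALL_BANDS = RADAR_BANDS + ("cover",)


@dataclass
class RadarScene:
    """One annual radar scene: HH and HV gamma-nought in linear power."""

    hh: Grid2D
    hv: Grid2D
    year: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hh.require_same_geometry(self.hv)


@dataclass
class TreeCoverSeries:
    """Base-year percent tree cover plus annual loss-year raster (0 = none)."""

    base_cover: Grid2D
    loss_year: Grid2D

    def __post_init__(self) -> None:
        self.base_cover.require_same_geometry(self.loss_year)


@dataclass
class PredictorStack:
    """Co-registered predictor bands at one resolution.

    ``bands`` maps band name -> Grid2D; ``band_order`` fixes the feature
    order used by the height models; ``analysis_mask`` is True where the
    pixel belongs to the woody-vegetation analysis domain (cover >= 1 % or
    cover unknown after a past disturbance).
    """

    bands: dict[str, Grid2D]
    band_order: tuple[str, ...]
    analysis_mask: np.ndarray

    @property
    def pixel_size_m(self) -> float:
        return self.bands[self.band_order[0]].pixel_size_m

    def grid(self, name: str) -> Grid2D:
        return self.bands[name]

    def feature_matrix(self, names: tuple[str, ...]) -> np.ndarray:
        """(npix, nband) matrix with NaN under each band's no-data mask."""
        return np.stack([self.bands[n].masked_values().ravel() for n in names], axis=1)


# ---------------------------------------------------------------------------
# circular moving-window statistics

def _disc_kernel(diameter_px: int) -> np.ndarray:
    if diameter_px < 3:
        raise ValueError("window diameter must be >= 3 pixels")
    r = diameter_px / 2.0
    n = diameter_px if diameter_px % 2 == 1 else diameter_px + 1
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return ((yy - c) ** 2 + (xx - c) ** 2 <= r * r).astype(float)


def circular_window_stats(grid: Grid2D, diameter_px: int = 100,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and SD over a circular disc window.

    Edges are handled by renormalizing the kernel over the valid pixels that
    actually fall inside the image (no padding is invented); no-data pixels
    are excluded the same way.
    """
    kernel = _disc_kernel(diameter_px)
    vals = np.where(grid.valid, grid.values, 0.0)
    ok = grid.valid.astype(float)
    # FFT convolution: window areas are ~7,800 px so direct convolution is slow
    weight = signal.fftconvolve(ok, kernel, mode="same")
    s1 = signal.fftconvolve(vals, kernel, mode="same")
    s2 = signal.fftconvolve(vals * vals, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / weight
        var = np.clip(s2 / weight - mean * mean, 0.0, None)
    sd = np.sqrt(var)
    mean[weight < 0.5] = np.nan
    sd[weight < 0.5] = np.nan
    return mean, sd


@dataclass
class BaselineStats:
    """Window statistics of the multi-year baseline mosaic, per polarisation."""

    mean: dict[str, np.ndarray]  # pol -> local window mean
    sd: dict[str, np.ndarray]
    mosaic: dict[str, Grid2D]    # per-pixel multi-year mean mosaic
    window_diameter_px: int
    years: tuple[int, ...]


def compute_baseline(scenes: list[RadarScene], window_diameter_px: int = 100) -> BaselineStats:
    """Per-pixel mean mosaic of the baseline years and its window statistics."""
    if not scenes:
        raise ValueError("need at least one baseline scene")
    ref = scenes[0]
    mosaic: dict[str, Grid2D] = {}
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for pol in ("hh", "hv"):
        grids = [getattr(s, pol) for s in scenes]
        for g in grids[1:]:
            grids[0].require_same_geometry(g)
        stack = np.stack([g.masked_values() for g in grids])
        with np.errstate(invalid="ignore"):
            m = np.nanmean(stack, axis=0)
        mosaic[pol] = grids[0].like(m)
        mean[pol], sd[pol] = circular_window_stats(mosaic[pol], window_diameter_px)
    return BaselineStats(mean=mean, sd=sd, mosaic=mosaic,
                         window_diameter_px=window_diameter_px,
                         years=tuple(sorted(s.year for s in scenes)))


def normalize_scene(scene: RadarScene, baseline: BaselineStats,
                    window_diameter_px: int | None = None) -> RadarScene:
    """Normalize one scene to the baseline's local moments.

    Pixels whose current window SD is ~0 receive only the mean shift (the
    gain term is undefined there); they are counted in
    ``meta['sd_passthrough_px']``.
    """
    d = window_diameter_px or baseline.window_diameter_px
    out: dict[str, Grid2D] = {}
    passthrough = 0
    for pol in ("hh", "hv"):
        grid: Grid2D = getattr(scene, pol)
        grid.require_same_geometry(baseline.mosaic[pol])
        mu_t, sd_t = circular_window_stats(grid, d)
        mu_b, sd_b = baseline.mean[pol], baseline.sd[pol]
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = np.where(sd_t > 1e-12, sd_b / np.where(sd_t > 1e-12, sd_t, 1.0), 1.0)
        passthrough += int(np.sum((sd_t <= 1e-12) & grid.valid))
        vals = (grid.values - mu_t) * gain + mu_b
        vals = np.clip(vals, 1e-9, None)
        nodata = grid.nodata | ~np.isfinite(vals)
        vals = np.where(nodata, np.nan, vals)
        out[pol] = grid.like(vals, nodata)
    res = RadarScene(hh=out["hh"], hv=out["hv"], year=scene.year)
    res.meta["sd_passthrough_px"] = passthrough
    res.meta["normalized"] = True
    return res


# ---------------------------------------------------------------------------
# indices

def compute_indices(scene: RadarScene) -> tuple[Grid2D, Grid2D]:
    """CpR = HH/HV and RFDI = (HH-HV)/(HH+HV), computed in linear power."""
    hh, hv = scene.hh.values, scene.hv.values
    valid = scene.hh.valid & scene.hv.valid
    with np.errstate(invalid="ignore", divide="ignore"):
        cpr = hh / hv
        rfdi = (hh - hv) / (hh + hv)
    cpr_bad = ~valid | ~np.isfinite(cpr)
    rfdi_bad = ~valid | ~np.isfinite(rfdi)
    cpr = np.where(cpr_bad, np.nan, cpr)
    rfdi = np.where(rfdi_bad, np.nan, rfdi)
    return scene.hh.like(cpr, cpr_bad), scene.hh.like(rfdi, rfdi_bad)


# ---------------------------------------------------------------------------
# tree-cover annualization

def derive_annual_cover(series: TreeCoverSeries, target_year: int) -> Grid2D:
    """Annual percent-cover layer for ``target_year``.

    Loss in the target year -> 0 % (bare after the event); loss in any
    earlier year -> no-data, because the base product assumes no regrowth;
    loss in a later year is invisible at the target year.
    """
    if not 2007 <= target_year <= 2017:
        raise ValueError("target year must be within 2007-2017")
    loss = series.loss_year.values
    cover = series.base_cover.values.copy()
    nodata = series.base_cover.nodata.copy()
    lost_now = (loss == target_year)
    lost_before = (loss >= 2000) & (loss < target_year)
    cover[lost_now] = 0.0
    cover[lost_before] = np.nan
    nodata |= lost_before
    return series.base_cover.like(cover, nodata)


# ---------------------------------------------------------------------------
# predictor stacks

def build_predictor_stacks(scene_norm: RadarScene,
                           indices: tuple[Grid2D, Grid2D],
                           annual_cover: Grid2D,
                           min_cover_percent: float = 1.0,
                           ) -> tuple[PredictorStack, PredictorStack]:
    """Assemble co-registered 50 m and 100 m predictor stacks.

    The 100 m stack is the 2x2 block mean of the 50 m stack. The analysis
    mask keeps pixels with cover >= ``min_cover_percent`` plus pixels whose
    cover is unknown after a past loss (those are handled by the radar-only
    height model); it drops pixels known to be below the cover threshold.
    """
    cpr, rfdi = indices
    bands50 = {"hh": scene_norm.hh, "hv": scene_norm.hv, "cpr": cpr,
               "rfdi": rfdi, "cover": annual_cover}
    ref = scene_norm.hh
    for name, g in bands50.items():
        try:
            ref.require_same_geometry(g)
        except GeoreferencingError as err:
            raise GeoreferencingError(f"band {name!r}: {err}") from err

    def mask_for(cover: Grid2D) -> np.ndarray:
        known_low = cover.valid & (cover.values < min_cover_percent)
        return ~known_low

    stack50 = PredictorStack(bands=bands50, band_order=ALL_BANDS,
                             analysis_mask=mask_for(annual_cover))
    bands100 = {name: block_mean(g, 2) for name, g in bands50.items()}
    stack100 = PredictorStack(bands=bands100, band_order=ALL_BANDS,
                              analysis_mask=mask_for(bands100["cover"]))
    return stack50, stack100
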