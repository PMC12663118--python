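"""Synthetic landscape generator with known truth.

The downstream chain (radar normalization -> canopy-height model -> biomass
model -> change detection -> stock accounting) was designed for continental
Earth-observation inputs that cannot ship with a package. This module builds
a desk-scale stand-in with the same statistical structure:

* a smooth per-biome aboveground biomass density (AGBD) field evolving
  2007-2017 under growth and scheduled disturbance events, with the
  disturbance rate stepping up after a configurable switch year;
* canopy height tied to biomass through a saturating exponential
  ``h = h_max * (1 - exp(-AGBD / lambda))``, invertible below saturation;
* annual L-band backscatter scenes (HH/HV, linear power, 50 m) as a
  saturating function of biomass with multiplicative speckle and a smooth
  additive large-scale "moisture" artefact that differs between years;
* a Landsat-style percent-tree-cover product (base cover + annual loss year);
* spaceborne-LiDAR footprints on straight tracks with geolocation error and
  quality metadata (beam type, solar elevation, sensitivity, quality flag);
* airborne-LiDAR (ALS) biomass patches and field plots with measurement
  error for calibration and validation.

All generators are pure functions of (config, seed): the same seed yields
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid2D, upsample_nearest

__all__ = [
    "ConfigurationError",
    "MissingYearError",
    "BoundsError",
    "BiomeSpec",
    "LandscapeConfig",
    "RadarSimParams",
    "CoverSimParams",
    "FootprintSimParams",
    "ReferenceSimParams",
    "DisturbanceEvent",
    "SyntheticTruth",
    "generate_truth",
    "simulate_radar_scene",
    "simulate_tree_cover",
    "simulate_footprints",
    "simulate_reference_data",
]


class ConfigurationError(ValueError):
    """Invalid landscape or pipeline configuration."""


class MissingYearError(KeyError):
    """A year was requested that the truth does not cover."""


class BoundsError(IndexError):
    """A requested window or coordinate falls outside the grid."""


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class BiomeSpec:
    """One biome stratum of the synthetic landscape.

    ``mean_agbd`` is the target base-year biome mean (Mg ha^-1);
    ``carrying_capacity`` caps growth; ``growth_rate`` is the mean annual
    increment (Mg ha^-1 yr^-1) of undisturbed pixels below capacity.
    """

    code: int
    name: str
    fraction: float
    mean_agbd: float
    carrying_capacity: float
    growth_rate: float
    landcover_class: int


#: Default two-biome layout: moist broadleaf forest vs grassland/savanna,
#: with base-year means of 300 and 32 Mg ha^-1 respectively.
DEFAULT_BIOMES: tuple[BiomeSpec, ...] = (
    BiomeSpec(1, "tropical_moist_broadleaf_forest", 0.4, 300.0, 450.0, 1.0, 1),
    BiomeSpec(2, "tropical_grassland_savanna_shrubland", 0.6, 32.0, 80.0, 0.4, 12),
)


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Disturbance rates are annual Bernoulli probabilities applied to woody
    pixels (AGBD >= ``min_disturbable_agbd``); ``disturbance_rate_after``
    applies to years strictly after ``disturbance_switch_year``. Each event
    removes exactly ``disturbance_fraction_removed`` of the pixel's biomass.
    """

    nrows: int = 128
    ncols: int = 128
    pixel_size_m: float = 100.0
    years: tuple[int, ...] = tuple(range(2007, 2018))
    radar_years: tuple[int, ...] = (2007, 2008, 2009, 2010, 2015, 2016, 2017)
    #: years with no L-band mosaic; the pipeline refuses to fabricate them
    missing_radar_years: tuple[int, ...] = (2011, 2012, 2013, 2014)
    biomes: tuple[BiomeSpec, ...] = DEFAULT_BIOMES
    disturbance_rate_before: float = 0.002
    disturbance_rate_after: float = 0.015
    disturbance_switch_year: int = 2010
    disturbance_fraction_removed: float = 0.6
    min_disturbable_agbd: float = 20.0
    h_max: float = 50.0
    lambda_agbd: float = 150.0
    agbd_cv: float = 0.25
    biome_patch_scale_px: float = 12.0
    nonvegetated_fraction: float = 0.02
    nonvegetated_class: int = 20

    def validate(self) -> None:
        if self.nrows < 32 or self.ncols < 32:
            raise ConfigurationError("grid must be at least 32 x 32 pixels")
        total = sum(b.fraction for b in self.biomes)
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"biome fractions sum to {total}, expected 1")
        for rate in (self.disturbance_rate_before, self.disturbance_rate_after):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("disturbance rates must lie in [0, 1]")
        if not 0.0 <= self.disturbance_fraction_removed <= 1.0:
            raise ConfigurationError("removed fraction must lie in [0, 1]")
        if self.years[0] > 2007 or self.years[-1] < 2017:
            raise ConfigurationError("years must cover 2007-2017")
        forbidden = set(self.radar_years) & set(self.missing_radar_years)
        if forbidden:
            raise ConfigurationError(
                f"no radar mosaics exist for {sorted(forbidden)}; refusing to fabricate")


@dataclass(frozen=True)
class RadarSimParams:
    """Backscatter forward model HV = a*(1-exp(-b*AGBD)) + floor, linear power.

    HH shares the saturation curve with a larger amplitude and a higher
    floor, so the two polarisations are correlated through biomass. Speckle
    is multiplicative gamma noise with ``looks`` looks; the default of 64
    emulates a 16-look 25 m mosaic product aggregated onto the 50 m
    simulation grid (4 independent mosaic pixels per grid cell). The
    moisture artefact is an additive random field built from Fourier modes
    whose wavelengths all exceed twice the normalization window, differing
    by year.
    """

    a_hv: float = 0.08
    b_hv: float = 0.010
    floor_hv: float = 0.003
    a_hh: float = 0.16
    b_hh: float = 0.008
    floor_hh: float = 0.012
    looks: int = 64
    speckle: bool = True
    moisture_amplitude: float = 0.004
    moisture_max_mode: int = 1
    #: relative amplitude of the non-constant modes. A synoptic moisture
    #: front is nearly uniform across a ~13 km scene, so the scene-wide
    #: offset dominates and the within-scene wave is a mild gradient.
    moisture_wave_fraction: float = 0.25


@dataclass(frozen=True)
class CoverSimParams:
    """Percent tree cover = 100*(1-exp(-AGBD/k_cover)) + optional noise."""

    k_cover: float = 60.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class FootprintSimParams:
    """LiDAR footprint sampling geometry, noise and quality metadata.

    The 12 m geolocation SD reflects the first product version's 15-20 m
    error budget. Beam type and solar elevation are orbit-level attributes
    (assigned per track); sensitivity and the quality flag vary per
    footprint.
    """

    spacing_m: float = 25.0
    geolocation_sd_m: float = 12.0
    rh100_noise_sd_m: float = 2.0
    coverage_beam_fraction: float = 0.2
    daytime_fraction: float = 0.3
    low_sensitivity_fraction: float = 0.10
    bad_quality_fraction: float = 0.05
    sample_year: int | None = None  # default: last truth year


@dataclass(frozen=True)
class ReferenceSimParams:
    """ALS patch and field-plot error model.

    Plot SD grows linearly with biomass (floor + rel * AGBD), mimicking the
    plot-harmonisation error bookkeeping; most plots are dated early in the
    record, as in typical inventory archives.
    """

    als_noise_sd: float = 10.0
    als_year: int = 2016
    plot_sd_floor: float = 5.0
    plot_rel_sd: float = 0.10
    early_year_fraction: float = 0.7
    early_years: tuple[int, ...] = (2007, 2008, 2009)


# ---------------------------------------------------------------------------
# truth container

@dataclass(frozen=True)
class DisturbanceEvent:
    year: int
    rows: np.ndarray
    cols: np.ndarray
    fraction_removed: float


@dataclass
class SyntheticTruth:
    """Known ground truth of the synthetic landscape."""

    config: LandscapeConfig
    rng_seed: int
    true_agbd_by_year: dict[int, Grid2D]
    true_height_by_year: dict[int, Grid2D]
    biome_map: Grid2D
    landcover_map: Grid2D
    growth_rate_map: Grid2D
    disturbance_log: list[DisturbanceEvent] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        return sorted(self.true_agbd_by_year)

    def require_year(self, year: int) -> None:
        if year not in self.true_agbd_by_year:
            raise MissingYearError(f"year {year} not simulated (have {self.years})")


def _smooth_field(shape: tuple[int, int], scale_px: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=scale_px, mode="wrap")
    return (sm - sm.mean()) / max(sm.std(), 1e-12)


def height_from_agbd(agbd: np.ndarray, h_max: float, lam: float) -> np.ndarray:
    """Saturating height-biomass relation h = h_max*(1-exp(-AGBD/lambda))."""
    return h_max * (1.0 - np.exp(-np.asarray(agbd, float) / lam))


def agbd_from_height(h: np.ndarray, h_max: float, lam: float) -> np.ndarray:
    """Inverse of :func:`height_from_agbd`, valid for h < h_max."""
    frac = np.clip(1.0 - np.asarray(h, float) / h_max, 1e-12, 1.0)
    return -lam * np.log(frac)


def generate_truth(config: LandscapeConfig, seed: int = 0) -> SyntheticTruth:
    """Build the full multi-year truth for one landscape realization."""
    config.validate()
    rng = np.random.default_rng(seed)
    shape = (config.nrows, config.ncols)

    # biome layout: threshold a smooth field at fraction quantiles -> blobby,
    # contiguous biome patches with the configured area shares
    layout = _smooth_field(shape, config.biome_patch_scale_px, rng)
    edges = np.quantile(layout, np.cumsum([b.fraction for b in config.biomes])[:-1])
    biome_idx = np.searchsorted(edges, layout, side="right")
    biome_codes = np.array([b.code for b in config.biomes])
    biome_map_arr = biome_codes[biome_idx]

    landcover = np.empty(shape, dtype=float)
    growth = np.empty(shape, dtype=float)
    capacity = np.empty(shape, dtype=float)
    agbd0 = np.zeros(shape, dtype=float)
    texture = _smooth_field(shape, 4.0, rng)
    for i, biome in enumerate(config.biomes):
        sel = biome_idx == i
        landcover[sel] = biome.landcover_class
        growth[sel] = biome.growth_rate
        capacity[sel] = biome.carrying_capacity
        f = np.clip(1.0 + config.agbd_cv * texture[sel], 0.0, None)
        vals = np.minimum(f * biome.mean_agbd, biome.carrying_capacity)
        # renormalize after capping so the realized biome mean hits the target
        scale = biome.mean_agbd / max(vals.mean(), 1e-12)
        agbd0[sel] = np.minimum(vals * scale, biome.carrying_capacity)

    nonveg = rng.random(shape) < config.nonvegetated_fraction
    landcover[nonveg] = config.nonvegetated_class
    agbd0[nonveg] = 0.0
    growth[nonveg] = 0.0

    base = Grid2D(np.zeros(shape), np.zeros(shape, bool),
                  pixel_size_m=config.pixel_size_m, origin=(0.0, config.nrows * config.pixel_size_m))

    log: list[DisturbanceEvent] = []
    agbd_by_year: dict[int, Grid2D] = {}
    current = agbd0
    years = sorted(config.years)
    agbd_by_year[years[0]] = base.like(current.copy())
    for prev, year in zip(years, years[1:]):
        rate = (config.disturbance_rate_after
                if year > config.disturbance_switch_year
                else config.disturbance_rate_before)
        eligible = current >= config.min_disturbable_agbd
        hit = eligible & (rng.random(shape) < rate)
        nxt = np.minimum(current + growth, capacity)
        nxt[nonveg] = current[nonveg]
        if hit.any():
            f = config.disturbance_fraction_removed
            nxt[hit] = (1.0 - f) * current[hit]  # exact fractional removal
            rr, cc = np.nonzero(hit)
            log.append(DisturbanceEvent(year=year, rows=rr, cols=cc, fraction_removed=f))
        current = nxt
        agbd_by_year[year] = base.like(current.copy())

    height_by_year = {
        y: base.like(height_from_agbd(g.values, config.h_max, config.lambda_agbd))
        for y, g in agbd_by_year.items()
    }
    return SyntheticTruth(
        config=config,
        rng_seed=seed,
        true_agbd_by_year=agbd_by_year,
        true_height_by_year=height_by_year,
        biome_map=base.like(biome_map_arr.astype(float)),
        landcover_map=base.like(landcover),
        growth_rate_map=base.like(growth),
        disturbance_log=log,
    )


# ---------------------------------------------------------------------------
# radar scenes

def _moisture_field(shape: tuple[int, int], amplitude: float, max_mode: int,
                    rng: np.random.Generator, wave_fraction: float = 0.25) -> np.ndarray:
    """Smooth additive artefact: scene-wide offset + low-order Fourier waves.

    Only modes with |k| <= max_mode are used, so for a 256-pixel 50 m scene
    all non-constant spectral power sits at wavelengths >= ~180 px (9 km),
    far above the ~2,000 ha normalization window. The constant term gets
    the full ``amplitude``; the waves are scaled by ``wave_fraction``.
    """
    nrows, ncols = shape
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    out = np.full(shape, rng.normal(0.0, amplitude))
    for ky in range(-max_mode, max_mode + 1):
        for kx in range(-max_mode, max_mode + 1):
            if ky == 0 and kx == 0:
                continue
            amp = rng.normal(0.0, amplitude * wave_fraction)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            out += amp * np.cos(2.0 * np.pi * (ky * yy / nrows + kx * xx / ncols) + phase)
    return out


def simulate_radar_scene(truth: SyntheticTruth, year: int, seed: int = 0,
                         params: RadarSimParams = RadarSimParams()):
    """Simulate one annual HH/HV scene (linear power, 50 m grid).

    Returns a :class:`afbiomass.radar_prep.RadarScene`. The moisture artefact
    realization is stored in ``scene.meta['moisture_field']`` so tests can
    verify the normalization removes it.
    """
    from .radar_prep import RadarScene  # local import to avoid cycle at import time

    truth.require_year(year)
    rng = np.random.default_rng(np.random.SeedSequence((seed, year, 0x5AD)))
    agbd50 = upsample_nearest(truth.true_agbd_by_year[year], 2)
    a = agbd50.values

    hv = params.a_hv * (1.0 - np.exp(-params.b_hv * a)) + params.floor_hv
    hh = params.a_hh * (1.0 - np.exp(-params.b_hh * a)) + params.floor_hh
    if params.speckle:
        hv = hv * rng.gamma(params.looks, 1.0 / params.looks, size=a.shape)
        hh = hh * rng.gamma(params.looks, 1.0 / params.looks, size=a.shape)
    moisture = _moisture_field(a.shape, params.moisture_amplitude,
                               params.moisture_max_mode, rng,
                               params.moisture_wave_fraction)
    hv = np.clip(hv + moisture, 1e-5, None)
    hh = np.clip(hh + moisture, 1e-5, None)

    scene = RadarScene(hh=agbd50.like(hh), hv=agbd50.like(hv), year=year)
    scene.meta["moisture_field"] = moisture
    scene.meta["seed"] = seed
    return scene


# ---------------------------------------------------------------------------
# tree cover

def simulate_tree_cover(truth: SyntheticTruth, seed: int = 0,
                        params: CoverSimParams = CoverSimParams()):
    """Base percent cover (from base-year biomass) + annual loss-year raster.

    Returns a :class:`afbiomass.radar_prep.TreeCoverSeries` on the 50 m grid.
    """
    from .radar_prep import TreeCoverSeries

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0F)))
    base_year = truth.years[0]
    agbd50 = upsample_nearest(truth.true_agbd_by_year[base_year], 2)
    cover = 100.0 * (1.0 - np.exp(-agbd50.values / params.k_cover))
    if params.noise_sd > 0:
        cover = cover + rng.normal(0.0, params.noise_sd, size=cover.shape)
    cover = np.clip(cover, 0.0, 100.0)

    loss100 = np.zeros(truth.biome_map.shape, dtype=float)
    for event in truth.disturbance_log:
        fresh = loss100[event.rows, event.cols] == 0
        loss100[event.rows[fresh], event.cols[fresh]] = event.year
    loss50 = upsample_nearest(truth.biome_map.like(loss100), 2)
    return TreeCoverSeries(base_cover=agbd50.like(cover), loss_year=loss50)


# ---------------------------------------------------------------------------
# LiDAR footprints

def simulate_footprints(truth: SyntheticTruth, n_tracks: int, footprints_per_track: int,
                        seed: int = 0,
                        params: FootprintSimParams = FootprintSimParams()) -> pd.DataFrame:
    """Sample LiDAR footprints on straight tracks across the landscape.

    Columns follow the footprint-record contract used by
    :mod:`afbiomass.footprints`; ``true_*`` columns carry the noise-free
    truth for diagnostics only.
    """
    if n_tracks < 1:
        raise ConfigurationError("need at least one track")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF00)))
    cfg = truth.config
    height = truth.true_height_by_year[
        params.sample_year if params.sample_year is not None else truth.years[-1]
    ]
    width_m = cfg.ncols * cfg.pixel_size_m
    height_m = cfg.nrows * cfg.pixel_size_m

    records: list[dict] = []
    fid = 0
    for track in range(n_tracks):
        x0 = rng.uniform(0.0, width_m)
        y0 = rng.uniform(0.0, height_m)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        dx, dy = np.cos(theta), np.sin(theta)
        beam = "coverage" if rng.random() < params.coverage_beam_fraction else "power"
        daytime = rng.random() < params.daytime_fraction
        for i in range(footprints_per_track):
            tx = x0 + i * params.spacing_m * dx
            ty = y0 + i * params.spacing_m * dy
            if not (0.0 <= tx < width_m and 0.0 <= ty < height_m):
                continue
            row, col = height.rowcol(tx, ty)
            true_h = height.values[row, col]
            rh100 = max(0.0, true_h + rng.normal(0.0, params.rh100_noise_sd_m))
            solar = rng.uniform(5.0, 60.0) if daytime else rng.uniform(-60.0, -5.0)
            if rng.random() < params.low_sensitivity_fraction:
                sens = rng.uniform(0.50, 0.95)
            else:
                sens = rng.uniform(0.96, 1.0)
            records.append(dict(
                id=fid,
                track_id=track,
                along_track_index=i,
                x=tx + rng.normal(0.0, params.geolocation_sd_m),
                y=ty + rng.normal(0.0, params.geolocation_sd_m),
                rh100=rh100,
                beam_type=beam,
                solar_elevation=solar,
                sensitivity=sens,
                quality_ok=bool(rng.random() >= params.bad_quality_fraction),
                landcover_class=int(truth.landcover_map.values[row, col]),
                true_x=tx,
                true_y=ty,
                true_height=true_h,
            ))
            fid += 1
    return pd.DataFrame.from_records(
        records,
        columns=["id", "track_id", "along_track_index", "x", "y", "rh100", "beam_type",
                 "solar_elevation", "sensitivity", "quality_ok", "landcover_class",
                 "true_x", "true_y", "true_height"],
    )


# ---------------------------------------------------------------------------
# reference data (ALS + plots)

def simulate_reference_data(truth: SyntheticTruth,
                            als_site_boxes: Sequence[tuple[int, int, int, int]],
                            n_plots: int, seed: int = 0,
                            params: ReferenceSimParams = ReferenceSimParams(),
                            ) -> tuple[list[Grid2D], pd.DataFrame]:
    """ALS biomass patches and field plots with measurement error.

    ``als_site_boxes`` are ``(row0, row1, col0, col1)`` half-open pixel
    windows on the 100 m truth grid. Plot SD grows linearly with biomass.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA15)))
    cfg = truth.config
    truth.require_year(params.als_year)
    agbd_als = truth.true_agbd_by_year[params.als_year]

    patches: list[Grid2D] = []
    for (r0, r1, c0, c1) in als_site_boxes:
        if not (0 <= r0 < r1 <= cfg.nrows and 0 <= c0 < c1 <= cfg.ncols):
            raise BoundsError(f"ALS box {(r0, r1, c0, c1)} outside {cfg.nrows}x{cfg.ncols} grid")
        vals = agbd_als.values[r0:r1, c0:c1].copy()
        if params.als_noise_sd > 0:
            vals = np.clip(vals + rng.normal(0.0, params.als_noise_sd, vals.shape), 0.0, None)
        origin = (agbd_als.origin[0] + c0 * cfg.pixel_size_m,
                  agbd_als.origin[1] - r0 * cfg.pixel_size_m)
        patches.append(Grid2D(vals, np.zeros(vals.shape, bool),
                              pixel_size_m=cfg.pixel_size_m, origin=origin,
                              crs_id=agbd_als.crs_id))

    years = np.array(truth.years)
    early = np.isin(years, params.early_years)
    if early.any() and (~early).any():
        p = np.where(early, params.early_year_fraction / early.sum(),
                     (1.0 - params.early_year_fraction) / (~early).sum())
    else:
        p = np.full(len(years), 1.0 / len(years))
    rows = rng.integers(0, cfg.nrows, n_plots)
    cols = rng.integers(0, cfg.ncols, n_plots)
    meas_years = rng.choice(years, size=n_plots, p=p)
    plots = []
    for i in range(n_plots):
        y = int(meas_years[i])
        true_val = truth.true_agbd_by_year[y].values[rows[i], cols[i]]
        sd = params.plot_sd_floor + params.plot_rel_sd * true_val
        obs = max(0.0, true_val + rng.normal(0.0, sd))
        px, py = agbd_als.xy(rows[i], cols[i])
        jitter = cfg.pixel_size_m * 0.4
        plots.append(dict(
            id=i,
            x=float(px + rng.uniform(-jitter, jitter)),
            y=float(py + rng.uniform(-jitter, jitter)),
            area_ha=float(rng.uniform(0.1, 1.0)),
            measurement_year=y,
            agbd=obs,
            agbd_sd=sd,
            biome=int(truth.biome_map.values[rows[i], cols[i]]),
            true_agbd=true_val,
        ))
    return patches, pd.DataFrame.from_records(plots)
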