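"""End-to-end orchestration: simulate -> normalize -> height -> biomass ->
change -> stocks -> validate, as one reproducible, seeded run.

The run configuration gathers every module parameter in one validated
object (YAML-loadable; unknown keys rejected) and is echoed into the
summary so a run is reproducible from its report alone. The demo scale is
a 128 x 128 landscape at 100 m (~16,400 ha), which keeps a full run under
a minute while exercising every stage at full fidelity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import accounting, biomass_model, change_detect, footprints, height_model
from . import radar_prep, synthdata, validation
from .grids import write_ascii_grid
from .synthdata import (ConfigurationError, CoverSimParams, FootprintSimParams,
                        LandscapeConfig, RadarSimParams, ReferenceSimParams)

logger = logging.getLogger("afbiomass")

__all__ = ["RunConfig", "run_end_to_end", "load_config"]


@dataclass
class RunConfig:
    """All knobs of one end-to-end run."""

    seed: int = 7
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    radar: RadarSimParams = field(default_factory=RadarSimParams)
    cover: CoverSimParams = field(default_factory=CoverSimParams)
    footprint_sim: FootprintSimParams = field(default_factory=FootprintSimParams)
    reference: ReferenceSimParams = field(default_factory=ReferenceSimParams)

    #: track density is chosen so the spatial k-fold training set holds
    #: ~200 clusters (~20 per fold), the minimum for stable fold forests;
    #: real LiDAR mission density over a scene this size is far higher
    n_tracks: int = 400
    footprints_per_track: int = 60
    train_fraction: float = 0.10
    k_regions: int = 10
    n_trees: int = 100
    window_diameter_px: int = 100
    min_cover_percent: float = 1.0
    sd_measurement_m: float = 0.0
    sd_sampling_m: float = 0.0
    sd_temporal_m: float = 0.0
    #: relative radiometric noise of one 100 m feature (16-look 25 m
    #: product: 25% / sqrt(16 px per 100 m cell) = 6.25%), propagated
    #: through the height model into the prediction SD
    radiometric_rel_sd: float = 0.0625

    als_boxes: tuple[tuple[int, int, int, int], ...] = (
        (8, 24, 8, 24), (40, 56, 90, 106), (96, 112, 20, 36), (70, 86, 60, 76),
    )
    n_plots: int = 400
    calibration_fraction: float = 0.5

    growth_threshold: float = 50.0
    ipcc_growth: dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.3})
    carbon_fraction: float = 0.5
    block_px: int = 10
    #: plot-aggregation cell edge; the 12.8 km demo landscape uses a
    #: proportionally scaled-down analogue of the 0.1-degree cell
    validation_cell_m: float = 1600.0
    periods: tuple[tuple[int, int], ...] = ((2007, 2010), (2010, 2015), (2015, 2017))


def _from_dict(cls, data: dict):
    """Build a (possibly nested) dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = {"landscape": LandscapeConfig, "radar": RadarSimParams,
               "cover": CoverSimParams, "footprint_sim": FootprintSimParams,
               "reference": ReferenceSimParams}.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(sub, value)
        elif name == "ipcc_growth" and isinstance(value, dict):
            kwargs[name] = {int(k): float(v) for k, v in value.items()}
        elif name in {"als_boxes", "periods"}:
            kwargs[name] = tuple(tuple(v) for v in value)
        elif name in {"years", "radar_years", "biomes", "early_years"}:
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (unknown keys rejected)."""
    import yaml

    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if "landscape" in data and "biomes" in data["landscape"]:
        data["landscape"]["biomes"] = tuple(
            synthdata.BiomeSpec(**b) for b in data["landscape"]["biomes"])
    return _from_dict(RunConfig, data)


def _config_digest(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_end_to_end(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full chain on a synthetic landscape; return the summary.

    Any stage failure aborts with the stage name attached so the report
    says where the chain broke.
    """
    config.landscape.validate()  # config errors surface before any stage runs
    summary: dict = {"config_digest": _config_digest(config), "seed": config.seed,
                     "stages": {}}
    stage = "init"
    t_all = time.time()
    try:
        # ---- synthetic truth -------------------------------------------
        stage = "simulate"
        t0 = time.time()
        truth = synthdata.generate_truth(config.landscape, seed=config.seed)
        cover_series = synthdata.simulate_tree_cover(truth, seed=config.seed,
                                                     params=config.cover)
        scenes = {y: synthdata.simulate_radar_scene(truth, y, seed=config.seed,
                                                    params=config.radar)
                  for y in config.landscape.radar_years}
        logger.info("simulate: %d scenes, %d disturbance events (%.1f s)",
                    len(scenes), len(truth.disturbance_log), time.time() - t0)
        summary["stages"]["simulate"] = dict(
            n_scenes=len(scenes), n_disturbance_events=len(truth.disturbance_log))

        # ---- radar normalization + stacks ------------------------------
        stage = "normalize"
        t0 = time.time()
        baseline_years = [y for y in (2007, 2008, 2009, 2010) if y in scenes]
        baseline = radar_prep.compute_baseline([scenes[y] for y in baseline_years],
                                               config.window_diameter_px)
        stacks50: dict[int, radar_prep.PredictorStack] = {}
        stacks100: dict[int, radar_prep.PredictorStack] = {}
        for year, scene in scenes.items():
            norm = radar_prep.normalize_scene(scene, baseline)
            indices = radar_prep.compute_indices(norm)
            annual_cover = radar_prep.derive_annual_cover(cover_series, year)
            s50, s100 = radar_prep.build_predictor_stacks(
                norm, indices, annual_cover, config.min_cover_percent)
            stacks50[year], stacks100[year] = s50, s100
        logger.info("normalize: baseline %s (%.1f s)", baseline_years, time.time() - t0)
        summary["stages"]["normalize"] = dict(baseline_years=baseline_years)

        # ---- footprints -------------------------------------------------
        stage = "footprints"
        t0 = time.time()
        sample_year = (config.footprint_sim.sample_year
                       or max(config.landscape.radar_years))
        fp = synthdata.simulate_footprints(truth, config.n_tracks,
                                           config.footprints_per_track,
                                           seed=config.seed, params=config.footprint_sim)
        filt = footprints.filter_footprints(fp)
        clusters = footprints.cluster_footprints(filt.kept)
        train, valid = footprints.split_train_validation(
            clusters, config.train_fraction, config.k_regions, seed=config.seed)
        train = height_model.extract_signatures(train, stacks50[sample_year])
        valid_sig = height_model.extract_signatures(valid, stacks50[sample_year])
        logger.info("footprints: %d -> %d kept -> %d clusters (%d train) (%.1f s)",
                    len(fp), len(filt.kept), len(clusters), len(train), time.time() - t0)
        summary["stages"]["footprints"] = dict(
            simulated=len(fp), kept=len(filt.kept), removed=filt.removed_counts,
            clusters=len(clusters), train=len(train), validation=len(valid))

        # ---- height models ----------------------------------------------
        stage = "height_model"
        t0 = time.time()
        ensembles = {
            v: height_model.train_height_ensemble(
                train, v, k=config.k_regions, n_trees=config.n_trees, seed=config.seed)
            for v in (height_model.VARIANT_WITH_COVER, height_model.VARIANT_RADAR_ONLY)
        }
        chm_maps: dict[int, height_model.CanopyHeightMap] = {}
        for year in scenes:
            chm = height_model.predict_height(
                ensembles, stacks100[year], cover_series, year,
                radiometric_rel_sd=config.radiometric_rel_sd)
            chm.sd_height = height_model.total_height_error(
                chm.sd_height, config.sd_measurement_m, config.sd_sampling_m,
                config.sd_temporal_m)
            chm_maps[year] = chm
        # independent cluster validation of the with-cover model
        wc = ensembles[height_model.VARIANT_WITH_COVER]
        Xv = valid_sig[[f"sig_{b}" for b in wc.band_order]].to_numpy(float)
        yv = valid_sig["mean_rh100"].to_numpy(float)
        okv = np.isfinite(Xv).all(axis=1)
        chm_val = validation.metrics(
            height_model.predict_members(wc, Xv[okv]).mean(axis=0), yv[okv])
        logger.info("height_model: oof R2=%s (%.1f s)",
                    {r: round(v, 3) for r, v in wc.oof_r2.items()}, time.time() - t0)
        summary["stages"]["height_model"] = dict(
            oof_r2_mean=float(np.mean(list(wc.oof_r2.values()))),
            validation_r2=chm_val.r2, validation_rmsd_m=chm_val.rmsd)

        # ---- biomass calibration ---------------------------------------
        stage = "biomass_model"
        t0 = time.time()
        als_patches, plots = synthdata.simulate_reference_data(
            truth, config.als_boxes, config.n_plots, seed=config.seed,
            params=config.reference)
        als_year = config.reference.als_year
        chm_als = chm_maps[als_year].mean_height
        pairs = []
        for patch in als_patches:
            r0, c0 = chm_als.rowcol(patch.origin[0] + 0.5 * patch.pixel_size_m,
                                    patch.origin[1] - 0.5 * patch.pixel_size_m)
            h = chm_als.masked_values()[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]]
            pairs.append(np.column_stack([h.ravel(), patch.values.ravel()]))
        als_pairs = np.concatenate(pairs)
        model, holdout = biomass_model.fit_sqrt_model(
            als_pairs, config.calibration_fraction, seed=config.seed)
        holdout_pred = np.clip(model.linear_predictor(holdout[:, 0]), 0, None) ** 2 * model.ratio
        holdout_metrics = validation.metrics(holdout_pred, holdout[:, 1])
        agbd_maps = {y: biomass_model.predict_agbd(chm_maps[y], model) for y in scenes}
        logger.info("biomass_model: beta0=%.3f beta1=%.3f ratio=%.4f (%.1f s)",
                    model.beta0, model.beta1, model.ratio, time.time() - t0)
        summary["stages"]["biomass_model"] = dict(
            beta0=model.beta0, beta1=model.beta1, ratio=model.ratio,
            residual_sd=model.residual_sd, fit_n=model.fit_n,
            holdout_rmsd=holdout_metrics.rmsd, holdout_r2=holdout_metrics.r2)

        # ---- change detection ------------------------------------------
        stage = "change_detect"
        t0 = time.time()
        years = sorted(agbd_maps)
        agbd_stack = np.stack([agbd_maps[y].agbd.masked_values() for y in years])
        sd_stack = np.stack([agbd_maps[y].sd.masked_values() for y in years])
        cls = change_detect.cumulative_significant_change(years, agbd_stack, sd_stack)
        slope, mk_p = change_detect.sen_slope_map(years, agbd_stack)
        cls.sen_slope, cls.mk_p = slope, mk_p
        ref_map = agbd_maps[years[-1]]
        increment = change_detect.apply_growth_policy(
            ref_map.agbd.masked_values(), cls.class_map, slope, mk_p,
            truth.biome_map.values, config.ipcc_growth, config.growth_threshold)
        gap_years = tuple(y for y in config.landscape.years if y not in years)
        series = change_detect.build_consistent_series(
            ref_map, cls, increment, tuple(years), fill_gap_years=gap_years)
        logger.info("change_detect: %d loss / %d gain px (%.1f s)",
                    int((cls.class_map == change_detect.CLASS_LOSS).sum()),
                    int((cls.class_map == change_detect.CLASS_GAIN).sum()),
                    time.time() - t0)
        summary["stages"]["change_detect"] = dict(
            n_sig_loss=int((cls.class_map == change_detect.CLASS_LOSS).sum()),
            n_sig_gain=int((cls.class_map == change_detect.CLASS_GAIN).sum()))

        # ---- accounting -------------------------------------------------
        stage = "accounting"
        t0 = time.time()
        legend = {b.code: b.name for b in config.landscape.biomes}
        stocks: dict[int, float] = {}
        sds: dict[int, float] = {}
        biome_tables = {}
        for y in years:
            table = accounting.biome_totals(series[y], truth.biome_map,
                                            pixel_area_ha=1.0, legend=legend,
                                            block_px=config.block_px)
            biome_tables[y] = table
            stocks[y] = float(table.loc[-1, "stock_tg"])
            sds[y] = float(table.loc[-1, "stock_sd_tg"])
        reference_stock = stocks[years[-1]]
        period_estimates = [
            accounting.period_net_change(stocks, sds, t0_, t1_, reference_stock)
            for (t0_, t1_) in config.periods
        ]
        mean_rate = accounting.weighted_mean_rate(
            [(p.rate, p.t_end - p.t_start) for p in period_estimates])
        carbon = accounting.biomass_to_carbon(reference_stock, config.carbon_fraction)
        logger.info("accounting: stock %.1f Tg, rates %s (%.1f s)",
                    reference_stock,
                    [round(p.rate, 2) for p in period_estimates], time.time() - t0)
        summary["stages"]["accounting"] = dict(
            stock_tg={str(y): stocks[y] for y in years},
            stock_sd_tg={str(y): sds[y] for y in years},
            reference_stock_tg=reference_stock,
            carbon_stock=carbon,
            period_estimates=[dataclasses.asdict(p) for p in period_estimates],
            weighted_mean_rate_tg_yr=mean_rate)

        # ---- validation -------------------------------------------------
        stage = "validation"
        t0 = time.time()
        growth_rates = {b.code: b.growth_rate for b in config.landscape.biomes}
        adj = validation.adjust_plots(plots, years[-1], growth_rates)
        cells = validation.aggregate_cells(series[years[-1]], adj,
                                           cell_size_m=config.validation_cell_m)
        plot_metrics = (validation.metrics(cells["map_mean"], cells["ref_mean"])
                        if len(cells) >= 3 else None)
        summary["stages"]["validation"] = dict(
            n_cells=len(cells),
            metrics=(dataclasses.asdict(plot_metrics) if plot_metrics else None))

        # ---- truth recovery diagnostics --------------------------------
        stage = "diagnostics"
        truth_loss = np.zeros(truth.biome_map.shape, bool)
        strong_loss = np.zeros(truth.biome_map.shape, bool)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
            mean_sd = np.nanmean(sd_stack, axis=0)
        detectable = [e for e in truth.disturbance_log if e.year <= years[-1] - 1]
        for event in detectable:
            truth_loss[event.rows, event.cols] = True
            before = truth.true_agbd_by_year[event.year - 1].values
            removed = event.fraction_removed * before[event.rows, event.cols]
            big = removed >= 3.0 * mean_sd[event.rows, event.cols]
            strong_loss[event.rows[big], event.cols[big]] = True
        pred_loss = cls.class_map == change_detect.CLASS_LOSS
        tp = int((pred_loss & truth_loss).sum())
        precision = tp / max(int(pred_loss.sum()), 1)
        recall = tp / max(int(truth_loss.sum()), 1)
        strong_recall = (int((pred_loss & strong_loss).sum())
                         / max(int(strong_loss.sum()), 1))
        # the 3x-SD condition applies to both sides of the power experiment:
        # precision over detections whose magnitude clears 3x the pixel SD
        pred_strong = pred_loss & (np.abs(cls.net_change) >= 3.0 * mean_sd)
        strong_precision = (int((pred_strong & truth_loss).sum())
                            / max(int(pred_strong.sum()), 1))
        truth_stocks = {
            y: float(np.sum(truth.true_agbd_by_year[y].values)) / accounting.MG_PER_TG
            for y in years}
        map2017 = series[years[-1]].agbd.masked_values()
        t17 = truth.true_agbd_by_year[years[-1]].values
        ok = np.isfinite(map2017)
        map_vs_truth = validation.metrics(map2017[ok], t17[ok])
        summary["stages"]["diagnostics"] = dict(
            loss_precision=precision, loss_recall=recall,
            strong_loss_recall=strong_recall,
            strong_loss_precision=strong_precision,
            n_truth_loss_px=int(truth_loss.sum()),
            n_strong_loss_px=int(strong_loss.sum()),
            n_pred_strong_loss_px=int(pred_strong.sum()),
            false_loss_fraction=float(pred_loss.sum() - tp) / max(int((~cls.masked).sum()), 1),
            truth_stock_tg={str(y): truth_stocks[y] for y in years},
            map_vs_truth_2017=dataclasses.asdict(map_vs_truth))

        summary["elapsed_s"] = round(time.time() - t_all, 2)
        summary["ok"] = True
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    summary = _round_floats(summary)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for y in years:
            write_ascii_grid(series[y].agbd, out_dir / f"agbd_{y}.asc")
        write_ascii_grid(truth.biome_map, out_dir / "biome_map.asc")
        cells.to_csv(out_dir / "validation_cells.csv", index=False)
        biome_tables[years[-1]].to_csv(out_dir / "biome_stocks_final_year.csv")
        with (out_dir / "summary.json").open("w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary
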