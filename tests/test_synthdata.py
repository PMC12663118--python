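"""Synthetic landscape generator: determinism, conservation, structure."""

import numpy as np
import pytest

from afbiomass.grids import block_mean
from afbiomass.synthdata import (BiomeSpec, ConfigurationError, FootprintSimParams,
                                 LandscapeConfig, MissingYearError, RadarSimParams,
                                 ReferenceSimParams, BoundsError, generate_truth,
                                 simulate_footprints, simulate_radar_scene,
                                 simulate_reference_data, simulate_tree_cover)


def test_same_seed_gives_identical_truth(small_config):
    a = generate_truth(small_config, seed=42)
    b = generate_truth(small_config, seed=42)
    for year in a.years:
        np.testing.assert_array_equal(a.true_agbd_by_year[year].values,
                                      b.true_agbd_by_year[year].values)
    np.testing.assert_array_equal(a.biome_map.values, b.biome_map.values)
    assert len(a.disturbance_log) == len(b.disturbance_log)


def test_biome_means_near_target(default_truth):
    base = default_truth.true_agbd_by_year[2007].values
    for biome in default_truth.config.biomes:
        sel = default_truth.biome_map.values == biome.code
        realized = base[sel].mean()
        assert realized == pytest.approx(biome.mean_agbd, rel=0.10)


def test_zero_disturbance_is_monotone_nondecreasing(small_config):
    cfg = LandscapeConfig(nrows=small_config.nrows, ncols=small_config.ncols,
                          disturbance_rate_before=0.0, disturbance_rate_after=0.0)
    truth = generate_truth(cfg, seed=1)
    assert truth.disturbance_log == []
    years = truth.years
    for y0, y1 in zip(years, years[1:]):
        diff = truth.true_agbd_by_year[y1].values - truth.true_agbd_by_year[y0].values
        assert (diff >= -1e-9).all()


def test_disturbance_removes_exact_fraction(default_truth):
    f = default_truth.config.disturbance_fraction_removed
    years = default_truth.years
    for event in default_truth.disturbance_log:
        before = default_truth.true_agbd_by_year[event.year - 1].values
        after = default_truth.true_agbd_by_year[event.year].values
        np.testing.assert_allclose(after[event.rows, event.cols],
                                   (1 - f) * before[event.rows, event.cols], rtol=1e-12)
    assert years[0] == 2007 and years[-1] == 2017


def test_disturbance_rate_switch(default_truth):
    cfg = default_truth.config
    per_year = {e.year: len(e.rows) for e in default_truth.disturbance_log}
    early = sum(per_year.get(y, 0) for y in range(2008, cfg.disturbance_switch_year + 1))
    late = sum(per_year.get(y, 0) for y in range(cfg.disturbance_switch_year + 1, 2018))
    # expected counts ~ rate * eligible pixels * years; late rate is 7.5x higher
    assert late > 3 * early


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        generate_truth(LandscapeConfig(nrows=16, ncols=16), seed=0)
    bad_biomes = (BiomeSpec(1, "a", 0.5, 100, 200, 1, 1),
                  BiomeSpec(2, "b", 0.3, 30, 60, 0.5, 12))
    with pytest.raises(ConfigurationError):
        generate_truth(LandscapeConfig(biomes=bad_biomes), seed=0)


class TestRadarScene:
    def test_missing_year_raises(self, small_truth):
        with pytest.raises(MissingYearError):
            simulate_radar_scene(small_truth, 1999, seed=0)

    def test_noise_free_floor_and_monotonicity(self, small_truth):
        params = RadarSimParams(speckle=False, moisture_amplitude=0.0)
        scene = simulate_radar_scene(small_truth, 2007, seed=0, params=params)
        agbd = np.kron(small_truth.true_agbd_by_year[2007].values, np.ones((2, 2)))
        # zero-biomass pixels sit exactly on the noise floor
        zero = agbd == 0
        if zero.any():
            np.testing.assert_allclose(scene.hv.values[zero], params.floor_hv, rtol=1e-9)
        # noise-free HV is non-decreasing in biomass
        order = np.argsort(agbd.ravel())
        hv_sorted = scene.hv.values.ravel()[order]
        assert (np.diff(hv_sorted) >= -1e-12).all()

    def test_moisture_field_dominates_interannual_difference(self, small_truth):
        params = RadarSimParams(speckle=False, moisture_amplitude=0.005)
        s1 = simulate_radar_scene(small_truth, 2007, seed=0, params=params)
        s2 = simulate_radar_scene(small_truth, 2008, seed=0, params=params)
        agbd_same = np.array_equal(small_truth.true_agbd_by_year[2007].values,
                                   small_truth.true_agbd_by_year[2008].values)
        diff = s2.hv.values - s1.hv.values
        expected = s2.meta["moisture_field"] - s1.meta["moisture_field"]
        if agbd_same:
            np.testing.assert_allclose(diff, expected, atol=1e-12)
        else:
            # moisture accounts for the bulk of the large-scale difference
            resid = diff - expected
            assert np.abs(resid).mean() < np.abs(expected).mean()

    def test_same_seed_identical_scene(self, small_truth):
        a = simulate_radar_scene(small_truth, 2010, seed=9)
        b = simulate_radar_scene(small_truth, 2010, seed=9)
        np.testing.assert_array_equal(a.hv.values, b.hv.values)
        np.testing.assert_array_equal(a.hh.values, b.hh.values)


class TestTreeCover:
    def test_loss_year_matches_disturbance_log(self, default_truth):
        series = simulate_tree_cover(default_truth, seed=0)
        loss100 = block_mean(series.loss_year, 2).values  # children share the value
        first_loss = {}
        for e in default_truth.disturbance_log:
            for r, c in zip(e.rows, e.cols):
                first_loss.setdefault((r, c), e.year)
        for (r, c), year in first_loss.items():
            assert loss100[r, c] == year
        disturbed = set(first_loss)
        all_px = {(r, c) for r in range(loss100.shape[0]) for c in range(loss100.shape[1])}
        undisturbed = all_px - disturbed
        rr = np.array([p[0] for p in undisturbed])
        cc = np.array([p[1] for p in undisturbed])
        assert (loss100[rr, cc] == 0).all()

    def test_cover_monotone_in_biomass(self, small_truth):
        series = simulate_tree_cover(small_truth, seed=0)
        agbd = np.kron(small_truth.true_agbd_by_year[2007].values, np.ones((2, 2)))
        hi = agbd > 390
        lo = (agbd > 0) & (agbd < 6)
        if hi.any() and lo.any():
            assert series.base_cover.values[hi].min() > series.base_cover.values[lo].max()
        assert series.base_cover.values.min() >= 0
        assert series.base_cover.values.max() <= 100


class TestFootprints:
    def test_noise_free_rh100_equals_truth(self, small_truth):
        params = FootprintSimParams(geolocation_sd_m=0.0, rh100_noise_sd_m=0.0,
                                    coverage_beam_fraction=0.0, daytime_fraction=0.0,
                                    low_sensitivity_fraction=0.0, bad_quality_fraction=0.0)
        fp = simulate_footprints(small_truth, 10, 30, seed=0, params=params)
        height = small_truth.true_height_by_year[small_truth.years[-1]]
        rows, cols = height.rowcol(fp["x"].to_numpy(), fp["y"].to_numpy())
        np.testing.assert_allclose(fp["rh100"], height.values[rows, cols], atol=1e-9)

    def test_coverage_fraction_within_binomial_bounds(self, default_truth):
        params = FootprintSimParams(coverage_beam_fraction=0.2)
        fp = simulate_footprints(default_truth, 250, 8, seed=3, params=params)
        # beam type is a per-track attribute: count tracks, not footprints
        per_track = fp.groupby("track_id")["beam_type"].first()
        n = len(per_track)
        k = (per_track == "coverage").sum()
        sd = np.sqrt(n * 0.2 * 0.8)
        assert abs(k - 0.2 * n) < 2.6 * sd  # 99% bound

    def test_same_seed_identical_table(self, small_truth):
        a = simulate_footprints(small_truth, 5, 20, seed=4)
        b = simulate_footprints(small_truth, 5, 20, seed=4)
        assert a.equals(b)


class TestReferenceData:
    def test_noise_free_als_equals_truth(self, small_truth):
        params = ReferenceSimParams(als_noise_sd=0.0, als_year=2016)
        patches, _ = simulate_reference_data(small_truth, [(4, 12, 4, 12)], 10,
                                             seed=0, params=params)
        truth_vals = small_truth.true_agbd_by_year[2016].values[4:12, 4:12]
        np.testing.assert_array_equal(patches[0].values, truth_vals)

    def test_plot_drawn_from_measurement_year(self, small_truth):
        _, plots = simulate_reference_data(small_truth, [(0, 4, 0, 4)], 200, seed=1)
        grid = small_truth.biome_map
        for _, p in plots.sample(20, random_state=0).iterrows():
            r, c = grid.rowcol(p["x"], p["y"])
            y = int(p["measurement_year"])
            assert p["true_agbd"] == small_truth.true_agbd_by_year[y].values[r, c]

    def test_out_of_grid_box_raises(self, small_truth):
        with pytest.raises(BoundsError):
            simulate_reference_data(small_truth, [(0, 100, 0, 4)], 5, seed=0)
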