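"""SD-overlap change rule, cumulative attribution, trends, reconstruction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import afbiomass.change_detect as cd
from afbiomass.biomass_model import AGBDMap
from afbiomass.grids import Grid2D


class TestClassifyPair:
    def test_printed_inequality(self):
        assert cd.classify_pair(100, 10, 70, 15) == cd.CLASS_LOSS   # 90 > 85
        assert cd.classify_pair(100, 10, 105, 10) == cd.CLASS_UNDISTURBED
        assert cd.classify_pair(70, 15, 100, 10) == cd.CLASS_GAIN

    def test_swap_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        a1, s1 = rng.uniform(0, 300, 200), rng.uniform(0, 40, 200)
        a2, s2 = rng.uniform(0, 300, 200), rng.uniform(0, 40, 200)
        fwd = cd.classify_pair(a1, s1, a2, s2)
        rev = cd.classify_pair(a2, s2, a1, s1)
        np.testing.assert_array_equal(fwd, -rev)
        for c in (0.01, 3.7):
            np.testing.assert_array_equal(
                cd.classify_pair(c * a1, c * s1, c * a2, c * s2), fwd)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            cd.classify_pair(10, -1, 5, 1)


class TestCumulative:
    def years_stack(self, series):
        """series: list of (year, agbd, sd) for a single pixel."""
        years = [y for y, _, _ in series]
        agbd = np.array([[[a]] for _, a, _ in series], float)
        sd = np.array([[[s]] for _, _, s in series], float)
        return years, agbd, sd

    def test_two_losses_assigned_to_largest(self):
        series = [(2008, 200, 5), (2009, 170, 5), (2010, 170, 5),
                  (2015, 170, 5), (2016, 120, 5), (2017, 120, 5)]
        years, agbd, sd = self.years_stack(series)
        res = cd.cumulative_significant_change(years, agbd, sd)
        assert res.class_map[0, 0] == cd.CLASS_LOSS
        assert res.net_change[0, 0] == pytest.approx(-80.0)
        assert res.assigned_year[0, 0] == 2016  # the larger loss
        assert res.net_change_sd[0, 0] == pytest.approx(np.sqrt(4 * 25))

    def test_gain_and_loss_cancel(self):
        series = [(2008, 100, 2), (2009, 80, 2), (2010, 100, 2), (2011, 100, 2)]
        years, agbd, sd = self.years_stack(series)
        res = cd.cumulative_significant_change(years, agbd, sd)
        assert res.class_map[0, 0] == cd.CLASS_UNDISTURBED
        assert res.net_change[0, 0] == pytest.approx(0.0)
        assert res.assigned_year[0, 0] == 0

    def test_insignificant_changes_ignored(self):
        series = [(2008, 100, 30), (2009, 80, 30), (2010, 120, 30)]
        years, agbd, sd = self.years_stack(series)
        res = cd.cumulative_significant_change(years, agbd, sd)
        assert res.class_map[0, 0] == cd.CLASS_UNDISTURBED

    def test_masked_year_bridged(self):
        # pixel masked in 2009; the 2008->2010 pair still finds the loss
        series = [(2008, 200, 5), (2009, np.nan, np.nan), (2010, 100, 5)]
        years, agbd, sd = self.years_stack(series)
        res = cd.cumulative_significant_change(years, agbd, sd)
        assert res.class_map[0, 0] == cd.CLASS_LOSS
        assert res.assigned_year[0, 0] == 2010

    def test_all_masked_pixel_flagged(self):
        series = [(2008, np.nan, np.nan), (2009, np.nan, np.nan)]
        years, agbd, sd = self.years_stack(series)
        res = cd.cumulative_significant_change(years, agbd, sd)
        assert res.masked[0, 0]


class TestSenSlope:
    def test_perfect_line(self):
        res = cd.sen_slope([1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0])
        assert res.slope == pytest.approx(1.0)
        assert res.defined

    def test_constant_series(self):
        res = cd.sen_slope([1, 2, 3, 4, 5], np.zeros(5))
        assert res.slope == 0.0
        assert res.mk_p == pytest.approx(1.0)

    def test_short_series_undefined(self):
        res = cd.sen_slope([1, 2], [0.0, 5.0])
        assert not res.defined
        assert res.slope == 0.0

    def test_matches_bruteforce_median_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = rng.integers(3, 11)
            years = np.sort(rng.choice(np.arange(2000, 2020), size=n, replace=False))
            vals = rng.normal(0, 10, n)
            res = cd.sen_slope(years, vals)
            pairwise = [(vals[j] - vals[i]) / (years[j] - years[i])
                        for i in range(n) for j in range(i + 1, n)]
            assert res.slope == pytest.approx(float(np.median(pairwise)))

    def test_exact_mk_p_matches_kendalltau_exact(self):
        # independent oracle: exact Kendall tau p-value equals the exact
        # Mann-Kendall p for tie-free series
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            vals = rng.normal(0, 1, n)
            res = cd.sen_slope(np.arange(n), vals)
            ref = stats.kendalltau(np.arange(n), vals, method="exact")
            assert res.mk_p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_mk_p_with_ties_matches_direct_enumeration(self):
        vals = np.array([1.0, 2.0, 2.0, 3.0, 1.0, 4.0])
        res = cd.sen_slope(np.arange(6), vals)
        s_obs = abs(sum(np.sign(b - a) for a, b in itertools.combinations(vals, 2)))
        worse = total = 0
        for perm in itertools.permutations(vals):
            s = abs(sum(np.sign(b - a) for a, b in itertools.combinations(perm, 2)))
            worse += s >= s_obs
            total += 1
        assert res.mk_p == pytest.approx(worse / total, abs=1e-12)

    def test_normal_approximation_reasonable_for_long_series(self):
        rng = np.random.default_rng(3)
        vals = np.arange(20) + rng.normal(0, 0.1, 20)
        res = cd.sen_slope(np.arange(20), vals)
        assert res.mk_p < 1e-6  # strong monotone trend

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_slope_sign_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        vals = rng.normal(0, 5, n)
        a = cd.sen_slope(np.arange(n), vals)
        b = cd.sen_slope(np.arange(n), -vals)
        assert a.slope == pytest.approx(-b.slope)
        assert a.mk_p == pytest.approx(b.mk_p)


class TestGrowthPolicy:
    def setup_method(self):
        self.biomes = np.array([[1, 1], [2, 2]])
        self.factors = {1: 0.8, 2: 0.3}

    def test_high_biomass_uses_ipcc_factor(self):
        agbd = np.array([[200.0, 200.0], [60.0, 60.0]])
        inc = cd.apply_growth_policy(agbd, np.zeros((2, 2), int),
                                     np.full((2, 2), 5.0), np.full((2, 2), 0.001),
                                     self.biomes, self.factors)
        np.testing.assert_allclose(inc, [[0.8, 0.8], [0.3, 0.3]])

    def test_low_biomass_uses_significant_sen_slope(self):
        agbd = np.full((2, 2), 30.0)
        sen = np.full((2, 2), 0.5)
        mk_p = np.array([[0.01, 0.2], [0.01, 0.2]])
        inc = cd.apply_growth_policy(agbd, np.zeros((2, 2), int), sen, mk_p,
                                     self.biomes, self.factors)
        np.testing.assert_allclose(inc, [[0.5, 0.0], [0.5, 0.0]])

    def test_disturbed_pixels_get_zero(self):
        agbd = np.full((2, 2), 200.0)
        cls = np.array([[cd.CLASS_LOSS, 0], [0, cd.CLASS_GAIN]])
        inc = cd.apply_growth_policy(agbd, cls, np.zeros((2, 2)), np.ones((2, 2)),
                                     self.biomes, self.factors)
        assert inc[0, 0] == 0.0 and inc[1, 1] == 0.0

    def test_missing_factor_rejected(self):
        from afbiomass.synthdata import ConfigurationError
        with pytest.raises(ConfigurationError):
            cd.apply_growth_policy(np.full((2, 2), 200.0), np.zeros((2, 2), int),
                                   np.zeros((2, 2)), np.ones((2, 2)),
                                   self.biomes, {1: 0.8})


def _agbd_map(vals, sds=None, year=2017):
    vals = np.asarray(vals, float)
    sds = np.zeros_like(vals) if sds is None else np.asarray(sds, float)
    g = Grid2D(vals.copy(), ~np.isfinite(vals), 100.0, (0.0, vals.shape[0] * 100.0))
    return AGBDMap(g, g.like(sds.copy()), year)


class TestConsistentSeries:
    def test_single_loss_backward_reconstruction(self):
        years = (2015, 2016, 2017)
        ref = _agbd_map(np.full((1, 1), 120.0))
        cls = cd.ChangeClassification(
            years=years, class_map=np.array([[cd.CLASS_LOSS]]),
            net_change=np.array([[-80.0]]), net_change_sd=np.array([[7.0]]),
            assigned_year=np.array([[2016]]), masked=np.zeros((1, 1), bool))
        series = cd.build_consistent_series(ref, cls, np.zeros((1, 1)), years)
        assert series[2017].agbd.values[0, 0] == pytest.approx(120.0)
        assert series[2016].agbd.values[0, 0] == pytest.approx(120.0)
        assert series[2015].agbd.values[0, 0] == pytest.approx(200.0)
        # change SD appears only on the early side of the assigned year
        assert series[2015].sd.values[0, 0] == pytest.approx(7.0)
        assert series[2016].sd.values[0, 0] == pytest.approx(0.0)

    def test_no_changes_zero_growth_identity(self):
        years = (2007, 2010, 2017)
        ref = _agbd_map(np.array([[50.0, 120.0]]))
        cls = cd.ChangeClassification(
            years=years, class_map=np.zeros((1, 2), int),
            net_change=np.zeros((1, 2)), net_change_sd=np.zeros((1, 2)),
            assigned_year=np.zeros((1, 2), int), masked=np.zeros((1, 2), bool))
        series = cd.build_consistent_series(ref, cls, np.zeros((1, 2)), years)
        for y in years:
            np.testing.assert_allclose(series[y].agbd.values, ref.agbd.values)

    def test_backward_then_forward_identity(self):
        rng = np.random.default_rng(4)
        years = (2007, 2008, 2009, 2010, 2015, 2016, 2017)
        shape = (6, 6)
        ref = _agbd_map(rng.uniform(50, 300, shape))
        cls_map = rng.choice([cd.CLASS_LOSS, 0, cd.CLASS_GAIN], shape, p=[0.2, 0.6, 0.2])
        net = np.where(cls_map == cd.CLASS_LOSS, -rng.uniform(5, 30, shape), 0.0)
        net += np.where(cls_map == cd.CLASS_GAIN, rng.uniform(5, 30, shape), 0.0)
        assigned = np.where(cls_map != 0, rng.choice(years[1:], shape), 0)
        growth = np.where(cls_map == 0, rng.uniform(0, 1, shape), 0.0)
        cls = cd.ChangeClassification(
            years=years, class_map=cls_map, net_change=net,
            net_change_sd=np.abs(net) * 0.1, assigned_year=assigned,
            masked=np.zeros(shape, bool))
        series = cd.build_consistent_series(ref, cls, growth, years)
        # roll forward from 2007 by the same rules
        cur = series[2007].agbd.values.copy()
        for earlier, later in zip(years, years[1:]):
            step = later - earlier
            changed = (assigned > earlier) & (assigned <= later)
            cur = cur + np.where(changed, net, 0.0)
            cur = cur + np.where(cls_map == 0, growth * step, 0.0)
            np.testing.assert_allclose(cur, series[later].agbd.values, atol=1e-9)

    def test_gap_years_interpolated_and_flagged(self):
        years = (2010, 2015)
        ref = _agbd_map(np.full((1, 1), 100.0), year=2015)
        cls = cd.ChangeClassification(
            years=years, class_map=np.array([[cd.CLASS_LOSS]]),
            net_change=np.array([[-50.0]]), net_change_sd=np.array([[5.0]]),
            assigned_year=np.array([[2015]]), masked=np.zeros((1, 1), bool))
        series = cd.build_consistent_series(ref, cls, np.zeros((1, 1)), years,
                                            fill_gap_years=(2011, 2012, 2013, 2014))
        assert series[2010].agbd.values[0, 0] == pytest.approx(150.0)
        # flat apportioning across the gap
        for i, y in enumerate((2011, 2012, 2013, 2014), start=1):
            expected = 150.0 - 50.0 * i / 5
            assert series[y].agbd.values[0, 0] == pytest.approx(expected)
            assert series[y].agbd.meta.get("derived_only") is True
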