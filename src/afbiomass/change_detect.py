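"""Significance-gated biomass change detection and series reconstruction.

A change between two dates is *significant* only when the one-standard-
deviation error bars do not overlap:

    loss  iff AGBD_t1 - SD_t1 > AGBD_t2 + SD_t2
    gain  iff AGBD_t1 + SD_t1 < AGBD_t2 - SD_t2

Per pixel, significant consecutive-pair changes are accumulated over the
series; a pixel whose cumulative significant change at the end of the
record is negative is a significant loss, with the full net value assigned
to the year of its largest significant loss (ties -> earliest year);
symmetric for gains. Pixels without significant net change are
"undisturbed" and receive an annual growth increment: the Theil-Sen slope
of their series when the Mann-Kendall test is significant (p < 0.05) and
biomass is low, or a user-supplied IPCC mature-forest growth factor for
their biome above a biomass threshold (default 50 Mg/ha) where radar
sensitivity is too weak to measure growth.

Finally the record is made temporally consistent by taking the last map
(2017) as reference and rolling only the significant changes (plus the
growth increments) back to the first year.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from .biomass_model import AGBDMap
from .grids import Grid2D
from .synthdata import ConfigurationError

__all__ = [
    "CLASS_LOSS",
    "CLASS_GAIN",
    "CLASS_UNDISTURBED",
    "TrendResult",
    "ChangeClassification",
    "classify_pair",
    "cumulative_significant_change",
    "sen_slope",
    "sen_slope_map",
    "apply_growth_policy",
    "build_consistent_series",
]

CLASS_LOSS = -1
CLASS_UNDISTURBED = 0
CLASS_GAIN = 1


# ---------------------------------------------------------------------------
# pairwise rule

def classify_pair(agbd_t1, sd_t1, agbd_t2, sd_t2) -> np.ndarray:
    """Label change between two dates: -1 loss, +1 gain, 0 insignificant.

    Accepts scalars or arrays (broadcast). SDs must be non-negative.
    """
    a1, s1, a2, s2 = (np.asarray(v, float) for v in (agbd_t1, sd_t1, agbd_t2, sd_t2))
    if (s1 < 0).any() or (s2 < 0).any():
        raise ValueError("standard deviations must be non-negative")
    loss = (a1 - s1) > (a2 + s2)
    gain = (a1 + s1) < (a2 - s2)
    out = np.where(loss, CLASS_LOSS, np.where(gain, CLASS_GAIN, CLASS_UNDISTURBED))
    return out.astype(int) if out.ndim else int(out)


# ---------------------------------------------------------------------------
# cumulative change over a series

@dataclass
class ChangeClassification:
    """Per-pixel change verdicts over the full series.

    ``class_map``: -1 significant loss, +1 significant gain, 0 undisturbed;
    ``net_change``: cumulative significant change (Mg/ha);
    ``net_change_sd``: quadrature SD of the accumulated significant pairs;
    ``assigned_year``: calendar year carrying the net change (0 if none);
    ``masked``: pixels with fewer than two valid years.
    Sen/Mann-Kendall layers are attached when trends are computed.
    """

    years: tuple[int, ...]
    class_map: np.ndarray
    net_change: np.ndarray
    net_change_sd: np.ndarray
    assigned_year: np.ndarray
    masked: np.ndarray
    sen_slope: np.ndarray | None = None
    mk_p: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def cumulative_significant_change(years, agbd_stack, sd_stack) -> ChangeClassification:
    """Accumulate significant consecutive-pair changes per pixel.

    ``agbd_stack``/``sd_stack`` are (n_years, nrows, ncols) arrays with NaN
    for no-data; ``years`` the matching calendar years in ascending order.
    Consecutive pairs are formed per pixel from its own valid years, so a
    pixel masked in one year (or the whole 2011-2014 radar gap) simply
    contributes a longer step.
    """
    years = tuple(int(y) for y in years)
    agbd = np.asarray(agbd_stack, float)
    sd = np.asarray(sd_stack, float)
    if agbd.shape != sd.shape or agbd.shape[0] != len(years):
        raise ValueError("stack shapes inconsistent with years")
    if len(years) < 2:
        raise ValueError("need at least two years")

    shape = agbd.shape[1:]
    prev_val = np.full(shape, np.nan)
    prev_sd = np.full(shape, np.nan)
    n_valid = np.zeros(shape, dtype=int)
    cum = np.zeros(shape)
    cum_var = np.zeros(shape)
    best_loss = np.zeros(shape)
    best_loss_year = np.zeros(shape, dtype=int)
    best_gain = np.zeros(shape)
    best_gain_year = np.zeros(shape, dtype=int)

    for t, year in enumerate(years):
        cur = agbd[t]
        cur_sd = sd[t]
        valid = np.isfinite(cur) & np.isfinite(cur_sd)
        pair = valid & np.isfinite(prev_val)
        if pair.any():
            label = np.zeros(shape, dtype=int)
            label[pair] = classify_pair(prev_val[pair], prev_sd[pair],
                                        cur[pair], cur_sd[pair])
            delta = cur - prev_val
            sig = label != 0
            cum[sig] += delta[sig]
            cum_var[sig] += prev_sd[sig] ** 2 + cur_sd[sig] ** 2
            is_loss = label == CLASS_LOSS
            # strict > keeps the earliest year on ties
            upd = is_loss & (-delta > best_loss)
            best_loss[upd] = -delta[upd]
            best_loss_year[upd] = year
            is_gain = label == CLASS_GAIN
            upd = is_gain & (delta > best_gain)
            best_gain[upd] = delta[upd]
            best_gain_year[upd] = year
        prev_val = np.where(valid, cur, prev_val)
        prev_sd = np.where(valid, cur_sd, prev_sd)
        n_valid += valid

    masked = n_valid < 2
    class_map = np.zeros(shape, dtype=int)
    class_map[cum < 0] = CLASS_LOSS
    class_map[cum > 0] = CLASS_GAIN
    class_map[masked] = 0
    cum[masked] = 0.0
    cum_var[masked] = 0.0
    assigned = np.zeros(shape, dtype=int)
    assigned[class_map == CLASS_LOSS] = best_loss_year[class_map == CLASS_LOSS]
    assigned[class_map == CLASS_GAIN] = best_gain_year[class_map == CLASS_GAIN]
    return ChangeClassification(
        years=years, class_map=class_map, net_change=cum,
        net_change_sd=np.sqrt(cum_var), assigned_year=assigned, masked=masked,
    )


# ---------------------------------------------------------------------------
# Theil-Sen slope and Mann-Kendall test

@dataclass
class TrendResult:
    slope: float
    mk_p: float
    defined: bool = True


def _mk_s(values: np.ndarray) -> int:
    diff = values[None, :] - values[:, None]
    return int(np.sign(np.triu(diff, 1)).sum())


@lru_cache(maxsize=256)
def _exact_s_distribution(rank_pattern: tuple[int, ...]) -> dict[int, float]:
    """Exact null distribution of the Mann-Kendall S statistic.

    ``rank_pattern`` is the tied-rank multiset of the series (so the cache
    is shared by all series with the same tie structure). Enumerates all
    permutations; feasible for n <= 8.
    """
    counts: dict[int, int] = {}
    total = 0
    for perm in itertools.permutations(rank_pattern):
        s = _mk_s(np.array(perm, dtype=float))
        counts[s] = counts.get(s, 0) + 1
        total += 1
    return {s: c / total for s, c in counts.items()}


def _mk_p_exact(values: np.ndarray) -> float:
    ranks = stats.rankdata(values, method="average")
    pattern = tuple(sorted(ranks))
    dist = _exact_s_distribution(pattern)
    s_obs = abs(_mk_s(values))
    return float(sum(p for s, p in dist.items() if abs(s) >= s_obs))


def _mk_p_normal(values: np.ndarray) -> float:
    n = len(values)
    s = _mk_s(values)
    _, tie_counts = np.unique(values, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5)
           - np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))) / 18.0
    if var <= 0:
        return 1.0
    z = (s - np.sign(s)) / np.sqrt(var)  # continuity correction
    return float(2.0 * stats.norm.sf(abs(z)))


def sen_slope(years, values, exact_max_n: int = 8) -> TrendResult:
    """Theil-Sen slope + two-sided Mann-Kendall p-value for one series.

    Slope is the median of all pairwise slopes (value_j - value_i) /
    (year_j - year_i), i < j. The Mann-Kendall p-value uses exhaustive
    permutation enumeration for n <= ``exact_max_n`` (tie-aware) and the
    tie-corrected normal approximation above. Fewer than 3 finite points
    yield an undefined trend carried as slope 0.
    """
    yr = np.asarray(years, float)
    v = np.asarray(values, float)
    ok = np.isfinite(yr) & np.isfinite(v)
    yr, v = yr[ok], v[ok]
    if len(v) < 3:
        return TrendResult(slope=0.0, mk_p=1.0, defined=False)
    i, j = np.triu_indices(len(v), k=1)
    slopes = (v[j] - v[i]) / (yr[j] - yr[i])
    slope = float(np.median(slopes))
    if len(v) <= exact_max_n:
        p = _mk_p_exact(v)
    else:
        p = _mk_p_normal(v)
    return TrendResult(slope=slope, mk_p=p)


def sen_slope_map(years, agbd_stack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Theil-Sen slope and Mann-Kendall p over a map stack.

    Pixels reuse the cached exact S distribution (series lengths here are
    at most 7 usable years), so this stays fast at map scale.
    """
    years = np.asarray(years, float)
    stack = np.asarray(agbd_stack, float)
    shape = stack.shape[1:]
    slope = np.zeros(shape)
    pval = np.ones(shape)
    flat = stack.reshape(len(years), -1)
    for px in range(flat.shape[1]):
        res = sen_slope(years, flat[:, px])
        slope.ravel()[px] = res.slope
        pval.ravel()[px] = res.mk_p
    return slope, pval


# ---------------------------------------------------------------------------
# growth policy

def apply_growth_policy(agbd: np.ndarray, class_map: np.ndarray,
                        sen: np.ndarray, mk_p: np.ndarray,
                        biome_map: np.ndarray,
                        ipcc_growth: dict[int, float],
                        threshold: float = 50.0,
                        p_threshold: float = 0.05) -> np.ndarray:
    """Annual growth increment (Mg/ha/yr) for undisturbed pixels.

    Above the biomass ``threshold`` the radar signal saturates and measured
    trends are unreliable, so the biome's IPCC mature-forest growth factor
    is used; below it the Theil-Sen slope applies when significant
    (p < ``p_threshold``), otherwise zero. Disturbed pixels get zero.
    """
    agbd = np.asarray(agbd, float)
    increment = np.zeros(agbd.shape)
    undisturbed = (np.asarray(class_map) == CLASS_UNDISTURBED) & np.isfinite(agbd)
    high = undisturbed & (agbd > threshold)
    codes = np.unique(np.asarray(biome_map)[high]).astype(int)
    missing = [int(c) for c in codes if int(c) not in ipcc_growth]
    if missing:
        raise ConfigurationError(f"no IPCC growth factor for biome(s) {missing}")
    for code in codes:
        sel = high & (np.asarray(biome_map).astype(int) == code)
        increment[sel] = ipcc_growth[int(code)]
    low = undisturbed & ~high & (np.asarray(mk_p) < p_threshold)
    increment[low] = np.asarray(sen, float)[low]
    return increment


# ---------------------------------------------------------------------------
# consistent annual series

def build_consistent_series(reference_2017: AGBDMap,
                            classification: ChangeClassification,
                            growth_increment: np.ndarray,
                            years: tuple[int, ...],
                            fill_gap_years: tuple[int, ...] = (),
                            ) -> dict[int, AGBDMap]:
    """Roll significant changes (and growth) back from the reference map.

    Walking backwards from the last year, each earlier map equals the later
    map minus the net significant change assigned to any year inside the
    step and minus the growth increment accumulated over the step's length
    for undisturbed pixels; values clamp at zero. SD layers are expressed
    relative to the 2017 reference (zero there), accumulating the SD of
    applied changes in quadrature, so that differences between years carry
    exactly the uncertainty of the changes applied between them.

    ``fill_gap_years`` (e.g. 2011-2014) are filled by linear interpolation
    between the bracketing reconstructed maps and flagged
    ``derived_only`` in their metadata.
    """
    years = tuple(sorted(int(y) for y in years))
    if reference_2017.year != years[-1]:
        raise ValueError("reference map must be the last year of the series")
    ref_grid = reference_2017.agbd
    shape = ref_grid.shape
    assigned = classification.assigned_year
    net = classification.net_change
    net_sd = classification.net_change_sd
    undisturbed = (classification.class_map == CLASS_UNDISTURBED) & ~classification.masked

    out: dict[int, AGBDMap] = {}
    cur = ref_grid.masked_values()
    cur_var = np.zeros(shape)
    nodata = ref_grid.nodata.copy()
    out[years[-1]] = AGBDMap(agbd=ref_grid.like(cur, nodata.copy()),
                             sd=ref_grid.like(np.zeros(shape), nodata.copy()),
                             year=years[-1])
    for later, earlier in zip(years[::-1], years[::-1][1:]):
        step = later - earlier
        vals = cur.copy()
        changed = (assigned > earlier) & (assigned <= later)
        vals[changed] -= net[changed]
        cur_var = cur_var.copy()
        cur_var[changed] += net_sd[changed] ** 2
        vals[undisturbed] -= growth_increment[undisturbed] * step
        vals = np.clip(vals, 0.0, None)
        vals[nodata] = np.nan
        cur = vals
        out[earlier] = AGBDMap(agbd=ref_grid.like(cur, nodata.copy()),
                               sd=ref_grid.like(np.sqrt(cur_var), nodata.copy()),
                               year=earlier)

    for gap_year in sorted(fill_gap_years):
        lo = max(y for y in years if y < gap_year)
        hi = min(y for y in years if y > gap_year)
        w = (gap_year - lo) / (hi - lo)
        vals = (1 - w) * out[lo].agbd.masked_values() + w * out[hi].agbd.masked_values()
        sds = (1 - w) * out[lo].sd.masked_values() + w * out[hi].sd.masked_values()
        g_a = ref_grid.like(vals, nodata.copy())
        g_s = ref_grid.like(sds, nodata.copy())
        g_a.meta["derived_only"] = True
        g_s.meta["derived_only"] = True
        out[gap_year] = AGBDMap(agbd=g_a, sd=g_s, year=gap_year)
    return out
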