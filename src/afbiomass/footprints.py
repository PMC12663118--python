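"""Spaceborne-LiDAR footprint quality filtering, clustering and splitting.

Footprint records arrive as a table (one row per footprint) with the
columns produced by :func:`afbiomass.synthdata.simulate_footprints` or read
from CSV. Quality screening keeps only full-power-beam, night-time
(solar elevation < 0 deg), high-sensitivity (> 0.95), good-quality
footprints on vegetated land cover, and drops implausible heights above a
high percentile (default 99.9) of the quality-screened set.

Surviving footprints are grouped into clusters of exactly 4 consecutive
footprints along the track direction; the cluster mean top-of-canopy height
(rh100) averages out footprint-scale sampling and geolocation error and is
the reference for the canopy-height model. A random cluster-level split
reserves a small training share (default 10 %), and the training clusters
are partitioned into k spatially contiguous, equal-count regions (via
Hilbert-curve ordering of centroids) for spatial k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import ConfigurationError

__all__ = [
    "FilterResult",
    "filter_footprints",
    "cluster_footprints",
    "split_train_validation",
    "hilbert_order",
]

#: Copernicus-style vegetated classes: the 11 forest classes + shrubland.
DEFAULT_VEGETATED_CLASSES = frozenset(range(1, 12)) | {12}

CLUSTER_SIZE = 4


@dataclass
class FilterResult:
    """Kept footprints plus per-rule removal bookkeeping."""

    kept: pd.DataFrame
    removed_counts: dict[str, int]
    height_cap_m: float

    def total_removed(self) -> int:
        return sum(self.removed_counts.values())


def filter_footprints(records: pd.DataFrame,
                      vegetated_classes: frozenset[int] = DEFAULT_VEGETATED_CLASSES,
                      height_percentile: float = 99.9,
                      percentile_before_landcover: bool = True,
                      height_cap_m: float | None = None) -> FilterResult:
    """Apply the quality rules in sequence, counting removals per rule.

    Rules: power beam only; night acquisition (solar elevation < 0); beam
    sensitivity strictly > 0.95; quality flag OK; vegetated land-cover
    class; rh100 at or below the ``height_percentile`` quantile. The
    quantile is computed on the set surviving the instrument-quality rules;
    ``percentile_before_landcover`` controls whether that reference set is
    taken before (default) or after the land-cover rule. Passing the
    ``height_cap_m`` recorded in a previous :class:`FilterResult` reuses
    that threshold instead of recomputing it (making re-filtering exactly
    idempotent); otherwise the cap is data-dependent and a second pass may
    trim up to 0.1 % more.
    """
    counts: dict[str, int] = {}
    df = records

    def apply(name: str, keep_mask: pd.Series) -> None:
        nonlocal df
        counts[name] = int((~keep_mask).sum())
        df = df[keep_mask]

    apply("coverage_beam", df["beam_type"] == "power")
    apply("daytime", df["solar_elevation"] < 0.0)
    apply("low_sensitivity", df["sensitivity"] > 0.95)
    apply("bad_quality", df["quality_ok"].astype(bool))

    cap = np.inf if height_cap_m is None else float(height_cap_m)
    if percentile_before_landcover:
        if height_cap_m is None and len(df):
            cap = float(np.quantile(df["rh100"], height_percentile / 100.0))
        apply("landcover", df["landcover_class"].isin(vegetated_classes))
        apply("height_outlier", df["rh100"] <= cap)
    else:
        apply("landcover", df["landcover_class"].isin(vegetated_classes))
        if height_cap_m is None and len(df):
            cap = float(np.quantile(df["rh100"], height_percentile / 100.0))
        apply("height_outlier", df["rh100"] <= cap)

    return FilterResult(kept=df.reset_index(drop=True), removed_counts=counts,
                        height_cap_m=cap)


def cluster_footprints(records: pd.DataFrame) -> pd.DataFrame:
    """Group footprints into non-overlapping 4-footprint along-track clusters.

    Within each maximal run of consecutive ``along_track_index`` values on a
    track, groups of 4 are formed in index order starting at the run head;
    leftovers (< 4) are discarded. Returns one row per cluster with the
    member ids, centroid coordinates and mean rh100.
    """
    clusters: list[dict] = []
    cid = 0
    for track_id, group in records.groupby("track_id", sort=True):
        g = group.sort_values("along_track_index")
        idx = g["along_track_index"].to_numpy()
        run_breaks = np.flatnonzero(np.diff(idx) != 1) + 1
        for run in np.split(np.arange(len(g)), run_breaks):
            for start in range(0, len(run) - CLUSTER_SIZE + 1, CLUSTER_SIZE):
                members = g.iloc[run[start:start + CLUSTER_SIZE]]
                clusters.append(dict(
                    cluster_id=cid,
                    track_id=track_id,
                    member_ids=tuple(members["id"]),
                    x=float(members["x"].mean()),
                    y=float(members["y"].mean()),
                    mean_rh100=float(members["rh100"].mean()),
                ))
                cid += 1
    return pd.DataFrame.from_records(
        clusters, columns=["cluster_id", "track_id", "member_ids", "x", "y", "mean_rh100"]
    )


# ---------------------------------------------------------------------------
# spatial split

def _hilbert_d(order: int, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Distance along the Hilbert curve of 2**order x 2**order cells."""
    x = x.astype(np.int64).copy()
    y = y.astype(np.int64).copy()
    d = np.zeros_like(x)
    s = np.int64(1 << (order - 1))
    while s > 0:
        rx = ((x & s) > 0).astype(np.int64)
        ry = ((y & s) > 0).astype(np.int64)
        d += s * s * ((3 * rx) ^ ry)
        # rotate quadrant (standard xy2d recurrence, vectorized)
        lower = ry == 0
        flip = lower & (rx == 1)
        x[flip] = s - 1 - x[flip]
        y[flip] = s - 1 - y[flip]
        xs, ys = x[lower].copy(), y[lower].copy()
        x[lower], y[lower] = ys, xs
        s >>= 1
    return d


def hilbert_order(x: np.ndarray, y: np.ndarray, order: int = 10) -> np.ndarray:
    """Rank points by Hilbert-curve position (space-filling, locality-preserving)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = 1 << order
    span_x = max(x.max() - x.min(), 1e-12)
    span_y = max(y.max() - y.min(), 1e-12)
    xi = np.clip(((x - x.min()) / span_x * (n - 1)).astype(np.int64), 0, n - 1)
    yi = np.clip(((y - y.min()) / span_y * (n - 1)).astype(np.int64), 0, n - 1)
    return np.argsort(_hilbert_d(order, xi, yi), kind="stable")


def split_train_validation(clusters: pd.DataFrame, train_fraction: float = 0.10,
                           n_regions: int = 10, seed: int = 0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random cluster-level train/validation split plus spatial regions.

    Training clusters get a ``region_id`` in ``1..n_regions`` assigned by
    cutting the Hilbert ordering of their centroids into equal-count bands
    (sizes differ by at most 1), giving contiguous spatial folds.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(clusters)
    n_train = int(round(n * train_fraction))
    if n_train < n_regions:
        raise ConfigurationError(
            f"{n_train} training clusters cannot fill {n_regions} regions")
    perm = rng.permutation(n)
    train = clusters.iloc[np.sort(perm[:n_train])].copy()
    valid = clusters.iloc[np.sort(perm[n_train:])].copy()

    order = hilbert_order(train["x"].to_numpy(), train["y"].to_numpy())
    region = np.empty(len(train), dtype=int)
    # equal-count bands along the space-filling ordering
    bounds = np.linspace(0, len(train), n_regions + 1).round().astype(int)
    for r in range(n_regions):
        region[order[bounds[r]:bounds[r + 1]]] = r + 1
    train["region_id"] = region
    return train.reset_index(drop=True), valid.reset_index(drop=True)
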