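"""Two-scale spatial k-fold random-forest canopy height model.

Cluster signatures are extracted at 50 m (mean of the 2x2 block of 50 m
pixels under the cluster's 1 ha parent cell) and the model predicts at
100 m. Training uses a spatial jack-knife: the training clusters are
partitioned into k contiguous regions; member j of the ensemble is a
random forest (default 100 trees) fitted on all regions except j. At
prediction time all k members predict every pixel; their mean is the
canopy height estimate and their sample standard deviation the prediction
error.

Two ensemble variants are maintained: ``with_cover`` uses radar bands plus
percent tree cover and applies to undisturbed pixels; ``radar_only`` drops
the cover band and applies to pixels disturbed before the map year, where
annualized cover is no-data because the cover product assumes no regrowth.

Per-pixel ensemble spread can be combined with footprint measurement,
sampling and temporal-mismatch error components in quadrature to give the
total height error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .grids import Grid2D
from .radar_prep import PredictorStack, RADAR_BANDS, ALL_BANDS, TreeCoverSeries
from .synthdata import BoundsError, ConfigurationError

__all__ = [
    "VARIANT_WITH_COVER",
    "VARIANT_RADAR_ONLY",
    "CanopyHeightMap",
    "HeightModelEnsemble",
    "extract_cluster_signature",
    "extract_signatures",
    "train_height_ensemble",
    "predict_height",
    "total_height_error",
]

VARIANT_WITH_COVER = "with_cover"
VARIANT_RADAR_ONLY = "radar_only"

#: integer codes written into the variant layer of a CanopyHeightMap
VARIANT_CODES = {VARIANT_WITH_COVER: 1, VARIANT_RADAR_ONLY: 2, "masked": 0}

_VARIANT_BANDS = {
    VARIANT_WITH_COVER: ALL_BANDS,
    VARIANT_RADAR_ONLY: RADAR_BANDS,
}


@dataclass
class CanopyHeightMap:
    """Per-pixel canopy height mean + SD (m) at 100 m, with variant codes."""

    mean_height: Grid2D
    sd_height: Grid2D
    variant_used: Grid2D
    year: int


@dataclass
class HeightModelEnsemble:
    """k spatially cross-validated random forests for one predictor variant."""

    variant: str
    members: list[RandomForestRegressor]
    fold_regions: dict[int, int]          # region_id -> index of member holding it out
    band_order: tuple[str, ...]
    oof_r2: dict[int, float] = field(default_factory=dict)
    oof_rmsd: dict[int, float] = field(default_factory=dict)
    training_metadata: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# signatures

def extract_cluster_signature(cluster_x: float, cluster_y: float,
                              stack_50m: PredictorStack,
                              bands: tuple[str, ...] = ALL_BANDS) -> np.ndarray:
    """Per-band mean over the 2x2 block of 50 m pixels in the cluster's 1 ha cell.

    Bands that are no-data across the whole block yield NaN in the signature.
    """
    ref = stack_50m.grid(bands[0])
    half_px = ref.pixel_size_m  # 50 m; parent cell is 2x2 of these
    col100 = int(np.floor((cluster_x - ref.origin[0]) / (2 * half_px)))
    row100 = int(np.floor((ref.origin[1] - cluster_y) / (2 * half_px)))
    r0, c0 = 2 * row100, 2 * col100
    nrows, ncols = ref.shape
    if not (0 <= r0 < nrows and 0 <= c0 < ncols):
        raise BoundsError(f"cluster centroid ({cluster_x}, {cluster_y}) outside stack")
    sig = np.empty(len(bands))
    for j, name in enumerate(bands):
        block = stack_50m.grid(name).masked_values()[r0:r0 + 2, c0:c0 + 2]
        sig[j] = np.nanmean(block) if np.isfinite(block).any() else np.nan
    return sig


def extract_signatures(clusters: pd.DataFrame, stack_50m: PredictorStack,
                       bands: tuple[str, ...] = ALL_BANDS) -> pd.DataFrame:
    """Signature matrix for a cluster table; out-of-grid clusters are dropped."""
    rows = []
    for _, cl in clusters.iterrows():
        try:
            sig = extract_cluster_signature(cl["x"], cl["y"], stack_50m, bands)
        except BoundsError:
            continue
        rec = dict(cl)
        rec.update({f"sig_{b}": v for b, v in zip(bands, sig)})
        rows.append(rec)
    return pd.DataFrame.from_records(rows)


def _signature_matrix(clusters: pd.DataFrame, bands: tuple[str, ...]) -> np.ndarray:
    return clusters[[f"sig_{b}" for b in bands]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# training

def train_height_ensemble(train_clusters: pd.DataFrame, variant: str,
                          k: int = 10, n_trees: int = 100, seed: int = 0,
                          ) -> HeightModelEnsemble:
    """Fit the k-member spatially cross-validated ensemble.

    ``train_clusters`` must carry ``region_id`` (1..k), ``mean_rh100`` and
    the ``sig_*`` columns produced by :func:`extract_signatures`. Clusters
    whose signature has NaN in a band required by the variant are dropped.
    Held-out R^2 and RMSD are recorded per fold.
    """
    bands = _VARIANT_BANDS[variant]
    X = _signature_matrix(train_clusters, bands)
    y = train_clusters["mean_rh100"].to_numpy(dtype=float)
    regions = train_clusters["region_id"].to_numpy(dtype=int)
    ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y, regions = X[ok], y[ok], regions[ok]

    region_ids = sorted(set(regions))
    if len(region_ids) != k:
        raise ConfigurationError(f"expected {k} populated regions, found {len(region_ids)}")

    members: list[RandomForestRegressor] = []
    fold_regions: dict[int, int] = {}
    oof_r2: dict[int, float] = {}
    oof_rmsd: dict[int, float] = {}
    for j, region in enumerate(region_ids):
        held = regions == region
        if held.all() or not held.any():
            raise ConfigurationError(f"region {region} leaves an empty fold")
        # leaf size 5 (the canonical regression-forest nodesize): leaf-1
        # trees memorize single clusters, so one geolocation-corrupted
        # boundary cluster can imprint a discontinuous spike on the map
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed + j,
                                   min_samples_leaf=5, n_jobs=1)
        rf.fit(X[~held], y[~held])
        pred = rf.predict(X[held])
        resid = pred - y[held]
        sst = float(np.sum((y[held] - y[held].mean()) ** 2))
        oof_r2[region] = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else np.nan
        oof_rmsd[region] = float(np.sqrt(np.mean(resid ** 2)))
        members.append(rf)
        fold_regions[region] = j

    return HeightModelEnsemble(
        variant=variant, members=members, fold_regions=fold_regions,
        band_order=bands, oof_r2=oof_r2, oof_rmsd=oof_rmsd,
        training_metadata=dict(n_clusters=int(ok.sum()), seed=seed, k=k,
                               n_trees=n_trees, bands=list(bands)),
    )


def predict_members(ensemble: HeightModelEnsemble, X: np.ndarray) -> np.ndarray:
    """(k, n) member predictions for a feature matrix with finite rows."""
    return np.stack([m.predict(X) for m in ensemble.members])


# ---------------------------------------------------------------------------
# prediction

def _loss_year_100m(cover_history: TreeCoverSeries) -> np.ndarray:
    """Loss-year raster aggregated to the 100 m grid (max over the 2x2 block)."""
    loss = cover_history.loss_year.values
    nrows, ncols = loss.shape
    return loss.reshape(nrows // 2, 2, ncols // 2, 2).max(axis=(1, 3))


def _perturbed_features(X: np.ndarray, bands: tuple[str, ...], rel: float,
                        sign: int) -> np.ndarray:
    """Features with HH/HV shifted by one radiometric relative SD.

    HH and HV are perturbed in opposite directions (the worst case for the
    ratio indices, which are invariant to a common gain) and CpR/RFDI are
    recomputed from the perturbed polarisations.
    """
    out = X.copy()
    idx = {b: i for i, b in enumerate(bands)}
    hh = X[:, idx["hh"]] * (1.0 - sign * rel)
    hv = X[:, idx["hv"]] * (1.0 + sign * rel)
    out[:, idx["hh"]] = hh
    out[:, idx["hv"]] = hv
    if "cpr" in idx:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, idx["cpr"]] = hh / hv
    if "rfdi" in idx:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, idx["rfdi"]] = (hh - hv) / (hh + hv)
    return out


def predict_height(ensembles: dict[str, HeightModelEnsemble],
                   stack_100m: PredictorStack,
                   cover_history: TreeCoverSeries,
                   year: int,
                   radiometric_rel_sd: float = 0.0) -> CanopyHeightMap:
    """Predict the 1 ha canopy height map for one year.

    Per valid pixel all k members of the selected variant predict; the mean
    is the estimate and the sample SD (n-1) the prediction error. Pixels
    disturbed before the map year use the radar-only variant; pixels outside
    the analysis mask, or lacking a finite feature vector for their variant,
    are masked.

    The fold ensemble spreads only reflect training-data variance; where the
    radar signal saturates, year-to-year prediction jitter is driven by
    radiometric (speckle) noise the ensemble cannot see. When
    ``radiometric_rel_sd`` > 0, that input noise is propagated through the
    model by central differences (HH/HV perturbed one relative SD in
    opposite directions, indices recomputed) and the half-swing of the
    ensemble-mean prediction is added to the SD in quadrature.
    """
    ref = stack_100m.grid("hh")
    nrows, ncols = ref.shape
    loss100 = _loss_year_100m(cover_history)
    radar_only_px = (loss100 >= 2000) & (loss100 < year)

    mean = np.full((nrows, ncols), np.nan)
    sd = np.full((nrows, ncols), np.nan)
    variant_code = np.zeros((nrows, ncols))

    analysis = stack_100m.analysis_mask
    for variant, ens in ensembles.items():
        sel = radar_only_px if variant == VARIANT_RADAR_ONLY else ~radar_only_px
        X = stack_100m.feature_matrix(ens.band_order)
        finite = np.isfinite(X).all(axis=1).reshape(nrows, ncols)
        todo = sel & analysis & finite
        if not todo.any():
            continue
        Xs = X[todo.ravel()]
        preds = predict_members(ens, Xs)
        mean[todo] = preds.mean(axis=0)
        var = preds.std(axis=0, ddof=1) ** 2
        if radiometric_rel_sd > 0:
            up = predict_members(
                ens, _perturbed_features(Xs, ens.band_order, radiometric_rel_sd, +1)
            ).mean(axis=0)
            dn = predict_members(
                ens, _perturbed_features(Xs, ens.band_order, radiometric_rel_sd, -1)
            ).mean(axis=0)
            var = var + (0.5 * (up - dn)) ** 2
        sd[todo] = np.sqrt(var)
        variant_code[todo] = VARIANT_CODES[variant]

    nodata = ~np.isfinite(mean)
    return CanopyHeightMap(
        mean_height=ref.like(np.where(nodata, np.nan, np.clip(mean, 0.0, None)), nodata),
        sd_height=ref.like(np.where(nodata, np.nan, sd), nodata),
        variant_used=ref.like(variant_code, np.zeros_like(variant_code, bool)),
        year=year,
    )


# ---------------------------------------------------------------------------
# error propagation

def total_height_error(sd_ensemble: Grid2D, sd_measurement: float = 0.0,
                       sd_sampling: float = 0.0, sd_temporal: float = 0.0) -> Grid2D:
    """Combine independent height error components in quadrature (metres)."""
    for s in (sd_measurement, sd_sampling, sd_temporal):
        if s < 0:
            raise ValueError("error components must be non-negative")
    total = np.sqrt(sd_ensemble.values ** 2 + sd_measurement ** 2
                    + sd_sampling ** 2 + sd_temporal ** 2)
    total = np.where(sd_ensemble.nodata, np.nan, total)
    return sd_ensemble.like(total, sd_ensemble.nodata.copy())
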