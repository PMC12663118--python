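"""Square-root height-to-biomass model with ratio bias correction.

A single empirical linear model links canopy height (CHM, m) to the square
root of aboveground biomass density:

    sqrt(AGBD) = beta0 + beta1 * CHM + eps

fitted by ordinary least squares on 50 % of the airborne-LiDAR (ALS)
reference pixels; the square-root transform damps the heteroscedasticity of
biomass residuals. Back-transforming the fit underestimates the mean
(Jensen's inequality), which is corrected multiplicatively with Snowdon's
ratio estimator

    AGBD = (beta0 + beta1 * CHM)^2 * ratio,
    ratio = sum(observed) / sum((beta0 + beta1 * CHM)^2)

computed on the calibration half, which makes the corrected predictions
conserve the observed biomass total on that set exactly. Per-pixel SD is
propagated from the height SD by the delta method and combined in
quadrature with the back-transformed residual spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid2D
from .height_model import CanopyHeightMap

__all__ = [
    "BiomassModel",
    "AGBDMap",
    "fit_sqrt_model",
    "snowdon_ratio",
    "predict_agbd",
]


class EstimationError(ValueError):
    """Degenerate inputs make the model unidentifiable."""


@dataclass
class BiomassModel:
    """Calibrated height->biomass model (sqrt scale + Snowdon ratio)."""

    beta0: float          # sqrt(Mg/ha)
    beta1: float          # sqrt(Mg/ha) per m
    ratio: float          # dimensionless multiplicative bias correction
    residual_sd: float    # sqrt(Mg/ha), OLS residual SD on the sqrt scale
    fit_n: int
    split_seed: int

    def linear_predictor(self, chm: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(chm, float)


@dataclass
class AGBDMap:
    """Aboveground biomass density mean + SD (Mg/ha) at 100 m for one year."""

    agbd: Grid2D
    sd: Grid2D
    year: int


def snowdon_ratio(observed: np.ndarray, raw_backtransform: np.ndarray) -> float:
    """Snowdon's ratio estimator: sum(observed) / sum(raw back-transform)."""
    obs = np.asarray(observed, float)
    raw = np.asarray(raw_backtransform, float)
    if obs.shape != raw.shape:
        raise ValueError("observed and back-transformed arrays differ in length")
    denom = raw.sum()
    if denom <= 0:
        raise EstimationError("non-positive back-transform sum")
    return float(obs.sum() / denom)


def fit_sqrt_model(als_pairs: np.ndarray, calibration_fraction: float = 0.5,
                   seed: int = 0) -> tuple[BiomassModel, np.ndarray]:
    """Fit the sqrt-scale model on a random calibration half of the ALS pairs.

    ``als_pairs`` is an (n, 2) array of (CHM m, AGBD Mg/ha) rows. Returns
    the calibrated model and the untouched holdout rows for validation.
    """
    pairs = np.asarray(als_pairs, float)
    pairs = pairs[np.isfinite(pairs).all(axis=1)]
    if len(pairs) < 10:
        raise EstimationError("need at least 10 finite (CHM, AGBD) pairs")
    if (pairs[:, 1] < 0).any():
        raise EstimationError("negative AGBD in reference pairs")

    rng = np.random.default_rng(seed)
    n = len(pairs)
    n_cal = int(round(n * calibration_fraction))
    perm = rng.permutation(n)
    cal = pairs[perm[:n_cal]]
    holdout = pairs[perm[n_cal:]]

    chm, agbd = cal[:, 0], cal[:, 1]
    if np.ptp(chm) <= 0:
        raise EstimationError("zero-variance CHM: slope unidentifiable")
    design = np.column_stack([np.ones_like(chm), chm])
    coef, *_ = np.linalg.lstsq(design, np.sqrt(agbd), rcond=None)
    beta0, beta1 = float(coef[0]), float(coef[1])
    resid = np.sqrt(agbd) - (beta0 + beta1 * chm)
    dof = max(len(cal) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / dof))

    raw = (beta0 + beta1 * chm) ** 2
    ratio = snowdon_ratio(agbd, raw)
    model = BiomassModel(beta0=beta0, beta1=beta1, ratio=ratio,
                         residual_sd=residual_sd, fit_n=len(cal), split_seed=seed)
    return model, holdout


def predict_agbd(chm_map: CanopyHeightMap, model: BiomassModel) -> AGBDMap:
    """Apply the calibrated model to a canopy height map.

    The linear predictor L = beta0 + beta1 * height is clamped at zero
    before squaring (a negative L would fabricate biomass from
    below-intercept heights). SD combines, in quadrature, the delta-method
    term |2 L beta1 ratio| * sd_height and the back-transformed residual
    spread 2 |L| residual_sd ratio.
    """
    h = chm_map.mean_height.masked_values()
    sd_h = chm_map.sd_height.masked_values()
    L = model.linear_predictor(h)
    Lc = np.clip(L, 0.0, None)
    agbd = Lc ** 2 * model.ratio
    sd_height_term = np.abs(2.0 * Lc * model.beta1 * model.ratio) * np.where(
        np.isfinite(sd_h), sd_h, 0.0)
    sd_resid_term = 2.0 * np.abs(L) * model.residual_sd * model.ratio
    sd = np.sqrt(sd_height_term ** 2 + sd_resid_term ** 2)
    nodata = chm_map.mean_height.nodata.copy()
    agbd = np.where(nodata, np.nan, agbd)
    sd = np.where(nodata, np.nan, sd)
    return AGBDMap(agbd=chm_map.mean_height.like(agbd, nodata),
                   sd=chm_map.mean_height.like(sd, nodata.copy()),
                   year=chm_map.year)
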