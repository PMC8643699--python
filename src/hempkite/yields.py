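"""Biomass calibration and cannabinoid yield arithmetic.

Whole-plant wet biomass (WBM, kg) predicts whole-plant dry biomass (DBM)
and dry stripped floral biomass (DSBM) through simple linear calibrations
fitted on destructively sampled plants.  The field-trial reference
calibration is packaged:

    DBM  = −0.13322  + 0.31174·WBM   (residual sd 0.1446)
    DSBM =  0.113884 + 0.156749·WBM  (residual sd 0.1031)

Cannabinoid content is reported as "total potential" percentages combining
the acid and neutral forms with a decarboxylation mass-loss factor, and
yield per plant is total cannabinoid percentage times dry stripped floral
biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LinearCalibration",
    "BiomassCalibration",
    "REFERENCE_CALIBRATION",
    "fit_biomass_calibration",
    "predict_biomass",
    "total_potential",
    "cannabinoid_yield",
    "DECARB_FACTORS",
]

# Molar-mass decarboxylation factors: neutral MW / acid MW.  Pentyl series
# (THCA, CBDA, CBCA, CBGA, CBLA) 0.877; propyl (varin) series 0.867.
DECARB_FACTORS = {
    "THC": 0.877, "CBD": 0.877, "CBC": 0.877, "CBG": 0.877, "CBL": 0.877,
    "THCV": 0.867, "CBDV": 0.867,
}
_DEFAULT_FACTOR = 0.877


@dataclass(frozen=True)
class LinearCalibration:
    intercept: float
    slope: float
    residual_sd: float


@dataclass(frozen=True)
class BiomassCalibration:
    """Wet→dry and wet→stripped linear calibrations plus sample size."""

    dbm: LinearCalibration
    dsbm: LinearCalibration
    n_calibration: int


#: The field-trial calibration (34 destructively sampled plants).
REFERENCE_CALIBRATION = BiomassCalibration(
    dbm=LinearCalibration(intercept=-0.13322, slope=0.31174, residual_sd=0.1446),
    dsbm=LinearCalibration(intercept=0.113884, slope=0.156749, residual_sd=0.1031),
    n_calibration=34,
)


def _ols(x: np.ndarray, y: np.ndarray) -> LinearCalibration:
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    dof = max(n - 2, 1)
    return LinearCalibration(
        intercept=float(intercept), slope=float(slope),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def fit_biomass_calibration(wbm, dbm, dsbm) -> BiomassCalibration:
    """Fit fresh wet→dry and wet→stripped calibrations by OLS."""
    wbm = np.asarray(wbm, dtype=float)
    dbm = np.asarray(dbm, dtype=float)
    dsbm = np.asarray(dsbm, dtype=float)
    if wbm.size < 3:
        raise ValueError("need at least 3 calibration samples")
    if np.ptp(wbm) == 0:
        raise ValueError("wet biomass has no variance")
    return BiomassCalibration(
        dbm=_ols(wbm, dbm), dsbm=_ols(wbm, dsbm), n_calibration=int(wbm.size)
    )


def predict_biomass(wbm, cal: BiomassCalibration = REFERENCE_CALIBRATION):
    """Predict (DBM, DSBM) in kg from wet biomass; predictions clamped at 0.

    Accepts a scalar or array; raises on negative wet biomass.
    """
    w = np.asarray(wbm, dtype=float)
    if np.any(w < 0):
        raise ValueError("wet biomass must be non-negative")
    dbm = np.maximum(0.0, cal.dbm.intercept + cal.dbm.slope * w)
    dsbm = np.maximum(0.0, cal.dsbm.intercept + cal.dsbm.slope * w)
    if np.isscalar(wbm):
        return float(dbm), float(dsbm)
    return dbm, dsbm


def total_potential(neutral_pct: float, acid_pct: float,
                    compound: str = "CBD",
                    factor: float | None = None) -> float:
    """Total potential cannabinoid percentage: neutral + f·acid.

    f is the decarboxylation mass-loss factor (molar-mass ratio of the
    neutral to the acid form); pass ``factor=1.0`` for a simple sum.
    """
    if neutral_pct < 0 or acid_pct < 0:
        raise ValueError("percentages must be non-negative")
    if factor is None:
        factor = DECARB_FACTORS.get(compound.upper(), _DEFAULT_FACTOR)
    return neutral_pct + factor * acid_pct


def cannabinoid_yield(totals_pct, dsbm_kg: float) -> float:
    """Cannabinoid yield per plant (grams): (Σ total %)/100 × DSBM × 1000."""
    if dsbm_kg < 0:
        raise ValueError("dry stripped biomass must be non-negative")
    total = float(np.sum(np.asarray(totals_pct, dtype=float)))
    return total / 100.0 * dsbm_kg * 1000.0
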