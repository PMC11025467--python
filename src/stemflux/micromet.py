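"""Micrometeorological derivations.

Vapour pressure deficit (VPD) from air temperature and relative humidity via
the Magnus equation, and gap-filling of deep soil water content (SWC) from a
shallow co-located sensor by per-treatment linear cross-calibration.

Conventions
-----------
* Air temperature Ta in deg C, relative humidity RH in percent (0-100).
* VPD is reported in hPa by default.  The Magnus saturation-pressure
  coefficient 0.6108 produces kPa, so the hPa output carries a factor 10;
  the raw kPa value is available via ``units="kpa"``.
* Soil water content is volumetric, in percent of soil volume, bounded to
  [0, 100].
* Gaps in the hourly series are explicit nulls (NaN); this module never
  interpolates in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "MAGNUS_A_KPA",
    "MAGNUS_B",
    "MAGNUS_C",
    "SwcCalibration",
    "saturation_vapour_pressure",
    "compute_vpd",
    "match_swc_pairs",
    "fit_swc_calibration",
    "gapfill_swc",
    "derive_micromet",
    "validate_micromet_frame",
]

#: Magnus equation constants: es(Ta) = A * exp(B * Ta / (C + Ta)), es in kPa.
MAGNUS_A_KPA = 0.6108
MAGNUS_B = 17.2694
MAGNUS_C = 237.3  # deg C; denominator must stay positive


def saturation_vapour_pressure(ta):
    """Saturation vapour pressure (kPa) at air temperature ``ta`` (deg C).

    Raises :class:`DomainError` if ``ta`` <= -237.3 deg C, where the Magnus
    denominator becomes non-positive.
    """
    ta = np.asarray(ta, dtype=float)
    if np.any(ta <= -MAGNUS_C):
        raise DomainError(
            f"air temperature must exceed -{MAGNUS_C} degC for the Magnus equation"
        )
    return MAGNUS_A_KPA * np.exp(MAGNUS_B * ta / (MAGNUS_C + ta))


def compute_vpd(ta, rh, units: str = "hpa"):
    """Vapour pressure deficit from air temperature and relative humidity.

    Parameters
    ----------
    ta : array-like
        Air temperature, deg C.
    rh : array-like
        Relative humidity, percent in [0, 100].  NaN propagates.
    units : {"hpa", "kpa"}
        Output unit.  The Magnus coefficient yields kPa; "hpa" multiplies
        by 10.

    Returns
    -------
    ndarray (or scalar for scalar input)
        VPD >= 0 wherever defined.
    """
    ta_arr = np.asarray(ta, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    finite = np.isfinite(rh_arr)
    if np.any((rh_arr[finite] < 0.0) | (rh_arr[finite] > 100.0)):
        raise ValidationError("relative humidity must lie in [0, 100] %")
    if units not in ("hpa", "kpa"):
        raise ValidationError(f"unknown VPD unit {units!r}; use 'hpa' or 'kpa'")
    es = saturation_vapour_pressure(ta_arr)
    vpd_kpa = es * (1.0 - rh_arr / 100.0)
    out = vpd_kpa * 10.0 if units == "hpa" else vpd_kpa
    if np.isscalar(ta) and np.isscalar(rh):
        return float(out)
    return out


@dataclass(frozen=True)
class SwcCalibration:
    """Linear cross-calibration of deep SWC on a shallow co-sensor.

    One calibration per treatment plot: deep = slope * shallow + intercept.
    """

    treatment_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 2:
            raise InsufficientDataError("SWC calibration needs >= 2 paired points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("calibration R^2 must lie in [0, 1]")


def match_swc_pairs(
    shallow: pd.DataFrame,
    deep: pd.DataFrame,
    tolerance_minutes: float = 30.0,
) -> pd.DataFrame:
    """Pair shallow and deep SWC observations by nearest timestamp.

    Both frames need columns ``timestamp`` and ``swc``.  Points without a
    partner within ``tolerance_minutes`` are dropped.  Returns a frame with
    columns ``timestamp``, ``shallow``, ``deep``.
    """
    sh = shallow.dropna(subset=["swc"]).sort_values("timestamp")
    dp = deep.dropna(subset=["swc"]).sort_values("timestamp")
    merged = pd.merge_asof(
        sh.rename(columns={"swc": "shallow"}),
        dp.rename(columns={"swc": "deep"}),
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(minutes=tolerance_minutes),
    )
    return merged.dropna(subset=["deep"]).reset_index(drop=True)


def fit_swc_calibration(shallow_swc, deep_swc, treatment_id: str = "") -> SwcCalibration:
    """Ordinary-least-squares fit of deep SWC on shallow SWC.

    Parameters are paired, already time-matched series (array-like, percent).
    Raises :class:`InsufficientDataError` with fewer than two pairs and
    :class:`DegenerateFitError` when the shallow sensor has zero variance.
    """
    x = np.asarray(shallow_swc, dtype=float)
    y = np.asarray(deep_swc, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise InsufficientDataError(
            f"treatment {treatment_id or '?'}: need >= 2 paired SWC observations, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateFitError(
            f"treatment {treatment_id or '?'}: shallow SWC has zero variance"
        )
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):  # flat deep series: slope 0 fits exactly, define R2=1
        r2 = 1.0
    return SwcCalibration(
        treatment_id=treatment_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        n_points=int(x.size),
    )


def gapfill_swc(calibration: SwcCalibration, shallow_swc):
    """Predict deep SWC from shallow observations via a fitted calibration.

    Returns predictions clipped to the physical range [0, 100] %.  NaN inputs
    stay NaN.  Callers are expected to flag filled points as estimated.
    """
    if calibration is None:
        raise ValidationError("gapfill_swc requires a fitted SwcCalibration")
    x = np.asarray(shallow_swc, dtype=float)
    pred = calibration.slope * x + calibration.intercept
    return np.clip(pred, 0.0, 100.0)


def validate_micromet_frame(df: pd.DataFrame) -> None:
    """Check the hourly micromet invariants; raise :class:`ValidationError`.

    Timestamps strictly increasing, RH in [0, 100], precipitation >= 0 and
    SWC in [0, 100] where present.
    """
    if "timestamp" not in df.columns:
        raise ValidationError("micromet frame lacks a 'timestamp' column")
    ts = pd.to_datetime(df["timestamp"])
    if len(ts) > 1 and not ts.is_monotonic_increasing:
        raise ValidationError("micromet timestamps must be non-decreasing")
    if len(ts) > 1 and ts.duplicated().any():
        raise ValidationError("micromet timestamps must be strictly increasing")
    rh = df["rh_pct"].to_numpy(dtype=float)
    bad = np.isfinite(rh) & ((rh < 0) | (rh > 100))
    if bad.any():
        raise ValidationError(
            f"rh_pct outside [0, 100] at rows {np.flatnonzero(bad)[:5].tolist()}"
        )
    if "precip_mm" in df.columns:
        pr = df["precip_mm"].to_numpy(dtype=float)
        if np.any(np.isfinite(pr) & (pr < 0)):
            raise ValidationError("precip_mm must be >= 0")
    if "swc_pct" in df.columns:
        swc = df["swc_pct"].to_numpy(dtype=float)
        if np.any(np.isfinite(swc) & ((swc < 0) | (swc > 100))):
            raise ValidationError("swc_pct must lie in [0, 100] where present")


def derive_micromet(
    df: pd.DataFrame,
    vpd_units: str = "hpa",
    calibration: SwcCalibration | None = None,
    shallow_col: str = "swc_shallow_pct",
) -> pd.DataFrame:
    """Derive VPD and optionally gap-fill SWC on an hourly micromet table.

    Input columns: ``timestamp, ta_c, rh_pct, precip_mm, swc_pct`` (nullable)
    and optionally a shallow SWC column used for gap-filling.  Returns a copy
    with ``vpd_hpa`` (or ``vpd_kpa``) added and, when a calibration is given,
    missing ``swc_pct`` replaced by predictions where shallow data exist,
    flagged in ``swc_filled_flag``.
    """
    validate_micromet_frame(df)
    out = df.copy()
    vpd_col = f"vpd_{vpd_units}"
    out[vpd_col] = compute_vpd(
        out["ta_c"].to_numpy(dtype=float),
        out["rh_pct"].to_numpy(dtype=float),
        units=vpd_units,
    )
    if "swc_pct" in out.columns:
        out["swc_filled_flag"] = False
        if calibration is not None and shallow_col in out.columns:
            missing = out["swc_pct"].isna() & out[shallow_col].notna()
            if missing.any():
                filled = gapfill_swc(
                    calibration, out.loc[missing, shallow_col].to_numpy(dtype=float)
                )
                out.loc[missing, "swc_pct"] = filled
                out.loc[missing, "swc_filled_flag"] = True
    return out
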