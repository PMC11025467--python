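"""Zero-growth partitioning of dendrometer series and derived daily statistics.

Automated band dendrometers record stem diameter (as cumulative displacement,
um) hourly.  The series superimposes irreversible radial growth on reversible
water-related shrinking and swelling.  The zero-growth partition attributes
growth only when the diameter exceeds its preceding maximum:

    gro(t) = runmax(diameter)[t] - diameter[0]     (cumulative growth, um)
    twd(t) = runmax(diameter)[t] - diameter[t]     (tree water deficit, um)

so that diameter(t) = diameter(0) + gro(t) - twd(t) holds exactly.  (The
identity is bit-exact whenever all diameters share a common dyadic quantum,
which sensor output with fixed resolution does; for arbitrary floats it
holds to rounding error.)  TWD, the depth below the preceding maximum, is a
proxy for stem dehydration.

From the partition, daily increment rates (um/day), daily TWD maxima (um),
their 7-day moving averages and the cumulative TWD from a chosen start date
are derived.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "zero_growth_partition",
    "flag_sensor_jumps",
    "daily_stats",
    "moving_average",
    "add_moving_averages",
    "cumulative_twd",
]

#: |d(diameter)/dt| above this (um per hour) is flagged as a sensor jump.
DEFAULT_JUMP_UM_PER_H = 500.0

#: Observation gaps longer than this (hours) mark adjacent days' stats null.
DEFAULT_GAP_HOURS = 6.0


def zero_growth_partition(series: pd.DataFrame) -> pd.DataFrame:
    """Partition a diameter series into cumulative growth and water deficit.

    Parameters
    ----------
    series : DataFrame
        Columns ``timestamp`` (strictly increasing) and ``diameter`` (um).
        Gaps are allowed; the running maximum carries across them (the stem
        does not reset).

    Returns
    -------
    DataFrame
        Columns ``timestamp, diameter, gro, twd`` satisfying the exact
        reconstruction identity diameter = diameter[0] + gro - twd, with
        gro non-decreasing, gro[0] = twd[0] = 0 and twd >= 0.
    """
    if len(series) == 0:
        raise InsufficientDataError("cannot partition an empty diameter series")
    ts = pd.to_datetime(series["timestamp"])
    if len(ts) > 1 and not (ts.is_monotonic_increasing and not ts.duplicated().any()):
        raise ValidationError("dendrometer timestamps must be strictly increasing")
    d = series["diameter"].to_numpy(dtype=float)
    if np.any(~np.isfinite(d)):
        raise ValidationError("diameter series contains non-finite values")
    runmax = np.maximum.accumulate(d)
    gro = runmax - d[0]
    twd = runmax - d
    return pd.DataFrame(
        {"timestamp": ts.to_numpy(), "diameter": d, "gro": gro, "twd": twd}
    )


def flag_sensor_jumps(
    series: pd.DataFrame, max_rate_um_per_h: float = DEFAULT_JUMP_UM_PER_H
) -> np.ndarray:
    """Boolean mask of observations following an implausible diameter step.

    A step is a jump when |d(diameter)| / dt exceeds ``max_rate_um_per_h``.
    Jumps are flagged, never auto-corrected.
    """
    ts = pd.to_datetime(series["timestamp"])
    d = series["diameter"].to_numpy(dtype=float)
    flags = np.zeros(len(d), dtype=bool)
    if len(d) < 2:
        return flags
    dt_h = np.diff(ts.astype("int64").to_numpy()) / 3.6e12
    rate = np.abs(np.diff(d)) / np.where(dt_h > 0, dt_h, np.nan)
    flags[1:] = rate > max_rate_um_per_h
    return flags


def _gap_affected_days(ts: pd.Series, gap_hours: float) -> set:
    """Calendar days adjacent to an observation gap longer than ``gap_hours``."""
    if len(ts) < 2:
        return set()
    diffs_h = ts.diff().dt.total_seconds().to_numpy() / 3600.0
    days = ts.dt.date.to_numpy()
    affected = set()
    for i in np.flatnonzero(diffs_h > gap_hours):
        affected.add(days[i - 1])
        affected.add(days[i])
    return affected


def daily_stats(
    partitioned: pd.DataFrame, gap_hours: float = DEFAULT_GAP_HOURS
) -> pd.DataFrame:
    """Daily increment rate and daily TWD maximum from a partitioned series.

    Per local calendar day, the increment rate is gro at the day's last
    observation minus gro at the previous day's last observation (um/day);
    twd_max is the largest TWD observed within the day.  Days without
    observations, days adjacent to gaps longer than ``gap_hours`` and days
    whose previous day has no usable gro value get null statistics.

    Returns a frame indexed over the full date span with columns
    ``date, increment_um_d, twd_max_um``.
    """
    ts = pd.to_datetime(partitioned["timestamp"])
    df = partitioned.assign(_date=ts.dt.date)
    per_day = df.groupby("_date").agg(
        gro_last=("gro", "last"), twd_max_um=("twd", "max")
    )
    full_index = pd.date_range(
        per_day.index.min(), per_day.index.max(), freq="D"
    ).date
    per_day = per_day.reindex(full_index)
    increment = per_day["gro_last"].diff()
    out = pd.DataFrame(
        {
            "date": full_index,
            "increment_um_d": increment.to_numpy(),
            "twd_max_um": per_day["twd_max_um"].to_numpy(),
        }
    )
    gap_days = _gap_affected_days(ts, gap_hours)
    if gap_days:
        mask = np.array([d in gap_days for d in full_index])
        out.loc[mask, ["increment_um_d", "twd_max_um"]] = np.nan
        # a day right after a nulled day has no usable previous gro
        after = np.roll(mask, 1)
        after[0] = False
        out.loc[after, "increment_um_d"] = np.nan
    return out


def moving_average(
    values, window_days: int = 7, min_periods: int = 4, center: bool = True
):
    """Moving average of a daily series.

    Centered by default (a trailing window is available via
    ``center=False``); windows with fewer than ``min_periods`` non-null days
    yield null.
    """
    if window_days < 1:
        raise ValidationError("window_days must be >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return (
        s.rolling(window_days, min_periods=min_periods, center=center)
        .mean()
        .to_numpy()
    )


def add_moving_averages(
    daily: pd.DataFrame,
    window_days: int = 7,
    min_periods: int = 4,
    center: bool = True,
) -> pd.DataFrame:
    """Append 7-day moving averages of increment rate and TWD maxima."""
    out = daily.copy()
    out["increment_um_d_ma7"] = moving_average(
        out["increment_um_d"], window_days, min_periods, center
    )
    out["twd_max_um_ma7"] = moving_average(
        out["twd_max_um"], window_days, min_periods, center
    )
    return out


def cumulative_twd(daily: pd.DataFrame, from_date) -> pd.DataFrame:
    """Running sum of daily TWD maxima from ``from_date`` onward.

    Null days contribute zero; the cumulative series is monotone
    non-decreasing.  Returns columns ``date, twd_cum_um``.
    """
    from_date = pd.Timestamp(from_date).date()
    dates = pd.Series(daily["date"])
    if from_date > dates.max() or from_date < dates.min():
        raise ValidationError(f"from_date {from_date} outside the daily series span")
    sel = daily.loc[dates >= from_date].copy()
    sel["twd_cum_um"] = sel["twd_max_um"].fillna(0.0).cumsum()
    return sel[["date", "twd_cum_um"]].reset_index(drop=True)
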