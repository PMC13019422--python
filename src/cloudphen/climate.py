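"""Daily-rainfall climatology: gap filling, rolling accumulations, normals,
and rain-limited foraging time.

A daily rainfall table ("rain_daily" dialect) has one row per landscape-day:
``landscape, date, rain_mm, daytime_rain_h, daylight_h`` plus an optional
``filled_flag``. Gaps are filled by the normal-ratio method: each missing day
is the mean over reference stations of the reference value scaled by the
ratio of long-term means between target and reference. Accumulations are
trailing sums (the window ending on, and including, each date), since every
downstream lag is "previous rainfall". Normals are per-day-of-year means of
those accumulations across years, with 29 February folded into day 59.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "fill_normal_ratio",
    "rolling_accumulation",
    "compute_normals",
    "foraging_fraction",
    "seasonal_accumulation",
    "standardized_anomaly",
]


class UnfillableGapError(ValueError):
    """No reference station overlaps the target series."""


def _as_series(df: pd.DataFrame, col: str = "rain_mm") -> pd.Series:
    s = df.set_index(pd.DatetimeIndex(df["date"]))[col]
    if not s.index.is_monotonic_increasing:
        s = s.sort_index()
    return s


def fill_normal_ratio(target: pd.DataFrame, references: list[pd.DataFrame]) -> pd.DataFrame:
    """Fill missing rain_mm days in `target` from reference stations.

    Each gap day becomes mean_r(ratio_r * reference_r[day]) where
    ratio_r = mean(target)/mean(reference) over days where both report.
    Returns a copy with `filled_flag` True on filled rows.
    """
    out = target.copy()
    out["date"] = pd.to_datetime(out["date"])
    if "filled_flag" not in out.columns:
        out["filled_flag"] = False
    tser = _as_series(out)
    gaps = tser.index[tser.isna()]
    if len(gaps) == 0:
        return out

    fills = []
    for ref in references:
        rser = _as_series(ref.assign(date=pd.to_datetime(ref["date"])))
        both = tser.dropna().index.intersection(rser.dropna().index)
        if len(both) < 90:
            continue
        rmean = rser.loc[both].mean()
        if rmean <= 0:
            continue
        ratio = tser.loc[both].mean() / rmean
        fills.append(ratio * rser.reindex(gaps))
    if not fills:
        raise UnfillableGapError(
            f"no reference overlaps target for gap days {gaps.min().date()}.."
            f"{gaps.max().date()}")
    est = pd.concat(fills, axis=1).mean(axis=1)
    still = est.index[est.isna()]
    if len(still):
        raise UnfillableGapError(f"references never report on {list(still.date)}")

    idx = out.index[out["date"].isin(gaps)]
    out.loc[idx, "rain_mm"] = est.loc[out.loc[idx, "date"]].to_numpy()
    out.loc[idx, "filled_flag"] = True
    return out


def rolling_accumulation(series: pd.DataFrame, window_days: int) -> pd.Series:
    """Trailing rainfall sum over `window_days` ending at each date (incl.).

    NaN for the first window_days-1 dates. Index is the date.
    """
    if window_days <= 0:
        raise ValueError(f"window_days must be positive, got {window_days}")
    s = _as_series(series)
    if len(s) < window_days:
        raise ValueError(f"series covers {len(s)} days < window {window_days}")
    return s.rolling(window_days, min_periods=window_days).sum()


def compute_normals(series: pd.DataFrame, windows=(30, 90)) -> pd.DataFrame:
    """Long-term per-day-of-year mean accumulations (rainfall normals).

    Requires >= 2 full years. 29 February is merged into day-of-year 59.
    Returns a frame indexed by doy 1..365 with columns acc{w}_mm.
    """
    s = _as_series(series)
    span_days = (s.index[-1] - s.index[0]).days + 1
    if span_days < 2 * 365:
        raise ValueError(f"need >= 2 full years of data, have {span_days} days")
    out = {}
    for w in windows:
        acc = rolling_accumulation(series, w)
        doy = acc.index.dayofyear.to_numpy().copy()
        leap = acc.index.is_leap_year
        feb29 = leap & (doy == 60)
        doy[feb29] = 59
        doy[leap & (doy > 60)] -= 1
        out[f"acc{w}_mm"] = pd.Series(acc.to_numpy(), index=doy).groupby(level=0).mean()
    res = pd.DataFrame(out).reindex(range(1, 366))
    res.index.name = "doy"
    return res


def foraging_fraction(series: pd.DataFrame, month: int | None = None) -> float | pd.Series:
    """Fraction of daylight free of rain: 1 - mean(daytime_rain_h)/mean(daylight_h).

    With `month` given, a scalar for that calendar month; otherwise a Series
    over months 1..12. Clipped to [0, 1].
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["_m"] = df["date"].dt.month
    if month is not None:
        sub = df[df["_m"] == month]
        if sub.empty:
            raise ValueError(f"month {month} not present in series")
        f = 1.0 - sub["daytime_rain_h"].mean() / sub["daylight_h"].mean()
        return float(np.clip(f, 0.0, 1.0))
    g = df.groupby("_m")
    f = 1.0 - g["daytime_rain_h"].mean() / g["daylight_h"].mean()
    f.index.name = "month"
    return f.clip(0.0, 1.0)


def seasonal_accumulation(series: pd.DataFrame, months: tuple, year_of: str = "start") -> pd.Series:
    """Total rainfall over the given calendar months, per year.

    `year_of="start"` labels a Dec-Jan-spanning window by the year of its
    first month; months not spanning the year boundary are unaffected.
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    m = df["date"].dt.month
    df = df[m.isin(months)]
    year = df["date"].dt.year.to_numpy().copy()
    months = tuple(months)
    if 12 in months and 1 in months and year_of == "start":
        # label Dec by its own year, Jan.. by previous year
        early = [mm for mm in months if mm < 6]
        shift = df["date"].dt.month.isin(early).to_numpy()
        year[shift] -= 1
    out = df.assign(_y=year).groupby("_y")["rain_mm"].sum()
    out.index.name = "year"
    return out


def standardized_anomaly(series: pd.DataFrame, months: tuple) -> pd.Series:
    """Per-year seasonal accumulation standardized across years (mean 0, SD 1).

    This is the interannual rainfall anomaly used throughout the temporal
    analyses: positive = wetter than the landscape's own multi-year mean.
    """
    acc = seasonal_accumulation(series, months)
    sd = acc.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return acc * 0.0
    return (acc - acc.mean()) / sd
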