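"""Circular (day-of-year / month-of-year) arithmetic helpers.

Breeding dates live on a circle of period 365 days (or 12 months); all
peak comparisons, offsets and means must respect the wrap-around.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365.0
DAYS_PER_MONTH = 30.437  # reporting convention: months = days / 30.437


def circ_diff(a, b, period: float = DAYS_PER_YEAR):
    """Signed circular difference a - b, wrapped into (-period/2, period/2]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.where(d > period / 2, d - period, d)


def circ_dist(a, b, period: float = DAYS_PER_YEAR):
    """Absolute circular distance between a and b."""
    return np.abs(circ_diff(a, b, period))


def circ_mean(x, period: float = DAYS_PER_YEAR, weights=None):
    """Weighted circular mean of angles expressed on [0, period)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return np.nan
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    ang = 2 * np.pi * x / period
    s = np.sum(w * np.sin(ang))
    c = np.sum(w * np.cos(ang))
    if s == 0 and c == 0:
        return np.nan
    m = np.arctan2(s, c) * period / (2 * np.pi)
    return float(m % period)


def doy_to_month(doy) -> np.ndarray:
    """Map day-of-year (1-366) to calendar month 1-12 (365-day calendar)."""
    bounds = np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    return np.searchsorted(bounds, np.clip(np.asarray(doy) - 1, 0, 364), side="right") + 1


MONTH_START_DOY = np.array([1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335])


def month_mid_doy(month) -> np.ndarray:
    """Mid-point day-of-year of calendar month(s) 1-12."""
    m = np.asarray(month, dtype=int) - 1
    ends = np.append(MONTH_START_DOY[1:], 366)
    return (MONTH_START_DOY[m] + ends[m] - 1) / 2.0


def days_to_months(days):
    return np.asarray(days, dtype=float) / DAYS_PER_MONTH
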