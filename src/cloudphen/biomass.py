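"""Rainfall-driven foliage-arthropod biomass model.

Biomass (dry mg per m^2 of foliage) is predicted from rainfall alone via a
Gamma log-link regression fitted to beat-net samples in a companion field
study; here the coefficients are configuration, not re-fitted:

    biomass = exp(b0 + b1*r90 + b2*r90^2 + b3*min(r30, cap30))

where r90/r30 are trailing 90- and 30-day rainfall accumulations (mm). The
curvilinear 90-day term captures reduced biomass at both dry and very wet
extremes; the capped 30-day term captures the short-term flush as rain
returns, saturating at cap30 = 133 mm. Long-term seasonal means ("biomass
normals") come from a cyclic smooth of monthly predictions with
year-to-year level differences removed; "effective" biomass discounts the
raw value by the fraction of daylight hours available for foraging
(rain suppresses foraging).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from patsy import dmatrix

from .climate import rolling_accumulation
from .config import BiomassCoefficients
from ._circular import month_mid_doy

__all__ = [
    "predict_biomass",
    "monthly_series",
    "biomass_normals",
    "effective_biomass",
    "BiomassNormals",
]


def predict_biomass(r90, r30, coef: BiomassCoefficients):
    """Point prediction of foliage arthropod biomass (dry mg/m^2)."""
    r90 = np.asarray(r90, dtype=float)
    r30 = np.asarray(r30, dtype=float)
    eta = (coef.b0 + coef.b1 * r90 + coef.b2 * r90 ** 2
           + coef.b3 * np.minimum(r30, coef.cap30))
    return np.exp(eta)


def monthly_series(rain: pd.DataFrame, coef: BiomassCoefficients) -> pd.DataFrame:
    """Predicted biomass per landscape-month from month-end accumulations.

    Returns columns: landscape, year, month, r90_mm, r30_mm, biomass_mg_m2.
    Months whose month-end 90-day accumulation is undefined (start of the
    record) are dropped.
    """
    frames = []
    for lid, sub in rain.groupby("landscape"):
        acc90 = rolling_accumulation(sub, 90)
        acc30 = rolling_accumulation(sub, 30)
        idx = acc90.index
        month_end = idx.to_period("M").to_timestamp("M").normalize()
        is_end = idx.normalize() == month_end
        df = pd.DataFrame({
            "landscape": lid,
            "year": idx.year[is_end],
            "month": idx.month[is_end],
            "r90_mm": acc90[is_end].to_numpy(),
            "r30_mm": acc30[is_end].to_numpy(),
        }).dropna(subset=["r90_mm"])
        df["biomass_mg_m2"] = predict_biomass(df["r90_mm"], df["r30_mm"], coef)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class BiomassNormals:
    """Periodic day-of-year biomass curve for one landscape.

    Attributes: `doy` (1..365 grid), `value` (mg/m^2), `minimum`,
    `minimum_doy`, `maximum`, `amplitude` (max/min ratio).
    """

    def __init__(self, doy: np.ndarray, value: np.ndarray):
        self.doy = doy
        self.value = value
        i_min = int(np.argmin(value))
        i_max = int(np.argmax(value))
        self.minimum = float(value[i_min])
        self.minimum_doy = float(doy[i_min])
        self.maximum = float(value[i_max])
        self.amplitude = self.maximum / self.minimum

    def at(self, doy):
        return np.interp(np.asarray(doy, float), self.doy, self.value,
                         period=365.0)


def biomass_normals(series: pd.DataFrame, df_basis: int = 6) -> BiomassNormals:
    """Cyclic smooth of monthly biomass for one landscape.

    Year-to-year level differences are absorbed by centering log biomass
    within year (the random-intercept stand-in) before fitting a cyclic
    cubic regression spline on day-of-year; the overall mean level is
    restored afterwards. Requires >= 3 years of monthly values.
    """
    if series["year"].nunique() < 3:
        raise ValueError(
            f"biomass normals need >= 3 years, have {series['year'].nunique()}")
    y = np.log(series["biomass_mg_m2"].to_numpy(dtype=float))
    overall = y.mean()
    y = y - series.groupby("year")["biomass_mg_m2"].transform(
        lambda v: np.log(v).mean()).to_numpy() + overall
    x = month_mid_doy(series["month"].to_numpy())

    knots = np.linspace(0, 365, 13)  # ~12-month initial knot spacing
    X = np.asarray(dmatrix(
        "cc(x, knots=k[1:-1], lower_bound=0, upper_bound=365)",
        {"x": x, "k": knots}, return_type="dataframe"))
    # penalized fit: circular second-difference penalty on coefficients,
    # smoothing chosen by generalized cross-validation — an unpenalized
    # spline with monthly data interpolates the month means and oscillates
    # freely between them
    p = X.shape[1]
    D = np.zeros((p, p))
    for i in range(p):
        D[i, i] = -2.0
        D[i, (i - 1) % p] = 1.0
        D[i, (i + 1) % p] = 1.0
    P = D.T @ D
    XtX, Xty = X.T @ X, X.T @ y
    n = len(y)
    best = None
    for lam in 10.0 ** np.arange(-2, 5):
        A = XtX + lam * P
        beta = np.linalg.solve(A, Xty)
        hat_tr = float(np.trace(np.linalg.solve(A, XtX)))
        rss = float(((y - X @ beta) ** 2).sum())
        gcv = n * rss / max(n - hat_tr, 1e-9) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, beta)
    beta = best[1]
    grid = np.arange(1.0, 366.0)
    Xg = np.asarray(dmatrix(
        "cc(x, knots=k[1:-1], lower_bound=0, upper_bound=365)",
        {"x": grid, "k": knots}, return_type="dataframe"))
    return BiomassNormals(grid, np.exp(Xg @ beta))


def effective_biomass(series: pd.DataFrame, foraging_by_month: pd.Series) -> pd.DataFrame:
    """Discount biomass by the monthly fraction of rain-free daylight.

    `foraging_by_month` maps month 1..12 -> fraction in [0, 1].
    Adds an `effective_mg_m2` column (always <= biomass_mg_m2).
    """
    frac = series["month"].map(foraging_by_month).astype(float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("foraging fractions must lie in [0, 1]")
    out = series.copy()
    out["effective_mg_m2"] = out["biomass_mg_m2"] * frac
    return out
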