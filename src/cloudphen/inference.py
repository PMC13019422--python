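"""Community-level inference: model selection, guild models, breakpoints,
spatial-vs-temporal decomposition and drought responses.

All models work on the populations table produced by
:func:`cloudphen.phenology.population_phenology`. Crossed random intercepts
(phylogeny x landscape) are approximated by species-level cluster-robust
standard errors (optionally a species random intercept for Gaussian
responses); the approximation used is recorded in each result's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import SEASONS
from ._circular import DAYS_PER_MONTH, circ_diff, circ_mean
from .climate import standardized_anomaly

__all__ = [
    "aicc",
    "akaike_weights",
    "select_climate_window",
    "select_start_date",
    "fit_guild_model",
    "segmented_fit",
    "spatial_temporal_ratio",
    "regime_offset_months",
    "drought_response",
    "classify_regime",
    "guild_anomaly",
    "BreakpointFit",
    "GuildModel",
]


def aicc(loglik: float, k_params: int, n_obs: int) -> float:
    """Akaike information criterion corrected for small samples."""
    if n_obs <= k_params + 1:
        raise ValueError(
            f"AICc undefined for n={n_obs} <= k+1={k_params + 1}")
    return -2.0 * loglik + 2.0 * k_params \
        + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1)


def akaike_weights(aiccs) -> np.ndarray:
    a = np.asarray(aiccs, dtype=float)
    d = a - np.nanmin(a)
    w = np.exp(-d / 2.0)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


@dataclass
class GuildModel:
    """A fitted community model for one response and predictor set."""

    response: str
    formula: str
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    n_obs: int
    loglik: float
    aicc: float
    r2: float
    r2_adj: float
    family: str = "gaussian"
    approximation: str = "cluster-robust by species"
    converged: bool = True


def fit_guild_model(populations: pd.DataFrame, response: str, fixed: str,
                    family: str = "gaussian",
                    cluster: str = "species") -> GuildModel:
    """Fit `response ~ fixed` with species-level cluster-robust errors.

    Gaussian responses use OLS, strictly positive ones a Gamma log-link
    GLM, binary ones binomial-logit. Rows with missing values are dropped.
    """
    formula = f"{response} ~ {fixed}"
    df = populations.dropna(subset=[response]).copy()
    groups = df[cluster] if cluster in df.columns else None
    cov_kw = ({"cov_type": "cluster", "cov_kwds": {"groups": groups}}
              if groups is not None and groups.nunique() > 1 else {})
    try:
        if family == "gaussian":
            fit = smf.ols(formula, data=df).fit(**cov_kw)
            r2, r2a = fit.rsquared, fit.rsquared_adj
        elif family == "gamma":
            fit = smf.glm(formula, data=df,
                          family=sm.families.Gamma(sm.families.links.Log())
                          ).fit(**cov_kw)
            r2 = r2a = 1.0 - fit.deviance / fit.null_deviance
        elif family == "binomial":
            fit = smf.glm(formula, data=df,
                          family=sm.families.Binomial()).fit(**cov_kw)
            r2 = r2a = 1.0 - fit.deviance / fit.null_deviance
        else:
            raise ValueError(f"unknown family {family!r}")
        k = len(fit.params) + (1 if family == "gaussian" else 0)
        return GuildModel(
            response=response, formula=formula, params=fit.params,
            bse=fit.bse, conf_int=fit.conf_int(), n_obs=int(fit.nobs),
            loglik=float(fit.llf), aicc=aicc(float(fit.llf), k, int(fit.nobs)),
            r2=float(r2), r2_adj=float(r2a), family=family)
    except Exception:
        return GuildModel(response=response, formula=formula,
                          params=pd.Series(dtype=float),
                          bse=pd.Series(dtype=float),
                          conf_int=pd.DataFrame(), n_obs=len(df),
                          loglik=np.nan, aicc=np.inf, r2=np.nan,
                          r2_adj=np.nan, family=family, converged=False)


def select_climate_window(populations: pd.DataFrame, candidates: dict,
                          response: str = "linearized_day",
                          include_null: bool = True) -> pd.DataFrame:
    """AICc ranking of candidate climate predictors.

    `candidates` maps a window name to a per-population predictor series
    aligned with `populations`. Returns a table with AICc, delta and Akaike
    weights (singular fits dropped with a warning flag).
    """
    if len(candidates) < 2 and not include_null:
        raise ValueError("need at least two candidate windows")
    rows = []
    for name, pred in candidates.items():
        df = populations.copy()
        df["_x"] = np.asarray(pred, dtype=float)
        m = fit_guild_model(df, response, "_x")
        rows.append({"window": name, "aicc": m.aicc, "r2": m.r2,
                     "converged": m.converged, "n": m.n_obs})
    if include_null:
        m0 = fit_guild_model(populations, response, "1")
        rows.append({"window": "(null)", "aicc": m0.aicc, "r2": 0.0,
                     "converged": m0.converged, "n": m0.n_obs})
    tab = pd.DataFrame(rows)
    ok = tab["converged"] & np.isfinite(tab["aicc"])
    tab["weight"] = 0.0
    tab.loc[ok, "weight"] = akaike_weights(tab.loc[ok, "aicc"])
    tab["delta"] = tab["aicc"] - tab.loc[ok, "aicc"].min()
    return tab.sort_values("aicc").reset_index(drop=True)


@dataclass
class BreakpointFit:
    psi: float
    psi_ci: tuple
    intercept: float
    left_slope: float
    right_slope: float
    aicc_segmented: float
    aicc_linear: float
    r2: float
    converged: bool
    preferred: str = "segmented"  # or "linear"
    n_obs: int = 0


def _hinge_fit(x, y, psi):
    X = np.column_stack([np.ones_like(x), x, np.where(x > psi, x - psi, 0.0)])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _gauss_loglik(sse, n, scale=1.0):
    # relative floor keeps float-level residuals from dominating the
    # comparison on exactly-representable data
    s2 = max(sse / n, (1e-8 * (scale + 1e-12)) ** 2)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def segmented_fit(x, y, init: float | None = None,
                  tol: float = 1e-6, max_iter: int = 50) -> BreakpointFit:
    """Two-segment (broken-line) regression with estimated breakpoint psi.

    Iterative linearization: given psi, fit the hinge term (x-psi)*I(x>psi)
    plus its reparameterization gradient -I(x>psi), then update
    psi <- psi + gamma/beta_hinge; on divergence fall back to a profile grid
    search over interior psi values. The segmented fit is compared with a
    straight line by AICc; with no interior optimum the linear model is
    preferred and converged is False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 8:
        raise ValueError(f"need >= 8 points for a breakpoint fit, got {n}")
    lo, hi = np.quantile(x, 0.05), np.quantile(x, 0.95)
    span = x.max() - x.min()

    # linear reference
    Xl = np.column_stack([np.ones_like(x), x])
    bl, *_ = np.linalg.lstsq(Xl, y, rcond=None)
    sse_lin = float(((y - Xl @ bl) ** 2).sum())
    yscale = float(np.std(y)) or 1.0
    aicc_lin = aicc(_gauss_loglik(sse_lin, n, yscale), 3, n)

    psi = float(init) if init is not None else float(np.median(x))
    converged = False
    se_psi = np.nan
    for _ in range(max_iter):
        U = np.where(x > psi, x - psi, 0.0)
        V = np.where(x > psi, -1.0, 0.0)
        X = np.column_stack([np.ones_like(x), x, U, V])
        try:
            fit = sm.OLS(y, X).fit()
        except Exception:
            break
        b_u, gamma = fit.params[2], fit.params[3]
        if abs(b_u) < 1e-12:
            break
        step = gamma / b_u
        new = psi + step
        if not (lo <= new <= hi):
            break
        psi_prev, psi = psi, new
        if abs(step) < tol * max(span, 1.0):
            converged = True
            se_psi = float(fit.bse[3] / abs(b_u))
            break

    if not converged:
        # profile grid search over interior candidate breakpoints
        grid = np.unique(np.concatenate([
            np.linspace(lo, hi, 201),
            (np.sort(np.unique(x))[:-1] + np.sort(np.unique(x))[1:]) / 2.0]))
        grid = grid[(grid >= lo) & (grid <= hi)]
        sses = np.array([_hinge_fit(x, y, p)[1] for p in grid])
        psi = float(grid[int(np.argmin(sses))])
        converged = True
        # fall back to a gradient-based SE at the profile optimum
        U = np.where(x > psi, x - psi, 0.0)
        V = np.where(x > psi, -1.0, 0.0)
        try:
            fit = sm.OLS(y, np.column_stack([np.ones_like(x), x, U, V])).fit()
            if abs(fit.params[2]) > 1e-12:
                se_psi = float(fit.bse[3] / abs(fit.params[2]))
        except Exception:
            pass

    beta, sse_seg = _hinge_fit(x, y, psi)
    aicc_seg = aicc(_gauss_loglik(sse_seg, n, yscale), 5, n)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse_seg / sst if sst > 0 else np.nan
    interior = x.min() < psi < x.max()
    preferred = "segmented" if (aicc_seg < aicc_lin and interior) else "linear"
    if not interior:
        converged = False
    ci = (psi - 1.96 * se_psi, psi + 1.96 * se_psi) if np.isfinite(se_psi) \
        else (np.nan, np.nan)
    return BreakpointFit(
        psi=float(psi), psi_ci=ci, intercept=float(beta[0]),
        left_slope=float(beta[1]), right_slope=float(beta[1] + beta[2]),
        aicc_segmented=float(aicc_seg), aicc_linear=float(aicc_lin),
        r2=float(r2), converged=bool(converged), preferred=preferred,
        n_obs=n)


# ---------------------------------------------------------------------------
# regimes, anomalies, spatial-vs-temporal decomposition, drought response

_DRY_MONTHS = set(SEASONS["dry"])


def classify_regime(linearized_day) -> np.ndarray:
    """Pre- vs post-dry-season breeding regime from the insectivore
    linearized peak day (days since 1 April).

    Pre: peak in the transition to the dry season (Apr-May); post: peak
    after the dry season (Sep onward); peaks inside the dry season (Jun-Aug)
    are indeterminate and return 'dry'.
    """
    d = np.asarray(linearized_day, dtype=float)
    out = np.where(d < 61, "pre", np.where(d < 153, "dry", "post"))
    return np.where(np.isfinite(d), out, "na")


GUILD_ANOMALY_MONTHS = {
    "insectivore": (4, 5, 6),   # transition into the dry season
    "omnivore": (4, 5, 6),
    "frugivore": (1, 2, 3),     # wet-season rainfall
    "nectarivore": (5, 6, 7),   # dry-season onset
}


def guild_anomaly(rain: pd.DataFrame, guild: str) -> pd.DataFrame:
    """Standardized interannual rainfall anomaly per landscape and
    guild-specific phenology year.

    Insectivores/omnivores use the Apr-Jun accumulation of the year their
    season starts in; frugivores (season starting 1 October) the following
    calendar year's Jan-Mar wet-season accumulation.
    """
    months = GUILD_ANOMALY_MONTHS[guild]
    rows = []
    for lid, sub in rain.groupby("landscape"):
        z = standardized_anomaly(sub, months)
        for yr, v in z.items():
            byear = yr - 1 if guild == "frugivore" else yr
            rows.append({"landscape": lid, "year": int(byear),
                         "anomaly": float(v)})
    return pd.DataFrame(rows)


def drought_response(annual: pd.DataFrame, anomalies: pd.DataFrame,
                     min_years: int = 3) -> dict:
    """Interannual timing and effort response to rainfall anomalies.

    `annual` is a per-year populations table (one row per species x
    landscape x year); `anomalies` maps (landscape, year) to the
    standardized guild-relevant rainfall anomaly. For every population with
    >= `min_years` annual models, annual deviations of the linearized peak
    (months) and of log reproductive effort from the population mean are
    regressed on the anomaly, separately for pre- and post-dry-season
    regimes (regime from the population's mean peak; populations peaking
    inside the dry season are excluded).

    Returns per-regime dicts with `timing_slope_months` (signed months per
    SD anomaly; negative = earlier in wetter years), `effort_log_slope` and
    `effort_pct_change_dry` = percentage change of effort in a 1-SD drought.
    """
    df = annual.merge(anomalies, on=["landscape", "year"], how="left")
    df = df.dropna(subset=["anomaly"]).copy()
    out = {"pre": None, "post": None}
    counts = df.groupby(["species", "landscape"])["year"].transform("size")
    df = df[counts >= min_years].copy()
    if df.empty:
        return out
    # population mean peak and annual deviations are circular: a pre-dry
    # population shifted into March must not wrap around the 1-April origin
    g = df.groupby(["species", "landscape"])
    df["_mean_peak"] = g["peak_doy"].transform(
        lambda s: circ_mean(s.dropna().to_numpy()))
    df["dev_months"] = circ_diff(df["peak_doy"], df["_mean_peak"]) \
        / DAYS_PER_MONTH
    # interannual effort changes are measured on the season-integrated
    # event rate (events per capture over the whole year): it carries the
    # same multiplicative effort signal as the max monthly percentage but
    # without the upward noise bias of a max statistic. Zero-event years
    # are floored at half an event so they enter as low effort, not -inf.
    floor = 0.5 / df["n_captures"].clip(lower=1)
    eff = df["event_rate"] if "event_rate" in df.columns \
        else df["effort_max_pct"] / 100.0
    df["_log_eff"] = np.log(eff.clip(lower=floor))
    df["dev_logeff"] = df["_log_eff"] \
        - df.groupby(["species", "landscape"])["_log_eff"].transform("mean")
    df["regime"] = classify_regime((df["_mean_peak"] - 91.0) % 365.0)

    for regime in ("pre", "post"):
        sub = df[df["regime"] == regime]
        if len(sub) < 6:
            continue
        if sub["anomaly"].std() == 0:
            # no interannual variance: responses are identically zero
            out[regime] = {
                "timing_slope_months": 0.0, "timing_slope_ci": (0.0, 0.0),
                "effort_log_slope": 0.0, "effort_pct_change_dry": 0.0,
                "effort_pct_change_wet": 0.0, "effort_ci": (0.0, 0.0),
                "n_population_years": int(len(sub)),
                "n_populations": int(
                    sub.groupby(["species", "landscape"]).ngroups)}
            continue
        res = {}
        for resp, key in (("dev_months", "timing"), ("dev_logeff", "effort")):
            d = sub.dropna(subset=[resp, "anomaly"])
            if len(d) < 6:
                res[f"{key}_slope"] = np.nan
                res[f"{key}_ci"] = (np.nan, np.nan)
                continue
            kw = {}
            if d["species"].nunique() > 1:
                kw = {"cov_type": "cluster",
                      "cov_kwds": {"groups": d["species"]}}
            if resp == "dev_months" and "n_events" in d.columns:
                # peak variance scales as 1/events: inverse-variance weights
                fit = smf.wls(f"{resp} ~ anomaly", data=d,
                              weights=d["n_events"].clip(lower=1)).fit(**kw)
            else:
                fit = smf.ols(f"{resp} ~ anomaly", data=d).fit(**kw)
            slope = float(fit.params["anomaly"])
            lo, hi = fit.conf_int().loc["anomaly"]
            res[f"{key}_slope"] = slope
            res[f"{key}_ci"] = (float(lo), float(hi))
        res["timing_slope_months"] = res.pop("timing_slope")
        res["timing_slope_ci"] = res.pop("timing_ci")
        res["effort_log_slope"] = res.pop("effort_slope")
        gslope = res["effort_log_slope"]
        res["effort_pct_change_dry"] = float((np.exp(-gslope) - 1.0) * 100.0)
        res["effort_pct_change_wet"] = float((np.exp(gslope) - 1.0) * 100.0)
        res["effort_ci"] = res.pop("effort_ci")
        res["n_population_years"] = int(len(sub))
        res["n_populations"] = int(sub.groupby(["species", "landscape"]).ngroups)
        out[regime] = res
    return out


def spatial_temporal_ratio(populations: pd.DataFrame,
                           drought: dict,
                           gradient_span: pd.Series | None = None) -> dict:
    """Ratio of spatial (between-regime) to interannual timing variability.

    The spatial component is the fitted offset (months) between post- and
    pre-dry-season insectivore regimes across the rainfall gradient; the
    temporal component is the mean absolute interannual timing response per
    SD anomaly from :func:`drought_response`. The raw mean absolute
    annual deviation is available separately as `temporal_mad_months`.
    """
    spatial, n_pre, n_post = regime_offset_months(populations, gradient_span)

    slopes = [abs(d["timing_slope_months"])
              for d in (drought.get("pre"), drought.get("post"))
              if d is not None]
    temporal = float(np.mean(slopes)) if slopes else np.nan
    ratio = np.inf if temporal == 0 else spatial / temporal
    return {"spatial_months": spatial, "temporal_months": temporal,
            "ratio": float(ratio) if np.isfinite(ratio) else np.inf,
            "n_pre": n_pre, "n_post": n_post}


def regime_offset_months(populations: pd.DataFrame,
                         gradient_span: pd.Series | None = None,
                         exclude_bimodal: bool = True
                         ) -> tuple[float, int, int]:
    """Fitted post-minus-pre regime offset of the linearized peak (months).

    Regimes are classified from each population's peak position relative to
    the dry season; dry-season and flat-curve populations are excluded, and
    (by default) bimodal populations too — their primary/secondary modes
    are close in height, so the estimated primary can flip between regimes.
    Optional weights (e.g. the fraction of the rainfall gradient a species
    spans) turn the fit into WLS. Returns (offset, n_pre, n_post).
    """
    pops = populations.copy()
    if exclude_bimodal and "bimodal" in pops.columns:
        pops = pops[~pops["bimodal"].astype(bool)]
    pops["regime"] = classify_regime(pops["linearized_day"])
    pops = pops[pops["regime"].isin(["pre", "post"])]
    if pops["regime"].nunique() < 2:
        raise ValueError("need populations in both regimes")
    formula = "linearized_day ~ C(regime, Treatment('pre'))"
    if gradient_span is not None:
        pops["_w"] = np.asarray(gradient_span, dtype=float)
        m = smf.wls(formula, data=pops, weights=pops["_w"]).fit()
        params = m.params
    else:
        gm = fit_guild_model(pops, "linearized_day",
                             "C(regime, Treatment('pre'))")
        params = gm.params
    keys = [k for k in params.index if "T.post" in k]
    if keys:
        offset = float(params[keys[0]])
    else:
        # model fell back (tiny groups): plain difference of regime means
        means = pops.groupby("regime")["linearized_day"].mean()
        offset = float(means["post"] - means["pre"])
    return (offset / DAYS_PER_MONTH,
            int((pops["regime"] == "pre").sum()),
            int((pops["regime"] == "post").sum()))


def select_start_date(peak_doys, candidate_start_doys=None) -> pd.DataFrame:
    """Scroll candidate season-start dates and rank them by AICc.

    Each candidate start linearizes the circular peaks as days-since-start;
    a Gaussian intercept-only model is scored by AICc, so the winning start
    is the one that keeps the community's breeding season unwrapped (the
    smallest spread). Returns a table sorted by AICc with Akaike weights.
    """
    doys = np.asarray(peak_doys, dtype=float)
    doys = doys[np.isfinite(doys)]
    if len(doys) < 3:
        raise ValueError("need at least 3 peaks to scroll start dates")
    if candidate_start_doys is None:
        from ._circular import MONTH_START_DOY
        candidate_start_doys = [int(d) for d in MONTH_START_DOY]
    rows = []
    n = len(doys)
    for s0 in candidate_start_doys:
        lin = (doys - s0) % 365.0
        sse = float(((lin - lin.mean()) ** 2).sum())
        rows.append({"start_doy": int(s0),
                     "aicc": aicc(_gauss_loglik(sse, n), 2, n)})
    tab = pd.DataFrame(rows)
    tab["weight"] = akaike_weights(tab["aicc"])
    tab["delta"] = tab["aicc"] - tab["aicc"].min()
    return tab.sort_values("aicc").reset_index(drop=True)


def temporal_mad_months(annual: pd.DataFrame, min_years: int = 3) -> float:
    """Mean absolute deviation of annual peaks from the population mean."""
    df = annual.dropna(subset=["linearized_day"]).copy()
    counts = df.groupby(["species", "landscape"])["year"].transform("size")
    df = df[counts >= min_years]
    if df.empty:
        return np.nan
    g = df.groupby(["species", "landscape"])["linearized_day"]
    dev = (df["linearized_day"] - g.transform("mean")).abs()
    return float(dev.mean() / DAYS_PER_MONTH)
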