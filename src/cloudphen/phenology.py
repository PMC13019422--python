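"""Population breeding-phenology estimation from capture records.

The central method: current breeding evidence (brood patch / cloacal
protuberance), juvenile captures and molt captures are merged into a single
set of dated reproductive events — juveniles and molt are backdated to the
breeding event that produced them using stage durations — and a cyclic
(period-12-month) curve of event rate per capture is fitted per population
(species x landscape, optionally x year) with sampling effort as exposure.
From each fitted curve we extract the breeding peak (circular argmax), any
secondary peak in a different rainfall season (bimodal breeding), and
reproductive effort (the maximum monthly percentage of events).

Backdating emits the single most-likely event month for each capture, with
a weight below one expressing the width of the age/stage class, so that
total event mass is conserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix

from .config import (Durations, FilterTiers, PhenologyConfig, SEASONS,
                     GUILD_START_DOY, ANNUAL_SPLIT_DOY)
from ._circular import (circ_dist, circ_mean, month_mid_doy,
                        MONTH_START_DOY, DAYS_PER_MONTH)

__all__ = [
    "backdate_events",
    "monthly_event_table",
    "fit_population_curve",
    "extract_peak",
    "detect_bimodality",
    "reproductive_effort",
    "apply_filters",
    "population_phenology",
    "refine_peak",
    "PopulationCurve",
]

_PHENO_RE = re.compile(r"^(BR|JUV[123]|MOLT[123]|NONE)$")


def season_of_month(month: int) -> str:
    for name, months in SEASONS.items():
        if month in months:
            return name
    raise ValueError(f"month {month} outside 1..12")


def backdate_events(captures: pd.DataFrame,
                    durations: Durations | None = None) -> pd.DataFrame:
    """Turn phenophase captures into dated, weighted reproductive events.

    BR (and early molt retaining breeding characters) maps to the capture
    month with weight 1; JUVk is backdated by chick duration plus the age
    class midpoint; MOLTk by molt onset lag plus the stage midpoint, each
    with a weight reflecting class width. Records of birds before their
    first breeding season are dropped; NONE emits nothing.
    """
    dur = durations or Durations()
    df = captures.copy()
    df["date"] = pd.to_datetime(df["date"])

    bad = ~df["phenophase"].astype(str).str.match(_PHENO_RE)
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"unknown phenophase code {df.loc[row, 'phenophase']!r} at row {row}")

    df = df[df.get("age_class", "adult") != "pre-first-breeding"]

    out = []
    has_bchar = "breeding_char" in df.columns
    for code, sub in df.groupby("phenophase"):
        if code == "NONE":
            continue
        sub = sub.copy()
        if code == "BR":
            off, w, cls = 0.0, 1.0, "current"
        elif code.startswith("JUV"):
            k = int(code[3])
            off, w, cls = dur.juvenile_offset(k), dur.juvenile_weights[k - 1], \
                "backdated-juvenile"
        else:
            k = int(code[4])
            off, w, cls = dur.molt_offset(k), dur.molt_weights[k - 1], \
                "backdated-molt"
            if k == 1 and has_bchar:
                # early molt retaining breeding characters = current breeding
                cur = sub[sub["breeding_char"].astype(bool)].copy()
                sub = sub[~sub["breeding_char"].astype(bool)]
                if len(cur):
                    cur["event_date"] = cur["date"]
                    cur["weight"] = 1.0
                    cur["event_class"] = "current"
                    out.append(cur)
        sub["event_date"] = sub["date"] - pd.Timedelta(days=off)
        sub["weight"] = w
        sub["event_class"] = cls
        out.append(sub)

    if not out:
        cols = list(captures.columns) + ["event_date", "weight", "event_class",
                                         "implied_month"]
        return pd.DataFrame(columns=cols)
    ev = pd.concat(out, ignore_index=True)
    ev["implied_month"] = pd.to_datetime(ev["event_date"]).dt.month
    keep = ["capture_id", "species", "family", "genus", "guild", "landscape",
            "date", "event_date", "implied_month", "weight", "event_class"]
    return ev[[c for c in keep if c in ev.columns]]


def _channel_detectability(sampled: pd.Series, events: pd.DataFrame,
                           dur: Durations) -> pd.Series:
    """Relative detectability of an event implied in each month.

    A month-m event is observed through three channels: current breeding
    evidence (needs captures in m itself), juveniles (captures over the
    chick + juvenile-age window after m), and molt (captures over the molt
    window). Each channel counts only the fraction of its lag window that
    falls in sampled months. Channel masses are estimated from the
    population's own event-class weights; the result is scaled so the best
    month has detectability 1.
    """
    masses = {"current": 0.0, "backdated-juvenile": 0.0, "backdated-molt": 0.0}
    if len(events) and "event_class" in events.columns:
        for cls, w in events.groupby("event_class")["weight"].sum().items():
            masses[cls] = float(w)
    total = sum(masses.values())
    if total <= 0:
        return sampled.astype(float)

    windows = {
        "backdated-juvenile": (dur.chick_days + dur.juvenile_bounds[0] + 1,
                               dur.chick_days + dur.juvenile_bounds[-1]),
        "backdated-molt": (dur.molt_onset_lag + 1,
                           dur.molt_onset_lag + dur.molt_duration),
    }
    sampled_doy = np.zeros(365, dtype=bool)
    for m in range(1, 13):
        if sampled.get(m, False):
            lo = MONTH_START_DOY[m - 1]
            hi = MONTH_START_DOY[m] if m < 12 else 366
            sampled_doy[lo - 1:hi - 1] = True

    det = {}
    for m in range(1, 13):
        mid = int(month_mid_doy(m))
        d = masses["current"] * float(sampled.get(m, False))
        for cls, (lo, hi) in windows.items():
            days = (mid - 1 + np.arange(int(lo), int(hi) + 1)) % 365
            d += masses[cls] * float(sampled_doy[days].mean())
        det[m] = d / total
    det = pd.Series(det)
    peak = det.max()
    return det / peak if peak > 0 else det


def monthly_event_table(events: pd.DataFrame, captures: pd.DataFrame,
                        visits: pd.DataFrame | None = None,
                        exposure: str = "captures",
                        durations: Durations | None = None) -> pd.DataFrame:
    """Month x (weighted events, exposure) table for one population.

    `events` and `captures` must already be subset to the population.
    Base exposure per month is the number of captures (default) or summed
    net-hours from `visits`; it is then scaled by each month's relative
    detectability, which accounts for backdating: an event inside a
    sampling gap is still observable through juveniles and molt captured
    later, while an event whose juvenile/molt windows fall into the gap is
    partially censored. Gap months with implied event mass get the mean
    sampled exposure as base. Months with zero effective exposure are
    missing, not zero; their implied events move to the nearest sampled
    month if at most one month away, else they are dropped and counted in
    ``table.attrs['orphan_weight']``.
    """
    dur = durations or Durations()
    cap = captures.copy()
    cap["date"] = pd.to_datetime(cap["date"])
    months = pd.RangeIndex(1, 13)
    if exposure == "captures":
        expo = cap.groupby(cap["date"].dt.month).size().reindex(months, fill_value=0)
    elif exposure == "net_hours":
        if visits is None:
            raise ValueError("net_hours exposure requires visits")
        v = visits.copy()
        v["date_start"] = pd.to_datetime(v["date_start"])
        expo = v.groupby(v["date_start"].dt.month)["net_hours"].sum() \
            .reindex(months, fill_value=0.0)
    else:
        raise ValueError(f"unknown exposure {exposure!r}")
    visited = expo > 0
    expo = expo.astype(float)

    det = _channel_detectability(visited, events, dur)
    mean_expo = float(expo[visited].mean()) if visited.any() else 0.0
    base = expo.where(visited, mean_expo)
    eff_expo = base * det
    sampled = eff_expo > 0

    wt = pd.Series(0.0, index=months)
    orphans = 0.0
    if len(events):
        for m, w in events.groupby("implied_month")["weight"].sum().items():
            if sampled.get(m, False):
                wt[m] += w
                continue
            # nearest month with effective exposure, within one step
            for cand in ((m - 2) % 12 + 1, m % 12 + 1):
                if sampled.get(cand, False):
                    wt[cand] += w
                    break
            else:
                orphans += w
    # months never visited and with no event mass stay missing
    sampled &= visited | (wt > 0)
    eff_expo = eff_expo.where(sampled, 0.0)
    tab = pd.DataFrame({"weighted_events": wt,
                        "exposure": eff_expo,
                        "sampled": sampled})
    tab.index.name = "month"
    tab.attrs["orphan_weight"] = orphans
    return tab


@dataclass
class PopulationCurve:
    """Fitted periodic event-rate curve (per unit exposure) over months.

    `support` marks grid points inside sampled months; peaks are only
    admitted there — the smooth is unconstrained inside sampling gaps and
    can overshoot, so a maximum in an unsampled month is not evidence.
    """

    grid_month: np.ndarray            # fractional months on [0, 12)
    rate: np.ndarray                  # fitted events per capture
    support: np.ndarray = None        # bool mask of sampled months
    converged: bool = True
    flat: bool = False                # no usable seasonal signal
    n_events: float = 0.0
    months_covered: int = 0
    raw_max_rate: float = 0.0

    def __post_init__(self):
        if self.support is None:
            self.support = np.ones_like(self.grid_month, dtype=bool)

    @property
    def peak_month(self) -> float:
        r = np.where(self.support, self.rate, -np.inf)
        return float(self.grid_month[int(np.argmax(r))])

    @property
    def peak_doy(self) -> float:
        return float(self.peak_month / 12.0 * 365.0 % 365.0)

    def peak_month_near(self, anchor_month: float,
                        window_months: float = 3.0) -> float:
        """Maximum within a circular window around an anchor month.

        Used for annual models of bimodal or sparse populations, where the
        global maximum can jump to a secondary mode: the annual peak is the
        maximum nearest the population's pooled (multi-year) peak.
        """
        near = circ_dist(self.grid_month, anchor_month, period=12.0) \
            <= window_months
        r = np.where(self.support & near, self.rate, -np.inf)
        if not np.isfinite(r).any():
            return np.nan
        return float(self.grid_month[int(np.argmax(r))])

    def rate_at(self, month_frac):
        return np.interp(np.asarray(month_frac, float) % 12.0,
                         self.grid_month, self.rate, period=12.0)


def _design(month_mid: np.ndarray, basis: str, df: int):
    if basis == "cyclic_spline":
        X = dmatrix("cc(x, df=df_, lower_bound=0, upper_bound=12)",
                    {"x": month_mid, "df_": df}, return_type="matrix")
        return np.asarray(X), ("cyclic_spline", df)
    w = 2 * np.pi / 12.0
    cols = [np.ones_like(month_mid)]
    for h in (1, 2):
        cols += [np.cos(h * w * month_mid), np.sin(h * w * month_mid)]
    return np.column_stack(cols), ("harmonic", 2)


def _design_eval(grid: np.ndarray, basis_spec) -> np.ndarray:
    kind, df = basis_spec
    if kind == "cyclic_spline":
        X = dmatrix("cc(x, df=df_, lower_bound=0, upper_bound=12)",
                    {"x": grid, "df_": df}, return_type="matrix")
        return np.asarray(X)
    w = 2 * np.pi / 12.0
    cols = [np.ones_like(grid)]
    for h in (1, 2):
        cols += [np.cos(h * w * grid), np.sin(h * w * grid)]
    return np.column_stack(cols)


def fit_population_curve(table: pd.DataFrame,
                         basis: str = "harmonic",
                         basis_df: int = 4) -> PopulationCurve:
    """Fit the cyclic event-rate curve to a monthly event table.

    Weighted event counts are modelled as Poisson with log link on a cyclic
    basis of the month, with log exposure as offset, giving a non-negative
    periodic rate. Falls back to a 2-harmonic Fourier basis when the spline
    fit does not converge; populations with no events yield a flat flagged
    curve.
    """
    tab = table[table["sampled"]]
    y = tab["weighted_events"].to_numpy(dtype=float)
    expo = tab["exposure"].to_numpy(dtype=float)
    mm = tab.index.to_numpy(dtype=float) - 0.5
    grid = np.arange(0.0, 12.0, 0.05)
    sampled_months = set(tab.index)
    support = np.isin(np.floor(grid).astype(int) + 1, list(sampled_months))

    n_events = float(y.sum())
    months_covered = int((tab["exposure"] > 0).sum())
    raw = float((y / expo).max()) if len(y) else 0.0
    if n_events <= 0 or len(y) < 4:
        return PopulationCurve(grid, np.zeros_like(grid), support,
                               converged=False, flat=True, n_events=n_events,
                               months_covered=months_covered, raw_max_rate=raw)

    for b in ((basis, "harmonic") if basis != "harmonic" else ("harmonic",)):
        X, basis_spec = _design(mm, b, basis_df)
        if X.shape[1] >= len(y):
            continue
        try:
            fit = sm.GLM(y, X, family=sm.families.Poisson(),
                         offset=np.log(expo)).fit(maxiter=100)
            if not np.all(np.isfinite(fit.params)):
                continue
            rate = np.exp(_design_eval(grid, basis_spec) @ fit.params)
            if not np.all(np.isfinite(rate)) or rate.max() > 10 * max(raw, 1e-6):
                continue
            flat = rate.max() <= 1.02 * rate.min()
            return PopulationCurve(grid, rate, support, converged=True,
                                   flat=flat, n_events=n_events,
                                   months_covered=months_covered,
                                   raw_max_rate=raw)
        except Exception:
            continue
    return PopulationCurve(grid, np.zeros_like(grid), support,
                           converged=False, flat=True, n_events=n_events,
                           months_covered=months_covered, raw_max_rate=raw)


def extract_peak(curve: PopulationCurve, guild: str,
                 anchor_doy: float | None = None,
                 anchor_window_months: float = 3.0) -> dict:
    """Circular peak plus the guild-linearized day for timing regressions.

    Linearized day = days since the guild's season start (1 April for
    insectivores/omnivores, 1 October for frugivores, 1 January for
    nectarivores), so peaks never wrap inside a guild's breeding season.
    With `anchor_doy` given (annual models), the peak is the maximum within
    `anchor_window_months` of the anchor instead of the global maximum, so
    secondary modes cannot masquerade as interannual shifts.
    """
    start = GUILD_START_DOY[guild]
    if curve.flat or not curve.converged:
        return {"peak_doy": np.nan, "linearized_day": np.nan, "flat": True}
    if anchor_doy is None or not np.isfinite(anchor_doy):
        doy = curve.peak_doy
    else:
        pm = curve.peak_month_near(anchor_doy / 365.0 * 12.0,
                                   anchor_window_months)
        if not np.isfinite(pm):
            return {"peak_doy": np.nan, "linearized_day": np.nan, "flat": True}
        doy = float(pm / 12.0 * 365.0 % 365.0)
    return {"peak_doy": doy,
            "linearized_day": float((doy - start) % 365.0),
            "flat": False}


def _raw_rate_near(table: pd.DataFrame, month_frac: float,
                   halfwidth: int = 1) -> float:
    """Maximum raw monthly event rate within +-halfwidth months."""
    center = int(month_frac) % 12 + 1
    months = [(center - 1 + k) % 12 + 1 for k in range(-halfwidth,
                                                       halfwidth + 1)]
    sub = table.loc[table.index.isin(months) & table["sampled"]]
    if sub.empty or (sub["exposure"] <= 0).all():
        return 0.0
    return float((sub["weighted_events"] / sub["exposure"]).max())


def detect_bimodality(curve: PopulationCurve,
                      min_separation_months: float = 4.0,
                      min_height_frac: float = 0.25,
                      table: pd.DataFrame | None = None) -> dict:
    """Secondary breeding peak in a different rainfall season.

    A population is bimodal when the fitted curve has a secondary local
    maximum at least `min_separation_months` from the primary (circular
    distance), at least `min_height_frac` of the primary height, with the
    two peaks falling in different rainfall seasons. When the monthly event
    `table` is supplied, the candidate is confirmed against the raw monthly
    rates near both peaks — the smooth basis can produce antipodal
    sidelobes that raw data do not support.
    """
    if curve.flat or not curve.converged:
        return {"bimodal": False, "secondary_peak_doy": np.nan}
    r = curve.rate
    is_max = (r > np.roll(r, 1)) & (r >= np.roll(r, -1)) & curve.support
    peaks = np.flatnonzero(is_max)
    if len(peaks) < 2:
        return {"bimodal": False, "secondary_peak_doy": np.nan}
    prim = int(np.argmax(np.where(curve.support, r, -np.inf)))
    prim_m = curve.grid_month[prim]
    best = None
    for p in peaks:
        m = curve.grid_month[p]
        if circ_dist(m, prim_m, period=12.0) < min_separation_months:
            continue
        if r[p] < min_height_frac * r[prim]:
            continue
        s1 = season_of_month(int(prim_m) % 12 + 1)
        s2 = season_of_month(int(m) % 12 + 1)
        if s1 == s2:
            continue
        if table is not None:
            raw_prim = _raw_rate_near(table, prim_m)
            if raw_prim > 0 and _raw_rate_near(table, m) \
                    < min_height_frac * raw_prim:
                continue
        if best is None or r[p] > r[best]:
            best = p
    if best is None:
        return {"bimodal": False, "secondary_peak_doy": np.nan}
    return {"bimodal": True,
            "secondary_peak_doy": float(curve.grid_month[best] / 12.0 * 365.0)}


def reproductive_effort(table: pd.DataFrame, curve: PopulationCurve) -> dict:
    """Maximum monthly percentage of reproductive events in the population.

    Reported from the smoothed curve (primary) and the raw monthly
    proportion (alongside).
    """
    raw = float(np.clip(curve.raw_max_rate * 100, 0, 100))
    if curve.flat or not curve.converged:
        # no usable smooth: report the raw monthly maximum (an effort of
        # ~zero in a well-sampled year is data, not missingness)
        return {"effort_max_pct": raw, "effort_raw_pct": raw}
    rate = curve.rate[curve.support] if curve.support.any() else curve.rate
    return {"effort_max_pct": float(np.clip(rate.max() * 100, 0, 100)),
            "effort_raw_pct": raw}


def refine_peak(events: pd.DataFrame, table: pd.DataFrame,
                mode_doy: float, window_days: float = 90.0) -> float:
    """Sub-month peak estimate: exposure-weighted circular mean of event dates.

    The fitted monthly curve locates the mode to month resolution but its
    argmax carries month-boundary artifacts, especially next to sampling
    gaps. Events near the mode (within `window_days`, so secondary modes are
    excluded) carry exact implied dates; their circular mean, weighted by
    backdating certainty over the month's exposure, is an unbinned location
    estimate for the peak.
    """
    if not len(events) or not np.isfinite(mode_doy):
        return np.nan
    ev = events.copy()
    d = pd.to_datetime(ev["event_date"])
    doy = d.dt.dayofyear.to_numpy().astype(float)
    doy = np.where(d.dt.is_leap_year & (doy > 59), doy - 1, doy)
    expo = table["exposure"].reindex(ev["implied_month"]).to_numpy()
    ok = np.isfinite(expo) & (expo > 0)
    # mean-shift iteration: recentre the window on each estimate so an
    # off-centre starting mode does not truncate the cloud asymmetrically
    center = float(mode_doy)
    for _ in range(4):
        sel = ok & (circ_dist(doy, center) <= window_days)
        if sel.sum() == 0:
            return float(mode_doy)
        w = ev["weight"].to_numpy()[sel] / expo[sel]
        new = circ_mean(doy[sel], weights=w)
        if not np.isfinite(new):
            return center
        if circ_dist(new, center) < 1.0:
            center = new
            break
        center = new
    return float(center)


def apply_filters(n_events: float, months_covered: int,
                  tiers: FilterTiers | None = None) -> int:
    """Highest sampling-robustness tier the population satisfies (0 = none).

    Tiers are nested: passing tier k implies passing all lower tiers.
    """
    tiers = tiers or FilterTiers()
    best = 0
    for t in (1, 2, 3, 4):
        if tiers.passes(n_events, months_covered, t):
            best = t
    return best


def _bird_year_of(dates: pd.Series, guild: str) -> np.ndarray:
    doy = dates.dt.dayofyear.to_numpy()
    yr = dates.dt.year.to_numpy()
    start = ANNUAL_SPLIT_DOY[guild]
    return np.where(doy >= start, yr, yr - 1)


def population_phenology(captures: pd.DataFrame, visits: pd.DataFrame,
                         config: PhenologyConfig | None = None,
                         per_year: bool = False) -> pd.DataFrame:
    """Fit cyclic population models for every species x landscape (x year).

    Returns one row per population with peak timing (circular and
    guild-linearized), bimodality, reproductive effort, sample sizes and the
    sampling-filter tier. With `per_year=True` populations are split by the
    guild-specific phenology year of the *event* dates (annual models).
    """
    cfg = config or PhenologyConfig()
    captures = captures.copy()
    captures["date"] = pd.to_datetime(captures["date"])
    events = backdate_events(captures, cfg.durations)

    rows = []
    for (sp, lid), cap_sub in captures.groupby(["species", "landscape"]):
        ev_sub = events[(events["species"] == sp) & (events["landscape"] == lid)]
        guild = cap_sub["guild"].iloc[0]
        meta = {"species": sp, "landscape": lid, "guild": guild,
                "family": cap_sub["family"].iloc[0],
                "genus": cap_sub["genus"].iloc[0]}
        anchor = None
        if not per_year:
            groups = [(None, ev_sub, cap_sub)]
        else:
            # pooled multi-year peak anchors the annual peaks
            pooled_tab = monthly_event_table(ev_sub, cap_sub,
                                             exposure="captures",
                                             durations=cfg.durations)
            pooled = fit_population_curve(pooled_tab, cfg.basis, cfg.basis_df)
            if pooled.converged and not pooled.flat:
                anchor = pooled.peak_doy
            ev_y = _bird_year_of(pd.to_datetime(ev_sub["event_date"]), guild) \
                if len(ev_sub) else np.array([], dtype=int)
            cap_y = _bird_year_of(cap_sub["date"], guild)
            groups = [(y, ev_sub[ev_y == y], cap_sub[cap_y == y])
                      for y in np.unique(cap_y)]
        for year, ev, cap in groups:
            tab = monthly_event_table(ev, cap, exposure="captures",
                                      durations=cfg.durations)
            n_events = float(tab["weighted_events"].sum())
            months_covered = int(tab["sampled"].sum())
            if per_year:
                # inclusion by sampling effort, not event count: a well
                # sampled year with few events is evidence of low effort
                if (len(cap) < cfg.annual_min_captures
                        or months_covered < cfg.annual_min_months):
                    continue
                tier = apply_filters(n_events, months_covered, cfg.filters)
            else:
                tier = apply_filters(n_events, months_covered, cfg.filters)
                if tier < 1:
                    continue
            curve = fit_population_curve(tab, cfg.basis, cfg.basis_df)
            pk = extract_peak(curve, guild, anchor_doy=anchor)
            if np.isfinite(pk["peak_doy"]):
                refined = refine_peak(ev, tab, pk["peak_doy"])
                if np.isfinite(refined):
                    start = GUILD_START_DOY[guild]
                    pk = {"peak_doy": float(refined % 365.0),
                          "linearized_day": float((refined - start) % 365.0),
                          "flat": False}
            bi = detect_bimodality(curve, cfg.min_separation_months,
                                   cfg.min_height_frac, table=tab)
            ef = reproductive_effort(tab, curve)
            if per_year and n_events < cfg.annual_min_events:
                # too few events to place an annual peak; effort still stands
                pk = {"peak_doy": np.nan, "linearized_day": np.nan,
                      "flat": True}
            rows.append({**meta, "year": year if year is not None else -1,
                         "event_rate": n_events / max(len(cap), 1),
                         "peak_doy": pk["peak_doy"],
                         "linearized_day": pk["linearized_day"],
                         "flat": pk["flat"],
                         "bimodal": bi["bimodal"],
                         "secondary_peak_doy": bi["secondary_peak_doy"],
                         "effort_max_pct": ef["effort_max_pct"],
                         "effort_raw_pct": ef["effort_raw_pct"],
                         "n_events": n_events, "n_captures": len(cap),
                         "months_covered": months_covered,
                         "filter_tier": tier,
                         "converged": curve.converged})
    cols = ["species", "landscape", "guild", "family", "genus", "year",
            "event_rate", "peak_doy", "linearized_day", "flat", "bimodal",
            "secondary_peak_doy", "effort_max_pct", "effort_raw_pct",
            "n_events", "n_captures", "months_covered", "filter_tier",
            "converged"]
    return pd.DataFrame(rows, columns=cols)
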