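"""Seeded synthetic cloud-forest study system.

Generates the full raw-data stack the analysis pipeline consumes — landscape
configurations along a transition-dry-season rainfall gradient, daily
rainfall with ENSO-like interannual anomalies, a multi-guild bird community
with known ("true") breeding phenology, visit schedules, capture records
with phenophase codes, and flower/fruit point counts — so that every
downstream stage is testable by parameter recovery without any field data.

The community's planted structure mirrors the Andean system being modelled:
nectarivores nest at the dry-season onset, frugivores in the wet season, and
insectivores follow a two-regime rule — populations at landscapes whose
dry-season arthropod-biomass normal falls below a threshold (psi) nest after
the dry season, the rest before it, separated by `offset_months`. Interannual
couplings (timing shifts and effort changes per standardized rainfall
anomaly) are planted per guild and regime; biology responds to the realized
standardized anomaly of the simulated rainfall, the same quantity the
inference module recomputes from the daily-rain table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import biomass as _biomass
from .config import (SynthConfig, BiomassCoefficients, Durations,
                     ANNUAL_SPLIT_DOY)
from ._circular import DAYS_PER_MONTH

__all__ = [
    "LandscapeConfig",
    "generate_landscapes",
    "generate_rainfall",
    "generate_community",
    "generate_visits",
    "generate_captures",
    "generate_resources",
    "staggered_pair_community",
    "expected_biomass_curve",
    "seasonal_shape",
]

RAIN_PEAK_DOY = 91.0      # wettest day (~1 April)
RAIN_TROUGH_DOY = 205.0   # driest day (~24 July)
RAIN_LOG_AMP = 0.85
TRANSITION_DRY_DOYS = (92, 181)   # trailing-90 window ending 30 June


@dataclass
class LandscapeConfig:
    landscape_id: str
    elevation: float              # m
    annual_rain_normal: float     # mm/yr
    transition_dry_rain90: float  # mm, the gradient axis
    wet_peak_doy: float
    dry_cloud_cover: float        # fraction 0-1
    seasonal_amp: float = RAIN_LOG_AMP  # wet/dry contrast of the annual cycle


def seasonal_shape(doy, peak=RAIN_PEAK_DOY, trough=RAIN_TROUGH_DOY,
                   amp=RAIN_LOG_AMP):
    """Relative daily rainfall climatology: asymmetric single annual cycle.

    Falls from the wet peak to the dry trough over ~114 days and recovers
    over ~251 days, matching a Mar/Apr maximum and Jul/Aug minimum.
    """
    x = (np.asarray(doy, float) - peak) % 365
    fall = (trough - peak) % 365
    rise = 365 - fall
    h = np.where(x <= fall, np.cos(np.pi * x / fall),
                 -np.cos(np.pi * (x - fall) / rise))
    return np.exp(amp * h)


def _daily_scale(cfg: LandscapeConfig) -> float:
    """Scale factor so the climatological transition-dry 90-day accumulation
    matches cfg.transition_dry_rain90."""
    doys = np.arange(1.0, 366.0)
    g = seasonal_shape(doys, peak=cfg.wet_peak_doy, amp=cfg.seasonal_amp)
    lo, hi = TRANSITION_DRY_DOYS
    return cfg.transition_dry_rain90 / g[(doys >= lo) & (doys <= hi)].sum()


def generate_landscapes(n_landscapes: int, gradient_range=(200.0, 450.0),
                        seed: int = 0, wet_peak_doy: float = RAIN_PEAK_DOY,
                        ) -> list[LandscapeConfig]:
    """Landscapes whose transition-dry 90-day rainfall evenly spans the
    gradient; elevations are shuffled independently of rainfall."""
    if n_landscapes < 2:
        raise ValueError(f"need >= 2 landscapes, got {n_landscapes}")
    lo, hi = gradient_range
    if lo > hi:
        raise ValueError("gradient_range must be (low, high)")
    rng = np.random.default_rng(seed)
    rain90 = np.linspace(lo, hi, n_landscapes)
    elev = np.linspace(1700.0, 3100.0, n_landscapes)
    rng.shuffle(elev)  # uncorrelated with rainfall by construction
    # wet-peak timing varies spatially by < 2 weeks; cloud cover grows with
    # gradient position (wetter transition -> cloudier dry season)
    peaks = wet_peak_doy + rng.uniform(-7, 7, n_landscapes)
    frac = (rain90 - lo) / max(hi - lo, 1e-9)
    cloud = np.clip(0.25 + 0.4 * frac + rng.normal(0, 0.10, n_landscapes), 0, 1)
    # wet/dry seasonal contrast varies independently of the gradient, so
    # annual rainfall and transition-season rainfall decouple across sites
    amps = rng.uniform(0.70, 1.0, n_landscapes)
    out = []
    doys = np.arange(1.0, 366.0)
    for i in range(n_landscapes):
        g = seasonal_shape(doys, peak=peaks[i], amp=amps[i])
        annual = rain90[i] * g.sum() / g[(doys >= 92) & (doys <= 181)].sum()
        out.append(LandscapeConfig(
            landscape_id=f"L{i + 1}", elevation=float(elev[i]),
            annual_rain_normal=float(annual),
            transition_dry_rain90=float(rain90[i]),
            wet_peak_doy=float(peaks[i]), dry_cloud_cover=float(cloud[i]),
            seasonal_amp=float(amps[i])))
    return out


def generate_rainfall(cfg: LandscapeConfig, years: int, enso_anomalies=None,
                      seed: int = 0, start_year: int = 2015,
                      anomaly_cv: float = 0.18,
                      rain_hours_coef: float = 0.25) -> pd.DataFrame:
    """Daily rainfall for one landscape over `years` calendar years.

    `enso_anomalies` are per-year multipliers of the daily seasonal mean
    (1.0 = normal year); if given as standardized anomalies use
    ``1 + anomaly_cv * z``. Wet days follow a seasonal occurrence
    probability; wet-day amounts are Gamma draws whose expectation restores
    the daily climatological mean. Daytime rain hours rise sublinearly with
    the daily total and are capped at daylight.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if enso_anomalies is None:
        enso_anomalies = np.ones(years)
    enso_anomalies = np.asarray(enso_anomalies, dtype=float)
    if len(enso_anomalies) != years:
        raise ValueError("need one anomaly multiplier per year")
    if (enso_anomalies < 0).any():
        raise ValueError("anomaly multipliers must be non-negative")

    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + years - 1}-12-31",
                          freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    # fold leap-day so the climatology stays 365-periodic
    leap = dates.is_leap_year
    doy = np.where(leap & (doy > 59), doy - 1, doy)
    year_ix = dates.year.to_numpy() - start_year

    g = seasonal_shape(doy, peak=cfg.wet_peak_doy, amp=cfg.seasonal_amp)
    mean_daily = _daily_scale(cfg) * g * enso_anomalies[year_ix]

    p_wet = np.clip(0.55 * g / g.mean(), 0.05, 0.95)
    shape_k = 0.7
    wet = rng.random(len(dates)) < p_wet
    amounts = rng.gamma(shape_k, 1.0, len(dates)) * \
        (mean_daily / (p_wet * shape_k))
    rain = np.where(wet, amounts, 0.0)

    # daylight: ~12 h with a 41-46 min seasonal range peaking near the
    # December solstice at 5-6 degrees south
    daylight = 12.0 + 0.35 * np.cos(2 * np.pi * (doy - 355) / 365)
    rain_h = np.minimum(daylight, rain_hours_coef * rain ** 0.8)

    return pd.DataFrame({
        "landscape": cfg.landscape_id,
        "date": dates,
        "rain_mm": rain,
        "daytime_rain_h": rain_h,
        "daylight_h": daylight,
        "filled_flag": False,
    })


def expected_biomass_curve(cfg: LandscapeConfig, coef: BiomassCoefficients):
    """Deterministic day-of-year biomass curve from the rainfall climatology.

    Returns (doy grid, biomass). Used to plant insectivore regimes; the
    pipeline re-estimates the same curve from simulated daily rainfall.
    """
    doys = np.arange(1.0, 366.0)
    m = _daily_scale(cfg) * seasonal_shape(doys, peak=cfg.wet_peak_doy,
                                           amp=cfg.seasonal_amp)
    ext = np.concatenate([m, m, m])
    r90 = np.array([ext[365 + i - 89:365 + i + 1].sum() for i in range(365)])
    r30 = np.array([ext[365 + i - 29:365 + i + 1].sum() for i in range(365)])
    return doys, _biomass.predict_biomass(r90, r30, coef)


def dry_season_biomass_min(cfg: LandscapeConfig, coef: BiomassCoefficients,
                           window=(152, 288)) -> float:
    """Minimum of the climatological biomass curve over the dry season and
    its tail (Jun-mid Oct), the resource floor breeding must clear."""
    doys, bm = expected_biomass_curve(cfg, coef)
    sel = (doys >= window[0]) & (doys <= window[1])
    return float(bm[sel].min())


_FAMILIES = {
    "nectarivore": [("Trochilidae", ["Adelomyia", "Coeligena", "Metallura"]),
                    ("Thraupidae", ["Diglossa"])],
    "frugivore": [("Tyrannidae", ["Mionectes"]),
                  ("Thraupidae", ["Anisognathus", "Iridosornis"]),
                  ("Cotingidae", ["Pipreola"])],
    "insectivore": [("Parulidae", ["Myiothlypis", "Myioborus"]),
                    ("Furnariidae", ["Synallaxis", "Cranioleuca", "Margarornis"]),
                    ("Rhinocryptidae", ["Scytalopus"]),
                    ("Grallariidae", ["Grallaria"]),
                    ("Tyrannidae", ["Mecocerculus", "Phylloscartes"]),
                    ("Troglodytidae", ["Pheugopedius", "Henicorhina"])],
    "omnivore": [("Passerellidae", ["Atlapetes", "Arremon"])],
}


def generate_community(landscapes: list[LandscapeConfig],
                       guild_mix=(0.17, 0.17, 0.66, 0.0),
                       psi_true: float = 43.0,
                       offset_months: float = 4.9,
                       seed: int = 0,
                       cfg: SynthConfig | None = None,
                       coef: BiomassCoefficients | None = None,
                       n_species: int = 60) -> pd.DataFrame:
    """Plant a community of species x landscape populations with known truth.

    One row per population with columns: species, family, genus, guild,
    landscape, regime, true_peak_doy, true_effort, bimodal_flag,
    secondary_peak_doy, timing_slope (months per SD anomaly), effort_slope
    (log effort per SD anomaly) and relative abundance.
    """
    if abs(sum(guild_mix) - 1.0) > 1e-6:
        raise ValueError("guild_mix fractions must sum to 1")
    if not 0 <= offset_months <= 6:
        raise ValueError("offset_months must lie in [0, 6]")
    cfg = cfg or SynthConfig(psi_true=psi_true, offset_months=offset_months,
                             guild_mix=tuple(guild_mix), n_species=n_species)
    coef = coef or BiomassCoefficients()
    rng = np.random.default_rng(seed)

    bmins = {lc.landscape_id: dry_season_biomass_min(lc, coef)
             for lc in landscapes}
    vals = np.array(list(bmins.values()))
    if psi_true < vals.min() or psi_true > vals.max():
        import warnings
        warnings.warn(
            f"psi_true={psi_true} outside simulated biomass range "
            f"[{vals.min():.1f}, {vals.max():.1f}]: threshold unidentifiable",
            stacklevel=2)
    post_regime = {k: v < psi_true for k, v in bmins.items()}

    counts = _apportion(n_species, guild_mix)
    guild_of, fam_of, gen_of = [], [], []
    for guild, c in zip(("nectarivore", "frugivore", "insectivore", "omnivore"),
                        counts):
        fams = _FAMILIES[guild]
        for i in range(c):
            fam, genera = fams[i % len(fams)]
            guild_of.append(guild)
            fam_of.append(fam)
            gen_of.append(genera[(i // len(fams)) % len(genera)])

    # log-series abundance: a few common, many rare species
    abund = stats.logser.rvs(0.93, size=n_species, random_state=rng).astype(float)
    abund /= abund.mean()

    lids = [lc.landscape_id for lc in landscapes]
    rows = []
    for s in range(n_species):
        guild = guild_of[s]
        # ~60% of species occur at more than one landscape
        if rng.random() < 0.4 or len(lids) < 2:
            k = 1
        else:
            k = int(rng.integers(2, min(6, len(lids)) + 1))
        at = rng.choice(lids, size=k, replace=False)
        # species-level timing intercept (phylogenetic/idiosyncratic)
        sp_shift = rng.normal(0, 0.20) * DAYS_PER_MONTH
        base_effort = float(np.clip(
            cfg.effort_base[guild] * np.exp(rng.normal(0, 0.15)), 0.10, 0.60))
        for lid in at:
            pop_noise = rng.normal(0, cfg.peak_sd_months) * DAYS_PER_MONTH
            if guild == "nectarivore":
                peak = cfg.nect_peak_doy + sp_shift + pop_noise
                t_slope, e_slope, regime = 0.0, 0.0, "none"
            elif guild == "frugivore":
                peak = cfg.frug_peak_doy + sp_shift + pop_noise
                t_slope, e_slope, regime = 0.0, cfg.effort_slope_frugivore, "none"
            else:  # insectivore / omnivore: two-regime rule
                if post_regime[lid]:
                    peak = (cfg.pre_peak_doy + cfg.offset_months * DAYS_PER_MONTH
                            + sp_shift + pop_noise)
                    t_slope = -cfg.timing_slope_months   # later in drier years
                    e_slope = cfg.effort_slope_post_insect
                    regime = "post"
                else:
                    peak = cfg.pre_peak_doy + sp_shift + pop_noise
                    t_slope = cfg.timing_slope_months    # earlier in drier years
                    e_slope = 0.0
                    regime = "pre"
            bimodal = rng.random() < cfg.bimodal_prob[guild]
            sec = (peak + 6 * DAYS_PER_MONTH) % 365 if bimodal else np.nan
            rows.append({
                "species": f"sp{s + 1:03d}", "family": fam_of[s],
                "genus": gen_of[s], "guild": guild, "landscape": lid,
                "regime": regime, "true_peak_doy": float(peak % 365),
                "true_effort": base_effort, "bimodal_flag": bool(bimodal),
                "secondary_peak_doy": sec,
                "timing_slope": float(t_slope), "effort_slope": float(e_slope),
                "abundance": float(abund[s]),
                "biomass_min": bmins[lid],
            })
    return pd.DataFrame(rows)


def staggered_pair_community(landscapes: list[LandscapeConfig],
                             stagger_months: float = 2.2,
                             base_peak_doy: float = 135.0,
                             seed: int = 0,
                             cfg: SynthConfig | None = None) -> pd.DataFrame:
    """Two nectarivore species at shared landscapes with staggered peaks.

    Species B nests `stagger_months` after species A everywhere; both shift
    in tandem along the dry-season cloud-cover gradient (long- vs
    short-billed hummingbird pattern).
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    clouds = np.array([lc.dry_cloud_cover for lc in landscapes])
    cshift = 1.5 * (clouds - clouds.mean()) * DAYS_PER_MONTH  # tandem shift
    rows = []
    for j, lc in enumerate(landscapes):
        for name, fam, gen, off in (
                ("longbill", "Trochilidae", "Coeligena", 0.0),
                ("shortbill", "Trochilidae", "Adelomyia",
                 stagger_months * DAYS_PER_MONTH)):
            rows.append({
                "species": name, "family": fam, "genus": gen,
                "guild": "nectarivore", "landscape": lc.landscape_id,
                "regime": "none",
                "true_peak_doy": float((base_peak_doy + cshift[j] + off
                                        + rng.normal(0, 0.15 * DAYS_PER_MONTH))
                                       % 365),
                "true_effort": 0.45, "bimodal_flag": False,
                "secondary_peak_doy": np.nan, "timing_slope": 0.0,
                "effort_slope": 0.0, "abundance": 3.0,
                "biomass_min": np.nan,
            })
    return pd.DataFrame(rows)


def generate_visits(landscapes, years: int = 5, start_year: int = 2015,
                    style: str = "monthly", gap_months=(3, 4),
                    seed: int = 0) -> pd.DataFrame:
    """Visit schedule: one multi-day netting visit per sampled landscape-month.

    "monthly" visits every month outside the Mar/Apr gap; "snapshot"
    emulates 3-6-month field campaigns (Jun-Nov for three years, May-Jul for
    two, one Dec-Feb wet-season block).
    """
    rng = np.random.default_rng(seed)
    if style == "monthly":
        blocks = [(y, m) for y in range(years) for m in range(1, 13)
                  if m not in gap_months]
    elif style == "snapshot":
        blocks = []
        for y in range(min(3, years)):
            blocks += [(y, m) for m in (6, 7, 8, 9, 10, 11)]
        for y in range(3, years):
            blocks += [(y, m) for m in (5, 6, 7)]
        if years >= 4:
            blocks += [(3, 12), (4, 1), (4, 2)]
        blocks = sorted({b for b in blocks if b[0] < years
                         and b[1] not in gap_months})
    else:
        raise ValueError(f"unknown schedule style {style!r}")
    if not blocks:
        raise ValueError("empty visit schedule")

    rows = []
    vid = 0
    for lc in landscapes:
        for (y, m) in blocks:
            vid += 1
            day0 = int(rng.integers(3, 18))
            start = pd.Timestamp(year=start_year + y, month=m, day=day0)
            rows.append({
                "landscape": lc.landscape_id, "visit_id": f"V{vid:05d}",
                "date_start": start, "date_end": start + pd.Timedelta(days=5),
                "net_hours": float(np.round(60 + rng.normal(0, 6), 1)),
            })
    return pd.DataFrame(rows)


def _apportion(n, fractions):
    raw = np.asarray(fractions) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def _kernel(doy_grid, peak, power, bimodal_sec=None, bimodal_h=0.55):
    x = 2 * np.pi * (doy_grid - peak) / 365
    k = ((1 + np.cos(x)) / 2) ** power
    if bimodal_sec is not None and np.isfinite(bimodal_sec):
        x2 = 2 * np.pi * (doy_grid - bimodal_sec) / 365
        k = np.minimum(k + bimodal_h * ((1 + np.cos(x2)) / 2) ** power, 1.0)
    return k


def _bird_year(dates_doy, dates_year, start_doy):
    """Year label of the guild-specific phenology year containing each day."""
    return np.where(dates_doy >= start_doy, dates_year, dates_year - 1)


def generate_captures(community: pd.DataFrame, visits: pd.DataFrame,
                      rain: pd.DataFrame, detection: float = 1.0,
                      cfg: SynthConfig | None = None,
                      durations: Durations | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Capture records with phenophase codes for the planted community.

    Per population and visit, Poisson captures proportional to abundance and
    `detection`; each capture shows at most one phenophase (current breeding
    BR, juvenile JUV1-3, molt MOLT1-3, or NONE) drawn from the population's
    time-varying event intensity. Juveniles appear after peaks (fledged
    `chick_days` before capture minus their age), molt follows breeding, and
    26% / 2% of early / late molt captures retain breeding characteristics
    (`breeding_char`). A fraction of molting birds are first-cycle
    (pre-first-breeding) and carry age_class "pre-first-breeding".
    """
    if detection < 0:
        raise ValueError("detection must be >= 0")
    if visits.empty:
        raise ValueError("empty visit schedule")
    cfg = cfg or SynthConfig()
    dur = durations or Durations()
    rng = np.random.default_rng(seed)
    if detection == 0:
        return _empty_captures()

    from .climate import standardized_anomaly

    # per-landscape interannual anomalies: transition-dry (AMJ) for
    # insectivores/omnivores, wet-season (JFM) for frugivores
    z_amj, z_jfm = {}, {}
    for lid, sub in rain.groupby("landscape"):
        z_amj[lid] = standardized_anomaly(sub, (4, 5, 6))
        z_jfm[lid] = standardized_anomaly(sub, (1, 2, 3))

    t0 = pd.to_datetime(rain["date"]).min().normalize()
    t1 = pd.to_datetime(rain["date"]).max().normalize()
    span = pd.date_range(t0, t1, freq="D")
    span_doy = span.dayofyear.to_numpy().astype(float)
    leap = span.is_leap_year
    span_doy = np.where(leap & (span_doy > 59), span_doy - 1, span_doy)
    span_year = span.year.to_numpy()
    day_index = {d: i for i, d in enumerate(span)}

    visits = visits.copy()
    visits["date_start"] = pd.to_datetime(visits["date_start"])
    visits_by_lid = dict(tuple(visits.groupby("landscape")))

    j_lo = int(dur.chick_days + dur.juvenile_bounds[0]) + 1
    j_hi = int(dur.chick_days + dur.juvenile_bounds[-1])
    m_lo = int(dur.molt_onset_lag) + 1
    m_hi = int(dur.molt_onset_lag + dur.molt_duration)

    recs = []
    cap_n = 0
    for pop in community.itertuples(index=False):
        lid = pop.landscape
        if lid not in visits_by_lid:
            continue
        vsub = visits_by_lid[lid]
        # year boundary far from every peak so a season's shift never
        # straddles two coupling years
        start_doy = ANNUAL_SPLIT_DOY[pop.guild]
        by = _bird_year(span_doy, span_year, start_doy)
        if pop.guild in ("insectivore", "omnivore"):
            zser = z_amj[lid]
            zy = zser.reindex(by).fillna(0.0).to_numpy()
        elif pop.guild == "frugivore":
            zser = z_jfm[lid]
            zy = zser.reindex(by + 1).fillna(0.0).to_numpy()
        else:
            zy = np.zeros(len(span))

        shift = pop.timing_slope * DAYS_PER_MONTH * zy
        eff = np.clip(pop.true_effort * np.exp(pop.effort_slope * zy),
                      0.02, 0.90)
        kern = _kernel(span_doy - shift, pop.true_peak_doy, cfg.kernel_power,
                       pop.secondary_peak_doy, cfg.bimodal_height)
        intensity = eff * kern  # P(current breeding evidence) by day

        # juvenile / molting availability: trailing means of the event
        # intensity over the respective age windows
        juv_avail = _trailing_mean(intensity, j_lo, j_hi)
        molt_avail = _trailing_mean(intensity, m_lo, m_hi)

        mu = detection * cfg.mean_captures_per_visit * pop.abundance
        n_per_visit = rng.poisson(mu, len(vsub))
        total = int(n_per_visit.sum())
        if total == 0:
            continue
        vdates = np.repeat(vsub["date_start"].to_numpy(), n_per_visit)
        offs = rng.integers(0, 6, total)
        cdates = pd.DatetimeIndex(vdates) + pd.to_timedelta(offs, unit="D")
        ti = np.array([day_index[d] for d in cdates.normalize()])

        p_br = intensity[ti]
        p_juv = cfg.juvenile_rate * juv_avail[ti]
        p_molt = cfg.molt_rate * molt_avail[ti]
        tot = p_br + p_juv + p_molt
        scale = np.where(tot > 0.95, 0.95 / tot, 1.0)
        u = rng.random(total)
        is_br = u < p_br * scale
        is_juv = (~is_br) & (u < (p_br + p_juv) * scale)
        is_molt = (~is_br) & (~is_juv) & (u < tot * scale)

        pheno = np.full(total, "NONE", dtype=object)
        bchar = is_br.copy()
        ageclass = np.full(total, "adult", dtype=object)
        pheno[is_br] = "BR"
        for i in np.flatnonzero(is_juv):
            age = _sample_lag(rng, intensity, ti[i], j_lo, j_hi) - dur.chick_days
            k = int(np.searchsorted(dur.juvenile_bounds[1:-1], age,
                                    side="right")) + 1
            pheno[i] = f"JUV{k}"
        for i in np.flatnonzero(is_molt):
            prog = _sample_lag(rng, intensity, ti[i], m_lo, m_hi) - dur.molt_onset_lag
            k = int(np.searchsorted(dur.molt_stage_bounds[1:-1], prog,
                                    side="right")) + 1
            pheno[i] = f"MOLT{k}"
            p_overlap = cfg.overlap_early if k == 1 else cfg.overlap_late
            bchar[i] = rng.random() < p_overlap
            if rng.random() < cfg.prebreeding_molt_frac:
                ageclass[i] = "pre-first-breeding"

        ids = np.arange(cap_n + 1, cap_n + total + 1)
        cap_n += total
        recs.append(pd.DataFrame({
            "capture_id": [f"C{j:07d}" for j in ids],
            "individual_id": [f"I{j:07d}" for j in ids],
            "species": pop.species, "family": pop.family, "genus": pop.genus,
            "guild": pop.guild, "landscape": lid, "date": cdates,
            "phenophase": pheno, "age_class": ageclass,
            "breeding_char": bchar,
        }))

    if not recs:
        return _empty_captures()
    out = pd.concat(recs, ignore_index=True)
    return out.sort_values(["landscape", "date", "capture_id"]).reset_index(drop=True)


def _empty_captures() -> pd.DataFrame:
    cols = ["capture_id", "individual_id", "species", "family", "genus",
            "guild", "landscape", "date", "phenophase", "age_class",
            "breeding_char"]
    return pd.DataFrame(columns=cols)


def _trailing_mean(x: np.ndarray, lag_lo: int, lag_hi: int) -> np.ndarray:
    """Mean of x over trailing lags lag_lo..lag_hi (inclusive) at each index.

    Days before the start of the record are taken from the periodic
    continuation of its first year.
    """
    n = len(x)
    period = min(365, n)
    pre = np.tile(x[:period], int(np.ceil(lag_hi / period)) + 1)[-lag_hi:]
    ext = np.concatenate([pre, x])          # ext[lag_hi + i] == x[i]
    c = np.concatenate([[0.0], np.cumsum(ext)])
    i = np.arange(n) + lag_hi
    # sum of ext[i-lag_hi .. i-lag_lo]
    s = c[i - lag_lo + 1] - c[i - lag_hi]
    return s / (lag_hi - lag_lo + 1)


def _sample_lag(rng, intensity, t_idx, lag_lo, lag_hi) -> float:
    """Sample the event lag (days before capture) with weight proportional to
    the population's event intensity at the implied event date."""
    lags = np.arange(lag_lo, lag_hi + 1)
    idx = t_idx - lags
    w = np.where(idx >= 0, intensity[np.maximum(idx, 0)],
                 intensity[(idx % 365)])
    if w.sum() <= 0:
        w = np.ones_like(w)
    return float(rng.choice(lags, p=w / w.sum()))


def generate_resources(landscapes, visits: pd.DataFrame, rain: pd.DataFrame,
                       seed: int = 0, cfg: SynthConfig | None = None,
                       coef: BiomassCoefficients | None = None):
    """Flower/fruit point counts per visit plus the arthropod biomass truth.

    Bird-pollinated flowers peak at the dry-season onset and bird-dispersed
    fruit in the wet season, with Gamma-distributed per-visit totals whose
    log-scale seasonal range is configured to give a 3-4x max/min ratio of
    log abundance. Seasonal amplitude scales with the landscape's rainfall
    seasonality (a rain-free degenerate landscape yields flat resources).
    Arthropod truth comes from the biomass module applied to `rain`, so
    resource inference is internally consistent.
    Returns (resources_df, biomass_monthly_df).
    """
    cfg = cfg or SynthConfig()
    coef = coef or BiomassCoefficients()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.resource_log_range

    rain = rain.copy()
    rain["date"] = pd.to_datetime(rain["date"])
    seasonality = {}
    for lid, sub in rain.groupby("landscape"):
        mm = sub.groupby(sub["date"].dt.month)["rain_mm"].mean()
        tot = mm.max() + mm.min()
        seasonality[lid] = 0.0 if tot == 0 else (mm.max() - mm.min()) / tot

    rows = []
    visits = visits.copy()
    visits["date_start"] = pd.to_datetime(visits["date_start"])
    for v in visits.itertuples(index=False):
        doy = float(v.date_start.dayofyear)
        s = min(seasonality.get(v.landscape, 1.0) / 0.8, 1.0)
        for syndrome, peak in (("flower", 152.0), ("fruit", 15.0)):
            k = _kernel(np.array([doy]), peak, 2.0)[0]
            logmean = lo + (hi - lo) * (s * k + (1 - s) * 0.5)
            n_points = 10
            mean_count = np.exp(logmean) * n_points / 10.0
            count = rng.gamma(3.0, mean_count / 3.0)
            rows.append({
                "landscape": v.landscape, "visit_id": v.visit_id,
                "date": v.date_start, "syndrome": syndrome,
                "count": float(count), "n_points": n_points,
            })
    resources = pd.DataFrame(rows)
    bm = _biomass.monthly_series(rain, coef)
    return resources, bm
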