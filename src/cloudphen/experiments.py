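"""Parameter-recovery experiments on the synthetic community.

Each experiment simulates raw data with the generator's planted truths,
runs the estimation pipeline from captures and rainfall, and returns the
recovered community-level quantities. They are the package's built-in
validation studies: the planted effect sizes are the study conditions, and
the experiments measure how well the full capture-to-inference chain
returns them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import biomass as bio
from . import inference as inf
from . import phenology as phen
from . import synth
from .config import RunConfig, SynthConfig
from ._circular import circ_diff, DAYS_PER_MONTH

__all__ = [
    "insectivore_community_experiment",
    "staggered_pair_experiment",
    "frugivore_effort_experiment",
    "bimodality_experiment",
    "pooled_odds_ratio",
]


def _simulate(config: RunConfig):
    from .pipeline import simulate_study
    return simulate_study(config)


def landscape_biomass_minima(rain: pd.DataFrame, coef) -> dict:
    """Dry-season biomass floor per landscape, estimated from daily rain."""
    bm = bio.monthly_series(rain, coef)
    out = {}
    for lid, sub in bm.groupby("landscape"):
        n = bio.biomass_normals(sub)
        sel = (n.doy >= 152) & (n.doy <= 288)
        out[lid] = float(n.value[sel].min())
    return out


def insectivore_community_experiment(seed: int,
                                     config: RunConfig | None = None) -> dict:
    """Full-community recovery: regime offset, breakpoint, spatial:temporal
    ratio, interannual timing shift and regime-specific effort response.

    Simulates 8 landscapes x 5 years with the default community, fits pooled
    and annual population models, and returns:
    ``offset_months`` (between-regime insectivore peak offset),
    ``breakpoint_psi`` (resource threshold, mg/m^2), ``ratio``
    (spatial : interannual timing variability), ``timing_shift_months``
    (mean |peak shift| per SD rainfall anomaly) and
    ``effort_reduction_pct`` (post-dry-season effort loss per SD drought).
    """
    cfg = config or RunConfig()
    cfg.seed = int(seed)
    data = _simulate(cfg)

    pops = phen.population_phenology(data["captures"], data["visits"],
                                     cfg.phenology)
    pops = pops[pops["filter_tier"] >= cfg.filter_tier]
    annual = phen.population_phenology(data["captures"], data["visits"],
                                       cfg.phenology, per_year=True)
    ins = pops[pops["guild"].isin(["insectivore", "omnivore"])].dropna(
        subset=["linearized_day"]).copy()

    offset, n_pre, n_post = inf.regime_offset_months(ins)

    bmin = landscape_biomass_minima(data["rain_longterm"], cfg.biomass)
    ins["biomass_min"] = ins["landscape"].map(bmin)
    nb = ins[~ins["bimodal"].astype(bool)]
    bp = inf.segmented_fit(nb["biomass_min"], nb["linearized_day"]) \
        if len(nb) >= 8 else None

    anom = inf.guild_anomaly(data["rain"], "insectivore")
    ann_ins = annual[annual["guild"].isin(["insectivore", "omnivore"])]
    dr = inf.drought_response(ann_ins, anom)
    st = inf.spatial_temporal_ratio(ins, dr)

    slopes = [abs(d["timing_slope_months"]) for d in dr.values()
              if d is not None and np.isfinite(d["timing_slope_months"])]
    return {
        "offset_months": offset,
        "n_pre": n_pre, "n_post": n_post,
        "breakpoint_psi": bp.psi if bp is not None else np.nan,
        "breakpoint_preferred": bp.preferred if bp is not None else "none",
        "ratio": st["ratio"],
        "timing_shift_months": float(np.mean(slopes)) if slopes else np.nan,
        "effort_reduction_pct": (dr["post"]["effort_pct_change_dry"]
                                 if dr["post"] else np.nan),
        "n_populations": len(ins),
        "n_annual": len(ann_ins),
    }


def staggered_pair_experiment(seed: int, stagger_months: float = 2.2,
                              n_landscapes: int = 6) -> dict:
    """Recover the staggered peak offset of a short- vs long-billed
    nectarivore pair sharing the same landscapes."""
    cfg = RunConfig()
    ss = np.random.SeedSequence(int(seed))
    s_land, s_comm, s_rain, s_vis, s_cap = ss.spawn(5)
    landscapes = synth.generate_landscapes(n_landscapes, (200.0, 450.0),
                                           seed=s_land)
    mult = 1.0 + 0.18 * np.asarray(cfg.synth.enso_preset)
    rain = pd.concat([
        synth.generate_rainfall(lc, cfg.synth.years, mult, seed=sub,
                                start_year=cfg.synth.start_year)
        for lc, sub in zip(landscapes, s_rain.spawn(n_landscapes))],
        ignore_index=True)
    comm = synth.staggered_pair_community(landscapes, stagger_months,
                                          seed=s_comm)
    visits = synth.generate_visits(landscapes, cfg.synth.years,
                                   cfg.synth.start_year, seed=s_vis)
    captures = synth.generate_captures(comm, visits, rain, cfg=cfg.synth,
                                       seed=s_cap)
    pops = phen.population_phenology(captures, visits, cfg.phenology)
    wide = pops.pivot_table(index="landscape", columns="species",
                            values="peak_doy", aggfunc="first")
    if not {"longbill", "shortbill"} <= set(wide.columns):
        return {"stagger_months": np.nan, "n_landscapes": 0}
    d = circ_diff(wide["shortbill"], wide["longbill"]) / DAYS_PER_MONTH
    d = d[np.isfinite(d)]
    return {"stagger_months": float(np.mean(d)), "n_landscapes": int(len(d))}


def frugivore_effort_experiment(seed: int) -> dict:
    """Recover the frugivore wet-year effort increase (% per SD wet-season
    rainfall anomaly) from per-year population models."""
    cfg = RunConfig()
    cfg.seed = int(seed)
    cfg.synth.n_species = 24
    cfg.synth.guild_mix = (0.0, 1.0, 0.0, 0.0)
    data = _simulate(cfg)
    annual = phen.population_phenology(data["captures"], data["visits"],
                                       cfg.phenology, per_year=True)
    anom = inf.guild_anomaly(data["rain"], "frugivore")
    dr = inf.drought_response(annual, anom)
    # frugivores peak mid wet season, after the dry season on the
    # insectivore calendar, so they land in the "post" bucket
    d = dr["post"] or dr["pre"]
    if d is None:
        return {"effort_increase_pct": np.nan, "n": 0}
    return {"effort_increase_pct": d["effort_pct_change_wet"],
            "n": d["n_populations"]}


def bimodality_experiment(seed: int, n_insect_species: int = 36,
                          n_nect_species: int = 18) -> dict:
    """Detect bimodal breeding across guilds at high sampling effort.

    Returns the 2x2 detection counts (guild x bimodal) for pooling into an
    odds ratio across seeds.
    """
    cfg = RunConfig()
    cfg.seed = int(seed)
    n = n_insect_species + n_nect_species
    cfg.synth.n_species = n
    cfg.synth.guild_mix = (n_nect_species / n, 0.0, n_insect_species / n, 0.0)
    data = _simulate(cfg)
    # high sampling tier everywhere: no rare species in this design
    data["community"]["abundance"] = data["community"]["abundance"].clip(lower=1.5)
    data["captures"] = synth.generate_captures(
        data["community"], data["visits"], data["rain"], cfg=cfg.synth,
        seed=np.random.SeedSequence([cfg.seed, 17]).spawn(1)[0])
    # high-tier sampling: every population abundant enough for tier >= 3
    pops = phen.population_phenology(data["captures"], data["visits"],
                                     cfg.phenology)
    pops = pops[pops["filter_tier"] >= 3]
    out = {}
    for guild in ("insectivore", "nectarivore"):
        sub = pops[pops["guild"] == guild]
        out[guild] = {"n": int(len(sub)),
                      "bimodal": int(sub["bimodal"].sum())}
    return out


def pooled_odds_ratio(counts: list[dict]) -> float:
    """Pooled insectivore-vs-nectarivore bimodality odds ratio with a
    Haldane-Anscombe 0.5 correction."""
    bi = sum(c["insectivore"]["bimodal"] for c in counts)
    ni = sum(c["insectivore"]["n"] for c in counts)
    bn = sum(c["nectarivore"]["bimodal"] for c in counts)
    nn = sum(c["nectarivore"]["n"] for c in counts)
    a, b = bi + 0.5, (ni - bi) + 0.5
    c, d = bn + 0.5, (nn - bn) + 0.5
    return float((a / b) / (c / d))
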