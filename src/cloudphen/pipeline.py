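"""End-to-end pipeline: simulate (or load) raw tables, run every analysis
stage in dependency order, and write CSV artifacts plus a summary report.

Stages: synth -> climate (normals, foraging) -> biomass -> resources ->
phenology (pooled + annual population models) -> inference (climate-window
selection, breakpoint, spatial:temporal ratio, drought response) -> sem.
Any stage can be skipped by name via ``config.skip``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomass as bio
from . import climate as cli_mod
from . import inference as inf
from . import phenology as phen
from . import resources as res
from . import sem as sem_mod
from . import synth
from .config import RunConfig, GUILDS
from ._circular import DAYS_PER_MONTH

log = logging.getLogger("cloudphen")

__all__ = ["run_pipeline", "validate_inputs", "simulate_study"]


def simulate_study(config: RunConfig):
    """Generate the full synthetic raw-data stack for one seeded study.

    Returns dict with landscapes, rain, visits, community (truth), captures,
    resources, biomass_monthly.
    """
    sc = config.synth
    ss = np.random.SeedSequence(config.seed)
    s_land, s_rain, s_comm, s_vis, s_cap, s_res = ss.spawn(6)

    landscapes = synth.generate_landscapes(
        sc.n_landscapes, sc.gradient_range, seed=s_land,
        wet_peak_doy=sc.wet_peak_doy)
    mult = 1.0 + 0.18 * np.asarray(sc.enso_preset[:sc.years])
    rain_seeds = s_rain.spawn(2 * len(landscapes))
    rain = pd.concat([
        synth.generate_rainfall(lc, sc.years, mult, seed=sub,
                                start_year=sc.start_year,
                                rain_hours_coef=sc.rain_hours_coef)
        for lc, sub in zip(landscapes, rain_seeds[:len(landscapes)])],
        ignore_index=True)
    # long-term record (regional archive analogue) for climate and biomass
    # normals: i.i.d. interannual anomalies around the same climatology
    lt_years = sc.longterm_years
    lt_frames = []
    for lc, sub in zip(landscapes, rain_seeds[len(landscapes):]):
        rng_lt = np.random.default_rng(sub)
        lt_mult = np.clip(rng_lt.normal(1.0, 0.18, lt_years), 0.3, None)
        lt_frames.append(synth.generate_rainfall(
            lc, lt_years, lt_mult, seed=sub,
            start_year=sc.start_year - lt_years,
            rain_hours_coef=sc.rain_hours_coef))
    rain_longterm = pd.concat(lt_frames, ignore_index=True)
    community = synth.generate_community(
        landscapes, sc.guild_mix, sc.psi_true, sc.offset_months,
        seed=s_comm, cfg=sc, coef=config.biomass, n_species=sc.n_species)
    visits = synth.generate_visits(landscapes, sc.years, sc.start_year,
                                   style=sc.schedule_style,
                                   gap_months=sc.gap_months, seed=s_vis)
    captures = synth.generate_captures(community, visits, rain,
                                       cfg=sc,
                                       durations=config.phenology.durations,
                                       seed=s_cap)
    resources, bm_monthly = synth.generate_resources(
        landscapes, visits, rain, seed=s_res, cfg=sc, coef=config.biomass)
    return {"landscapes": landscapes, "rain": rain,
            "rain_longterm": rain_longterm, "visits": visits,
            "community": community, "captures": captures,
            "resources": resources, "biomass_monthly": bm_monthly}


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Run every stage on a seeded synthetic study and write artifacts.

    Returns the report dict (also written as report.json / report.md).
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skip = set(config.skip)
    report: dict = {"seed": config.seed}

    log.info("stage synth: simulating study (seed=%s)", config.seed)
    data = simulate_study(config)
    rain, visits, captures = data["rain"], data["visits"], data["captures"]
    rain.to_csv(out / "rain_daily.csv", index=False)
    visits.to_csv(out / "visits.csv", index=False)
    captures.to_csv(out / "captures.csv", index=False)
    data["resources"].to_csv(out / "resources.csv", index=False)
    report["n_captures"] = len(captures)

    # climate: normals (from the long-term record) and foraging fractions
    rain_lt = data["rain_longterm"]
    normals_rows, forage = [], {}
    for lid, sub in rain_lt.groupby("landscape"):
        nm = cli_mod.compute_normals(sub)
        nm = nm.assign(landscape=lid).reset_index()
        normals_rows.append(nm)
    for lid, sub in rain.groupby("landscape"):
        forage[lid] = cli_mod.foraging_fraction(sub)
    normals = pd.concat(normals_rows, ignore_index=True)
    normals.to_csv(out / "normals.csv", index=False)

    # biomass: monthly series (long-term), normals, effective biomass
    bm = bio.monthly_series(rain_lt, config.biomass)
    bm_norm = {lid: bio.biomass_normals(sub)
               for lid, sub in bm.groupby("landscape")}
    bm = pd.concat([bio.effective_biomass(sub, forage[lid])
                    for lid, sub in bm.groupby("landscape")],
                   ignore_index=True)
    bm.to_csv(out / "biomass_monthly.csv", index=False)
    # resource floor: biomass minimum over the dry season and its tail
    dry_min = {lid: float(n.value[(n.doy >= 152) & (n.doy <= 288)].min())
               for lid, n in bm_norm.items()}
    report["biomass_dry_minima"] = dry_min

    # resources
    if "resources" not in skip:
        rc_rows, pk_rows = [], []
        for syndrome in ("flower", "fruit"):
            fits = res.fit_seasonal_abundance(data["resources"], syndrome)
            for lid, curve in fits.items():
                if not curve.converged:
                    continue
                for m, a in zip(curve.months, curve.abundance):
                    rc_rows.append({"landscape": lid, "syndrome": syndrome,
                                    "month": int(m), "abundance": float(a)})
                pk_rows.append({"landscape": lid, "syndrome": syndrome,
                                "peak_month": curve.peak_month,
                                "log_amplitude": res.resource_amplitude(curve)})
        pd.DataFrame(rc_rows).to_csv(out / "resource_curves.csv", index=False)
        peaks = pd.DataFrame(pk_rows)
        peaks.to_csv(out / "resource_peaks.csv", index=False)
        if len(peaks):
            report["resource_peaks"] = {
                s: float(np.median(g["peak_month"]))
                for s, g in peaks.groupby("syndrome")}

    # phenology: pooled and annual population models
    pops = phen.population_phenology(captures, visits, config.phenology)
    pops = pops[pops["filter_tier"] >= config.filter_tier]
    annual = phen.population_phenology(captures, visits, config.phenology,
                                       per_year=True)
    pops.to_csv(out / "populations.csv", index=False)
    annual.to_csv(out / "populations_annual.csv", index=False)
    report["n_populations"] = len(pops)
    report["n_annual_models"] = len(annual)
    report["peaks_by_guild"] = {
        g: float(np.median(s["peak_doy"].dropna()))
        for g, s in pops.groupby("guild")}

    if "inference" not in skip:
        ins = pops[pops["guild"].isin(["insectivore", "omnivore"])].dropna(
            subset=["linearized_day"]).copy()
        ins["biomass_min"] = ins["landscape"].map(dry_min)

        # climate-window model selection
        land_rain90 = {lc.landscape_id: lc.transition_dry_rain90
                       for lc in data["landscapes"]}
        land_cloud = {lc.landscape_id: lc.dry_cloud_cover
                      for lc in data["landscapes"]}
        land_ann = {lc.landscape_id: lc.annual_rain_normal
                    for lc in data["landscapes"]}
        land_elev = {lc.landscape_id: lc.elevation
                     for lc in data["landscapes"]}
        cands = {
            "transition_dry_rain90": ins["landscape"].map(land_rain90),
            "annual_rainfall": ins["landscape"].map(land_ann),
            "dry_cloud_cover": ins["landscape"].map(land_cloud),
            "elevation": ins["landscape"].map(land_elev),
        }
        msel = inf.select_climate_window(ins, cands)
        msel.to_csv(out / "model_selection.csv", index=False)
        report["top_climate_window"] = str(msel.iloc[0]["window"])
        report["top_window_weight"] = float(msel.iloc[0]["weight"])

        # breakpoint on dry-season biomass
        if len(ins) >= 8:
            bp = inf.segmented_fit(ins["biomass_min"], ins["linearized_day"])
            pd.DataFrame([{
                "psi": bp.psi, "psi_lo": bp.psi_ci[0], "psi_hi": bp.psi_ci[1],
                "left_slope": bp.left_slope, "right_slope": bp.right_slope,
                "aicc_segmented": bp.aicc_segmented,
                "aicc_linear": bp.aicc_linear, "r2": bp.r2,
                "preferred": bp.preferred, "n": bp.n_obs,
            }]).to_csv(out / "breakpoints.csv", index=False)
            report["breakpoint_psi"] = bp.psi
            report["breakpoint_preferred"] = bp.preferred

        # drought response + spatial:temporal decomposition
        anom = inf.guild_anomaly(rain, "insectivore")
        ann_ins = annual[annual["guild"].isin(["insectivore", "omnivore"])]
        dr = inf.drought_response(ann_ins, anom)
        rows = []
        for regime, d in dr.items():
            if d is None:
                continue
            rows.append({"regime": regime, **{k: str(v) for k, v in d.items()}})
            report[f"drought_{regime}"] = {
                "timing_slope_months": d["timing_slope_months"],
                "effort_pct_change_dry": d["effort_pct_change_dry"]}
        pd.DataFrame(rows).to_csv(out / "drought_response.csv", index=False)
        try:
            st = inf.spatial_temporal_ratio(ins, dr)
            report["spatial_temporal"] = st
        except ValueError as e:
            report["spatial_temporal"] = {"error": str(e)}

    if "sem" not in skip:
        ins = pops[pops["guild"].isin(["insectivore", "omnivore"])].dropna(
            subset=["linearized_day"]).copy()
        if len(ins) >= 10:
            semdat = pd.DataFrame({
                "elevation": ins["landscape"].map(
                    {lc.landscape_id: lc.elevation
                     for lc in data["landscapes"]}),
                "rain_transition_dry": ins["landscape"].map(
                    {lc.landscape_id: lc.transition_dry_rain90
                     for lc in data["landscapes"]}),
                "arthropod_biomass": ins["landscape"].map(dry_min),
                "peak_timing": ins["linearized_day"],
                "species": ins["species"],
                "landscape_id": ins["landscape"],
            })
            for c in ("elevation", "rain_transition_dry",
                      "arthropod_biomass", "peak_timing"):
                s = semdat[c]
                semdat[c] = (s - s.mean()) / (s.std(ddof=0) or 1.0)
            dag = sem_mod.dag_from_edges(sem_mod.DAG_PRESETS["insectivore"])
            pm = sem_mod.dsep_test(dag, semdat, cluster="landscape_id")
            paths = sem_mod.standardize_paths(dag, semdat,
                                              cluster="landscape_id")
            pd.DataFrame([{"x": x, "y": y, "cond": "|".join(c), "p": p}
                          for (x, y, c), p in zip(pm.claims, pm.claim_pvalues)]
                         ).to_csv(out / "sem_claims.csv", index=False)
            paths.to_csv(out / "sem_paths.csv", index=False)
            report["sem"] = {"fisher_C": pm.fisher_C, "df": pm.df,
                             "global_p": pm.global_p}

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    (out / "report.md").write_text(_report_md(report))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _report_md(report: dict) -> str:
    lines = ["# cloudphen pipeline report", ""]
    for k, v in report.items():
        lines.append(f"- **{k}**: {v}")
    lines.append("")
    return "\n".join(lines)


ALLOWED_GUILDS = set(GUILDS)
ALLOWED_PHENO = {"BR", "JUV1", "JUV2", "JUV3", "MOLT1", "MOLT2", "MOLT3",
                 "NONE"}


def validate_inputs(tables: dict) -> dict:
    """Schema and invariant checks on the raw input tables.

    `tables` maps names ('captures', 'rain_daily', 'visits', 'resources')
    to DataFrames. Returns {'errors': [...], 'warnings': [...]}.
    """
    errors, warnings_ = [], []
    if "rain_daily" in tables:
        r = tables["rain_daily"]
        for col in ("landscape", "date", "rain_mm", "daytime_rain_h",
                    "daylight_h"):
            if col not in r.columns:
                errors.append(f"rain_daily missing column {col}")
        if {"daytime_rain_h", "daylight_h"} <= set(r.columns):
            bad = r["daytime_rain_h"] > r["daylight_h"] + 1e-9
            if bad.any():
                errors.append(
                    f"rain_daily: daytime_rain_h > daylight_h on "
                    f"{int(bad.sum())} rows")
        if "rain_mm" in r.columns and (r["rain_mm"] < 0).any():
            errors.append("rain_daily: negative rain_mm")
    if "captures" in tables:
        c = tables["captures"]
        if "guild" in c.columns:
            bad = set(c["guild"].unique()) - ALLOWED_GUILDS
            if bad:
                errors.append(
                    f"captures: unknown guild(s) {sorted(bad)}; allowed: "
                    f"{sorted(ALLOWED_GUILDS)}")
        if "phenophase" in c.columns:
            bad = set(c["phenophase"].unique()) - ALLOWED_PHENO
            if bad:
                errors.append(f"captures: unknown phenophase(s) {sorted(bad)}")
    if "visits" in tables:
        v = tables["visits"]
        if {"date_start", "date_end"} <= set(v.columns):
            if (pd.to_datetime(v["date_end"])
                    < pd.to_datetime(v["date_start"])).any():
                errors.append("visits: date_end before date_start")
    if "resources" in tables:
        rs = tables["resources"]
        if "n_points" in rs.columns and (rs["n_points"] <= 0).any():
            errors.append("resources: non-positive n_points")
        if "count" in rs.columns and (rs["count"] < 0).any():
            warnings_.append("resources: negative counts coerced upstream")
    return {"errors": errors, "warnings": warnings_}
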