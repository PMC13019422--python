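"""Run configuration: every tunable parameter of the pipeline with defaults.

Configuration is plain dataclasses that round-trip losslessly through YAML.
Defaults encode the study conditions of the Andean cloud-forest system the
package models: 8 landscapes spanning a 200-450 mm transition-dry-season
rainfall gradient, rainfall peaking in March/April and bottoming in
July/August, a community of ~60 species in a 17/17/66 nectarivore /
frugivore / insectivore mix, and five field years including ENSO-style
drought anomalies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

# Rainfall-season calendar (month numbers). "Transition dry" is the run-up
# into the dry season, "transition wet" the run-out of it.
SEASONS = {
    "wet": (12, 1, 2, 3),
    "transition_dry": (4, 5),
    "dry": (6, 7, 8),
    "transition_wet": (9, 10, 11),
}

GUILDS = ("nectarivore", "frugivore", "insectivore", "omnivore")

# Linearization start dates (day-of-year) for peak-timing regressions:
# insectivores/omnivores from 1 April, frugivores from 1 October,
# nectarivores from 1 January (their season never crosses the calendar year).
GUILD_START_DOY = {
    "insectivore": 91,
    "omnivore": 91,
    "frugivore": 274,
    "nectarivore": 1,
}

# Bird-year split for annual models: chosen maximally far from every
# regime's breeding season so drought-shifted event clouds are never cut
# across years (a 1 April split would bisect a pre-dry-season population
# shifted into March).
ANNUAL_SPLIT_DOY = {
    "insectivore": 32,
    "omnivore": 32,
    "frugivore": 274,
    "nectarivore": 1,
}


@dataclass
class Durations:
    """Phenophase stage durations (days) used for backdating.

    None of these are observable from captures alone; they are life-history
    constants for small cloud-forest passerines/hummingbirds.
    """

    chick_days: float = 30.0          # incubation + nestling
    juvenile_bounds: tuple = (0.0, 90.0, 120.0, 150.0)  # JUV1..3 age-class edges post-fledge
    juvenile_weights: tuple = (0.6, 0.8, 0.8)           # wider class -> lower certainty
    molt_onset_lag: float = 30.0      # breeding event -> molt start
    molt_duration: float = 90.0
    molt_stage_bounds: tuple = (0.0, 30.0, 60.0, 90.0)  # MOLT1..3 days into molt
    molt_weights: tuple = (0.8, 0.7, 0.6)

    def juvenile_offset(self, k: int) -> float:
        """Days to backdate a JUVk capture to its breeding event (class midpoint)."""
        lo, hi = self.juvenile_bounds[k - 1], self.juvenile_bounds[k]
        return self.chick_days + (lo + hi) / 2.0

    def molt_offset(self, k: int) -> float:
        lo, hi = self.molt_stage_bounds[k - 1], self.molt_stage_bounds[k]
        return self.molt_onset_lag + (lo + hi) / 2.0


@dataclass
class BiomassCoefficients:
    """Gamma log-link rainfall -> foliage-arthropod-biomass model.

    biomass = exp(b0 + b1*r90 + b2*r90^2 + b3*min(r30, cap30)) in dry mg/m^2.
    Defaults are calibrated so that, across the default 200-450 mm gradient,
    landscape dry-season biomass minima straddle the 43 mg/m^2 threshold and
    the within-landscape seasonal amplitude is ~1.5x.
    """

    b0: float = 3.4266
    b1: float = 3.2e-3
    b2: float = -4.0e-6
    b3: float = 0.8e-3
    cap30: float = 133.0


@dataclass
class FilterTiers:
    """Minimum events / months-of-coverage per sampling-robustness tier."""

    min_events: tuple = (5, 10, 20, 40)
    min_months: tuple = (4, 6, 8, 10)

    def passes(self, n_events: float, months_covered: int, tier: int) -> bool:
        if not 1 <= tier <= 4:
            raise ValueError(f"tier must be 1..4, got {tier}")
        return (n_events >= self.min_events[tier - 1]
                and months_covered >= self.min_months[tier - 1])


@dataclass
class PhenologyConfig:
    durations: Durations = field(default_factory=Durations)
    filters: FilterTiers = field(default_factory=FilterTiers)
    basis: str = "harmonic"        # or "cyclic_spline"
    basis_df: int = 4
    min_separation_months: float = 4.0
    min_height_frac: float = 0.25
    exposure: str = "captures"     # or "net_hours"
    annual_min_captures: int = 25   # include a population-year if sampled this much
    annual_min_events: float = 6.0  # minimum events for a usable annual peak
    annual_min_months: int = 5


@dataclass
class SynthConfig:
    n_landscapes: int = 8
    gradient_range: tuple = (200.0, 450.0)
    wet_peak_doy: float = 91.0          # rainfall maximum ~1 April
    years: int = 5
    start_year: int = 2015
    longterm_years: int = 30   # regional-archive analogue for normals
    # standardized ENSO-like anomaly per calendar year (negative = drought);
    # the second year is a 2016-style strong drought
    enso_preset: tuple = (0.5, -2.0, -0.5, 2.0, 0.0)
    n_species: int = 60
    guild_mix: tuple = (0.17, 0.17, 0.66, 0.0)  # nect / frug / insect / omni
    psi_true: float = 43.0              # biomass threshold (dry mg/m^2)
    offset_months: float = 4.9          # between-regime insectivore separation
    pre_peak_doy: float = 135.0         # pre-dry-season regime peak (~15 May)
    nect_peak_doy: float = 152.0        # dry-season onset (~1 Jun)
    frug_peak_doy: float = 15.0         # wet-season centre (~15 Jan)
    peak_sd_months: float = 0.35        # per-population timing noise
    timing_slope_months: float = 1.0    # |peak shift| per SD rainfall anomaly
    # baseline P(breeding evidence) in the peak month; kept well below 1 so
    # the max-percentage effort metric has headroom in wet years (the
    # estimator saturates at 100%)
    effort_base: dict = field(default_factory=lambda: {
        "nectarivore": 0.35, "frugivore": 0.25, "insectivore": 0.20,
        "omnivore": 0.20})
    # log-effort response per SD anomaly: post-dry-season insectivores lose
    # 42% in a 1-SD drought; frugivores gain 39% in a 1-SD wet year
    effort_slope_post_insect: float = 0.5447   # -ln(0.58)
    effort_slope_frugivore: float = 0.3293     # ln(1.39)
    bimodal_prob: dict = field(default_factory=lambda: {
        "nectarivore": 0.04545, "frugivore": 0.10, "insectivore": 0.25,
        "omnivore": 0.25})
    bimodal_height: float = 0.55
    kernel_power: float = 6.0           # seasonal breeding-kernel sharpness
    juvenile_rate: float = 0.5          # juvenile catchability vs breeding adults
    molt_rate: float = 0.8
    prebreeding_molt_frac: float = 0.08  # preformative molt in first-cycle birds
    overlap_early: float = 0.26         # P(breeding characters | early molt)
    overlap_late: float = 0.02
    # per-population expected captures per visit before abundance scaling;
    # sized so per-year population models reach the coverage the temporal
    # analyses need (roughly 200 insectivore population-years per study)
    mean_captures_per_visit: float = 5.0
    schedule_style: str = "monthly"     # or "snapshot"
    gap_months: tuple = (3, 4)          # Mar/Apr landslide season, unsampled
    rain_hours_coef: float = 0.25       # daytime rain-hours ~ coef * mm^0.8
    # flower/fruit seasonal log-abundance range (per 10 points): gives a
    # 3-4x max/min ratio of log abundance
    resource_log_range: tuple = (1.0, 3.5)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "cloudphen_out"
    synth: SynthConfig = field(default_factory=SynthConfig)
    biomass: BiomassCoefficients = field(default_factory=BiomassCoefficients)
    phenology: PhenologyConfig = field(default_factory=PhenologyConfig)
    filter_tier: int = 2
    skip: tuple = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kw = {}
        for sub, typ in (("synth", SynthConfig), ("biomass", BiomassCoefficients),
                         ("phenology", PhenologyConfig)):
            if sub in d:
                kw[sub] = _from_dict(typ, d.pop(sub))
        for k in ("seed", "out_dir", "filter_tier"):
            if k in d:
                kw[k] = d.pop(k)
        if "skip" in d:
            kw["skip"] = tuple(d.pop("skip"))
        return cls(**kw)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


def _plain(obj):
    """Recursively convert tuples to lists so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _from_dict(typ, d):
    kw = {}
    for f in dataclasses.fields(typ):
        if f.name not in d:
            continue
        v = d[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in ("durations", "filters"):
            sub = {"durations": Durations, "filters": FilterTiers}[f.name]
            kw[f.name] = _from_dict(sub, v)
        elif isinstance(v, list):
            kw[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            kw[f.name] = v
    return typ(**kw)
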