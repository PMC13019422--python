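# cloudphen

Multitrophic breeding-phenology analysis for tropical montane bird
communities, with a seeded synthetic study system for end-to-end parameter
recovery.

## The problem

In low-latitude mountains, day length and temperature barely vary, and
rainfall becomes the clock that schedules reproduction across the food web.
Nectar- and fruit-eating birds track regional flowering and fruiting
seasons, but insect-eating birds (two thirds of these communities) respond
to the *local* magnitude of seasonal rainfall: where the transition into
the dry season is wet, foliage-arthropod biomass stays above the level
breeding requires and insectivores nest before the dry season; where it is
dry, the resource floor drops below a threshold and the main nesting
season flips to after the dry season — a multi-month phenological
discontinuity between nearby valleys. Estimating this from field data is
hard: breeding evidence arrives as sparse mist-net captures (brood
patches, juveniles of various ages, molt stages) collected on an uneven
visit schedule with seasonal gaps.

`cloudphen` implements the full analysis chain:

* **climate** — gap filling by the normal-ratio method, trailing 30/90-day
  rainfall accumulations, day-of-year normals, rain-limited foraging time;
* **biomass** — foliage-arthropod biomass from rainfall via a Gamma
  log-link model `B = exp(b0 + b1·r90 + b2·r90² + b3·min(r30, 133))`,
  cyclic biomass normals and their dry-season minimum (the resource
  floor), and "effective" biomass discounted by foraging time;
* **resources** — Gamma GLM seasonal abundance of bird-pollinated flowers
  and bird-dispersed fruit from point counts, with a points offset;
* **phenology** — the core method: juvenile and molt captures are
  *backdated* to the breeding events that produced them, merged with
  current breeding evidence into effort-weighted monthly event counts, and
  a cyclic (period-12) curve per species × landscape (× year) yields the
  breeding peak, secondary peaks in other seasons (bimodality), and
  reproductive effort (maximum monthly percentage of events);
* **inference** — AICc model selection over climate windows, guild models
  with cluster-robust phylogenetic/landscape structure, segmented
  (breakpoint) regression for the resource threshold ψ, the spatial :
  interannual variability decomposition, and per-regime drought responses;
* **sem** — confirmatory path analysis by d-separation: basis-set claims,
  Fisher's C = −2 Σ ln pᵢ against χ² with 2k df, and range-standardized
  path coefficients;
* **synth** — a first-class generator that plants all of the above as
  ground truth (landscapes on a 200–450 mm gradient, ENSO-style drought
  years, guild-structured communities, phenophase-coded captures with
  calibrated molt–breeding overlap), so every stage is verifiable by
  parameter recovery.

## Worked example

```python
import cloudphen
from cloudphen.config import RunConfig
from cloudphen import phenology, inference, experiments

cfg = RunConfig(seed=1)
data = cloudphen.simulate_study(cfg)          # ~43k captures, 8 landscapes
pops = phenology.population_phenology(data["captures"], data["visits"],
                                      cfg.phenology)
ins = pops[(pops.guild == "insectivore") & (pops.filter_tier >= 2)]
offset, n_pre, n_post = inference.regime_offset_months(
    ins.dropna(subset=["linearized_day"]))
print(offset, n_pre, n_post)
```

On seed 1 this prints an offset of about `4.7` months between 14 pre- and
25 post-dry-season populations — the pipeline recovering the generator's
planted 4.9-month regime separation from raw captures. The scripts in
`examples/` walk through each capability; `examples/05_drought_response.py`
prints, for the same seed,

```
pre-dry-season regime (12 populations):
  timing: +1.01 months per SD anomaly (positive = later in wetter years)
  effort change in a 1-SD drought: -15.4%
post-dry-season regime (19 populations):
  timing: -0.86 months per SD anomaly (positive = later in wetter years)
  effort change in a 1-SD drought: -45.6%
spatial offset 4.5 months vs interannual response 0.93 months -> ratio 4.9:1
```

i.e. populations nesting before the dry season breed earlier in dry years
while maintaining effort, populations nesting after it skip breeding
instead, and spatial variation dwarfs interannual variation roughly 5:1.

A thin CLI wraps the pipeline end to end:

```bash
cloudphen run-all --seed 1 --out study_out --filter-tier 2
cloudphen validate study_out
```

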