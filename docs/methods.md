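# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the limits of what the package's tests demonstrate.

## The estimation problem

A population here is one species at one landscape (optionally in one
year). Its breeding phenology must be estimated from mist-net captures in
which reproduction is observed indirectly: a brood patch or cloacal
protuberance marks *current* breeding; a juvenile of age class *k* marks a
breeding event roughly `chick_days + midpoint(class k)` days earlier; a
bird in molt stage *k* marks one `molt_onset_lag + midpoint(stage k)` days
earlier. Backdating emits one dated event per capture at the most likely
day, weighted below 1 in proportion to the age/stage-class width, so total
event mass is conserved. Default stage constants (chick 30 d; juvenile
classes 0–90–120–150 d post-fledge; molt onset lag 30 d, duration 90 d in
three 30-d stages) are life-history values for small cloud-forest
passerines and hummingbirds; none is observable from the captures
themselves and all are configurable. Early-molt birds retaining breeding
characters (the calibrated 26% overlap; 2% in late molt) count as current
breeders; first-cycle birds in preformative molt are excluded.

## Monthly event tables and exposure

Events and captures are binned by calendar month. Exposure is the number
of captures per month (net-hours optional), scaled by a per-month
*detectability* factor: an event is observable through three channels —
current evidence (needs captures that month), juveniles, and molt
(captures over the respective lag windows) — and each channel counts only
the fraction of its window falling in sampled months. This matters at the
March/April sampling gap: events there are invisible to the current
channel but well covered by backdating, so gap months with implied event
mass are retained with an imputed, detectability-scaled exposure rather
than being folded into neighbouring months (folding double-loads the
gap-adjacent month and was measured to bias May-adjacent peaks about two
weeks early). Months with no information remain missing, never zero.

## Cyclic population curves and peak extraction

Weighted monthly events are modelled as Poisson with log link on a cyclic
basis of the month with log-exposure offset, giving a non-negative
periodic rate. The default basis is a 2-order Fourier series; a cyclic
cubic spline (patsy `cc`, default 4 df) is available but with 10–12
monthly cells and a 2-month gap its unpinned edge behaviour placed peaks
at gap boundaries, whereas the Fourier fit's small biases (+3–6 d) cancel
in the regime contrasts the analysis cares about. Peaks are only admitted
on sampled support, and the curve's argmax (month resolution) is refined
by an exposure-weighted circular mean of the event dates within ±90 d of
the mode, iterated mean-shift style — an unbinned location estimate free
of month-boundary artifacts. Annual models anchor their peak to the
population's pooled multi-year peak (maximum within ±3 months) so a
secondary mode cannot masquerade as an interannual shift; annual peaks are
reported only when the year has at least 6 events, while effort is
reported for any adequately sampled year (≥ 25 captures over ≥ 5 months)
because a well-sampled year with almost no events is evidence of low
effort, not missing data.

Bimodality: a secondary local maximum ≥ 4 months (circular) from the
primary, ≥ 25% of its height, in a different rainfall season (wet
Dec–Mar, transitions Apr–May and Sep–Nov, dry Jun–Aug), and confirmed
against the raw monthly rates near both peaks — the Fourier basis can
manufacture an antipodal sidelobe of relative height `exp(-2a)` that raw
data do not support. Reproductive effort is the maximum monthly percentage
of events, reported from the smoothed curve with the raw maximum
alongside; interannual effort *changes* are measured on the
season-integrated event rate (events per capture per year), which carries
the same multiplicative signal without the upward noise bias of a max
statistic.

Peak dates enter regressions linearized as days since a guild-specific
season start (1 April insectivores/omnivores, 1 October frugivores,
1 January nectarivores; `inference.select_start_date` re-derives these by
AICc). Annual models split years at 1 February for insectivores — a
boundary chosen maximally far from both regimes' seasons, because a
1 April split bisects a drought-shifted pre-dry-season population.

## Climate and biomass

Accumulations are trailing sums (every lag in the analysis is "previous
rainfall"); normals are per-day-of-year means across years with 29
February folded into day 59; the normal-ratio gap filler scales each
reference by the ratio of long-term means over all overlapping days.
Biomass is `exp(b0 + b1 r90 + b2 r90² + b3 min(r30, 133))` in dry mg/m²,
anchored at month-end accumulations. The coefficients are configuration:
defaults (b0 = 3.4266, b1 = 3.2e-3, b2 = −4.0e-6, b3 = 8e-4) were
calibrated once against the generator's rainfall climatology so the
landscape dry-season minima span ≈ 38–48 mg/m² (straddling the 43 mg/m²
threshold) with a mean seasonal amplitude near 1.5×. Biomass normals use
the cyclic spline with ~12-month knots, year-centred log values standing
in for a year random intercept, and a circular second-difference penalty
chosen by GCV — an unpenalized spline interpolates the twelve monthly
means and oscillates freely between them, biasing the minimum low. The
"dry-season minimum" is taken over June–mid-October (the dry season and
its tail, where the trailing accumulations bottom out). Normals should be
computed from a long record; the generator supplies a 30-year analogue of
a scaled regional archive, because five ENSO-perturbed years give volatile
minima.

## Community-level inference

Breeding regimes are classified from the peak itself: before the dry
season (Apr–May), after it (Sep onward), or indeterminate (inside
Jun–Aug, excluded). The between-regime offset is the regression contrast
of linearized peaks on regime, cluster-robust by species, excluding
detected-bimodal populations (their near-equal modes can flip regimes);
optional weights implement gradient-span down-weighting for intraspecific
shifts. The resource threshold is a two-segment regression of linearized
peak on the landscape biomass floor: Muggeo-style iteration on the hinge
term plus its reparameterization gradient, a profile grid search as
fallback, an AICc comparison against the straight line (with a relative
floor on the error variance so exactly-linear data cannot win on float
noise), and ψ's CI from the gradient-term standard error.

Interannual analysis regresses within-population deviations (circular, so
a March peak never wraps around a 1 April origin) on the standardized
seasonal rainfall anomaly — Apr–Jun accumulation for insectivores,
Jan–Mar for frugivores, standardized per landscape across years. Timing
regressions are weighted by annual event counts (peak variance scales as
1/events); effort regressions use within-population demeaned log event
rates with zero-event years floored at half an event. The
spatial:temporal ratio divides the regime offset (months) by the mean
absolute interannual timing response per SD anomaly; the raw mean
absolute annual deviation is also computed (`temporal_mad_months`) but is
inflated by estimation noise and by the sub-unit mean|z| of standardized
anomalies, so the regression-based component defines the ratio.

Mixed-effect structure is approximated throughout by species-level
cluster-robust standard errors (the full crossed phylogeny × landscape
intercepts are out of scope); each fitted model records the approximation
in its metadata. The d-separation machinery uses the union-of-parents
conditioning convention, floors numerically zero p-values at 1e-12 with a
warning, and clusters by landscape when the claim involves
landscape-level variables. Its calibration (global p > 0.05 for faithful
data) is verified on linear DAG simulations; on the threshold community
the linear claims are misspecified by construction and the global test
rejects — the documented alternate DAG preset with a direct wet-season
rainfall edge mirrors the workaround used when the transition-rainfall
model fails to converge.

## The synthetic study system

Defaults encode the study conditions: 8 landscapes evenly spanning
200–450 mm transition-dry 90-day rainfall, elevations (1700–3100 m)
shuffled independently, wet peaks within ±14 d of 1 April, seasonal
wet/dry contrast varying independently of the gradient (so annual and
transition-season rainfall decouple), and dry-season cloud cover loosely
increasing along the gradient. Daily rainfall follows an asymmetric
single-cycle climatology (fast 114-d decline into a late-July trough,
slow 251-d recovery), with seasonal wet-day occurrence and Gamma wet-day
amounts calibrated so the climatological Apr–Jun accumulation matches the
landscape's gradient value; five study years carry the standardized ENSO
preset (0.5, −2, −0.5, 2, 0 — year two a strong drought) as ±18%
multipliers per unit anomaly.

The community is ~60 species (17% nectarivore, 17% frugivore, 66%
insectivore), log-series abundances, ~60% of species at more than one
landscape. Planted truths are the quantities the pipeline must recover:
insectivore regimes split at a 43 mg/m² dry-season biomass floor with a
4.9-month separation (pre-regime peak ~15 May); nectarivores at the
dry-season onset (~1 June), frugivores mid wet season (~15 January);
timing shifts of ±1 month per SD anomaly with regime-dependent sign;
log-effort responses of −ln 0.58 (post-regime insectivores, i.e. −42% per
SD drought) and ln 1.39 (frugivores, +39% per SD wet anomaly); bimodality
probabilities 0.25 (insectivores) vs 0.0455 (nectarivores), an odds ratio
of 7, with secondary peaks 6 months from the primary at 55% height; and a
2.2-month staggered hummingbird pair. Baseline peak-month breeding
probabilities (0.20 insectivore, 0.25 frugivore, 0.35 nectarivore) are
deliberately well below 1: the effort metric saturates at 100%, so the
±1.4 SD planted swings must stay on the measurable scale. Biology couples
to the realized standardized anomaly of the simulated rainfall — the same
quantity the inference module recomputes from the daily table — so
recovery regressions are free of errors-in-variables by construction.

Capture emission: per population and visit, Poisson captures proportional
to abundance; each capture shows at most one phenophase drawn from the
population's daily event intensity (a wrapped cosine-power kernel, ~±1.5
month breeding window), with juvenile and molt availabilities as trailing
means of that intensity over the corresponding age windows. The default
visit schedule is monthly with the Mar/Apr gap; the sparser multi-month
"snapshot" campaign layout is available as a preset but cannot support
per-year models at this scale. Default capture intensity yields ~40k
captures per study — denser than a typical field campaign, sized so the
annual models reach roughly 200 insectivore population-years, the
coverage the interannual analyses need.

What the generator does **not** emulate: individual movement and true
recapture histories, nest records, observer effects, species-specific
detectability, diet switching within species, and any spatial correlation
beyond the landscape label. Passing recovery tests therefore demonstrates
that the estimation chain is consistent and approximately unbiased under
the stated sampling process, not that field data of this shape are
sufficient for any particular effect size.

## Recovery experiments and problem sizes

`cloudphen.experiments` packages the validation studies used by the tests
and by `scripts/acceptance.py`: the full-community experiment (8
landscapes × 5 years, ~60 species, ≥ 40 insectivore populations past
tier 2) recovers the regime offset, threshold location, spatial:temporal
ratio, timing shift and post-regime effort response in one run; smaller
designs cover the staggered pair (2 species × 6 landscapes), the
frugivore interannual response (24 frugivore species), and bimodality
detection (36 insectivore + 18 nectarivore species at high abundance,
tier ≥ 3, pooled into one odds ratio across replicates). The acceptance
script uses 16 community replicates and 20–40 replicates of the lighter
designs — enough for cross-seed means to stabilize within a few percent —
and the test suite reruns the same experiments at 3–8 replicates.

## Known limitations

* Peak estimation inside the Mar/Apr gap rests on the backdating channel
  and the detectability approximation; a residual attenuation of order
  10–20% remains in the post-dry-season interannual timing slope (drought
  years have few events by construction).
* The segmented fit assumes a single breakpoint and Gaussian errors; with
  eight landscape values of the predictor, ψ is localized only to the gap
  between adjacent landscapes.
* Cluster-robust errors with eight landscapes are anti-conservative; the
  d-separation p-values on landscape-level claims inherit this.
* The filter-tier thresholds (5/10/20/40 events; 4/6/8/10 months) are
  package defaults, not field-derived values, and are configurable.
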