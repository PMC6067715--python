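# Methods

This note documents the modelling assumptions, the parameters that
matter, the synthetic-data design, and the numerical conventions used
throughout `cycleshift`.

## Data model and units

Distances are miles, durations minutes, speeds mph, activity volumes
marginal MET-hours per week (MMETh). A survey is a one-week diary:
persons (age, gender, ethnicity, NS-SEC, car access, region, survey
weight), trips (main mode, distance, duration, diary day, purpose) and
optionally stages. Trips below the recording threshold (default
0.1 miles; ≈ 0.0621 miles for Dutch-style data recorded from 100 m) are
rejected at validation.

Two diary conventions are reproduced in preprocessing:

* **Embedded walking.** For bus/rail trips, `pt_walk_minutes` is the
  sum of the trip's walking-stage durations. This captures nearly all
  walking inside motorised trips; the small residual that stage data
  miss is ignored.
* **Short-walk replication.** Walks under 1 mile are recorded only on
  the final diary day, so each one is replicated six additional times
  (marked by `replicate_of`, not by weighting, so trip-level outcome
  code treats replicates like any trip). The operation is idempotent.

A *current cyclist* is a person with ≥ 1 cycle or e-bike trip in the
diary week. E-bike is a first-class main mode even though English-style
diaries do not record it, because scenarios must emit e-bike trips.

## Propensity, speeds and e-bike tables

Distance bands default to [0,1), [1,2), [2,3), [3,5), [5,8), [8,12),
[12,∞) miles — fine resolution where cycling is plausible, open-ended
above. Propensity strata are age band {18–39, 40–59, 60–79} × gender;
the 80+ band is retained in the data model but excluded from uptake and
from the health burden.

`p_cycle(stratum, band)` is the survey-weighted ratio of cycled to all
trips in the band among the stratum's current cyclists (ratio of sums,
so the support-weighted stratum average reproduces the pooled estimate
exactly). Cells with fewer than 30 supporting trips (configurable) fall
back to the band's pooled estimate, avoiding noise-dominated cells.
Cycling speed per stratum is total cycled miles over total cycled hours;
e-bike speed is a configuration constant (reference-derived, never
estimated from an English-style survey). E-bike choice and propensity
tables are flat across age and gender; distances beyond the last
reference band carry the last band's values. No covariates beyond
distance band and stratum are used: a richer predictive model would be
harder to interpret and less transferable across settings.

## Scenario engine

Step 1 uses **exact quota sampling**: `round((T − b)·N)` non-cyclists
under 80 are drawn without replacement (uniformly under equity,
otherwise with probabilities proportional to stratum baseline
prevalence). A quota, rather than independent Bernoulli conversion,
makes the defining quantity of the scenario — the regular-cyclist share
— exact, and makes results deterministic given the seed. With the
default prevalences (8.4%/3.7% for men/women 18–59, 4.4%/1.6% at
60–79) a younger man is nearly twice as likely to convert as an older
man under non-equity uptake.

Step 2 draws one uniform variate per trip of each converted person.
Trips keep their distance (trip numbers and distances are fixed by
design — no induced or suppressed demand); switched trips get
`duration = distance / speed × 60` and lose their `pt_walk_minutes`
(the whole door-to-door journey becomes cycling). Existing cyclists'
diaries are never touched: the propensity function applies only to
converted persons. Replicated short walks are eligible like any trip,
each replicate drawing independently.

Scenario enumeration: 6 target levels × equity × e-bike = 24
combinations per geography; the four 5% combinations exist only where
the baseline is below 4%; at the 100% level equity no longer affects
who converts, and exactly one duplicate — (100%, equity on, e-bike on)
— is removed, giving 23 or 19 specs per geography and 206 over ten
geographies with four low-baseline regions. Removing a single duplicate
(rather than the two that full equity-collapse would suggest) follows
the published per-geography counts; which of the two equity-on
combinations is dropped is an arbitrary labelling choice with no effect
on results.

One global seed spawns per-scenario child seeds via a CRC-32 hash of
the scenario fields, so a scenario's result is independent of the order
in which scenarios are enumerated or run.

## Physical activity

Travel MMETh per week sums intensity × hours over walk trips (2.6
MMET), cycle trips (4.6), e-bike trips (3.5) and the embedded walking
of public-transport trips (2.6). Non-travel activity is fused from an
activity-survey sample by **rank-matching**: within each age-band ×
gender stratum, persons ranked by travel MMETh (seeded tie-breaks) are
assigned the matching weighted quantile (inverted CDF) of the stratum's
non-travel distribution. Rank-matching preserves both marginals and
imposes a transparent positive dependence between travel and non-travel
activity; it is a deliberate, replaceable stand-in for a richer fusion
model, and the non-travel values are computed once at baseline and held
fixed in every scenario, so scenario activity changes are purely travel
changes. Guideline thresholds are 2.5 h and 5 h per week at the
3.5-MMET moderate midpoint — 8.75 and 17.5 MMETh/week — with closed
(≥) bounds.

## Health

The dose-response curve RR(MMETh) is a configuration table with linear
interpolation between knots and a flat tail, anchored at RR(0) = 1 and
monotone non-increasing. The bundled default (plateau 0.63) is
**illustrative only** — a placeholder with the right qualitative shape;
substitute a published meta-analytic curve via CSV for substantive use.
A lookup table subsumes any published functional form and keeps the
contract testable.

PIFs are computed within geography × age-band × gender cells over
persons aged 20–79 (18–19-year-olds contribute to travel outcomes but
not to burden attribution) and applied to the cell's YLL and deaths;
aggregate percentages are burden-weighted. Impacts are computed against
a hypothetical constant state, with no time dimension or lag. Injury,
air-pollution and noise pathways, morbidity, life tables and
Monte-Carlo uncertainty are out of scope.

## Transport outcomes

Mode shares are weighted trip-count proportions (car reported split and
combined). Car miles count `car_driver` trips only — counting
passengers would double-count vehicles — though a config switch can
include passenger distance. CO₂ is exactly car miles × 0.313 kg
CO₂e/mile, so percentage CO₂ changes equal percentage car-mile changes
by construction. Journey-time deltas compare the recomputed cycling
duration with the previous self-reported duration (for public
transport, the full door-to-door time including waiting); ties count
as neither faster nor slower.

## Synthetic data

The generators are pure functions of (config, seed) and exist because
the real travel-diary and activity microdata are restricted. What they
emulate: stratum-specific cyclist prevalence (the four printed age ×
gender rates, with per-region scaling so the national baseline lands
near 4.8% and exactly four of nine regions fall below the 4% rule —
north_east 3.1% and south_west 6.1% anchor the range); Poisson trip
counts (mean 18/week); per-mode lognormal distances; duration =
distance/speed with lognormal noise (σ = 0.15) and age/gender cycling
speed factors; short walks kept only on day 7 so that replication
restores the week; bus/rail trips with embedded walking minutes.
Cyclists cycle a subset of their trips chosen by a planted logistic
distance decay p(d) = 0.8 / (1 + (d/2)²), which gives the propensity
estimator genuine structure to recover (most cyclists do not cycle all
their trips). A cyclist who draws no cycled trip has their shortest
trip forced to cycling so the flag matches the diary definition.

Stratum shares are independent marginals over age band × gender ×
ethnicity × region — a product measure, adequate because nothing in the
model consumes higher-order interactions. Non-travel activity is gamma
per stratum and independent of travel within stratum: the transparent
default absent evidence on the dependence structure. Trips-per-person
and distance parameters are placeholders chosen to be realistic for an
English-style diary, not fitted to any survey.

What passing tests on synthetic data do **not** show: agreement with
real diary marginals beyond the planted structure, realistic
correlation between travel and non-travel activity, geographic or
purpose structure in trip distances, or the magnitude of real-world
health impacts (which depend on the true dose-response curve and
burden). The tests demonstrate the engine's contracts — conservation,
partition exactness, quota exactness, statistical recovery of planted
parameters — not empirical calibration.

## Numerical conventions and problem sizes

Sampling without replacement uses numpy's Generator.choice; weighted
quantiles use the inverted-CDF definition; rank ties are broken by a
seeded shuffle. Degenerate inputs fail loudly: no current cyclists,
missing activity strata, non-covering tables and infeasible quotas all
raise typed errors. The test suite and the acceptance script run on
populations of 8,000–50,000 synthetic persons with fixed seeds — sizes
chosen so stratum cells have enough support for 3-standard-error
statistical checks while the whole suite stays fast; the acceptance
run uses 20,000 persons and a 20,000-record activity sample.

## Known limitations

* The default propensity/speed/e-bike numbers are estimated from
  synthetic data or are labelled placeholders; substantive applications
  must supply tables estimated from real diaries.
* The dose-response default is illustrative, not published evidence.
* Mean speeds are assumed accurate and unchanged by the scenario (no
  congestion feedback); mode switches are distance-based only (no
  time/cost utilities); uncertainty is not propagated (no Monte-Carlo
  layer).
* Occupational activity is outside the activity accounting; non-travel
  activity never responds to the scenario.
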