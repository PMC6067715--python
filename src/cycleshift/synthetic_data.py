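"""Seeded generators for travel surveys, activity samples and burden tables.

Restricted national travel-diary and activity-survey microdata cannot be
redistributed, so the pipeline is exercised on synthetic populations
that reproduce the statistical structure the model consumes:

* stratum-specific current-cyclist prevalence (age band x gender, with
  per-region scaling so that regional baselines straddle the 4% rule
  that governs which scenario levels exist);
* per-mode lognormal trip-distance distributions and Poisson
  trips-per-person counts;
* cyclists who cycle only a subset of their trips, chosen by a logistic
  distance-decay rule, so that the propensity estimator has genuine
  distance structure to recover;
* gamma-distributed non-travel physical activity per stratum;
* a burden-of-disease table (years of life lost and deaths by geography
  x age band x gender) built from rates and population counts.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InfeasibleConfigError, ValidationError
from .travel_data import (AGE_BANDS, GENDERS, ETHNICITIES, TravelSurvey,
                          age_to_band)

REGIONS = ("north_east", "north_west", "yorkshire", "east_midlands",
           "west_midlands", "east_of_england", "london", "south_east",
           "south_west")

#: Stratum-specific current-cyclist prevalence (age band x gender).
#: The 18-59 rates apply to both adult bands below 60; persons aged 80+
#: are never cyclists at baseline and are excluded from uptake.
DEFAULT_CYCLIST_PREVALENCE = {
    ("18-39", "male"): 0.084, ("40-59", "male"): 0.084,
    ("18-39", "female"): 0.037, ("40-59", "female"): 0.037,
    ("60-79", "male"): 0.044, ("60-79", "female"): 0.016,
    ("80+", "male"): 0.0, ("80+", "female"): 0.0,
}

#: Regional baseline cyclist prevalence targets.  The extremes (3.1% in
#: the North East, 6.1% in the South West) follow the national pattern
#: being emulated; the rest are chosen so exactly four regions fall
#: below the 4% threshold and the population-weighted national baseline
#: lands near 4.8%.
DEFAULT_REGION_BASELINE = {
    "north_east": 0.031, "north_west": 0.038, "yorkshire": 0.039,
    "east_midlands": 0.0395, "west_midlands": 0.046,
    "east_of_england": 0.055, "london": 0.048, "south_east": 0.060,
    "south_west": 0.061,
}

DEFAULT_REGION_SHARES = {
    "north_east": 0.05, "north_west": 0.13, "yorkshire": 0.10,
    "east_midlands": 0.085, "west_midlands": 0.10,
    "east_of_england": 0.11, "london": 0.16, "south_east": 0.16,
    "south_west": 0.105,
}

DEFAULT_AGE_BAND_SHARES = {"18-39": 0.36, "40-59": 0.34, "60-79": 0.25, "80+": 0.05}
DEFAULT_GENDER_SHARES = {"male": 0.49, "female": 0.51}
DEFAULT_ETHNICITY_SHARES = {"white": 0.86, "non-white": 0.14}
DEFAULT_NSSEC_LABELS = ("managerial", "intermediate", "routine", "never_worked")

#: Trip main-mode shares for the *candidate* (pre-cycling) mode draw;
#: the cycle entry is the target overall cycle share used only for the
#: feasibility check — realised cycling emerges from the decay rule.
DEFAULT_MODE_SHARE = {
    "walk": 0.245, "car_driver": 0.40, "car_passenger": 0.17,
    "bus": 0.065, "rail": 0.03, "other": 0.073, "cycle": 0.017,
}

#: (mean, sd) of log trip distance in miles, per candidate mode.
DEFAULT_DISTANCE_LOGNORMAL = {
    "walk": (-0.55, 0.75),
    "car_driver": (1.25, 1.05),
    "car_passenger": (1.25, 1.05),
    "bus": (1.0, 0.8),
    "rail": (2.1, 0.8),
    "other": (1.0, 1.0),
}

DEFAULT_SPEED_MPH = {
    "walk": 3.0, "cycle": 9.5, "ebike": 12.0, "car_driver": 24.0,
    "car_passenger": 24.0, "bus": 10.0, "rail": 24.0, "other": 18.0,
}

#: Multiplicative cycling-speed structure: younger cyclists are faster.
CYCLE_SPEED_AGE_FACTOR = {"18-39": 1.10, "40-59": 1.00, "60-79": 0.85, "80+": 0.80}
CYCLE_SPEED_GENDER_FACTOR = {"male": 1.05, "female": 0.95}


@dataclass(frozen=True)
class DistanceDecay:
    """Logistic-in-log-distance rule by which synthetic cyclists pick
    which of their trips to cycle: p(d) = pmax / (1 + (d / d50)**slope).

    ``pmax`` is the propensity for very short trips, ``d50`` the
    distance (miles) at which propensity halves relative to pmax, and
    ``slope`` controls how fast long trips are abandoned.
    """
    pmax: float = 0.8
    d50: float = 2.0
    slope: float = 2.0

    def probability(self, distance) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        return self.pmax / (1.0 + (d / self.d50) ** self.slope)


@dataclass
class PopulationConfig:
    """Configuration of the synthetic travel-survey generator.

    Stratum shares are independent marginals over age band, gender,
    ethnicity and region (their product defines the joint shares).
    """
    n_persons: int = 10_000
    seed: int = 0
    geography_label: str = "england"
    age_band_shares: dict = field(default_factory=lambda: dict(DEFAULT_AGE_BAND_SHARES))
    gender_shares: dict = field(default_factory=lambda: dict(DEFAULT_GENDER_SHARES))
    ethnicity_shares: dict = field(default_factory=lambda: dict(DEFAULT_ETHNICITY_SHARES))
    region_shares: dict = field(default_factory=lambda: dict(DEFAULT_REGION_SHARES))
    nssec_labels: tuple = DEFAULT_NSSEC_LABELS
    cyclist_prevalence_by_stratum: dict = field(
        default_factory=lambda: dict(DEFAULT_CYCLIST_PREVALENCE))
    region_prevalence_scale: dict | None = None  # default derived from baselines
    trips_per_person_mean: float = 18.0
    mode_share_by_mode: dict = field(default_factory=lambda: dict(DEFAULT_MODE_SHARE))
    distance_lognormal_params_by_mode: dict = field(
        default_factory=lambda: dict(DEFAULT_DISTANCE_LOGNORMAL))
    speed_mph_by_mode: dict = field(default_factory=lambda: dict(DEFAULT_SPEED_MPH))
    duration_noise_sd: float = 0.15
    decay: DistanceDecay = field(default_factory=DistanceDecay)
    car_access_prob: float = 0.8
    min_distance_miles: float = 0.1

    def __post_init__(self):
        if self.n_persons < 0:
            raise ValidationError("n_persons must be >= 0")
        for name, shares in (("age_band_shares", self.age_band_shares),
                             ("gender_shares", self.gender_shares),
                             ("ethnicity_shares", self.ethnicity_shares),
                             ("region_shares", self.region_shares),
                             ("mode_share_by_mode", self.mode_share_by_mode)):
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in shares.values()):
                raise ValidationError(f"{name} must be non-negative")
        for k, p in self.cyclist_prevalence_by_stratum.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"prevalence for {k} outside [0, 1]")
        if self.region_prevalence_scale is None:
            base = self.expected_prevalence_unscaled()
            if base > 0 and set(self.region_shares) <= set(DEFAULT_REGION_BASELINE):
                self.region_prevalence_scale = {
                    r: DEFAULT_REGION_BASELINE[r] / base for r in self.region_shares}
            else:
                self.region_prevalence_scale = {r: 1.0 for r in self.region_shares}
        # Feasibility: only cyclists produce cycle trips, so the overall
        # cycle mode share cannot exceed the cyclist prevalence.
        target_cycle = self.mode_share_by_mode.get("cycle", 0.0)
        attainable = self.expected_prevalence()
        if target_cycle > attainable:
            raise InfeasibleConfigError(
                f"cycle mode share {target_cycle} exceeds attainable share "
                f"given cyclist prevalence {attainable:.4f}")

    def expected_prevalence_unscaled(self) -> float:
        return sum(self.age_band_shares[a] * self.gender_shares[g]
                   * self.cyclist_prevalence_by_stratum.get((a, g), 0.0)
                   for a in self.age_band_shares for g in self.gender_shares)

    def expected_prevalence(self) -> float:
        """Population cyclist prevalence implied by the configuration."""
        scale = self.region_prevalence_scale or {r: 1.0 for r in self.region_shares}
        mean_scale = sum(self.region_shares[r] * scale.get(r, 1.0)
                         for r in self.region_shares)
        return self.expected_prevalence_unscaled() * mean_scale


def _draw_categorical(rng, shares: dict, n: int) -> np.ndarray:
    labels = list(shares)
    p = np.array([shares[k] for k in labels], dtype=float)
    return rng.choice(np.array(labels, dtype=object), size=n, p=p / p.sum())


_AGE_RANGES = {"18-39": (18, 40), "40-59": (40, 60), "60-79": (60, 80),
               "80+": (80, 95)}


def generate_population(config: PopulationConfig) -> TravelSurvey:
    """Generate a synthetic one-week travel survey.

    Persons are drawn from the configured marginals; cyclist status is
    Bernoulli per stratum prevalence (region-scaled).  Trip counts are
    Poisson (cyclists are guaranteed at least one trip); each trip draws
    a candidate mode and a per-mode lognormal distance, then cyclists'
    trips switch to ``cycle`` with the logistic distance-decay
    probability (a cyclist with no trip selected cycles their shortest
    trip, so flagged cyclists always satisfy the diary definition).
    Durations are distance / speed with multiplicative lognormal noise;
    bus and rail trips embed a short walking time.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    empty_trips = pd.DataFrame({
        "trip_id": pd.Series(dtype=str), "person_id": pd.Series(dtype=str),
        "main_mode": pd.Series(dtype=str), "distance_miles": pd.Series(dtype=float),
        "duration_min": pd.Series(dtype=float), "day_index": pd.Series(dtype=int),
        "purpose": pd.Series(dtype=str), "pt_walk_minutes": pd.Series(dtype=float),
        "replicate_of": pd.Series(dtype=object)})
    if n == 0:
        persons = pd.DataFrame({c: pd.Series(dtype=object)
                                for c in ("person_id", "gender", "ethnicity",
                                          "nssec", "region", "age_band")})
        persons["age"] = pd.Series(dtype=int)
        persons["car_access"] = pd.Series(dtype=bool)
        persons["survey_weight"] = pd.Series(dtype=float)
        return TravelSurvey(persons=persons, trips=empty_trips,
                            geography_label=config.geography_label)

    age_band = _draw_categorical(rng, config.age_band_shares, n)
    lo = np.array([_AGE_RANGES[b][0] for b in age_band])
    hi = np.array([_AGE_RANGES[b][1] for b in age_band])
    age = rng.integers(lo, hi)
    gender = _draw_categorical(rng, config.gender_shares, n)
    ethnicity = _draw_categorical(rng, config.ethnicity_shares, n)
    region = _draw_categorical(rng, config.region_shares, n)
    nssec = rng.choice(np.array(config.nssec_labels, dtype=object), size=n)

    persons = pd.DataFrame({
        "person_id": [f"p{i:06d}" for i in range(n)],
        "age": age, "age_band": age_band, "gender": gender,
        "ethnicity": ethnicity, "nssec": nssec,
        "car_access": rng.random(n) < config.car_access_prob,
        "region": region, "survey_weight": 1.0,
    })

    scale = config.region_prevalence_scale
    prev = np.array([config.cyclist_prevalence_by_stratum.get((a, g), 0.0)
                     * scale.get(r, 1.0)
                     for a, g, r in zip(age_band, gender, region)])
    is_cyclist = rng.random(n) < np.clip(prev, 0.0, 1.0)

    counts = rng.poisson(config.trips_per_person_mean, size=n)
    counts = np.where(is_cyclist, np.maximum(counts, 1), counts)

    person_idx = np.repeat(np.arange(n), counts)
    m = len(person_idx)
    if m == 0:
        return TravelSurvey(persons=persons, trips=empty_trips,
                            geography_label=config.geography_label)

    candidate_shares = {k: v for k, v in config.mode_share_by_mode.items()
                        if k not in ("cycle", "ebike")}
    tot = sum(candidate_shares.values())
    candidate_shares = {k: v / tot for k, v in candidate_shares.items()}
    mode = _draw_categorical(rng, candidate_shares, m)

    mu = np.array([config.distance_lognormal_params_by_mode[mo][0] for mo in mode])
    sd = np.array([config.distance_lognormal_params_by_mode[mo][1] for mo in mode])
    distance = np.exp(rng.normal(mu, sd))
    distance = np.maximum(distance, config.min_distance_miles)

    # Cyclists switch trips per the distance-decay rule.
    trip_is_cyclist = is_cyclist[person_idx]
    p_cyc = config.decay.probability(distance)
    cycled = trip_is_cyclist & (rng.random(m) < p_cyc)
    # Guarantee every flagged cyclist cycles at least one trip: force the
    # shortest trip of each cyclist who drew none.
    df = pd.DataFrame({"pidx": person_idx, "distance": distance, "cycled": cycled})
    has_cycle = df.groupby("pidx")["cycled"].any()
    need = has_cycle.index[(~has_cycle) & is_cyclist[has_cycle.index]]
    if len(need):
        shortest = (df.loc[df["pidx"].isin(need)]
                    .sort_values("distance").groupby("pidx").head(1).index)
        cycled[shortest.to_numpy()] = True
    mode = np.where(cycled, "cycle", mode)

    base_speed = np.array([config.speed_mph_by_mode[mo] for mo in mode])
    cyc_factor = np.array([CYCLE_SPEED_AGE_FACTOR[b] * CYCLE_SPEED_GENDER_FACTOR[g]
                           for b, g in zip(age_band[person_idx], gender[person_idx])])
    speed = np.where(mode == "cycle", base_speed * cyc_factor, base_speed)
    duration = distance / speed * 60.0 * np.exp(
        rng.normal(0.0, config.duration_noise_sd, size=m))
    duration = np.maximum(duration, 1.0)

    day = rng.integers(1, 8, size=m)
    # Diary convention: short walks go unrecorded except on the final
    # day, so the generated week keeps only day-7 short walks (the
    # preprocessing step later replicates them six additional times to
    # restore a full week of walking).
    short_walk = (mode == "walk") & (distance < 1.0)
    keep = ~short_walk | (day == 7)
    person_idx, mode, distance, duration, day = (
        a[keep] for a in (person_idx, mode, distance, duration, day))
    m = len(person_idx)

    is_pt = np.isin(mode, ("bus", "rail"))
    ptw = np.where(is_pt,
                   np.minimum(rng.uniform(2.0, 15.0, size=m), 0.4 * duration), 0.0)

    purpose = rng.choice(np.array(["commute", "shopping", "leisure", "personal"],
                                  dtype=object), size=m)

    trips = pd.DataFrame({
        "trip_id": [f"t{i:07d}" for i in range(m)],
        "person_id": persons["person_id"].to_numpy()[person_idx],
        "main_mode": mode,
        "distance_miles": distance,
        "duration_min": duration,
        "day_index": day,
        "purpose": purpose,
        "pt_walk_minutes": ptw,
        "replicate_of": pd.Series([pd.NA] * m, dtype="object"),
    })
    return TravelSurvey(persons=persons, trips=trips,
                        geography_label=config.geography_label)


DEFAULT_GAMMA_PARAMS = {
    (a, g): (1.3, 8.0) for a in AGE_BANDS for g in GENDERS
}
DEFAULT_GAMMA_PARAMS.update({
    ("60-79", "male"): (1.1, 6.0), ("60-79", "female"): (1.1, 5.0),
    ("80+", "male"): (0.9, 4.0), ("80+", "female"): (0.9, 3.5),
})


def generate_activity_survey(n: int, gamma_params_by_stratum=None,
                             seed: int = 0) -> pd.DataFrame:
    """Generate a non-travel physical-activity sample.

    Returns a DataFrame (age_band, gender, nontravel_mmeth, weight) with
    gamma-distributed weekly non-travel marginal MET-hours per stratum.
    """
    params = gamma_params_by_stratum or DEFAULT_GAMMA_PARAMS
    for k, (shape, scl) in params.items():
        if shape <= 0 or scl <= 0:
            raise ValidationError(f"gamma shape/scale must be > 0 for {k}")
    rng = np.random.default_rng(seed)
    strata = list(params)
    idx = rng.integers(0, len(strata), size=n)
    shape = np.array([params[strata[i]][0] for i in idx])
    scl = np.array([params[strata[i]][1] for i in idx])
    values = rng.gamma(shape, scl) if n else np.array([])
    return pd.DataFrame({
        "age_band": [strata[i][0] for i in idx],
        "gender": [strata[i][1] for i in idx],
        "nontravel_mmeth": values,
        "weight": 1.0,
    })


#: Illustrative all-cause-mortality YLL rates per 100,000 by age band and
#: gender (synthetic stand-in for a burden-of-disease extract).
DEFAULT_YLL_RATE_PER_100K = {
    ("20-39", "male"): 1_800.0, ("20-39", "female"): 1_000.0,
    ("40-59", "male"): 5_200.0, ("40-59", "female"): 3_300.0,
    ("60-79", "male"): 16_000.0, ("60-79", "female"): 11_000.0,
}
DEFAULT_DEATH_RATE_PER_100K = {
    ("20-39", "male"): 110.0, ("20-39", "female"): 55.0,
    ("40-59", "male"): 430.0, ("40-59", "female"): 280.0,
    ("60-79", "male"): 2_400.0, ("60-79", "female"): 1_600.0,
}


def generate_burden_table(geographies, yll_per_100k_by_stratum=None,
                          populations_by_stratum=None,
                          deaths_per_100k_by_stratum=None) -> pd.DataFrame:
    """Build an absolute burden table from rates and population counts.

    absolute YLL = rate x population / 1e5 per (geography, age band,
    gender) stratum; deaths handled identically.
    """
    yll_rates = yll_per_100k_by_stratum or DEFAULT_YLL_RATE_PER_100K
    death_rates = deaths_per_100k_by_stratum or DEFAULT_DEATH_RATE_PER_100K
    if populations_by_stratum is None:
        populations_by_stratum = {k: 1_000_000.0 for k in yll_rates}
    rows = []
    for geo in geographies:
        for (band, gender), rate in yll_rates.items():
            pop = populations_by_stratum.get((band, gender), 0.0)
            drate = death_rates.get((band, gender), 0.0)
            if rate < 0 or pop < 0 or drate < 0:
                raise ValidationError("burden rates and populations must be >= 0")
            rows.append({"geography": geo, "age_band": band, "gender": gender,
                         "yll": rate * pop / 1e5, "deaths": drate * pop / 1e5})
    return pd.DataFrame(rows)


DEFAULT_EBIKE_OWN_BOTH_SHARE = 0.53  # e-bike owners who also own a pedal bike


def default_ebike_reference(bands=None):
    """Placeholder Dutch-style e-bike tables (flatter distance decay,
    e-bike preferred for longer trips; pedal bike kept for short ones,
    as roughly half of e-bike owners also own a traditional bike)."""
    from .propensity import make_bands
    bands = bands if bands is not None else make_bands()
    k = len(bands)
    mid = np.array([(b.lower + (b.upper if np.isfinite(b.upper) else b.lower + 8))
                    / 2 for b in bands])
    propensity = 0.75 / (1.0 + (mid / 5.0) ** 1.2)   # flatter than pedal decay
    choice = 1.0 - DEFAULT_EBIKE_OWN_BOTH_SHARE * np.exp(-mid / 4.0)
    return {"choice_prob_by_band": np.clip(choice, 0, 1),
            "ebike_propensity_by_band": np.clip(propensity, 0, 1),
            "bands": bands}
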