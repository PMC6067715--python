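"""Two-step cycling-uptake scenario engine.

Step 1 converts non-cyclists into *regular cyclists* until the target
share of the population cycles regularly.  The number converted is the
difference between the target and the baseline prevalence (e.g. a 25%
target on a 4.8% baseline converts 20.2 percentage points of the
population).  Conversion is exact quota sampling without replacement:
under an *equity* scenario every eligible non-cyclist (aged under 80)
is equally likely to be picked; otherwise sampling probabilities are
proportional to the baseline cyclist prevalence of the person's
age-band x gender stratum, so uptake perpetuates current demographic
differences.

Step 2 runs over every trip of every converted person and switches it
to cycling with the distance-band propensity of current cyclists (or,
in e-bike scenarios, with the e-bike owners' propensity, then splits
e-bike vs pedal bike by the band's choice probability).  Switched trips
keep their distance, get their duration recomputed from the stratum's
cycling speed and lose any embedded public-transport walking time.

After Step 2 the population partitions into four groups: existing
cyclists (cycled at baseline), new cyclists (converted and switched at
least one trip), regular cyclists (converted but switched none this
week), and non-cyclists.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, InfeasibleConfigError, ValidationError
from .propensity import EbikeTables, PropensityTable, SpeedTable, assign_band
from .travel_data import TravelSurvey, classify_current_cyclists

logger = logging.getLogger(__name__)

TARGET_LEVELS = (5, 10, 25, 50, 75, 100)
#: The 5% level only exists where the baseline prevalence is below 4%.
FIVE_PCT_BASELINE_CUTOFF = 0.04
#: Persons aged 80+ are never converted.
MAX_UPTAKE_AGE = 80

GROUP_EXISTING = "existing_cyclist"
GROUP_REGULAR = "regular_cyclist"
GROUP_NEW = "new_cyclist"
GROUP_NON = "non_cyclist"


def conversion_increment_pct(target_pct: float, baseline_prevalence: float) -> float:
    """Percentage points of the population converted in Step 1.

    E.g. target 25% on a 4.8% baseline gives 25 - 4.8 = 20.2.
    """
    return target_pct - 100.0 * baseline_prevalence


@dataclass(frozen=True)
class ScenarioSpec:
    """The three scenario parameters plus geography and seed."""
    geography: str
    target_pct: int
    equity: bool
    ebike: bool
    seed: int = 0

    def __post_init__(self):
        if self.target_pct not in TARGET_LEVELS:
            raise ValidationError(
                f"target_pct must be one of {TARGET_LEVELS}, got {self.target_pct}")

    @property
    def scenario_id(self) -> str:
        eq = "eq1" if self.equity else "eq0"
        eb = "eb1" if self.ebike else "eb0"
        return f"{self.geography}_{self.target_pct}_{eq}_{eb}"


def scenario_seed(global_seed: int, spec: ScenarioSpec) -> int:
    """Stable per-scenario child seed (independent of enumeration order)."""
    key = f"{spec.geography}|{spec.target_pct}|{int(spec.equity)}|{int(spec.ebike)}"
    return (int(global_seed) ^ zlib.crc32(key.encode())) & 0x7FFFFFFF


@dataclass
class ScenarioResult:
    """A mutated survey plus the four-group person classification."""
    survey: TravelSurvey
    group_by_person: pd.Series  # person_id -> group label
    spec: ScenarioSpec
    baseline_prevalence: float

    def group_ids(self, group: str) -> set:
        return set(self.group_by_person.index[self.group_by_person == group])


def select_regular_cyclists(survey: TravelSurvey, spec: ScenarioSpec,
                            baseline_prevalence: float,
                            stratum_prevalence: pd.Series | None = None,
                            rng: np.random.Generator | None = None) -> set:
    """Step 1: quota-sample the non-cyclists who become regular cyclists.

    Returns a set of person_ids of size
    ``round((target_pct/100 - baseline) * n_adults)`` drawn without
    replacement from non-cyclists aged under 80.  ``equity`` draws
    uniformly; otherwise draw probabilities are proportional to the
    baseline cyclist prevalence of each person's age-band x gender
    stratum (supplied or estimated from the survey).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    persons = survey.persons
    cyclists = classify_current_cyclists(survey)
    n_adults = len(persons)
    n_convert = int(round((spec.target_pct / 100.0 - baseline_prevalence) * n_adults))
    if n_convert <= 0:
        logger.warning("target %s%% at or below baseline %.1f%%: nobody converted",
                       spec.target_pct, 100 * baseline_prevalence)
        return set()

    eligible = persons.loc[(~persons["person_id"].isin(cyclists))
                           & (persons["age"] < MAX_UPTAKE_AGE)]
    if n_convert > len(eligible):
        raise InfeasibleConfigError(
            f"need {n_convert} converts but only {len(eligible)} eligible "
            f"non-cyclists under {MAX_UPTAKE_AGE}")

    if spec.equity:
        p = None
    else:
        if stratum_prevalence is None:
            from .travel_data import stratum_prevalences
            stratum_prevalence = stratum_prevalences(survey)
        key = pd.MultiIndex.from_arrays([eligible["age_band"], eligible["gender"]])
        w = stratum_prevalence.reindex(key).to_numpy(dtype=float)
        w = np.nan_to_num(w, nan=0.0)
        if w.sum() <= 0:
            raise InfeasibleConfigError(
                "all eligible non-cyclists have zero stratum prevalence weight")
        p = w / w.sum()
        if (p > 0).sum() < n_convert:
            raise InfeasibleConfigError(
                "not enough eligible persons with positive uptake weight")

    chosen = rng.choice(eligible["person_id"].to_numpy(), size=n_convert,
                        replace=False, p=p)
    return set(chosen.tolist())


def switch_trips(survey: TravelSurvey, regular_ids: set,
                 propensity: PropensityTable, ebike_tables: EbikeTables | None,
                 speeds: SpeedTable, spec: ScenarioSpec,
                 rng: np.random.Generator | None = None) -> ScenarioResult:
    """Step 2: probabilistically switch converted persons' trips to cycling.

    Only trips of converted (regular) cyclists are touched; existing
    cyclists and non-cyclists keep their diaries unchanged.  Distances
    never change; switched trips get ``duration = distance / speed * 60``
    and ``pt_walk_minutes = 0``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if spec.ebike and ebike_tables is None:
        raise CoverageError("e-bike scenario requires e-bike tables")

    out = survey.copy()
    persons = out.persons.set_index("person_id")
    trips = out.trips
    baseline_cyclists = classify_current_cyclists(survey)

    mask = trips["person_id"].isin(regular_ids).to_numpy()
    idx = np.flatnonzero(mask)
    switched_mode = np.full(len(idx), "", dtype=object)

    if len(idx):
        sub = trips.iloc[idx]
        band_idx = assign_band(sub["distance_miles"].to_numpy(), propensity.bands)
        age_band = persons.loc[sub["person_id"], "age_band"].to_numpy()
        gender = persons.loc[sub["person_id"], "gender"].to_numpy()

        if spec.ebike:
            choice_p, prop_p = ebike_tables.lookup(band_idx)
            cycled = rng.random(len(idx)) < prop_p
            use_ebike = rng.random(len(idx)) < choice_p
            switched_mode[cycled & use_ebike] = "ebike"
            switched_mode[cycled & ~use_ebike] = "cycle"
        else:
            p = propensity.lookup(age_band, gender, band_idx)
            cycled = rng.random(len(idx)) < p
            switched_mode[cycled] = "cycle"

        sw = switched_mode != ""
        if sw.any():
            sw_idx = idx[sw]
            new_mode = switched_mode[sw]
            speed = speeds.lookup(age_band[sw], gender[sw], new_mode)
            new_dur = sub["distance_miles"].to_numpy()[sw] / speed * 60.0
            col = {c: trips.columns.get_loc(c)
                   for c in ("main_mode", "duration_min", "pt_walk_minutes")}
            trips.iloc[sw_idx, col["main_mode"]] = new_mode
            trips.iloc[sw_idx, col["duration_min"]] = new_dur
            trips.iloc[sw_idx, col["pt_walk_minutes"]] = 0.0

    switchers = set(trips.iloc[idx].loc[np.asarray(switched_mode) != "",
                                        "person_id"].unique()) if len(idx) else set()

    pid = survey.persons["person_id"]
    group = np.where(pid.isin(baseline_cyclists), GROUP_EXISTING,
                     np.where(pid.isin(switchers), GROUP_NEW,
                              np.where(pid.isin(regular_ids), GROUP_REGULAR,
                                       GROUP_NON)))
    group_by_person = pd.Series(group, index=pid.to_numpy(), name="group")

    from .travel_data import cyclist_prevalence
    baseline_prev = cyclist_prevalence(survey)
    logger.info("scenario %s: %d converted, %d switched >=1 trip",
                spec.scenario_id, len(regular_ids), len(switchers))
    return ScenarioResult(survey=out, group_by_person=group_by_person,
                          spec=spec, baseline_prevalence=baseline_prev)


def run_scenario(survey: TravelSurvey, spec: ScenarioSpec,
                 propensity: PropensityTable, speeds: SpeedTable,
                 ebike_tables: EbikeTables | None = None,
                 baseline_prevalence: float | None = None,
                 stratum_prevalence: pd.Series | None = None) -> ScenarioResult:
    """Run Steps 1 and 2 for one scenario (single deterministic seed)."""
    from .travel_data import cyclist_prevalence
    if baseline_prevalence is None:
        baseline_prevalence = cyclist_prevalence(survey)
    rng = np.random.default_rng(spec.seed)
    regular = select_regular_cyclists(survey, spec, baseline_prevalence,
                                      stratum_prevalence=stratum_prevalence, rng=rng)
    return switch_trips(survey, regular, propensity, ebike_tables, speeds,
                        spec, rng=rng)


def enumerate_scenarios(geographies_with_baselines: dict,
                        global_seed: int = 0) -> list[ScenarioSpec]:
    """All scenario specs per geography, with the published counting.

    Each geography starts from 6 levels x equity on/off x e-bike on/off
    = 24 combinations.  Where the baseline prevalence is 4% or above,
    the four 5% combinations are dropped.  At the 100% level equity no
    longer changes who is converted, so one duplicate — (100%, equity
    on, e-bike on) — is removed, leaving 23 (or 19) specs per
    geography.  Ten geographies of which four are low-baseline thus
    yield 6*19 + 4*23 = 206 scenarios.
    """
    specs = []
    for geo, baseline in geographies_with_baselines.items():
        for level in TARGET_LEVELS:
            if level == 5 and baseline >= FIVE_PCT_BASELINE_CUTOFF:
                continue
            for equity in (False, True):
                for ebike in (False, True):
                    if level == 100 and equity and ebike:
                        continue
                    spec = ScenarioSpec(geography=geo, target_pct=level,
                                        equity=equity, ebike=ebike)
                    specs.append(ScenarioSpec(
                        geography=geo, target_pct=level, equity=equity,
                        ebike=ebike, seed=scenario_seed(global_seed, spec)))
    return specs


def raw_combinations(geography: str = "any") -> list[tuple]:
    """The 24 level x equity x e-bike combinations before exclusions."""
    return [(geography, level, eq, eb)
            for level in TARGET_LEVELS
            for eq in (False, True)
            for eb in (False, True)]
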