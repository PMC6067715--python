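"""Travel-survey data model, CSV I/O and diary preprocessing.

The package works on one-week individual travel diaries: a ``persons``
table (demographics, car access, survey weight), a ``trips`` table
(main mode, distance in miles, duration in minutes, diary day) and an
optional ``stages`` table giving the mode-specific legs of each trip.
Tables are plain :class:`pandas.DataFrame` objects bundled in a
:class:`TravelSurvey`; all operations are vectorised.

Two diary conventions of the English survey tradition are implemented
here: walking minutes embedded in public-transport trips are recovered
from stage data, and short walking trips — recorded only on the final
diary day — are replicated six additional times so that a full week of
walking is represented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

AGE_BANDS = ("18-39", "40-59", "60-79", "80+")
GENDERS = ("male", "female")
ETHNICITIES = ("white", "non-white")
MODES = ("walk", "cycle", "ebike", "car_driver", "car_passenger", "bus", "rail", "other")
PT_MODES = ("bus", "rail")
CYCLE_MODES = ("cycle", "ebike")
CAR_MODES = ("car_driver", "car_passenger")

#: Minimum recorded trip distance in miles (English diary convention;
#: use 0.0621 ≈ 100 m for Dutch-style data).
DEFAULT_MIN_DISTANCE_MILES = 0.1
#: Walks shorter than this (miles) are recorded on the final diary day only.
DEFAULT_SHORT_WALK_MILES = 1.0
#: Final day of the one-week diary.
DEFAULT_FINAL_DAY = 7
#: Slack (minutes) allowed when stage durations are checked against the trip.
STAGE_DURATION_TOLERANCE_MIN = 1.0

PERSON_COLUMNS = ("person_id", "age", "gender", "ethnicity", "nssec",
                  "car_access", "region", "survey_weight")
TRIP_COLUMNS = ("trip_id", "person_id", "main_mode", "distance_miles",
                "duration_min", "day_index", "purpose")
TRIP_OPTIONAL_COLUMNS = ("pt_walk_minutes", "replicate_of")
STAGE_COLUMNS = ("stage_id", "trip_id", "mode", "duration_min")


def age_to_band(age) -> pd.Series:
    """Map integer ages (>=18) to the four adult age bands."""
    age = pd.Series(np.asarray(age))
    return pd.cut(age, bins=[18, 40, 60, 80, np.inf], labels=AGE_BANDS,
                  right=False, include_lowest=True).astype(str)


@dataclass
class TravelSurvey:
    """A validated one-week travel diary: persons + trips (+ stages).

    Attributes
    ----------
    persons, trips, stages
        The survey tables.  ``persons`` additionally carries a derived
        ``age_band`` column.  ``stages`` may be ``None``.
    geography_label
        Name of the geography the survey represents (a region name or
        an umbrella label such as ``"england"``).
    """

    persons: pd.DataFrame
    trips: pd.DataFrame
    stages: pd.DataFrame | None = None
    geography_label: str = "all"

    def copy(self) -> "TravelSurvey":
        return replace(
            self,
            persons=self.persons.copy(),
            trips=self.trips.copy(),
            stages=None if self.stages is None else self.stages.copy(),
        )

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_trips(self) -> int:
        return len(self.trips)


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing mandatory column(s): "
                          + ", ".join(missing))


def validate_survey(survey: TravelSurvey,
                    min_distance_miles: float = DEFAULT_MIN_DISTANCE_MILES) -> TravelSurvey:
    """Check all type and referential invariants; raise on violation.

    Returns the survey unchanged on success so calls can be chained.
    """
    persons, trips, stages = survey.persons, survey.trips, survey.stages

    _require_columns(persons, PERSON_COLUMNS, "persons")
    _require_columns(trips, TRIP_COLUMNS, "trips")

    if persons["person_id"].duplicated().any():
        dupes = persons.loc[persons["person_id"].duplicated(), "person_id"].tolist()
        raise IntegrityError(f"duplicate person_id(s): {dupes[:10]}")
    if trips["trip_id"].duplicated().any():
        dupes = trips.loc[trips["trip_id"].duplicated(), "trip_id"].tolist()
        raise IntegrityError(f"duplicate trip_id(s): {dupes[:10]}")

    orphans = trips.loc[~trips["person_id"].isin(persons["person_id"]), "trip_id"]
    if len(orphans):
        raise IntegrityError("trips reference unknown person_id; trip_ids: "
                             + ", ".join(map(str, orphans.tolist()[:10])))

    if (persons["age"] < 18).any():
        bad = persons.loc[persons["age"] < 18, "person_id"].tolist()
        raise ValidationError(f"persons under 18 not allowed: {bad[:10]}")
    if "age_band" in persons.columns:
        expected = age_to_band(persons["age"].to_numpy())
        mismatch = persons.loc[persons["age_band"].to_numpy() != expected.to_numpy(),
                               "person_id"]
        if len(mismatch):
            raise ValidationError("age_band inconsistent with age for person_id(s): "
                                  + ", ".join(map(str, mismatch.tolist()[:10])))
    if (persons["survey_weight"] < 0).any():
        raise ValidationError("survey_weight must be >= 0")
    bad_gender = set(persons["gender"].unique()) - set(GENDERS)
    if bad_gender:
        raise ValidationError(f"unknown gender label(s): {sorted(bad_gender)}")

    bad_mode = set(trips["main_mode"].unique()) - set(MODES)
    if bad_mode:
        raise ValidationError(f"unknown main_mode label(s): {sorted(bad_mode)}")
    if (trips["distance_miles"] < min_distance_miles - 1e-12).any():
        bad = trips.loc[trips["distance_miles"] < min_distance_miles - 1e-12,
                        "trip_id"].tolist()
        raise ValidationError(
            f"trip distance below recording threshold {min_distance_miles} mi: {bad[:10]}")
    if (trips["duration_min"] <= 0).any():
        bad = trips.loc[trips["duration_min"] <= 0, "trip_id"].tolist()
        raise ValidationError(f"non-positive trip duration: {bad[:10]}")
    if (~trips["day_index"].isin(range(1, 8))).any():
        raise ValidationError("day_index must be in 1..7")

    if "pt_walk_minutes" in trips.columns:
        ptw = trips["pt_walk_minutes"].fillna(0.0)
        if (ptw < 0).any():
            raise ValidationError("pt_walk_minutes must be >= 0")
        if (ptw > trips["duration_min"] + 1e-9).any():
            bad = trips.loc[ptw > trips["duration_min"] + 1e-9, "trip_id"].tolist()
            raise ValidationError(f"pt_walk_minutes exceeds trip duration: {bad[:10]}")
        non_pt = ~trips["main_mode"].isin(PT_MODES)
        if (ptw[non_pt] > 0).any():
            bad = trips.loc[non_pt & (ptw > 0), "trip_id"].tolist()
            raise ValidationError(
                f"pt_walk_minutes > 0 on non-public-transport trips: {bad[:10]}")

    if stages is not None:
        _require_columns(stages, STAGE_COLUMNS, "stages")
        orphan_stages = stages.loc[~stages["trip_id"].isin(trips["trip_id"]), "stage_id"]
        if len(orphan_stages):
            raise IntegrityError("stages reference unknown trip_id; stage_ids: "
                                 + ", ".join(map(str, orphan_stages.tolist()[:10])))
        if (stages["duration_min"] <= 0).any():
            raise ValidationError("non-positive stage duration")
        stage_sum = stages.groupby("trip_id")["duration_min"].sum()
        trip_dur = trips.set_index("trip_id")["duration_min"]
        over = stage_sum[stage_sum > trip_dur.reindex(stage_sum.index)
                         + STAGE_DURATION_TOLERANCE_MIN]
        if len(over):
            raise ValidationError("stage durations exceed trip duration for trip_id(s): "
                                  + ", ".join(map(str, over.index.tolist()[:10])))
    return survey


def _normalise_trips(trips: pd.DataFrame) -> pd.DataFrame:
    trips = trips.copy()
    if "pt_walk_minutes" not in trips.columns:
        trips["pt_walk_minutes"] = 0.0
    trips["pt_walk_minutes"] = trips["pt_walk_minutes"].fillna(0.0).astype(float)
    if "replicate_of" not in trips.columns:
        trips["replicate_of"] = pd.Series([pd.NA] * len(trips), dtype="object")
    else:
        trips["replicate_of"] = (trips["replicate_of"].astype(object)
                                 .where(trips["replicate_of"].notna(), pd.NA))
    return trips


def read_survey(person_path, trip_path, stage_path=None,
                geography_label: str = "all",
                min_distance_miles: float = DEFAULT_MIN_DISTANCE_MILES) -> TravelSurvey:
    """Read persons/trips(/stages) CSV files and return a validated survey.

    CSV schemas (UTF-8, header row, "." decimal point):

    * persons.csv: person_id, age, gender, ethnicity, nssec, car_access,
      region, survey_weight
    * trips.csv: trip_id, person_id, main_mode, distance_miles,
      duration_min, day_index, purpose [, pt_walk_minutes, replicate_of]
    * stages.csv: stage_id, trip_id, mode, duration_min
    """
    persons = pd.read_csv(person_path, dtype={"person_id": str})
    _require_columns(persons, PERSON_COLUMNS, "persons")
    persons["car_access"] = persons["car_access"].astype(bool)
    persons["survey_weight"] = persons["survey_weight"].astype(float)
    persons["age"] = persons["age"].astype(int)
    persons["age_band"] = age_to_band(persons["age"].to_numpy()).to_numpy()

    trips = pd.read_csv(trip_path, dtype={"trip_id": str, "person_id": str,
                                          "replicate_of": str})
    _require_columns(trips, TRIP_COLUMNS, "trips")
    trips = _normalise_trips(trips)

    stages = None
    if stage_path is not None:
        stages = pd.read_csv(stage_path, dtype={"stage_id": str, "trip_id": str})
        _require_columns(stages, STAGE_COLUMNS, "stages")

    survey = TravelSurvey(persons=persons, trips=trips, stages=stages,
                          geography_label=geography_label)
    return validate_survey(survey, min_distance_miles=min_distance_miles)


def write_survey(survey: TravelSurvey, person_path, trip_path,
                 stage_path=None) -> None:
    """Write a survey back to the documented CSV schema (round-trip safe)."""
    survey.persons.loc[:, list(PERSON_COLUMNS)].to_csv(person_path, index=False)
    trip_cols = list(TRIP_COLUMNS) + [c for c in TRIP_OPTIONAL_COLUMNS
                                      if c in survey.trips.columns]
    survey.trips.loc[:, trip_cols].to_csv(trip_path, index=False)
    if stage_path is not None and survey.stages is not None:
        survey.stages.loc[:, list(STAGE_COLUMNS)].to_csv(stage_path, index=False)


def derive_pt_walk_minutes(survey: TravelSurvey) -> TravelSurvey:
    """Set ``pt_walk_minutes`` from walking stages of bus/rail trips.

    For every trip whose main mode is public transport, the embedded
    walking time is the sum of its walking-stage durations; every other
    trip gets 0.  If the survey carries no stage table this is a no-op
    (a warning is logged and loaded values are kept).
    """
    if survey.stages is None:
        logger.warning("derive_pt_walk_minutes: no stage table; "
                       "pt_walk_minutes left as loaded")
        return survey
    out = survey.copy()
    walk_stage_sum = (survey.stages.loc[survey.stages["mode"] == "walk"]
                      .groupby("trip_id")["duration_min"].sum())
    is_pt = out.trips["main_mode"].isin(PT_MODES)
    ptw = out.trips["trip_id"].map(walk_stage_sum).fillna(0.0)
    out.trips["pt_walk_minutes"] = np.where(is_pt, ptw, 0.0)
    return out


def replicate_short_walks(survey: TravelSurvey,
                          short_walk_threshold: float = DEFAULT_SHORT_WALK_MILES,
                          final_day: int = DEFAULT_FINAL_DAY) -> TravelSurvey:
    """Replicate final-day short walks six additional times.

    Short walks (< ``short_walk_threshold`` miles) are only recorded on
    the last diary day, so each one stands for a whole week of such
    walks: six copies are added (marked via ``replicate_of``), giving
    seven in total.  Idempotent: a survey that already contains
    replicates is returned unchanged.
    """
    out = survey.copy()
    trips = out.trips
    if trips["replicate_of"].notna().any():
        logger.warning("replicate_short_walks: replicates already present; no-op")
        return out
    mask = ((trips["main_mode"] == "walk")
            & (trips["distance_miles"] < short_walk_threshold)
            & (trips["day_index"] == final_day))
    if not mask.any():
        return out
    originals = trips.loc[mask]
    copies = []
    for k in range(1, 7):
        c = originals.copy()
        c["replicate_of"] = originals["trip_id"].to_numpy()
        c["trip_id"] = originals["trip_id"].astype(str) + f"_r{k}"
        copies.append(c)
    out.trips = pd.concat([trips] + copies, ignore_index=True)
    logger.info("replicated %d short walks x6 -> %d new trips",
                len(originals), 6 * len(originals))
    return out


def classify_current_cyclists(survey: TravelSurvey) -> set:
    """Persons with at least one cycle or e-bike trip in the diary week."""
    mask = survey.trips["main_mode"].isin(CYCLE_MODES)
    return set(survey.trips.loc[mask, "person_id"].unique())


def cyclist_prevalence(survey: TravelSurvey, weighted: bool = True) -> float:
    """Share of the adult population who are current cyclists."""
    cyclists = classify_current_cyclists(survey)
    is_cyc = survey.persons["person_id"].isin(cyclists)
    if weighted:
        w = survey.persons["survey_weight"]
        tot = w.sum()
        if tot == 0:
            raise ValidationError("total survey weight is zero")
        return float(w[is_cyc].sum() / tot)
    return float(is_cyc.mean())


def stratum_prevalences(survey: TravelSurvey, weighted: bool = True) -> pd.Series:
    """Current-cyclist prevalence by age_band x gender.

    Returns a Series indexed by (age_band, gender).  These are the
    uptake weights used by non-equity scenarios.
    """
    persons = survey.persons
    cyclists = classify_current_cyclists(survey)
    is_cyc = persons["person_id"].isin(cyclists).astype(float)
    w = persons["survey_weight"] if weighted else pd.Series(1.0, index=persons.index)
    num = (is_cyc * w).groupby([persons["age_band"], persons["gender"]]).sum()
    den = w.groupby([persons["age_band"], persons["gender"]]).sum()
    return (num / den).rename("prevalence")


def miles_to_km(miles):
    return np.asarray(miles) * 1.609344


def km_to_miles(km):
    return np.asarray(km) / 1.609344
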