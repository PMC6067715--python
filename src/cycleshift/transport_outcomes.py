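"""Transport and emissions outcomes: mode share, miles, CO2, journey time.

All quantities are survey-weighted and, because the diary covers one
week, per-person totals are per person per week (pppw).  CO2 is a
simple multiple of car-driver vehicle miles (default 0.313 kg CO2e per
mile), so proportional changes in CO2 always equal proportional changes
in car miles.  Public-transport reductions carry no CO2 credit: fewer
passengers need not shrink the bus or rail fleet's mileage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scenario_engine import ScenarioResult
from .travel_data import CAR_MODES, MODES, TravelSurvey

#: Mean tailpipe emission factor per private motor-vehicle mile.
DEFAULT_KG_CO2E_PER_CAR_MILE = 0.313


@dataclass(frozen=True)
class EmissionConfig:
    kg_co2e_per_car_mile: float = DEFAULT_KG_CO2E_PER_CAR_MILE
    #: Count only car_driver trips as vehicle miles (passengers would
    #: double-count vehicles); set False to include passenger distance.
    driver_only: bool = True

    def __post_init__(self):
        if self.kg_co2e_per_car_mile <= 0:
            raise ValidationError("emission factor must be > 0")


def _filtered(survey: TravelSurvey, subgroup: dict | None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Persons and their trips after applying a person-level filter.

    ``subgroup`` maps person columns to a value or list of values, e.g.
    ``{"gender": "female", "ethnicity": "non-white"}``.
    """
    persons = survey.persons
    if subgroup:
        mask = pd.Series(True, index=persons.index)
        for col, val in subgroup.items():
            if col not in persons.columns:
                raise ValidationError(f"unknown subgroup column: {col}")
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            mask &= persons[col].isin(vals)
        persons = persons.loc[mask]
    trips = survey.trips.loc[survey.trips["person_id"].isin(persons["person_id"])]
    return persons, trips


def mode_share(survey: TravelSurvey, subgroup: dict | None = None) -> pd.Series:
    """Survey-weighted trip-share by main mode.

    Returns a Series over all modes (zero where absent) plus a
    ``car_combined`` entry (driver + passenger).
    """
    persons, trips = _filtered(survey, subgroup)
    if len(trips) == 0:
        raise ValidationError(f"no trips after subgroup filter {subgroup}")
    w = trips["person_id"].map(persons.set_index("person_id")["survey_weight"])
    shares = (w.groupby(trips["main_mode"].to_numpy()).sum() / w.sum())
    shares = shares.reindex(MODES).fillna(0.0)
    shares.loc["car_combined"] = shares[list(CAR_MODES)].sum()
    return shares.rename("mode_share")


def miles_by_mode_pppw(survey: TravelSurvey, subgroup: dict | None = None
                       ) -> pd.Series:
    """Weighted person-miles per person per week by main mode."""
    persons, trips = _filtered(survey, subgroup)
    wp = persons.set_index("person_id")["survey_weight"]
    denom = wp.sum()
    if denom == 0:
        raise ValidationError("zero total person weight in subgroup")
    w = trips["person_id"].map(wp).to_numpy()
    miles = pd.Series(w * trips["distance_miles"].to_numpy(),
                      index=trips["main_mode"].to_numpy()).groupby(level=0).sum()
    return (miles.reindex(MODES).fillna(0.0) / denom).rename("miles_pppw")


def miles_cycled_pppw(survey: TravelSurvey, subgroup: dict | None = None) -> float:
    m = miles_by_mode_pppw(survey, subgroup)
    return float(m["cycle"] + m["ebike"])


def car_miles_and_co2(survey: TravelSurvey,
                      config: EmissionConfig = EmissionConfig(),
                      subgroup: dict | None = None) -> tuple[float, float]:
    """(car vehicle-miles pppw, kg CO2e pppw) for the (sub)population."""
    m = miles_by_mode_pppw(survey, subgroup)
    car = float(m["car_driver"]) if config.driver_only else float(
        m["car_driver"] + m["car_passenger"])
    return car, car * config.kg_co2e_per_car_mile


def journey_time_deltas(baseline: TravelSurvey, result: ScenarioResult,
                        subgroup: dict | None = None) -> dict:
    """Duration changes of switched trips, by prior mode.

    A trip counts as switched when its main mode differs between the
    baseline and scenario surveys.  For public-transport trips the prior
    duration is the full door-to-door time including waiting, as
    self-reported.  Deltas are ``new - old`` minutes; a trip is faster
    when delta < 0, slower when delta > 0, ties are neither.
    """
    persons, _ = _filtered(baseline, subgroup)
    keep = set(persons["person_id"])
    b = baseline.trips.set_index("trip_id")
    s = result.survey.trips.set_index("trip_id")
    if set(b.index) != set(s.index):
        raise ValidationError("baseline and scenario trip sets differ")
    s = s.reindex(b.index)
    switched = (b["main_mode"] != s["main_mode"]) & b["person_id"].isin(keep)
    deltas = pd.DataFrame({
        "trip_id": b.index[switched],
        "person_id": b.loc[switched, "person_id"].to_numpy(),
        "prior_mode": b.loc[switched, "main_mode"].to_numpy(),
        "new_mode": s.loc[switched, "main_mode"].to_numpy(),
        "delta_min": (s.loc[switched, "duration_min"]
                      - b.loc[switched, "duration_min"]).to_numpy(),
    })
    n = len(deltas)
    summary = {
        "n_switched": n,
        "pct_faster": float(100.0 * (deltas["delta_min"] < 0).mean()) if n else 0.0,
        "pct_slower": float(100.0 * (deltas["delta_min"] > 0).mean()) if n else 0.0,
        "mean_delta_min": float(deltas["delta_min"].mean()) if n else 0.0,
    }
    by_prior = {}
    for mode, grp in deltas.groupby("prior_mode"):
        by_prior[mode] = {
            "n": len(grp),
            "pct_faster": float(100.0 * (grp["delta_min"] < 0).mean()),
            "pct_slower": float(100.0 * (grp["delta_min"] > 0).mean()),
            "mean_delta_min": float(grp["delta_min"].mean()),
        }
    return {"deltas": deltas, "summary": summary, "by_prior_mode": by_prior}


def outcome_report(baseline: TravelSurvey, result: ScenarioResult | None = None,
                   emissions: EmissionConfig = EmissionConfig(),
                   subgroup: dict | None = None) -> dict:
    """Tidy summary of transport outcomes (baseline, and vs-scenario).

    With ``result=None`` only baseline quantities are reported.
    """
    survey = baseline if result is None else result.survey
    shares = mode_share(survey, subgroup)
    car, co2 = car_miles_and_co2(survey, emissions, subgroup)
    report = {
        "mode_share": shares.to_dict(),
        "miles_cycled_pppw": miles_cycled_pppw(survey, subgroup),
        "car_miles_pppw": car,
        "co2_kg_pppw": co2,
    }
    if result is not None:
        base_car, base_co2 = car_miles_and_co2(baseline, emissions, subgroup)
        jt = journey_time_deltas(baseline, result, subgroup)
        report["pct_car_miles_change"] = (
            100.0 * (car - base_car) / base_car if base_car > 0 else 0.0)
        report["pct_co2_change"] = (
            100.0 * (co2 - base_co2) / base_co2 if base_co2 > 0 else 0.0)
        report["journey_time"] = jt["summary"]
        report["journey_time_by_prior_mode"] = jt["by_prior_mode"]
        groups = result.group_by_person
        keep = _filtered(baseline, subgroup)[0]["person_id"]
        report["group_counts"] = (groups.loc[groups.index.isin(set(keep))]
                                  .value_counts().to_dict())
    return report
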