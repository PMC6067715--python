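import numpy as np
import pandas as pd
import pytest

from cycleshift.propensity import build_ebike_tables, estimate_propensity, estimate_speeds
from cycleshift.synthetic_data import (PopulationConfig, default_ebike_reference,
                                       generate_population)
from cycleshift.travel_data import TravelSurvey, replicate_short_walks


def make_persons(rows):
    """Build a persons frame from (person_id, age, gender[, weight]) tuples."""
    from cycleshift.travel_data import age_to_band
    recs = []
    for r in rows:
        pid, age, gender = r[0], r[1], r[2]
        weight = r[3] if len(r) > 3 else 1.0
        recs.append({"person_id": pid, "age": age, "gender": gender,
                     "ethnicity": "white", "nssec": "routine",
                     "car_access": True, "region": "london",
                     "survey_weight": weight})
    df = pd.DataFrame(recs)
    df["age_band"] = age_to_band(df["age"].to_numpy()).to_numpy()
    return df


def make_trips(rows):
    """Build a trips frame from (trip_id, person_id, mode, miles, minutes[, day])."""
    recs = []
    for r in rows:
        recs.append({"trip_id": r[0], "person_id": r[1], "main_mode": r[2],
                     "distance_miles": float(r[3]), "duration_min": float(r[4]),
                     "day_index": int(r[5]) if len(r) > 5 else 1,
                     "purpose": "commute", "pt_walk_minutes": 0.0,
                     "replicate_of": pd.NA})
    return pd.DataFrame(recs)


def make_survey(person_rows, trip_rows, geography="london"):
    return TravelSurvey(persons=make_persons(person_rows),
                        trips=make_trips(trip_rows),
                        geography_label=geography)


@pytest.fixture
def tiny_survey():
    """Two persons, three trips: one cyclist, one car commuter."""
    return make_survey(
        [("p1", 30, "male"), ("p2", 45, "female")],
        [("t1", "p1", "cycle", 2.0, 12.0),
         ("t2", "p1", "walk", 0.5, 10.0, 7),
         ("t3", "p2", "car_driver", 8.0, 20.0)])


@pytest.fixture(scope="session")
def base_survey():
    """Mid-sized synthetic baseline (single seed, short-walk replicated)."""
    cfg = PopulationConfig(n_persons=10_000, seed=11)
    return replicate_short_walks(generate_population(cfg))


@pytest.fixture(scope="session")
def tables(base_survey):
    prop = estimate_propensity(base_survey)
    speeds = estimate_speeds(base_survey)
    ref = default_ebike_reference(prop.bands)
    ebike = build_ebike_tables(
        {k: v for k, v in ref.items() if k != "bands"}, prop.bands)
    return prop, speeds, ebike
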