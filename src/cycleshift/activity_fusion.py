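"""Weekly physical-activity accounting in marginal MET-hours (MMETh).

Travel activity is the sum over a person's week of walking trips,
cycling trips, e-bike trips and the walking embedded in public
transport, each weighted by its marginal MET intensity (activity above
rest): walking 2.6, pedal cycling 4.6, e-biking 3.5 MMET.  Non-travel
activity comes from a separate activity survey and is fused onto the
travel diary by rank-matching within age-band x gender strata; it is
held fixed across scenarios, so scenario changes in total activity are
purely changes in travel.

Guideline attainment uses the conventional interpretation of the WHO
recommendation — 2.5 h/week of moderate activity at the 3.5 MMET
midpoint, i.e. 8.75 MMETh/week, with a higher 5 h/week (17.5 MMETh)
level — with closed (>=) bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .travel_data import PT_MODES, TravelSurvey

MODERATE_MMET = 3.5  # midpoint marginal intensity of moderate activity


def guideline_thresholds(hours_low: float = 2.5, hours_high: float = 5.0,
                         moderate_mmet: float = MODERATE_MMET) -> tuple[float, float]:
    """MMETh/week thresholds for the low and high activity guidelines."""
    return hours_low * moderate_mmet, hours_high * moderate_mmet


@dataclass(frozen=True)
class IntensityConfig:
    """Marginal MET intensities and guideline thresholds (MMETh/week)."""
    walk_mmet: float = 2.6
    cycle_mmet: float = 4.6
    ebike_mmet: float = 3.5
    guideline_low: float = guideline_thresholds()[0]   # 8.75
    guideline_high: float = guideline_thresholds()[1]  # 17.5

    def __post_init__(self):
        vals = (self.walk_mmet, self.cycle_mmet, self.ebike_mmet,
                self.guideline_low, self.guideline_high)
        if any(v <= 0 for v in vals):
            raise ValidationError("intensities and thresholds must be > 0")
        if self.guideline_low >= self.guideline_high:
            raise ValidationError("guideline_low must be < guideline_high")


def travel_mmeth(trips: pd.DataFrame,
                 intensities: IntensityConfig = IntensityConfig()) -> pd.Series:
    """Weekly travel MMETh per person from a trips table.

    intensity x duration (hours) summed over walk, cycle and e-bike
    trips plus the embedded walking minutes of public-transport trips;
    other modes contribute nothing.  Returns a Series indexed by
    person_id (persons absent from ``trips`` are simply absent; use
    :func:`activity_profiles` for a full-population table).
    """
    if (trips["duration_min"] < 0).any():
        raise ValidationError("negative trip duration")
    hours = trips["duration_min"].to_numpy() / 60.0
    mode = trips["main_mode"].to_numpy()
    mmet = np.select(
        [mode == "walk", mode == "cycle", mode == "ebike"],
        [intensities.walk_mmet, intensities.cycle_mmet, intensities.ebike_mmet],
        default=0.0)
    contrib = mmet * hours
    ptw = trips["pt_walk_minutes"].to_numpy() if "pt_walk_minutes" in trips else 0.0
    contrib = contrib + np.where(np.isin(mode, PT_MODES),
                                 np.asarray(ptw) / 60.0 * intensities.walk_mmet, 0.0)
    return (pd.Series(contrib, index=trips["person_id"].to_numpy())
            .groupby(level=0).sum().rename("travel_mmeth"))


def _weighted_quantile(values: np.ndarray, weights: np.ndarray,
                       q: np.ndarray) -> np.ndarray:
    """Inverted-CDF quantiles of a weighted sample (smallest value whose
    cumulative weight share reaches q)."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / w.sum()
    pos = np.searchsorted(cum, q, side="left")
    return v[np.minimum(pos, len(v) - 1)]


def fuse_nontravel(survey: TravelSurvey, activity: pd.DataFrame,
                   seed: int = 0,
                   intensities: IntensityConfig = IntensityConfig()) -> pd.Series:
    """Assign each person a non-travel MMETh value by rank-matching.

    Within each age-band x gender stratum, survey persons are ranked by
    their baseline travel MMETh (ties broken by a seeded shuffle) and
    mapped to the matching quantile of the stratum's weighted non-travel
    activity distribution.  Deterministic given the seed; the result is
    stored per person so scenario recomputations reuse baseline values.
    """
    rng = np.random.default_rng(seed)
    persons = survey.persons
    tm = travel_mmeth(survey.trips, intensities)
    travel = persons["person_id"].map(tm).fillna(0.0).to_numpy()

    required = set(map(tuple, persons[["age_band", "gender"]].drop_duplicates()
                       .itertuples(index=False)))
    available = set(map(tuple, activity[["age_band", "gender"]].drop_duplicates()
                        .itertuples(index=False)))
    missing = required - available
    if missing:
        raise ValidationError(
            "activity sample missing stratum(s): " + ", ".join(map(str, sorted(missing))))

    out = np.empty(len(persons))
    jitter = rng.random(len(persons))  # seeded tie-breaking
    for (band, gender), grp in persons.groupby(["age_band", "gender"],
                                               observed=True):
        pos = grp.index.to_numpy()
        loc = persons.index.get_indexer(pos)
        sub = activity.loc[(activity["age_band"] == band)
                           & (activity["gender"] == gender)]
        order = np.lexsort((jitter[loc], travel[loc]))
        ranks = np.empty(len(loc), dtype=float)
        ranks[order] = np.arange(len(loc))
        q = (ranks + 0.5) / len(loc)
        out[loc] = _weighted_quantile(sub["nontravel_mmeth"].to_numpy(dtype=float),
                                      sub["weight"].to_numpy(dtype=float), q)
    return pd.Series(out, index=persons["person_id"].to_numpy(),
                     name="nontravel_mmeth")


def activity_profiles(survey: TravelSurvey, nontravel: pd.Series,
                      intensities: IntensityConfig = IntensityConfig()
                      ) -> pd.DataFrame:
    """Per-person profile: travel, non-travel and total MMETh/week.

    ``nontravel`` is the baseline fusion result; passing the same Series
    for baseline and scenario surveys keeps non-travel activity fixed.
    """
    persons = survey.persons
    tm = travel_mmeth(survey.trips, intensities)
    travel = persons["person_id"].map(tm).fillna(0.0).to_numpy()
    nt = persons["person_id"].map(nontravel).fillna(0.0).to_numpy()
    return pd.DataFrame({
        "person_id": persons["person_id"].to_numpy(),
        "travel_mmeth": travel,
        "nontravel_mmeth": nt,
        "total_mmeth": travel + nt,
        "weight": persons["survey_weight"].to_numpy(),
    })


def guideline_attainment(profiles: pd.DataFrame,
                         intensities: IntensityConfig = IntensityConfig()
                         ) -> tuple[float, float]:
    """Weighted population shares meeting the low and high guidelines."""
    if len(profiles) == 0:
        raise ValidationError("empty profile set")
    w = (profiles["weight"].to_numpy() if "weight" in profiles
         else np.ones(len(profiles)))
    total = profiles["total_mmeth"].to_numpy()
    wsum = w.sum()
    low = float(w[total >= intensities.guideline_low].sum() / wsum)
    high = float(w[total >= intensities.guideline_high].sum() / wsum)
    return low, high


def mean_mmeth(profiles: pd.DataFrame) -> float:
    """Weighted mean total MMETh/week across the population."""
    w = (profiles["weight"].to_numpy() if "weight" in profiles
         else np.ones(len(profiles)))
    return float(np.average(profiles["total_mmeth"].to_numpy(), weights=w))
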