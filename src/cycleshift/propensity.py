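"""Distance-band cycling propensity, cycling speeds and e-bike tables.

The central behavioural input of the scenario engine is the propensity
table: among *current* cyclists of an age-band x gender stratum, the
probability that a trip in a given distance band is cycled.  The model
premise is that existing cyclists do not cycle all their trips and are
markedly less likely to cycle longer ones, so the table is estimated
directly from their diaries as a survey-weighted ratio

    p_cycle(stratum, band) = W(cycled trips in band) / W(all trips in band)

with a pooled (all-strata) fallback for cells with too few trips.

Cycling speeds per stratum are ratio-of-sums estimates (total cycled
miles over total cycled hours).  E-bike behaviour comes from a separate
reference (a Dutch-style survey that records e-bikes as a mode, or a
ready-made table): the probability that an e-bike owner's cycled trip
uses the e-bike rather than a pedal bike, and the owner's distance
propensity, both flat across age and gender.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError
from .travel_data import (AGE_BANDS, GENDERS, CYCLE_MODES, TravelSurvey,
                          classify_current_cyclists)

logger = logging.getLogger(__name__)

#: Band edges in miles; the last band is open-ended.  They bracket the
#: distance horizon over which a shift to cycling is plausible, with the
#: finest resolution below 3 miles where most cycled trips fall.
DEFAULT_BAND_EDGES = (0.0, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0, np.inf)

#: Strata for propensity and speed estimation: the 80+ band is excluded
#: from uptake, so only the three younger bands are modelled.
UPTAKE_AGE_BANDS = ("18-39", "40-59", "60-79")
DEFAULT_STRATA = tuple((a, g) for a in UPTAKE_AGE_BANDS for g in GENDERS)

#: Minimum trips in a (stratum, band) cell before its own estimate is used.
DEFAULT_MIN_SUPPORT = 30

#: Placeholder e-bike speed (mph), constant across strata.
DEFAULT_EBIKE_SPEED_MPH = 12.0
#: Placeholder pedal-cycle speed (mph) used when a survey has no cycle trips.
DEFAULT_CYCLE_SPEED_MPH = 9.0


@dataclass(frozen=True)
class DistanceBand:
    """Half-open trip-distance interval [lower, upper) in miles."""
    lower: float
    upper: float

    def __contains__(self, distance: float) -> bool:
        return self.lower <= distance < self.upper


def make_bands(edges=DEFAULT_BAND_EDGES) -> list[DistanceBand]:
    """Build contiguous bands from increasing edges covering (0, inf)."""
    edges = list(edges)
    if edges[0] != 0.0 or not np.isinf(edges[-1]):
        raise ValidationError("band edges must start at 0 and end at inf")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("band edges must be strictly increasing")
    return [DistanceBand(a, b) for a, b in zip(edges, edges[1:])]


def assign_band(distances, bands: list[DistanceBand]) -> np.ndarray:
    """Index of the band containing each distance (vectorised)."""
    inner_edges = np.array([b.lower for b in bands[1:]])
    return np.digitize(np.asarray(distances, dtype=float), inner_edges)


@dataclass
class PropensityTable:
    """P(cycle a trip | distance band, age_band x gender stratum).

    ``table`` has one row per (age_band, gender, band) with columns
    band_lower_miles, band_upper_miles, p_cycle, n_trips.
    """
    table: pd.DataFrame
    bands: list[DistanceBand]

    def __post_init__(self):
        p = self.table["p_cycle"]
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("p_cycle must lie in [0, 1]")

    def lookup(self, age_band, gender, band_idx) -> np.ndarray:
        """Vectorised probability lookup for trip arrays."""
        key = pd.MultiIndex.from_arrays(
            [np.asarray(age_band), np.asarray(gender), np.asarray(band_idx)])
        indexed = self.table.set_index(["age_band", "gender", "band_idx"])["p_cycle"]
        try:
            return indexed.loc[key].to_numpy()
        except KeyError as exc:
            raise CoverageError(f"propensity table does not cover {exc}") from exc

    def to_csv(self, path) -> None:
        cols = ["age_band", "gender", "band_lower_miles", "band_upper_miles",
                "p_cycle", "n_trips"]
        self.table.loc[:, cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PropensityTable":
        df = pd.read_csv(path)
        edges = sorted(df["band_lower_miles"].unique().tolist()) + [np.inf]
        bands = make_bands(edges)
        df = df.copy()
        df["band_idx"] = assign_band(df["band_lower_miles"] + 1e-9, bands)
        return cls(table=df, bands=bands)


@dataclass
class SpeedTable:
    """Cycling speed (mph) by stratum, plus a flat e-bike speed."""
    table: pd.DataFrame  # columns: age_band, gender, mode, speed_mph
    ebike_speed_mph: float = DEFAULT_EBIKE_SPEED_MPH

    def __post_init__(self):
        if (self.table["speed_mph"] <= 0).any() or self.ebike_speed_mph <= 0:
            raise ValidationError("speeds must be positive")

    def lookup(self, age_band, gender, mode) -> np.ndarray:
        """Speed for each trip given stratum and target mode."""
        age_band = np.asarray(age_band)
        gender = np.asarray(gender)
        mode = np.asarray(mode)
        cyc = (self.table.loc[self.table["mode"] == "cycle"]
               .set_index(["age_band", "gender"])["speed_mph"])
        key = pd.MultiIndex.from_arrays([age_band, gender])
        try:
            speeds = cyc.loc[key].to_numpy(dtype=float)
        except KeyError as exc:
            raise CoverageError(f"speed table does not cover {exc}") from exc
        return np.where(mode == "ebike", self.ebike_speed_mph, speeds)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ebike_speed_mph=DEFAULT_EBIKE_SPEED_MPH) -> "SpeedTable":
        return cls(table=pd.read_csv(path), ebike_speed_mph=ebike_speed_mph)


def _cyclist_trips(survey: TravelSurvey) -> pd.DataFrame:
    cyclists = classify_current_cyclists(survey)
    if not cyclists:
        raise ValidationError("survey contains no current cyclists")
    persons = survey.persons.set_index("person_id")
    trips = survey.trips.loc[survey.trips["person_id"].isin(cyclists)].copy()
    trips["age_band"] = trips["person_id"].map(persons["age_band"])
    trips["gender"] = trips["person_id"].map(persons["gender"])
    trips["weight"] = trips["person_id"].map(persons["survey_weight"])
    trips["is_cycled"] = trips["main_mode"].isin(CYCLE_MODES)
    return trips


def estimate_propensity(survey: TravelSurvey,
                        bands: list[DistanceBand] | None = None,
                        strata=DEFAULT_STRATA,
                        min_support: int = DEFAULT_MIN_SUPPORT) -> PropensityTable:
    """Estimate the distance-band cycling propensity of current cyclists.

    For each (age_band, gender, band) cell the survey-weighted share of
    cycled trips among all trips made by that stratum's current cyclists
    is computed.  Cells supported by fewer than ``min_support`` trips
    fall back to the band's pooled (all-strata) estimate; an empty band
    everywhere falls back to 0 with a warning.
    """
    bands = bands if bands is not None else make_bands()
    trips = _cyclist_trips(survey)
    trips["band_idx"] = assign_band(trips["distance_miles"], bands)

    trips["w_cycled"] = trips["weight"] * trips["is_cycled"]
    grp = trips.groupby(["age_band", "gender", "band_idx"], observed=True)
    w_all = grp["weight"].sum()
    w_cyc = grp["w_cycled"].sum()
    n = grp.size()

    pooled_grp = trips.groupby("band_idx")
    pooled_all = pooled_grp["weight"].sum()
    pooled_cyc = trips.loc[trips["is_cycled"]].groupby("band_idx")["weight"].sum()
    pooled_p = (pooled_cyc.reindex(pooled_all.index).fillna(0.0)
                / pooled_all).to_dict()

    rows = []
    for (a, g) in strata:
        for i, band in enumerate(bands):
            key = (a, g, i)
            support = int(n.get(key, 0))
            if support > 0 and support >= min_support:
                p = float(w_cyc.get(key, 0.0) / w_all.get(key))
            elif i in pooled_p:
                p = float(pooled_p[i])
            else:
                logger.warning("band %s empty everywhere; propensity set to 0", band)
                p = 0.0
            rows.append({"age_band": a, "gender": g, "band_idx": i,
                         "band_lower_miles": band.lower,
                         "band_upper_miles": band.upper,
                         "p_cycle": p, "n_trips": support})
    return PropensityTable(table=pd.DataFrame(rows), bands=bands)


def estimate_speeds(survey: TravelSurvey, strata=DEFAULT_STRATA,
                    ebike_speed_mph: float = DEFAULT_EBIKE_SPEED_MPH,
                    default_cycle_speed_mph: float = DEFAULT_CYCLE_SPEED_MPH
                    ) -> SpeedTable:
    """Estimate pedal-cycle speed per stratum (ratio of sums, weighted).

    stratum speed = total cycled miles / total cycled hours.  A stratum
    without cycle trips falls back to the pooled speed, then to the
    configured default.  The e-bike speed is taken from configuration
    (reference data), never estimated from the English-style survey.
    """
    trips = _cyclist_trips(survey)
    cyc = trips.loc[trips["main_mode"] == "cycle"]

    def ratio(df):
        hours = (df["duration_min"] * df["weight"]).sum() / 60.0
        miles = (df["distance_miles"] * df["weight"]).sum()
        return miles / hours if hours > 0 else np.nan

    pooled = ratio(cyc) if len(cyc) else np.nan
    if not np.isfinite(pooled):
        logger.warning("no cycle trips at all; using default cycle speed %.1f mph",
                       default_cycle_speed_mph)
        pooled = default_cycle_speed_mph

    rows = []
    for (a, g) in strata:
        sub = cyc.loc[(cyc["age_band"] == a) & (cyc["gender"] == g)]
        speed = ratio(sub) if len(sub) else np.nan
        if not np.isfinite(speed):
            logger.warning("no cycle trips for stratum (%s, %s); pooled fallback", a, g)
            speed = pooled
        rows.append({"age_band": a, "gender": g, "mode": "cycle",
                     "speed_mph": float(speed)})
    return SpeedTable(table=pd.DataFrame(rows), ebike_speed_mph=ebike_speed_mph)


@dataclass
class EbikeTables:
    """Per-band e-bike behaviour of e-bike owners (flat across strata).

    ``choice_prob``: P(e-bike rather than pedal bike | trip cycled);
    ``propensity``: P(trip cycled | distance band).  Both are aligned
    with ``bands``; trips beyond the last reference band carry the last
    band's values (open-ended band contract).
    """
    bands: list[DistanceBand]
    choice_prob: np.ndarray
    propensity: np.ndarray

    def __post_init__(self):
        self.choice_prob = np.asarray(self.choice_prob, dtype=float)
        self.propensity = np.asarray(self.propensity, dtype=float)
        for name, arr in (("choice_prob", self.choice_prob),
                          ("propensity", self.propensity)):
            if len(arr) != len(self.bands):
                raise ValidationError(f"{name} must have one entry per band")
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError(f"{name} probabilities must lie in [0, 1]")

    def lookup(self, band_idx) -> tuple[np.ndarray, np.ndarray]:
        idx = np.minimum(np.asarray(band_idx), len(self.bands) - 1)
        return self.choice_prob[idx], self.propensity[idx]

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "band_lower_miles": [b.lower for b in self.bands],
            "band_upper_miles": [b.upper for b in self.bands],
            "choice_prob": self.choice_prob,
            "ebike_propensity": self.propensity,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EbikeTables":
        df = pd.read_csv(path)
        edges = df["band_lower_miles"].tolist() + [np.inf]
        return cls(bands=make_bands(edges),
                   choice_prob=df["choice_prob"].to_numpy(),
                   propensity=df["ebike_propensity"].to_numpy())


def build_ebike_tables(reference, bands: list[DistanceBand] | None = None
                       ) -> EbikeTables:
    """Build (choice probability, e-bike propensity) per distance band.

    ``reference`` is either an :class:`EbikeTables` (validated and
    returned as-is), a mapping with ``choice_prob_by_band`` /
    ``ebike_propensity_by_band`` arrays, or a Dutch-style
    :class:`~cycleshift.travel_data.TravelSurvey` whose trips record
    ``ebike`` as a mode, in which case both tables are estimated from
    the diaries of persons with at least one e-bike trip (the e-bike
    owners): per band, P(e-bike | cycled trip) and P(cycled | trip).
    """
    bands = bands if bands is not None else make_bands()
    if isinstance(reference, EbikeTables):
        return reference
    if isinstance(reference, dict):
        return EbikeTables(bands=bands,
                           choice_prob=reference["choice_prob_by_band"],
                           propensity=reference["ebike_propensity_by_band"])
    if isinstance(reference, TravelSurvey):
        trips = reference.trips.copy()
        owners = set(trips.loc[trips["main_mode"] == "ebike", "person_id"].unique())
        if not owners:
            raise ValidationError(
                "reference survey has no ebike trips; supply the e-bike "
                "tables directly instead")
        trips = trips.loc[trips["person_id"].isin(owners)]
        trips["band_idx"] = assign_band(trips["distance_miles"], bands)
        choice, prop = [], []
        last_choice, last_prop = 0.0, 0.0
        for i in range(len(bands)):
            sub = trips.loc[trips["band_idx"] == i]
            cycled = sub.loc[sub["main_mode"].isin(CYCLE_MODES)]
            if len(sub):
                last_prop = len(cycled) / len(sub)
            if len(cycled):
                last_choice = (cycled["main_mode"] == "ebike").mean()
            prop.append(last_prop)
            choice.append(last_choice)
        return EbikeTables(bands=bands, choice_prob=np.array(choice),
                           propensity=np.array(prop))
    raise ValidationError(f"unsupported e-bike reference type: {type(reference)!r}")
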