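"""Comparative risk assessment: activity -> relative risk -> averted burden.

Each person's weekly physical-activity volume (total MMETh) maps to an
all-cause-mortality relative risk through a nonlinear dose-response
curve, supplied as a lookup table of (exposure, RR) knots with linear
interpolation and a flat tail — anchored at RR(0) = 1 and monotone
non-increasing.  The bundled default curve is *illustrative* (plateau
around 0.63); substitute a published meta-analytic curve via CSV for
real analyses.

For each geography x age-band x gender stratum the population impact
fraction compares scenario to baseline risks person by person,

    PIF = 1 - sum_i w_i RR(scenario_i) / sum_i w_i RR(baseline_i),

and is applied to a burden table of years of life lost (YLL) and deaths
for ages 20-79: averted burden = PIF x stratum burden, aggregated as a
burden-weighted percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

HEALTH_AGE_BANDS = ("20-39", "40-59", "60-79")

#: Illustrative dose-response knots (MMETh/week -> relative risk of
#: all-cause mortality): monotone, RR(0)=1, plateau ~0.63.  NOT a
#: published curve; replace via DoseResponse.from_csv for real use.
DEFAULT_DOSE_RESPONSE_KNOTS = (
    (0.0, 1.0),
    (4.375, 0.90),
    (8.75, 0.82),
    (17.5, 0.74),
    (35.0, 0.67),
    (70.0, 0.63),
)


@dataclass
class DoseResponse:
    """Piecewise-linear RR-vs-exposure curve, flat beyond the last knot."""
    exposures: np.ndarray
    rrs: np.ndarray

    def __post_init__(self):
        self.exposures = np.asarray(self.exposures, dtype=float)
        self.rrs = np.asarray(self.rrs, dtype=float)
        if len(self.exposures) != len(self.rrs) or len(self.exposures) < 1:
            raise ValidationError("knots must be non-empty parallel arrays")
        if (np.diff(self.exposures) <= 0).any():
            raise ValidationError("knot exposures must be strictly increasing")
        if self.exposures[0] != 0.0 or self.rrs[0] != 1.0:
            raise ValidationError("first knot must be (0, 1.0)")
        if (np.diff(self.rrs) > 0).any():
            raise ValidationError("RR must be non-increasing in exposure")
        if ((self.rrs <= 0) | (self.rrs > 1)).any():
            raise ValidationError("RR values must lie in (0, 1]")

    @classmethod
    def from_knots(cls, knots) -> "DoseResponse":
        e, r = zip(*knots)
        return cls(exposures=np.array(e), rrs=np.array(r))

    @classmethod
    def default(cls) -> "DoseResponse":
        return cls.from_knots(DEFAULT_DOSE_RESPONSE_KNOTS)

    @classmethod
    def from_csv(cls, path) -> "DoseResponse":
        df = pd.read_csv(path)
        return cls(exposures=df["exposure_mmeth"].to_numpy(),
                   rrs=df["rr"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"exposure_mmeth": self.exposures,
                      "rr": self.rrs}).to_csv(path, index=False)

    def rr(self, total_mmeth) -> np.ndarray:
        """Relative risk at the given exposure(s); flat extrapolation."""
        x = np.asarray(total_mmeth, dtype=float)
        if (x < 0).any():
            raise ValidationError("exposure must be >= 0")
        return np.interp(x, self.exposures, self.rrs)


def individual_rr(total_mmeth, dr: DoseResponse) -> float | np.ndarray:
    """Relative risk for one exposure (or an array of exposures)."""
    out = dr.rr(total_mmeth)
    return float(out) if np.ndim(total_mmeth) == 0 else out


def stratum_pif(baseline_profiles: pd.DataFrame, scenario_profiles: pd.DataFrame,
                dr: DoseResponse, weights=None) -> float:
    """Population impact fraction of a stratum's activity change.

    Both profile frames must cover the same persons (matched on
    ``person_id``).  PIF = 1 - sum w.RR(scenario)/sum w.RR(baseline);
    weights default to the profiles' survey weights (unit if absent).
    """
    b = baseline_profiles.set_index("person_id")
    s = scenario_profiles.set_index("person_id")
    if set(b.index) != set(s.index):
        raise ValidationError("baseline and scenario profiles cover different persons")
    s = s.reindex(b.index)
    if weights is None:
        w = b["weight"].to_numpy() if "weight" in b else np.ones(len(b))
    else:
        w = np.asarray(weights, dtype=float)
    rr_b = dr.rr(b["total_mmeth"].to_numpy())
    rr_s = dr.rr(s["total_mmeth"].to_numpy())
    return float(1.0 - (w * rr_s).sum() / (w * rr_b).sum())


def person_health_band(age) -> pd.Series:
    """Map ages to burden age bands 20-39/40-59/60-79 (NaN outside 20-79).

    Persons aged 18-19 contribute to travel outcomes but not to the
    mortality burden.
    """
    age = pd.Series(np.asarray(age))
    return pd.cut(age, bins=[20, 40, 60, 80], labels=HEALTH_AGE_BANDS,
                  right=False)


def validate_burden(burden: pd.DataFrame) -> pd.DataFrame:
    required = {"geography", "age_band", "gender", "yll", "deaths"}
    missing = required - set(burden.columns)
    if missing:
        raise ValidationError(f"burden table missing column(s): {sorted(missing)}")
    if (burden["yll"] < 0).any() or (burden["deaths"] < 0).any():
        raise ValidationError("burden values must be >= 0")
    if burden.duplicated(["geography", "age_band", "gender"]).any():
        raise ValidationError("duplicate burden strata")
    return burden


def compute_pifs(persons: pd.DataFrame, baseline_profiles: pd.DataFrame,
                 scenario_profiles: pd.DataFrame, dr: DoseResponse,
                 geography: str) -> pd.DataFrame:
    """PIF per (geography, health age band, gender) cell of a survey."""
    info = persons.set_index("person_id")
    hband = person_health_band(info["age"].to_numpy())
    info = info.assign(health_band=hband.to_numpy())
    info = info.loc[info["health_band"].notna()]

    b = baseline_profiles.set_index("person_id")
    s = scenario_profiles.set_index("person_id")
    rows = []
    for (band, gender), grp in info.groupby(["health_band", "gender"],
                                            observed=True):
        ids = grp.index
        pif = stratum_pif(b.loc[ids].reset_index(), s.loc[ids].reset_index(), dr)
        rows.append({"geography": geography, "age_band": str(band),
                     "gender": gender, "pif": pif, "n_persons": len(ids)})
    return pd.DataFrame(rows)


def yll_averted(pifs: pd.DataFrame, burden: pd.DataFrame) -> dict:
    """Apply stratum PIFs to the burden table.

    Burden strata without scenario persons get PIF 0.  Returns a dict
    with a per-stratum DataFrame and aggregates: absolute YLL averted,
    percent of total YLL, and the same for deaths (ages 20-79).
    """
    validate_burden(burden)
    merged = burden.merge(pifs, on=["geography", "age_band", "gender"],
                          how="left")
    merged["pif"] = merged["pif"].fillna(0.0)
    merged["yll_averted"] = merged["pif"] * merged["yll"]
    merged["deaths_averted"] = merged["pif"] * merged["deaths"]
    tot_yll = merged["yll"].sum()
    tot_deaths = merged["deaths"].sum()
    return {
        "by_stratum": merged,
        "yll_averted": float(merged["yll_averted"].sum()),
        "pct_yll_averted": float(100.0 * merged["yll_averted"].sum() / tot_yll)
        if tot_yll > 0 else 0.0,
        "deaths_averted": float(merged["deaths_averted"].sum()),
        "pct_deaths_averted": float(100.0 * merged["deaths_averted"].sum()
                                    / tot_deaths) if tot_deaths > 0 else 0.0,
    }
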