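"""Config-driven end-to-end pipeline: inputs -> baseline -> scenarios -> results.

The four stages are (1) load or simulate the input tables, (2) build
the baseline population (diary preprocessing, propensity/speed/e-bike
estimation, activity fusion), (3) run the requested uptake scenarios,
and (4) write per-scenario outcome files plus a JSON run manifest
(seeds, input digests, package version) so any output is traceable to
its generating configuration.  One global seed spawns stable
per-scenario child seeds from a hash of the scenario fields, so results
do not depend on enumeration order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity_fusion import (IntensityConfig, activity_profiles,
                              fuse_nontravel, guideline_attainment, mean_mmeth)
from .errors import ValidationError
from .health_cra import DoseResponse, compute_pifs, yll_averted
from .propensity import build_ebike_tables, estimate_propensity, estimate_speeds
from .scenario_engine import (ScenarioSpec, enumerate_scenarios, run_scenario,
                              scenario_seed)
from .synthetic_data import (PopulationConfig, default_ebike_reference,
                             generate_activity_survey, generate_burden_table)
from .synthetic_data import generate_population
from .transport_outcomes import EmissionConfig, outcome_report
from .travel_data import (TravelSurvey, cyclist_prevalence,
                          derive_pt_walk_minutes, read_survey,
                          replicate_short_walks, stratum_prevalences,
                          write_survey)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Input tables come either from CSV paths or from the synthetic
    generators (``synthetic_population`` holds PopulationConfig
    overrides).  Scenarios are an explicit list of
    (geography, target_pct, equity, ebike) dicts, or ``enumerate_all``
    to build the full published set from per-geography baselines.
    """
    out_dir: str = "results"
    seed: int = 0
    persons_path: str | None = None
    trips_path: str | None = None
    stages_path: str | None = None
    activity_path: str | None = None
    burden_path: str | None = None
    dose_response_path: str | None = None
    synthetic_population: dict = field(default_factory=dict)
    synthetic_activity_n: int = 20_000
    scenarios: list = field(default_factory=list)
    enumerate_all: bool = False
    intensity: dict = field(default_factory=dict)
    emissions: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        return cls(**data)

    def validate_paths(self) -> None:
        for p in (self.persons_path, self.trips_path, self.stages_path,
                  self.activity_path, self.burden_path, self.dose_response_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input file does not exist: {p}")


def _digest(obj) -> str:
    if isinstance(obj, (str, Path)) and Path(obj).exists():
        return hashlib.sha256(Path(obj).read_bytes()).hexdigest()[:16]
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def load_baseline(config: RunConfig) -> TravelSurvey:
    """Stage 1-2a: obtain and preprocess the baseline survey."""
    if config.persons_path and config.trips_path:
        survey = read_survey(config.persons_path, config.trips_path,
                             config.stages_path)
        if survey.stages is not None:
            survey = derive_pt_walk_minutes(survey)
    else:
        pop_kwargs = dict(config.synthetic_population)
        pop_kwargs.setdefault("seed", config.seed)
        survey = generate_population(PopulationConfig(**pop_kwargs))
    survey = replicate_short_walks(survey)
    logger.info("baseline: %d persons, %d trips, prevalence %.2f%%",
                survey.n_persons, survey.n_trips,
                100 * cyclist_prevalence(survey))
    return survey


def _subsurvey(survey: TravelSurvey, geography: str) -> TravelSurvey:
    """Restrict a survey to one region (umbrella label keeps everything)."""
    if geography in (survey.geography_label, "all"):
        return survey
    persons = survey.persons.loc[survey.persons["region"] == geography]
    if len(persons) == 0:
        raise ValidationError(f"no persons in geography {geography!r}")
    trips = survey.trips.loc[survey.trips["person_id"].isin(persons["person_id"])]
    return TravelSurvey(persons=persons.reset_index(drop=True),
                        trips=trips.reset_index(drop=True),
                        geography_label=geography)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages for every requested scenario; write outputs.

    Returns a dict with the baseline report, per-scenario results and
    the manifest.  Re-running with the same config reproduces outputs
    bit-exactly.
    """
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    survey = load_baseline(config)
    intensities = IntensityConfig(**config.intensity)
    emissions = EmissionConfig(**config.emissions)

    if config.activity_path:
        activity = pd.read_csv(config.activity_path)
    else:
        activity = generate_activity_survey(config.synthetic_activity_n,
                                            seed=config.seed + 1)
    if config.burden_path:
        burden = pd.read_csv(config.burden_path)
    else:
        geos = sorted(survey.persons["region"].unique().tolist())
        burden = generate_burden_table([survey.geography_label] + geos)
    dr = (DoseResponse.from_csv(config.dose_response_path)
          if config.dose_response_path else DoseResponse.default())

    prop = estimate_propensity(survey)
    speeds = estimate_speeds(survey)
    ebike = build_ebike_tables(
        {k: v for k, v in default_ebike_reference(prop.bands).items()
         if k != "bands"}, prop.bands)

    nontravel = fuse_nontravel(survey, activity, seed=config.seed + 2,
                               intensities=intensities)
    base_profiles = activity_profiles(survey, nontravel, intensities)
    base_report = outcome_report(survey, emissions=emissions)
    base_low, base_high = guideline_attainment(base_profiles, intensities)
    base_report["pct_meeting_low_guideline"] = 100 * base_low
    base_report["pct_meeting_high_guideline"] = 100 * base_high
    base_report["mean_total_mmeth"] = mean_mmeth(base_profiles)
    base_report["cyclist_prevalence"] = cyclist_prevalence(survey)

    if config.enumerate_all:
        regions = sorted(survey.persons["region"].unique().tolist())
        baselines = {survey.geography_label: cyclist_prevalence(survey)}
        for r in regions:
            baselines[r] = cyclist_prevalence(_subsurvey(survey, r))
        specs = enumerate_scenarios(baselines, global_seed=config.seed)
    else:
        specs = []
        for sc in config.scenarios:
            spec = ScenarioSpec(geography=sc.get("geography",
                                                 survey.geography_label),
                                target_pct=int(sc["target_pct"]),
                                equity=bool(sc.get("equity", False)),
                                ebike=bool(sc.get("ebike", False)))
            specs.append(ScenarioSpec(
                geography=spec.geography, target_pct=spec.target_pct,
                equity=spec.equity, ebike=spec.ebike,
                seed=scenario_seed(config.seed, spec)))

    stratum_prev = stratum_prevalences(survey)
    results = {}
    for spec in specs:
        try:
            geo_survey = _subsurvey(survey, spec.geography)
            baseline_prev = cyclist_prevalence(geo_survey)
            res = run_scenario(geo_survey, spec, prop, speeds,
                               ebike_tables=ebike,
                               baseline_prevalence=baseline_prev,
                               stratum_prevalence=stratum_prev)
            sc_profiles = activity_profiles(res.survey, nontravel, intensities)
            geo_base_profiles = base_profiles.loc[
                base_profiles["person_id"].isin(
                    set(geo_survey.persons["person_id"]))]
            report = outcome_report(geo_survey, res, emissions=emissions)
            low, high = guideline_attainment(sc_profiles, intensities)
            report["pct_meeting_low_guideline"] = 100 * low
            report["pct_meeting_high_guideline"] = 100 * high
            report["mean_total_mmeth"] = mean_mmeth(sc_profiles)
            pifs = compute_pifs(geo_survey.persons, geo_base_profiles,
                                sc_profiles, dr, spec.geography)
            geo_burden = burden.loc[burden["geography"] == spec.geography]
            if len(geo_burden):
                health = yll_averted(pifs, geo_burden)
                report["health"] = {k: v for k, v in health.items()
                                    if k != "by_stratum"}
                health["by_stratum"].to_csv(
                    out_dir / f"{spec.scenario_id}_health.csv", index=False)
            results[spec.scenario_id] = report
            write_survey(res.survey,
                         out_dir / f"{spec.scenario_id}_persons.csv",
                         out_dir / f"{spec.scenario_id}_trips.csv")
            res.group_by_person.rename_axis("person_id").reset_index().to_csv(
                out_dir / f"{spec.scenario_id}_groups.csv", index=False)
        except Exception as exc:
            raise type(exc)(
                f"scenario {spec.scenario_id}: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "global_seed": config.seed,
        "scenario_seeds": {s.scenario_id: s.seed for s in specs},
        "input_digests": {
            "persons": _digest(config.persons_path or config.synthetic_population),
            "trips": _digest(config.trips_path or config.synthetic_population),
            "activity": _digest(config.activity_path or config.synthetic_activity_n),
            "burden": _digest(config.burden_path or "synthetic-default"),
            "dose_response": _digest(config.dose_response_path or "bundled-default"),
        },
        "n_scenarios": len(specs),
    }
    payload = {"baseline": base_report, "scenarios": results,
               "manifest": manifest}
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2,
                                                     default=float))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return payload
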