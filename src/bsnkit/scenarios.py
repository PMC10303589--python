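"""Named design scenarios, case-study runner and report writers.

The built-in scenarios are the four sports-injury monitoring cases used to
exercise the model — tennis elbow, runner's knee, shin splints and heel
inflammation — plus shin-splints variants at longer monitoring times with a
raised readout requirement.  Scenarios round-trip through a small YAML/JSON
config schema (units: seconds, cm/s, cm, minutes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import yaml

from .errors import InfeasibleSiteError, ScenarioFormatError
from .hemodynamics import (
    BodySegmentParams,
    expected_path_length,
    path_length,
    sample_velocity_series,
    validate_physiology,
)
from .readout_model import (
    CollectorSpec,
    FeasibleRange,
    MonitoringSpec,
    ReadoutCurve,
    feasible_sensor_range,
    optimal_sensor_count,
    pass_probability,
    readout_curve,
)
from .sss import SSSResult, smart_sensor_selection

__all__ = [
    "Scenario",
    "CaseStudyReport",
    "builtin_scenarios",
    "get_scenario",
    "load_scenario",
    "save_scenario",
    "run_case_study",
    "multi_site_minimum",
    "write_report",
]


@dataclass(frozen=True)
class Scenario:
    """A named design problem: physiology, collector, session and requirement."""

    name: str
    segment: BodySegmentParams
    collector: CollectorSpec
    monitoring: MonitoringSpec
    s_min: float

    def __post_init__(self) -> None:
        if self.s_min < 1:
            raise ScenarioFormatError([f"s_min must be >= 1, got {self.s_min}"])


@dataclass(frozen=True)
class CaseStudyReport:
    """Everything a single-site design run computes, plus run metadata."""

    scenario: Scenario
    mode: str
    seed: Optional[int]
    l: float
    p_c: float
    curve: ReadoutCurve
    optimal_n: int
    max_s_floor: int
    feasible_range: FeasibleRange
    sss: SSSResult
    timestamp: str = ""

    def summary(self) -> dict:
        """JSON-serializable summary (deterministic apart from the timestamp)."""
        rng = self.feasible_range
        return {
            "scenario": self.scenario.name,
            "mode": self.mode,
            "seed": self.seed,
            "path_length_cm": self.l,
            "pass_probability": self.p_c,
            "optimal_n": self.optimal_n,
            "max_readouts_floor": self.max_s_floor,
            "s_min": self.s_min,
            "feasible_n_min": rng.n_min,
            "feasible_n_max": rng.n_max,
            "sss_n": self.sss.n,
            "sss_readouts_floor": self.sss.s,
            "sss_feasible": self.sss.feasible,
            "timestamp": self.timestamp,
        }

    @property
    def s_min(self) -> float:
        return self.scenario.s_min


def builtin_scenarios() -> list[Scenario]:
    """The bundled case-study scenarios.

    Four base sites (required readouts 100, 10-minute sessions) and three
    shin-splints monitoring-time variants (required readouts 250 at 10, 12
    and 14 minutes).
    """
    elbow = BodySegmentParams(t_c=50, v_min=1.5, v_max=19.0)
    leg = BodySegmentParams(t_c=60, v_min=3.0, v_max=15.0)
    tm10 = MonitoringSpec(duration_minutes=10.0)
    shin = CollectorSpec(w=50.0, site="shin")
    scenarios = [
        Scenario("tennis_elbow", elbow, CollectorSpec(w=20.0, site="elbow"), tm10, 100),
        Scenario("runners_knee", leg, CollectorSpec(w=15.0, site="knee"), tm10, 100),
        Scenario("shin_splints", leg, shin, tm10, 100),
        Scenario("heel_inflammation", leg, CollectorSpec(w=10.0, site="heel"), tm10, 100),
    ]
    for minutes in (10.0, 12.0, 14.0):
        scenarios.append(
            Scenario(
                f"shin_splints_tm{int(minutes)}",
                leg,
                shin,
                MonitoringSpec(duration_minutes=minutes),
                250,
            )
        )
    return scenarios


def get_scenario(name: str) -> Scenario:
    """Look up a built-in scenario by name."""
    for scenario in builtin_scenarios():
        if scenario.name == name:
            return scenario
    known = ", ".join(s.name for s in builtin_scenarios())
    raise KeyError(f"unknown scenario {name!r}; built-ins: {known}")


# ------------------------------------------------------------------ config IO

_SEGMENT_KEYS = {"t_c", "v_min", "v_max", "q_min", "q_max", "r_min", "r_max"}


def scenario_to_dict(scenario: Scenario) -> dict:
    segment = {
        k: v
        for k, v in dataclasses.asdict(scenario.segment).items()
        if v is not None
    }
    return {
        "name": scenario.name,
        "segment": segment,
        "collector": {"w": scenario.collector.w, "site": scenario.collector.site},
        "monitoring": {
            "duration_minutes": scenario.monitoring.duration_minutes,
            "opportunity_rate": scenario.monitoring.opportunity_rate,
        },
        "s_min": scenario.s_min,
    }


def save_scenario(scenario: Scenario, path) -> None:
    """Write a scenario config as YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    payload = scenario_to_dict(scenario)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def load_scenario(path) -> Scenario:
    """Parse and validate a YAML/JSON scenario config.

    Units are fixed by the schema: ``t_c`` seconds, velocities cm/s, ``w`` cm,
    monitoring duration minutes.  Raises :class:`ScenarioFormatError` listing
    every offending field.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ScenarioFormatError([f"unparseable config: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ScenarioFormatError(["config root must be a mapping"])

    problems: list[str] = []
    for key in ("name", "segment", "collector", "monitoring", "s_min"):
        if key not in raw:
            problems.append(f"missing required field '{key}'")
    if problems:
        raise ScenarioFormatError(problems)

    segment_raw = raw["segment"] if isinstance(raw["segment"], dict) else {}
    unknown = set(segment_raw) - _SEGMENT_KEYS
    if unknown:
        problems.append(f"unknown segment fields: {sorted(unknown)}")
    collector_raw = raw["collector"] if isinstance(raw["collector"], dict) else {}
    if "w" not in collector_raw:
        problems.append("missing required field 'w' in collector")
    monitoring_raw = raw["monitoring"] if isinstance(raw["monitoring"], dict) else {}
    if "duration_minutes" not in monitoring_raw:
        problems.append("missing required field 'duration_minutes' in monitoring")
    if problems:
        raise ScenarioFormatError(problems)

    try:
        segment = BodySegmentParams(**segment_raw)
        collector = CollectorSpec(
            w=collector_raw["w"], site=collector_raw.get("site", "")
        )
        monitoring = MonitoringSpec(
            duration_minutes=monitoring_raw["duration_minutes"],
            opportunity_rate=monitoring_raw.get("opportunity_rate", 1.0),
        )
        return Scenario(
            name=str(raw["name"]),
            segment=segment,
            collector=collector,
            monitoring=monitoring,
            s_min=raw["s_min"],
        )
    except (ScenarioFormatError, ValueError, TypeError) as exc:
        raise ScenarioFormatError([str(exc)]) from exc


# ------------------------------------------------------------------ analyses

# Curves are swept to a multiple of the analytic peak so the post-peak decline
# is always visible in exports.
CURVE_SWEEP_FACTOR = 3


def run_case_study(
    scenario: Scenario,
    mode: Literal["expectation", "stochastic"] = "expectation",
    seed: Optional[int] = None,
) -> CaseStudyReport:
    """Full single-site analysis of a scenario.

    Computes the path length (expectation or one seeded draw), the pass
    probability, the readout curve up to three times the peak count, the
    optimal count and its floored readouts, the feasible range for the
    scenario's requirement, and the incremental sensor-selection result.
    Expectation-mode results are seed-invariant.
    """
    if mode == "expectation":
        l = expected_path_length(scenario.segment)
    else:
        l = path_length(sample_velocity_series(scenario.segment, seed=seed))
    p_c = pass_probability(scenario.collector, l)
    optimal_n = optimal_sensor_count(p_c)
    curve = readout_curve(p_c, CURVE_SWEEP_FACTOR * optimal_n, scenario.monitoring)
    rng = feasible_sensor_range(p_c, scenario.s_min, scenario.monitoring)
    sss = smart_sensor_selection(
        scenario.monitoring, scenario.s_min, scenario.segment, scenario.collector,
        mode=mode, seed=seed,
    )
    return CaseStudyReport(
        scenario=scenario,
        mode=mode,
        seed=seed,
        l=l,
        p_c=p_c,
        curve=curve,
        optimal_n=optimal_n,
        max_s_floor=curve.peak.s_floor,
        feasible_range=rng,
        sss=sss,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def multi_site_minimum(
    scenarios: Sequence[Scenario],
    s_min: Optional[float] = None,
    mode: Literal["expectation", "stochastic"] = "expectation",
    seed: Optional[int] = None,
) -> int:
    """Minimum size of one shared sensor pool serving every site.

    One circulating pool visits all collectors, so the pool must be at least
    each site's own minimal feasible count: the answer is the maximum of the
    per-site minima.  ``s_min`` overrides every scenario's own requirement
    when given.

    Raises
    ------
    InfeasibleSiteError
        Naming the first site whose requirement cannot be met at any count.
    """
    if not scenarios:
        raise ScenarioFormatError(["multi_site_minimum needs at least one scenario"])
    minima = []
    for scenario in scenarios:
        requirement = scenario.s_min if s_min is None else s_min
        result = smart_sensor_selection(
            scenario.monitoring, requirement, scenario.segment, scenario.collector,
            mode=mode, seed=seed,
        )
        if not result.feasible:
            raise InfeasibleSiteError(scenario.name)
        minima.append(result.n)
    return max(minima)


def write_report(
    report: CaseStudyReport, out_dir, formats: Iterable[str] = ("csv", "json")
) -> dict[str, Path]:
    """Write the curve CSV (n, p_s, s, s_floor) and/or the summary JSON.

    Outputs are bit-stable for fixed inputs and seed, except for the
    timestamp field in the JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    formats = set(formats)
    unknown = formats - {"csv", "json"}
    if unknown:
        raise ScenarioFormatError([f"unknown report formats: {sorted(unknown)}"])
    if "csv" in formats:
        csv_path = out_dir / f"{report.scenario.name}_curve.csv"
        report.curve.to_csv(csv_path)
        written["csv"] = csv_path
    if "json" in formats:
        json_path = out_dir / f"{report.scenario.name}_summary.json"
        json_path.write_text(json.dumps(report.summary(), indent=2, sort_keys=True) + "\n")
        written["json"] = json_path
    return written


def physiology_report(scenario: Scenario):
    """Physiological plausibility check of a scenario's parameters."""
    return validate_physiology(scenario.segment, scenario.monitoring)
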