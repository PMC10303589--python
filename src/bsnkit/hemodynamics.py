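"""Blood-circulation transport of in-body sensors.

In-body chemical sensors drift passively with the blood, so their speed is the
blood's bulk velocity v = Q / A, with A = pi r^2 the vessel cross-section.  Over
one circulation of duration ``t_c`` seconds the sensor covers the loop length

    L = integral_0^{T_C} v(t) dt,

discretized here on a 1-second grid (left Riemann sum).  Two parameterizations
are supported: direct velocity bounds (the form used in the case studies) and
volumetric-flow / vessel-radius bounds (the form used by the sensor-selection
pseudocode).  Two evaluation modes are supported: a seeded stochastic draw of
the per-second velocity trajectory, and a deterministic expectation mode that
uses the mean velocity — the mode all design computations default to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import DomainError, UnsupportedModeError

__all__ = [
    "BodySegmentParams",
    "VelocitySeries",
    "PhysiologyCheckReport",
    "Violation",
    "velocity_from_flow",
    "sample_velocity_series",
    "path_length",
    "expected_path_length",
    "validate_physiology",
    "CIRCULATION_TIME_BOUNDS_S",
    "VESSEL_RADIUS_BOUNDS_CM",
    "MONITORING_TO_CIRCULATION_RATIO",
]

# Physiological plausibility bounds used by validate_physiology.
# Whole-body circulation time: typical human values span 45-60 s.
CIRCULATION_TIME_BOUNDS_S = (45.0, 60.0)
# Vessel radius: 4 um (capillary) to 12.5 mm (aorta), in cm.
VESSEL_RADIUS_BOUNDS_CM = (4e-4, 1.25)
# Monitoring must be much longer than one circulation; "much" is taken as 10x.
MONITORING_TO_CIRCULATION_RATIO = 10.0


def velocity_from_flow(q: float, r: float) -> float:
    """Blood velocity (cm/s) from volumetric flow ``q`` (mL/s) and vessel radius ``r`` (cm).

    v = q / (pi r^2): the bulk velocity through a circular cross-section.

    Raises
    ------
    DomainError
        If ``q`` or ``r`` is not strictly positive.
    """
    if q <= 0:
        raise DomainError(f"volumetric flow must be positive, got q={q}")
    if r <= 0:
        raise DomainError(f"vessel radius must be positive, got r={r}")
    return q / (math.pi * r * r)


@dataclass(frozen=True)
class BodySegmentParams:
    """Physiological parameters of the monitored circulation loop.

    Exactly one parameterization is active:

    * ``mode="velocity"`` — per-second velocity drawn uniformly on
      ``[v_min, v_max]`` (cm/s).  This is the primary form; the case studies
      state velocity ranges directly.
    * ``mode="flow"`` — per-second flow ``Q`` uniform on ``[q_min, q_max]``
      (mL/s) and radius ``r`` uniform on ``[r_min, r_max]`` (cm), with
      v = Q / (pi r^2).

    ``t_c`` is the whole-body circulation time in seconds, treated as an
    integer count of 1-s steps.
    """

    t_c: int
    v_min: Optional[float] = None
    v_max: Optional[float] = None
    q_min: Optional[float] = None
    q_max: Optional[float] = None
    r_min: Optional[float] = None
    r_max: Optional[float] = None

    def __post_init__(self) -> None:
        if int(self.t_c) != self.t_c or self.t_c <= 0:
            raise DomainError(f"t_c must be a positive integer number of seconds, got {self.t_c}")
        has_v = self.v_min is not None or self.v_max is not None
        has_flow = any(x is not None for x in (self.q_min, self.q_max, self.r_min, self.r_max))
        if has_v and has_flow:
            raise DomainError("give either velocity bounds or flow/radius bounds, not both")
        if has_v:
            if self.v_min is None or self.v_max is None:
                raise DomainError("velocity mode needs both v_min and v_max")
            if not (0 < self.v_min <= self.v_max):
                raise DomainError(f"need 0 < v_min <= v_max, got [{self.v_min}, {self.v_max}]")
        elif has_flow:
            if None in (self.q_min, self.q_max, self.r_min, self.r_max):
                raise DomainError("flow mode needs q_min, q_max, r_min and r_max")
            if not (0 < self.q_min <= self.q_max):
                raise DomainError(f"need 0 < q_min <= q_max, got [{self.q_min}, {self.q_max}]")
            if not (0 < self.r_min <= self.r_max):
                raise DomainError(f"need 0 < r_min <= r_max, got [{self.r_min}, {self.r_max}]")
        else:
            raise DomainError("no parameterization given (velocity or flow/radius bounds)")

    @property
    def mode(self) -> Literal["velocity", "flow"]:
        return "velocity" if self.v_min is not None else "flow"


@dataclass(frozen=True)
class VelocitySeries:
    """Per-second velocity trajectory (cm/s) over one circulation.

    ``seed`` records the RNG seed that produced a stochastic draw; it is
    ``None`` for deterministic (expectation-mode) series.
    """

    values: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise DomainError("velocity series must be a non-empty 1-D array")
        if np.any(self.values <= 0):
            raise DomainError("velocities must be strictly positive")

    def __len__(self) -> int:
        return int(self.values.size)


def sample_velocity_series(params: BodySegmentParams, seed: Optional[int] = None) -> VelocitySeries:
    """Draw one random per-second velocity trajectory of length ``params.t_c``.

    Velocity mode draws v(i) ~ Uniform[v_min, v_max]; flow mode draws
    r(i) ~ Uniform[r_min, r_max] and Q(i) ~ Uniform[q_min, q_max] independently
    and sets v(i) = Q(i) / (pi r(i)^2).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    t_c = int(params.t_c)
    if params.mode == "velocity":
        values = rng.uniform(params.v_min, params.v_max, size=t_c)
    else:
        r = rng.uniform(params.r_min, params.r_max, size=t_c)
        q = rng.uniform(params.q_min, params.q_max, size=t_c)
        values = q / (math.pi * r * r)
    return VelocitySeries(values=values, seed=seed)


def path_length(series: VelocitySeries | Sequence[float]) -> float:
    """Circulation path length L (cm): sum of per-second velocities times dt = 1 s."""
    values = series.values if isinstance(series, VelocitySeries) else np.asarray(series, dtype=float)
    if values.size == 0:
        raise DomainError("cannot integrate an empty velocity series")
    return float(values.sum())


def expected_path_length(params: BodySegmentParams) -> float:
    """Closed-form E[L] = mean velocity x t_c for velocity-mode parameters.

    The flow/radius parameterization has no elementary mean velocity
    (E[Q / (pi r^2)] involves the reciprocal-square of a uniform variate), so
    it must be estimated by sampling instead.
    """
    if params.mode != "velocity":
        raise UnsupportedModeError(
            "expected_path_length needs velocity-mode bounds; "
            "estimate flow-mode E[L] by averaging sampled path lengths"
        )
    return 0.5 * (params.v_min + params.v_max) * params.t_c


@dataclass(frozen=True)
class Violation:
    parameter: str
    value: float
    bound: str
    severity: Literal["warning", "error"]


@dataclass(frozen=True)
class PhysiologyCheckReport:
    """Outcome of plausibility checks; empty ``violations`` means all pass."""

    violations: tuple[Violation, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def has_errors(self) -> bool:
        return any(v.severity == "error" for v in self.violations)


def validate_physiology(params: BodySegmentParams, monitoring=None) -> PhysiologyCheckReport:
    """Check parameters against physiological plausibility bounds.

    Flags (never raises):

    * circulation time outside 45-60 s — warning, so pathological cases stay
      explorable;
    * vessel radii outside 4 um - 12.5 mm (flow mode) — error, the anatomy
      cannot supply such vessels;
    * monitoring duration shorter than 10 circulations — warning, the
      steady-state occupancy picture behind the pass probability needs many
      loops to average over.

    ``monitoring`` is an optional :class:`~bsnkit.readout_model.MonitoringSpec`.
    """
    violations: list[Violation] = []
    t_lo, t_hi = CIRCULATION_TIME_BOUNDS_S
    if not (t_lo <= params.t_c <= t_hi):
        violations.append(
            Violation("t_c", float(params.t_c), f"[{t_lo:g}, {t_hi:g}] s", "warning")
        )
    if params.mode == "flow":
        r_lo, r_hi = VESSEL_RADIUS_BOUNDS_CM
        for name, value in (("r_min", params.r_min), ("r_max", params.r_max)):
            if not (r_lo <= value <= r_hi):
                violations.append(
                    Violation(name, float(value), f"[{r_lo:g}, {r_hi:g}] cm", "error")
                )
    if monitoring is not None:
        duration_s = monitoring.duration_minutes * 60.0
        floor = MONITORING_TO_CIRCULATION_RATIO * params.t_c
        if duration_s < floor:
            violations.append(
                Violation("duration_minutes", float(monitoring.duration_minutes),
                          f">= {floor / 60.0:g} min (10 circulations)", "warning")
            )
    return PhysiologyCheckReport(violations=tuple(violations))
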