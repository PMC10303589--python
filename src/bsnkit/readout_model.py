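"""Collision-aware readout model: the analytic core.

A wearable collector of length ``w`` covers a fraction ``P_C = w / L`` of the
circulation loop of length ``L``, so at any transmission opportunity each
sensor is independently in the collector window with probability ``P_C``.  A
readout is collected only when exactly one of the ``n`` sensors is in the
window (two or more collide), hence the per-sensor success probability

    P_S = P_C (1 - P_C)^(n-1)

and the expected readouts over a monitoring session with ``K`` transmission
opportunities

    S(n) = n P_C (1 - P_C)^(n-1) K.

S(n) is unimodal in n: the ratio S(n+1)/S(n) = ((n+1)/n)(1 - P_C) crosses 1
exactly once, so the integer argmax has the closed form floor(1 / P_C) (at an
exact tie the larger count realizes it) and the set {n : S(n) >= S_min} is a
contiguous interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, InfeasibleGeometryError, SearchBoundError

__all__ = [
    "CollectorSpec",
    "MonitoringSpec",
    "DesignPoint",
    "ReadoutCurve",
    "FeasibleRange",
    "pass_probability",
    "success_probability",
    "expected_readouts",
    "readout_curve",
    "optimal_sensor_count",
    "feasible_sensor_range",
]


@dataclass(frozen=True)
class CollectorSpec:
    """Wearable data collector: length ``w`` in cm and the body site it covers."""

    w: float
    site: str = ""

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise DomainError(f"collector length must be positive, got w={self.w}")


@dataclass(frozen=True)
class MonitoringSpec:
    """Monitoring session: duration in minutes and transmission opportunities per second.

    The readout expectation multiplies a per-opportunity probability by the
    number of opportunities; with the default ``opportunity_rate`` of one per
    second a 10-minute session offers 600 opportunities.
    """

    duration_minutes: float
    opportunity_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_minutes <= 0:
            raise DomainError(f"monitoring duration must be positive, got {self.duration_minutes}")
        if self.opportunity_rate <= 0:
            raise DomainError(f"opportunity rate must be positive, got {self.opportunity_rate}")

    @property
    def opportunities(self) -> float:
        """Total transmission opportunities in the session."""
        return self.duration_minutes * 60.0 * self.opportunity_rate


@dataclass(frozen=True)
class DesignPoint:
    """One evaluated sensor count: probabilities and expected readouts.

    ``s`` is the real-valued expectation; ``s_floor`` is the integer reported
    to practitioners (readouts are counts, so display floors).
    """

    n: int
    p_c: float
    p_s: float
    s: float

    @property
    def s_floor(self) -> int:
        return int(math.floor(self.s))


@dataclass(frozen=True)
class ReadoutCurve:
    """Expected readouts for n = 1..n_max; unimodal with a single interior or edge peak."""

    points: tuple[DesignPoint, ...]

    @property
    def peak(self) -> DesignPoint:
        return max(self.points, key=lambda p: (p.s, p.n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": [p.n for p in self.points],
                "p_s": [p.p_s for p in self.points],
                "s": [p.s for p in self.points],
                "s_floor": [p.s_floor for p in self.points],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class FeasibleRange:
    """Contiguous interval of sensor counts meeting the readout requirement.

    Empty when even the peak of the readout curve falls short.
    """

    n_min: Optional[int] = None
    n_max: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.n_min is None) != (self.n_max is None):
            raise DomainError("n_min and n_max must both be set or both be None")
        if self.n_min is not None and self.n_min > self.n_max:
            raise DomainError(f"need n_min <= n_max, got [{self.n_min}, {self.n_max}]")

    @property
    def empty(self) -> bool:
        return self.n_min is None

    def __contains__(self, n: int) -> bool:
        return not self.empty and self.n_min <= n <= self.n_max


def pass_probability(collector: CollectorSpec, l: float) -> float:
    """Probability P_C = w / L that a sensor sits in the collector window.

    Raises
    ------
    InfeasibleGeometryError
        If the collector is as long as the loop (w >= L), where the
        probability would leave (0, 1).
    """
    if l <= 0:
        raise DomainError(f"path length must be positive, got L={l}")
    if collector.w >= l:
        raise InfeasibleGeometryError(
            f"collector length w={collector.w} cm must be shorter than the "
            f"circulation path L={l} cm"
        )
    return collector.w / l


def success_probability(p_c: float, n: int) -> float:
    """P_S = P_C (1 - P_C)^(n-1): one chosen sensor in-window, the other n-1 out."""
    _check_p_c(p_c)
    if n < 1 or int(n) != n:
        raise DomainError(f"sensor count must be a positive integer, got n={n}")
    return p_c * (1.0 - p_c) ** (n - 1)


def expected_readouts(p_c: float, n: int, monitoring: MonitoringSpec) -> DesignPoint:
    """Expected readouts S(n) = n P_S K over the session's K opportunities.

    Returns a :class:`DesignPoint` carrying both the real expectation ``s``
    and the floored integer ``s_floor``.
    """
    p_s = success_probability(p_c, n)
    return DesignPoint(n=int(n), p_c=p_c, p_s=p_s, s=n * p_s * monitoring.opportunities)


def readout_curve(p_c: float, n_max: int, monitoring: MonitoringSpec) -> ReadoutCurve:
    """Evaluate the readout expectation for every n in 1..n_max."""
    if n_max < 1:
        raise DomainError(f"n_max must be >= 1, got {n_max}")
    _check_p_c(p_c)
    n = np.arange(1, int(n_max) + 1)
    s = n * p_c * (1.0 - p_c) ** (n - 1) * monitoring.opportunities
    points = tuple(
        DesignPoint(n=int(ni), p_c=p_c, p_s=p_c * (1.0 - p_c) ** (int(ni) - 1), s=float(si))
        for ni, si in zip(n, s)
    )
    return ReadoutCurve(points=points)


def optimal_sensor_count(p_c: float) -> int:
    """Integer argmax of n P_C (1 - P_C)^(n-1), in closed form floor(1 / P_C).

    The ratio test shows S(n+1) >= S(n) iff n <= (1 - P_C) / P_C, so the
    maximizer is floor(1/P_C); when (1 - P_C)/P_C is an integer the two
    adjacent counts tie and floor(1/P_C) returns the larger one.
    """
    _check_p_c(p_c)
    return max(1, int(math.floor(1.0 / p_c)))


def feasible_sensor_range(
    p_c: float,
    s_min: float,
    monitoring: MonitoringSpec,
    n_cap: int = 1_000_000,
) -> FeasibleRange:
    """Interval of sensor counts with S(n) >= s_min (unfloored comparison).

    By unimodality the feasible set is contiguous: scan up from 1 to the peak
    for the lower edge, then down the post-peak tail for the upper edge.
    Returns an empty range when the peak itself falls short.

    Raises
    ------
    SearchBoundError
        If the decreasing tail has not dropped below ``s_min`` within
        ``n_cap`` sensors (only possible for tiny p_c with huge budgets).
    """
    if s_min < 1:
        raise DomainError(f"required readouts must be >= 1, got s_min={s_min}")
    n_star = optimal_sensor_count(p_c)
    if expected_readouts(p_c, n_star, monitoring).s < s_min:
        return FeasibleRange()
    n_min = next(
        n for n in range(1, n_star + 1) if expected_readouts(p_c, n, monitoring).s >= s_min
    )
    n = n_star
    while expected_readouts(p_c, n + 1, monitoring).s >= s_min:
        n += 1
        if n > n_cap:
            raise SearchBoundError(f"feasible range upper edge not closed within n_cap={n_cap}")
    return FeasibleRange(n_min=n_min, n_max=n)


def _check_p_c(p_c: float) -> None:
    if not (0.0 < p_c < 1.0):
        raise DomainError(f"pass probability must lie strictly in (0, 1), got {p_c}")
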