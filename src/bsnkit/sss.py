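"""Smart Sensor Selection: minimum sensor count meeting a readout requirement.

The procedure mirrors the incremental design search: compute the circulation
path length L (one seeded stochastic draw, or the deterministic mean-velocity
expectation), derive the pass probability P_C = w/L, then try n = 1, 2, ...
until the expected readouts reach S_min.  The expectation S(n) is unimodal in
n, so once n passes the analytic peak floor(1/P_C) with S still short the
requirement is unattainable and the search stops with ``feasible=False``
(the search as literally specified would never terminate on such inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .hemodynamics import (
    BodySegmentParams,
    expected_path_length,
    path_length,
    sample_velocity_series,
)
from .readout_model import (
    CollectorSpec,
    MonitoringSpec,
    expected_readouts,
    optimal_sensor_count,
    pass_probability,
)

__all__ = ["SSSResult", "smart_sensor_selection"]


@dataclass(frozen=True)
class SSSResult:
    """Outcome of the sensor-count search.

    ``n`` is the selected count (the peak count when infeasible), ``s`` the
    floored readouts achieved at ``n``, ``l`` the path length used, and
    ``evaluations`` the number of candidate counts tried.
    """

    n: int
    s: int
    l: float
    feasible: bool
    evaluations: int


def smart_sensor_selection(
    monitoring: MonitoringSpec,
    s_min: float,
    params: BodySegmentParams,
    collector: CollectorSpec,
    mode: Literal["expectation", "stochastic"] = "expectation",
    seed: Optional[int] = None,
) -> SSSResult:
    """Find the smallest sensor count n with expected readouts S(n) >= s_min.

    In ``expectation`` mode L is the closed-form mean-velocity path length
    (deterministic; reproduces the printed case-study designs).  In
    ``stochastic`` mode L comes from one seeded per-second velocity draw, as
    a single patient realization would.

    Feasibility compares the unfloored expectation to ``s_min``; the reported
    ``s`` is floored for display.
    """
    if s_min < 1:
        from .errors import DomainError

        raise DomainError(f"required readouts must be >= 1, got s_min={s_min}")
    if mode == "expectation":
        l = expected_path_length(params)
    elif mode == "stochastic":
        l = path_length(sample_velocity_series(params, seed=seed))
    else:
        from .errors import DomainError

        raise DomainError(f"mode must be 'expectation' or 'stochastic', got {mode!r}")

    p_c = pass_probability(collector, l)
    n_peak = optimal_sensor_count(p_c)
    evaluations = 0
    for m in range(1, n_peak + 1):
        evaluations += 1
        point = expected_readouts(p_c, m, monitoring)
        if point.s >= s_min:
            return SSSResult(n=m, s=point.s_floor, l=l, feasible=True, evaluations=evaluations)
    # Past the peak S(n) only decreases: the requirement is unattainable.
    peak_point = expected_readouts(p_c, n_peak, monitoring)
    return SSSResult(
        n=n_peak, s=peak_point.s_floor, l=l, feasible=False, evaluations=evaluations
    )
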