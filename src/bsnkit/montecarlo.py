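"""Discrete-event Monte Carlo oracle for the collision-aware readout model.

Each transmission opportunity is simulated mechanistically: every one of the
``n`` sensors is independently inside the collector window with probability
``p_c`` and transmits if it is; a readout is collected iff exactly one sensor
transmits (two or more collide, zero means silence).  The per-opportunity
success count is therefore Binomial(n, p_c) evaluated at exactly 1, whose
probability is n p_c (1 - p_c)^(n-1) — the quantity the analytic model
multiplies by the opportunity count.  Simulated means are compared to that
expectation with a z-test over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError

__all__ = [
    "SimulationResult",
    "ComparisonReport",
    "simulate_monitoring",
    "run_replicates",
    "compare_to_analytic",
]


@dataclass(frozen=True)
class SimulationResult:
    """Readout totals from seeded replicates of one monitoring session."""

    replicate_counts: np.ndarray
    n: int
    p_c: float
    opportunities: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "replicate_counts", np.asarray(self.replicate_counts, dtype=np.int64)
        )

    @property
    def mean(self) -> float:
        return float(self.replicate_counts.mean())

    @property
    def sd(self) -> float:
        return float(self.replicate_counts.std(ddof=1)) if self.replicate_counts.size > 1 else 0.0

    @property
    def replicates(self) -> int:
        return int(self.replicate_counts.size)


@dataclass(frozen=True)
class ComparisonReport:
    """Z-test of a simulated mean against the analytic expectation (3-sigma gate)."""

    empirical_mean: float
    analytic_mean: float
    z: float
    passed: bool


def _check_args(n: int, p_c: float, opportunities: int) -> None:
    if n < 1 or int(n) != n:
        raise DomainError(f"sensor count must be a positive integer, got n={n}")
    if not (0.0 < p_c < 1.0):
        raise DomainError(f"pass probability must lie strictly in (0, 1), got {p_c}")
    if opportunities < 1:
        raise DomainError(f"need at least one opportunity, got {opportunities}")


def simulate_monitoring(
    n: int, p_c: float, opportunities: int, seed: Optional[int] = None
) -> int:
    """Total readouts collected in one simulated session.

    Draws, per opportunity, the number of in-window sensors ~ Binomial(n, p_c)
    and counts the opportunities where that number is exactly 1.
    Deterministic for a fixed seed.
    """
    _check_args(n, p_c, opportunities)
    rng = np.random.default_rng(seed)
    in_window = rng.binomial(n, p_c, size=int(opportunities))
    return int(np.count_nonzero(in_window == 1))


def run_replicates(
    n: int, p_c: float, opportunities: int, replicates: int, seed: Optional[int] = None
) -> SimulationResult:
    """Repeat :func:`simulate_monitoring` with independent per-replicate streams.

    A seed sequence spawns one child stream per replicate, so replicates are
    statistically independent yet fully reproducible from the single seed.
    """
    _check_args(n, p_c, opportunities)
    if replicates < 1:
        raise DomainError(f"need at least one replicate, got {replicates}")
    children = np.random.SeedSequence(seed).spawn(int(replicates))
    counts = np.empty(int(replicates), dtype=np.int64)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        counts[i] = np.count_nonzero(rng.binomial(n, p_c, size=int(opportunities)) == 1)
    return SimulationResult(
        replicate_counts=counts, n=int(n), p_c=p_c, opportunities=int(opportunities), seed=seed
    )


def compare_to_analytic(result: SimulationResult) -> ComparisonReport:
    """Z-score of the replicate mean against n p_c (1-p_c)^(n-1) x opportunities.

    Passes iff |z| <= 3.  With zero replicate variance the test passes only
    when the mean matches the expectation exactly (a degenerate but honest
    verdict; it needs at least 2 replicates for a standard error).
    """
    if result.replicates < 2:
        raise DomainError("compare_to_analytic needs at least 2 replicates")
    analytic = (
        result.n * result.p_c * (1.0 - result.p_c) ** (result.n - 1) * result.opportunities
    )
    diff = result.mean - analytic
    se = result.sd / np.sqrt(result.replicates)
    if se == 0.0:
        z = 0.0 if diff == 0.0 else float("inf") * np.sign(diff)
    else:
        z = diff / se
    return ComparisonReport(
        empirical_mean=result.mean, analytic_mean=analytic, z=float(z), passed=bool(abs(z) <= 3.0)
    )
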