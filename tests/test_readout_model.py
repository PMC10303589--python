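"""Analytic readout model: probabilities, curves, argmax and feasible ranges."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bsnkit import (
    CollectorSpec,
    DomainError,
    InfeasibleGeometryError,
    MonitoringSpec,
    expected_readouts,
    feasible_sensor_range,
    optimal_sensor_count,
    pass_probability,
    readout_curve,
    success_probability,
)

TM10 = MonitoringSpec(duration_minutes=10.0)


def brute_force_argmax(p_c: float, n_hi: int = 10_000) -> int:
    """Independent oracle: enumerate n p_c (1-p_c)^(n-1), ties to larger n."""
    best_n, best_s = 1, p_c
    for n in range(2, n_hi + 1):
        s = n * p_c * (1.0 - p_c) ** (n - 1)
        if s >= best_s:
            best_n, best_s = n, s
    return best_n


class TestPassProbability:
    @pytest.mark.parametrize(
        "w, l, expected",
        [(20.0, 512.5, 20.0 / 512.5), (15.0, 540.0, 1.0 / 36.0), (5.0, 10.0, 0.5)],
    )
    def test_window_fraction_of_loop(self, w, l, expected):
        assert pass_probability(CollectorSpec(w=w), l) == pytest.approx(expected, rel=1e-12)

    def test_collector_longer_than_loop_rejected(self):
        with pytest.raises(InfeasibleGeometryError):
            pass_probability(CollectorSpec(w=600.0), 512.5)

    def test_collector_equal_to_loop_rejected(self):
        with pytest.raises(InfeasibleGeometryError):
            pass_probability(CollectorSpec(w=512.5), 512.5)


class TestSuccessProbability:
    def test_single_sensor_never_collides(self):
        assert success_probability(0.037, 1) == pytest.approx(0.037)

    def test_two_sensors_at_half(self):
        assert success_probability(0.5, 2) == pytest.approx(0.25)

    def test_elbow_25_sensors_matches_explicit_product(self):
        p = 20.0 / 512.5
        product = p
        for _ in range(24):
            product *= 1.0 - p
        assert success_probability(p, 25) == pytest.approx(product, rel=1e-12)

    def test_invalid_count_rejected(self):
        with pytest.raises(DomainError):
            success_probability(0.1, 0)

    @given(p_c=st.floats(1e-4, 0.99), n=st.integers(1, 100))
    def test_bounded_and_decreasing_in_n(self, p_c, n):
        p_s = success_probability(p_c, n)
        assert 0.0 < p_s < 1.0
        assert success_probability(p_c, n + 1) < p_s


class TestExpectedReadouts:
    def test_single_sensor_collects_p_c_of_opportunities_exactly(self):
        point = expected_readouts(0.1, 1, TM10)
        assert point.s == pytest.approx(0.1 * 600, rel=1e-15)

    @pytest.mark.parametrize(
        "p_c, n, minutes, floor_expected",
        [
            (20.0 / 512.5, 25, 10.0, 225),   # elbow peak
            (50.0 / 540.0, 10, 10.0, 231),   # shin peak
            (15.0 / 540.0, 36, 10.0, 223),   # knee peak
            (10.0 / 540.0, 50, 10.0, 222),   # heel
            (50.0 / 540.0, 7, 12.0, 260),    # shin, longer session
            (50.0 / 540.0, 5, 14.0, 263),    # shin, longest session
        ],
    )
    def test_case_study_floored_readouts(self, p_c, n, minutes, floor_expected):
        point = expected_readouts(p_c, n, MonitoringSpec(duration_minutes=minutes))
        assert point.s_floor == floor_expected

    def test_opportunity_rate_scales_linearly(self):
        slow = expected_readouts(0.05, 3, MonitoringSpec(10.0, opportunity_rate=1.0))
        fast = expected_readouts(0.05, 3, MonitoringSpec(10.0, opportunity_rate=2.0))
        assert fast.s == pytest.approx(2 * slow.s)


class TestReadoutCurve:
    def test_small_curve_values(self):
        curve = readout_curve(0.5, 3, TM10)
        np.testing.assert_allclose(
            [p.s for p in curve.points], np.array([0.5, 0.5, 0.375]) * 600
        )

    def test_elbow_curve_peaks_at_25(self):
        curve = readout_curve(20.0 / 512.5, 75, TM10)
        assert curve.peak.n == 25

    @pytest.mark.parametrize("p_c", [0.01, 0.05, 1.0 / 36.0, 0.2, 0.5, 0.9])
    def test_unimodal_rise_then_fall(self, p_c):
        s = [p.s for p in readout_curve(p_c, 200, TM10).points]
        diffs = np.diff(s)
        switched = False
        for d in diffs:
            if d < 0:
                switched = True
            elif d > 0:
                assert not switched, "curve rose again after falling"

    def test_frame_has_expected_columns(self):
        frame = readout_curve(0.1, 5, TM10).to_frame()
        assert list(frame.columns) == ["n", "p_s", "s", "s_floor"]
        assert len(frame) == 5


class TestOptimalSensorCount:
    @pytest.mark.parametrize(
        "p_c, expected",
        [(20.0 / 512.5, 25), (50.0 / 540.0, 10), (0.5, 2), (1.0 / 36.0, 36)],
    )
    def test_known_optima(self, p_c, expected):
        assert optimal_sensor_count(p_c) == expected

    def test_tie_at_exact_reciprocal_goes_to_larger_count(self):
        # (1-p)/p integer => S(k) == S(k+1); floor(1/p) returns the larger.
        p = 1.0 / 36.0
        f35 = 35 * p * (1 - p) ** 34
        f36 = 36 * p * (1 - p) ** 35
        assert f35 == pytest.approx(f36, rel=1e-12)
        assert optimal_sensor_count(p) == 36

    def test_agrees_with_brute_force_over_random_draws(self):
        rng = np.random.default_rng(12345)
        for p_c in rng.uniform(0.005, 0.95, size=1000):
            assert optimal_sensor_count(p_c) == brute_force_argmax(p_c, n_hi=400)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_probability_rejected(self, bad):
        with pytest.raises(DomainError):
            optimal_sensor_count(bad)


class TestFeasibleSensorRange:
    @pytest.mark.parametrize(
        "p_c, s_min, minutes, expected",
        [
            (20.0 / 512.5, 100, 10.0, (6, 71)),   # elbow
            (50.0 / 540.0, 100, 10.0, (2, 29)),   # shin
        ],
    )
    def test_case_study_ranges(self, p_c, s_min, minutes, expected):
        rng = feasible_sensor_range(p_c, s_min, MonitoringSpec(duration_minutes=minutes))
        assert (rng.n_min, rng.n_max) == expected

    def test_unreachable_requirement_gives_empty_range(self):
        rng = feasible_sensor_range(50.0 / 540.0, 250, TM10)
        assert rng.empty

    @pytest.mark.parametrize("p_c, s_min", [(0.04, 50), (1.0 / 36.0, 150), (0.2, 80)])
    def test_boundary_sharpness(self, p_c, s_min):
        rng = feasible_sensor_range(p_c, s_min, TM10)
        assert not rng.empty
        assert expected_readouts(p_c, rng.n_min, TM10).s >= s_min
        assert expected_readouts(p_c, rng.n_max, TM10).s >= s_min
        if rng.n_min > 1:
            assert expected_readouts(p_c, rng.n_min - 1, TM10).s < s_min
        assert expected_readouts(p_c, rng.n_max + 1, TM10).s < s_min

    def test_every_interior_count_is_feasible(self):
        p_c, s_min = 20.0 / 512.5, 100
        rng = feasible_sensor_range(p_c, s_min, TM10)
        for n in range(rng.n_min, rng.n_max + 1):
            assert expected_readouts(p_c, n, TM10).s >= s_min

    def test_membership_operator(self):
        rng = feasible_sensor_range(20.0 / 512.5, 100, TM10)
        assert 6 in rng and 71 in rng and 5 not in rng and 72 not in rng
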