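"""Cycle extraction, loop classification, cessation and alternation."""

import numpy as np
import pytest

from legsearch import (classify_loop, cycle_average_loop,
                       detect_alternating_amplitude, detect_cessation,
                       extract_cycles, oscillation_stats)
from legsearch.errors import AnalysisError
from legsearch.fixtures import _polygon_loop, _RECTANGLE, _TRIANGLE
from legsearch.trace import SimTrace


def sine(period=1000.0, amp=15.0, offset=10.0, duration=10_000.0, dt=2.0,
         phase=0.0):
    t = np.arange(0.0, duration, dt)
    return t, offset + amp * np.sin(2 * np.pi * t / period + phase)


class TestExtractCycles:
    def test_sine_yields_full_cycles(self):
        t, x = sine()
        cycles = extract_cycles(t, x)
        assert 8 <= len(cycles) <= 10
        periods = [t[c.stop] - t[c.start] for c in cycles]
        assert np.allclose(periods, 1000.0, rtol=0.02)

    def test_constant_trace_yields_none(self):
        t = np.arange(0.0, 5000.0, 2.0)
        assert extract_cycles(t, np.full_like(t, 42.0)) == []

    def test_noise_jitter_does_not_split_cycles(self):
        t, x = sine()
        rng = np.random.default_rng(0)
        cycles = extract_cycles(t, x + rng.normal(0, 0.3, x.size))
        assert 8 <= len(cycles) <= 10


class TestClassifyLoop:
    @pytest.mark.parametrize("vertices,label", [
        (_TRIANGLE, "triangular"),
        (_RECTANGLE, "quadrilateral"),
    ])
    def test_constructed_polygons(self, vertices, label):
        t = np.arange(0.0, 1000.0, 1.0)
        beta, gamma = _polygon_loop(vertices, t, 1000.0)
        lc = classify_loop(np.column_stack([beta, gamma]))
        assert lc.label == label

    @pytest.mark.parametrize("scale,shift", [(0.1, 0.0), (10.0, -40.0), (3.0, 55.0)])
    def test_invariance_to_scaling_and_translation(self, scale, shift):
        t = np.arange(0.0, 1000.0, 1.0)
        beta, gamma = _polygon_loop(_TRIANGLE, t, 1000.0)
        loop = np.column_stack([beta, gamma]) * scale + shift
        assert classify_loop(loop, floor_deg=1e-6).label == "triangular"

    @pytest.mark.parametrize("vertices,label", [
        (_TRIANGLE, "triangular"),
        (_RECTANGLE, "quadrilateral"),
    ])
    @pytest.mark.parametrize("seed", range(4))
    def test_rounded_noisy_variants(self, vertices, label, seed):
        # 5% vertex noise plus smoothing must not change the label
        t = np.arange(0.0, 6000.0, 2.0)
        beta, gamma = _polygon_loop(vertices, t, 1000.0)
        rng = np.random.default_rng(seed)
        diam = np.hypot(*np.ptp(vertices, axis=0))
        beta = beta + rng.normal(0, 0.05 * diam / 3, beta.size)
        gamma = gamma + rng.normal(0, 0.05 * diam / 3, gamma.size)
        k = np.ones(25) / 25
        beta = np.convolve(beta, k, mode="same")
        gamma = np.convolve(gamma, k, mode="same")
        cyc = extract_cycles(t, beta)
        loop = cycle_average_loop(beta, gamma, cyc)
        assert classify_loop(loop).label == label

    def test_flat_gamma_is_degenerate_line(self):
        beta = np.linspace(-5, 30, 200)
        gamma = np.full_like(beta, 160.0)
        lc = classify_loop(np.column_stack([beta, gamma]))
        assert lc.label == "degenerate-line"

    def test_motionless_loop_is_quiescent(self):
        pts = np.array([[10.0, 150.0], [10.5, 150.2], [10.2, 150.4]] * 5)
        assert classify_loop(pts).label == "quiescent"

    def test_too_few_points_rejected(self):
        with pytest.raises(AnalysisError):
            classify_loop(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestDetectCessation:
    def test_constant_trace_single_full_interval(self):
        t = np.arange(0.0, 6000.0, 2.0)
        intervals = detect_cessation(t, np.full_like(t, 150.0))
        assert len(intervals) == 1
        a, b = intervals[0]
        assert a == 0.0 and b == t[-1]

    def test_large_oscillation_has_no_quiescence(self):
        t, x = sine(amp=20.0)
        assert detect_cessation(t, x) == []

    def test_freeze_interval_detected_near_stop_time(self):
        t, x = sine(amp=20.0)
        x = np.where(t < 4000.0, x, 150.0)
        intervals = detect_cessation(t, x)
        assert len(intervals) == 1
        assert abs(intervals[0][0] - 4000.0) < 900.0
        assert intervals[0][1] == t[-1]

    def test_idempotent_and_deterministic(self):
        t, x = sine(amp=20.0)
        x = np.where(t < 4000.0, x, 150.0)
        assert detect_cessation(t, x) == detect_cessation(t, x)


class TestAlternatingAmplitude:
    @staticmethod
    def envelope_signal(amps, period=1000.0, dt=2.0):
        t = np.arange(0.0, period * len(amps), dt)
        cyc = np.minimum((t // period).astype(int), len(amps) - 1)
        x = np.asarray(amps)[cyc] * np.sin(2 * np.pi * t / period)
        return t, x

    def test_constant_amplitudes_not_flagged(self):
        t, x = self.envelope_signal([10.0] * 8)
        assert detect_alternating_amplitude(t, x).flag is False

    def test_alternating_amplitudes_flagged_with_depth(self):
        t, x = self.envelope_signal([10.0, 6.0] * 5)
        res = detect_alternating_amplitude(t, x)
        assert res.flag is True
        assert res.depth == pytest.approx(0.4, abs=0.05)

    def test_noisy_constant_sine_majority_unflagged(self):
        # oracle: direct peak-table inspection over many independent noise
        # draws; 1% amplitude noise must almost never read as alternation
        flagged = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t, x = self.envelope_signal([10.0] * 10)
            res = detect_alternating_amplitude(t, x + rng.normal(0, 0.1, x.size))
            flagged += bool(res.flag)
        assert flagged < 20

    def test_too_few_peaks_undetermined(self):
        t, x = self.envelope_signal([10.0, 6.0])
        assert detect_alternating_amplitude(t, x).flag is None


class TestOscillationStats:
    def test_sine_range_and_period(self):
        t, x = sine()   # 10 + 15 sin, 1 Hz
        trace = SimTrace(t, x, np.full_like(t, 150.0), np.zeros_like(t))
        st = oscillation_stats(trace)
        lo, hi = st.ranges["beta"]
        assert lo == pytest.approx(-5.0, abs=0.1)
        assert hi == pytest.approx(25.0, abs=0.1)
        assert st.periods_ms["beta"] == pytest.approx(1000.0, rel=0.02)

    def test_constant_angle_reports_no_period(self):
        t = np.arange(0.0, 5000.0, 2.0)
        c = np.full_like(t, 1.0)
        trace = SimTrace(t, c * 10, c * 150, c * 5)
        st = oscillation_stats(trace)
        assert st.periods_ms["gamma"] is None
        lo, hi = st.ranges["gamma"]
        assert hi - lo == 0.0
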