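"""Filtering, contact detection and leg labelling against analytic oracles."""

import math

import numpy as np
import pytest

from rspgait.exceptions import DataError, InsufficientDataError, ParameterError
from rspgait.signal import (
    FilterSpec,
    StanceInterval,
    assign_legs,
    belt_speed_from_marker,
    butterworth_lowpass,
    detect_stances,
)
from rspgait.simulate import make_grf_pulse

RATE = 1000.0


def butter2_filtfilt_gain(f: float, cutoff: float) -> float:
    """Analytic magnitude of a forward-backward 2nd-order Butterworth."""
    return 1.0 / (1.0 + (f / cutoff) ** 4)


class TestButterworth:
    def test_dc_gain_is_unity(self):
        x = np.full(1000, 3.7)
        y = butterworth_lowpass(x, RATE, FilterSpec(cutoff=30.0))
        np.testing.assert_allclose(y, x, rtol=1e-9)

    def test_stopband_sine_strongly_attenuated(self):
        t = np.arange(0, 4.0, 1 / RATE)
        y = butterworth_lowpass(np.sin(2 * np.pi * 200.0 * t), RATE, FilterSpec(cutoff=30.0))
        mid = y[y.size // 4 : -y.size // 4]  # avoid edge transients
        assert 0.5 * (mid.max() - mid.min()) < 0.01

    def test_cutoff_sine_passes_at_half_amplitude(self):
        """Two passes of the 2nd-order design give |H|^2 = 1/2 at the cutoff."""
        t = np.arange(0, 4.0, 1 / RATE)
        y = butterworth_lowpass(np.sin(2 * np.pi * 30.0 * t), RATE, FilterSpec(cutoff=30.0))
        mid = y[y.size // 4 : -y.size // 4]
        amplitude = 0.5 * (mid.max() - mid.min())
        assert amplitude == pytest.approx(butter2_filtfilt_gain(30.0, 30.0), abs=0.01)
        assert amplitude == pytest.approx(0.5, abs=0.01)

    def test_passband_idempotence(self):
        t = np.arange(0, 2.0, 1 / RATE)
        x = np.sin(2 * np.pi * 2.0 * t)  # far below the 30 Hz cutoff
        once = butterworth_lowpass(x, RATE)
        thrice = butterworth_lowpass(butterworth_lowpass(once, RATE), RATE)
        mid = slice(200, -200)
        assert np.max(np.abs(thrice[mid] - once[mid])) < 1e-3

    def test_nan_input_rejected(self):
        x = np.zeros(100)
        x[50] = np.nan
        with pytest.raises(DataError, match="NaN"):
            butterworth_lowpass(x, RATE)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError, match="Nyquist"):
            butterworth_lowpass(np.zeros(100), RATE, FilterSpec(cutoff=500.0))

    def test_single_pass_shifts_phase_but_zero_phase_does_not(self):
        t = np.arange(0, 2.0, 1 / RATE)
        x = np.sin(2 * np.pi * 5.0 * t)
        zero = butterworth_lowpass(x, RATE, FilterSpec(cutoff=30.0, zero_phase=True))
        single = butterworth_lowpass(x, RATE, FilterSpec(cutoff=30.0, zero_phase=False))
        mid = slice(500, 1500)
        lag_zero = np.argmax(np.correlate(zero[mid], x[mid], "full")) - (mid.stop - mid.start - 1)
        lag_single = np.argmax(np.correlate(single[mid], x[mid], "full")) - (mid.stop - mid.start - 1)
        assert abs(lag_zero) <= 1
        assert lag_single > 1


class TestDetectStances:
    PEAK, DUR = 1500.0, 0.12

    def half_sine_crossing(self, threshold=30.0):
        """Closed-form threshold crossing times of the half-sine pulse."""
        t1 = (self.DUR / math.pi) * math.asin(threshold / self.PEAK)
        return t1, self.DUR - t1

    def test_all_zero_trace_yields_empty_list(self):
        assert detect_stances(np.zeros(2000), RATE) == []

    def test_half_sine_onset_offset_match_analytic_crossings(self):
        pad = 0.05
        pulse = make_grf_pulse(self.PEAK, self.DUR, RATE, pad=(pad, pad))
        stances = detect_stances(pulse, RATE)
        assert len(stances) == 1
        t1, t2 = self.half_sine_crossing()
        assert abs(stances[0].onset - round((pad + t1) * RATE)) <= 2
        assert abs(stances[0].offset - round((pad + t2) * RATE)) <= 2

    def test_mid_stance_dip_below_threshold_is_merged(self):
        pulse = make_grf_pulse(self.PEAK, self.DUR, RATE)
        dip = slice(50 + 55, 50 + 60)  # 5 ms dip mid-stance
        pulse[dip] = 10.0
        stances = detect_stances(pulse, RATE)
        assert len(stances) == 1

    def test_short_spike_is_purged(self):
        trace = np.zeros(1000)
        trace[500:510] = 100.0  # 10 ms ghost contact < min_contact
        assert detect_stances(trace, RATE) == []

    def test_robust_to_subthreshold_aerial_noise(self):
        rng = np.random.default_rng(11)
        pulse = make_grf_pulse(self.PEAK, self.DUR, RATE)
        clean = detect_stances(pulse, RATE)
        noisy = pulse + rng.uniform(-9.9, 9.9, pulse.size) * (pulse < 30.0)
        found = detect_stances(noisy, RATE)
        assert [(s.onset, s.offset) for s in found] == [
            (s.onset, s.offset) for s in clean
        ]

    def test_stance_plus_aerial_samples_partition_trace(self):
        pulses = np.concatenate([make_grf_pulse(self.PEAK, self.DUR, RATE)] * 3)
        stances = detect_stances(pulses, RATE)
        assert len(stances) == 3
        total = stances[-1].offset - stances[0].onset
        stance_samples = sum(s.n_samples for s in stances)
        aerial_samples = sum(
            b.onset - a.offset for a, b in zip(stances, stances[1:])
        )
        assert stance_samples + aerial_samples == total


class TestAssignLegs:
    def test_alternation_from_first_contact(self):
        stances = [StanceInterval(i * 200, i * 200 + 100) for i in range(4)]
        labeled = assign_legs(stances, "AL")
        assert [s.leg for s in labeled] == ["AL", "UL", "AL", "UL"]

    def test_empty_input(self):
        assert assign_legs([], "UL") == []

    def test_simulated_session_labels_match_truth(self, asym_session):
        from rspgait.signal import butterworth_lowpass as lp

        f_v = lp(asym_session.forces.f_v, RATE)
        stances = assign_legs(
            detect_stances(f_v, RATE), asym_session.config.first_contact_leg
        )
        truth_legs = asym_session.truth["leg"].tolist()
        assert [s.leg for s in stances] == truth_legs[: len(stances)]


class TestBeltSpeed:
    def test_constant_velocity_marker(self):
        t = np.arange(0, 0.2, 1 / 200.0)
        assert belt_speed_from_marker(t, -3.0 * t, 0.02, 0.15) == pytest.approx(3.0)

    def test_stationary_marker(self):
        t = np.arange(0, 0.2, 1 / 200.0)
        assert belt_speed_from_marker(t, np.zeros_like(t), 0.02, 0.15) == 0.0

    def test_too_few_samples_rejected(self):
        t = np.arange(0, 0.2, 1 / 200.0)
        with pytest.raises(InsufficientDataError):
            belt_speed_from_marker(t, -3.0 * t, 0.020, 0.028)

    def test_simulated_session_estimate_within_2pct(self, noisy_session):
        """Marker riding the belt during stance recovers the belt speed."""
        from rspgait.pipeline import analyze
        from conftest import as_session

        analysis = analyze(as_session(noisy_session))
        belt = noisy_session.config.belt_velocity
        assert analysis.belt_speed_marker == pytest.approx(belt, rel=0.02)
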