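"""Step metrics and trial aggregation."""

import numpy as np
import pytest

from rspgait.exceptions import DataError, MissingLegError
from rspgait.gait import (
    GRAVITY,
    StepRecord,
    step_metrics,
    summarize_trial,
    vmax_trial_valid,
)
from rspgait.signal import StanceInterval, assign_legs, butterworth_lowpass, detect_stances

RATE = 1000.0


def two_stances(gap=150):
    return assign_legs(
        [StanceInterval(100, 200), StanceInterval(200 + gap, 300 + gap)], "AL"
    )


def flat_trace(n, level, stances):
    x = np.zeros(n)
    for s in stances:
        x[s.slice()] = level
    return x


class TestStepMetrics:
    def test_definition_arithmetic(self):
        stances = two_stances(gap=150)
        f_v = flat_trace(600, 1000.0, stances)
        zeros = np.zeros(600)
        records = step_metrics(stances, f_v, zeros, zeros, RATE, v=8.0, body_mass=75.0)
        assert len(records) == 1  # last stance dropped
        r = records[0]
        assert r.t_c == pytest.approx(0.100)
        assert r.t_a == pytest.approx(0.150)
        assert r.t_step == pytest.approx(r.t_c + r.t_a)
        assert r.f_step * r.t_step == pytest.approx(1.0)
        assert r.L_c == pytest.approx(0.800)

    def test_constant_double_body_weight(self):
        stances = two_stances()
        m = 75.0
        f_v = flat_trace(600, 2 * m * GRAVITY, stances)
        zeros = np.zeros(600)
        r = step_metrics(stances, f_v, zeros, zeros, RATE, 8.0, m)[0]
        assert r.F_avg_bw == pytest.approx(2.0)
        assert r.F_peak_v == pytest.approx(2 * m * GRAVITY)

    def test_resultant_uses_all_three_channels(self):
        stances = two_stances()
        f_v = flat_trace(600, 300.0, stances)
        f_ap = flat_trace(600, 400.0, stances)
        zeros = np.zeros(600)
        r = step_metrics(stances, f_v, zeros, f_ap, RATE, 8.0, 75.0)[0]
        assert r.F_peak_res == pytest.approx(500.0)

    def test_overlapping_stances_rejected(self):
        stances = assign_legs([StanceInterval(0, 100), StanceInterval(50, 150)], "AL")
        z = np.zeros(200)
        with pytest.raises(DataError, match="overlap"):
            step_metrics(stances, z, z, z, RATE, 8.0, 75.0)

    def test_impulse_momentum_balance_on_simulation(self, symmetric_session):
        """Over a stride, vertical impulse balances body weight within 1%."""
        s = symmetric_session
        f_v = butterworth_lowpass(s.forces.f_v, RATE)
        stances = assign_legs(detect_stances(f_v, RATE), s.config.first_contact_leg)
        records = step_metrics(
            stances, f_v, s.forces.f_ml, s.forces.f_ap, RATE,
            s.config.belt_velocity, s.config.body_mass,
        )
        weight = s.config.body_mass * GRAVITY
        for a, b in zip(records, records[1:]):
            stride_impulse = a.F_avg * a.t_c + b.F_avg * b.t_c
            stride_time = a.t_step + b.t_step
            assert stride_impulse == pytest.approx(weight * stride_time, rel=0.01)

    def test_duty_factor_force_consistency(self, symmetric_session):
        """Stance-average vGRF in BW times duty factor is ~1 in steady running."""
        s = symmetric_session
        f_v = butterworth_lowpass(s.forces.f_v, RATE)
        stances = assign_legs(detect_stances(f_v, RATE), s.config.first_contact_leg)
        records = step_metrics(
            stances, f_v, s.forces.f_ml, s.forces.f_ap, RATE,
            s.config.belt_velocity, s.config.body_mass,
        )
        summary = summarize_trial(records)
        duty = np.mean([summary.both_legs["t_c"] / summary.both_legs["t_step"]])
        assert summary.both_legs["F_avg_bw"] * duty == pytest.approx(1.0, rel=0.02)


class TestSummarize:
    @staticmethod
    def record(leg, f_step):
        t_step = 1.0 / f_step
        return StepRecord(
            leg=leg, t_c=0.1, t_a=t_step - 0.1, t_step=t_step, f_step=f_step,
            L_c=0.8, F_avg=1500.0, F_avg_bw=2.0, F_peak_v=2500.0, F_peak_res=2600.0,
        )

    def test_both_legs_average_is_mean_of_leg_means(self):
        records = [self.record("AL", 2.0), self.record("UL", 2.2)]
        summary = summarize_trial(records)
        assert summary.both_legs["f_step"] == pytest.approx(2.1)
        assert summary.stride_count == 1

    def test_single_record_per_leg_equals_record(self):
        records = [self.record("AL", 2.0), self.record("UL", 2.0)]
        summary = summarize_trial(records)
        assert summary.per_leg["AL"]["f_step"] == pytest.approx(2.0)

    def test_missing_leg_raises(self):
        with pytest.raises(MissingLegError, match="UL"):
            summarize_trial([self.record("AL", 2.0)])

    def test_per_leg_means_match_simulator_truth(self, asym_session):
        from rspgait.pipeline import analyze
        from conftest import as_session

        s = asym_session
        analysis = analyze(as_session(s))
        truth = s.truth.groupby("leg")[["t_contact", "avg_vgrf", "peak_vgrf"]].mean()
        truth_t_step = (s.truth["t_contact"] + s.truth["t_aerial"]).groupby(
            s.truth["leg"]
        ).mean()
        for leg in ("AL", "UL"):
            # step time is onset-to-onset and carries no edge bias
            assert analysis.summary.per_leg[leg]["t_step"] == pytest.approx(
                truth_t_step[leg], rel=0.02
            )
            assert analysis.summary.per_leg[leg]["F_peak_v"] == pytest.approx(
                truth.loc[leg, "peak_vgrf"], rel=0.02
            )
            # threshold-crossing metrics inherit the zero-phase edge smear
            # (~3-4 ms per edge at a 30 Hz cutoff)
            assert analysis.summary.per_leg[leg]["t_c"] == pytest.approx(
                truth.loc[leg, "t_contact"], rel=0.08
            )
            assert analysis.summary.per_leg[leg]["F_avg"] == pytest.approx(
                truth.loc[leg, "avg_vgrf"], rel=0.08
            )


class TestVmaxValidity:
    @staticmethod
    def records(n_per_leg):
        return [TestSummarize.record(leg, 2.0) for _ in range(n_per_leg) for leg in ("AL", "UL")]

    def test_eight_strides_zero_drift_valid(self):
        ok, diag = vmax_trial_valid(self.records(8), touchdown_positions=[0.0] * 16)
        assert ok and diag["stride_count"] == 8

    def test_seven_strides_invalid_regardless_of_drift(self):
        ok, diag = vmax_trial_valid(self.records(7), touchdown_positions=[0.0] * 14)
        assert not ok

    def test_monotone_drift_beyond_limit_invalid(self):
        positions = np.linspace(0.0, 0.5, 16)
        ok, diag = vmax_trial_valid(self.records(8), touchdown_positions=positions)
        assert not ok and diag["drift_m"] == pytest.approx(0.5)

    def test_impulse_fallback_without_markers(self):
        ok, diag = vmax_trial_valid(
            self.records(8), f_ap=np.zeros(4000), rate=RATE, body_mass=75.0
        )
        assert ok and diag["drift_source"] == "impulse"
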