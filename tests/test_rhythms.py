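"""Period, amplitude, phase extraction and the circadian classification."""

import numpy as np
import pytest

from per2as.antisense import ModelVariant
from per2as.rhythms import (
    EQ4_CRITERIA,
    LimitCycleSummary,
    RhythmCriteria,
    Trajectory,
    classify_circadian_antiphasic,
    measure_amplitudes,
    measure_period,
    measure_period_autocorr,
    measure_phases,
    simulate,
    summarize_limit_cycle,
)


def sinusoid_trajectory(periods=(24.0, 24.0), offsets_h=(0.0, 12.0),
                        means=(2.0, 2.0), amps=(1.0, 1.0),
                        t_end=240.0, dt=0.1):
    """Two-species synthetic trajectory labelled Per2 / Per2AS."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    cols = [m + a * np.cos(2 * np.pi * (t - off) / T)
            for T, off, m, a in zip(periods, offsets_h, means, amps)]
    states = np.zeros((len(t), 20))
    states[:, 0] = cols[0]
    states[:, 19] = cols[1]
    states[:, 1:19] = 1.0
    return Trajectory(t, states, ModelVariant.PRE, "synthetic")


class TestPeriod:
    def test_pure_sinusoid_period(self):
        traj = sinusoid_trajectory()
        assert measure_period(traj, "Per2") == pytest.approx(24.0, abs=0.01)

    def test_autocorrelation_agrees_with_peaks(self):
        traj = sinusoid_trajectory()
        t_peak = measure_period(traj, "Per2")
        t_ac = measure_period_autocorr(traj, "Per2")
        assert t_ac == pytest.approx(t_peak, rel=0.01)

    def test_constant_signal_is_non_oscillatory(self):
        traj = sinusoid_trajectory(amps=(0.0, 0.0))
        assert measure_period(traj, "Per2") is None

    def test_amplitude_rescaling_leaves_period_unchanged(self):
        a = sinusoid_trajectory(amps=(1.0, 1.0))
        b = sinusoid_trajectory(amps=(0.01, 1.0))
        assert measure_period(a, "Per2") == pytest.approx(
            measure_period(b, "Per2"), rel=1e-6)


class TestAmplitudes:
    def test_offset_sinusoid_extrema(self):
        traj = sinusoid_trajectory(means=(2.0, 2.0), amps=(1.0, 1.0))
        a_max, a_min = measure_amplitudes(traj)["Per2"]
        assert a_max == pytest.approx(3.0, abs=1e-3)
        assert a_min == pytest.approx(1.0, abs=1e-3)

    def test_constant_trajectory_has_zero_amplitude(self):
        traj = sinusoid_trajectory(amps=(0.0, 0.0))
        a_max, a_min = measure_amplitudes(traj)["Per2"]
        assert a_max == pytest.approx(a_min)


class TestPhases:
    def test_antiphasic_sinusoids_are_12h_apart(self):
        traj = sinusoid_trajectory(offsets_h=(0.0, 12.0))
        phases = measure_phases(traj, "Per2AS")
        assert phases["Per2AS"] == 0.0
        d = abs(phases["Per2"]) % 24.0
        assert min(d, 24.0 - d) == pytest.approx(12.0, abs=0.05)

    def test_window_shift_invariance(self):
        """Phases are properties of the cycle, not of where the analysis
        window begins."""
        a = sinusoid_trajectory(t_end=240.0)
        t = np.arange(7.0, 247.0 + 0.05, 0.1)
        states = np.zeros((len(t), 20))
        states[:, 0] = 2 + np.cos(2 * np.pi * t / 24.0)
        states[:, 19] = 2 + np.cos(2 * np.pi * (t - 12.0) / 24.0)
        states[:, 1:19] = 1.0
        b = Trajectory(t, states, ModelVariant.PRE, "synthetic-shifted")
        pa = measure_phases(a, "Per2AS")["Per2"]
        pb = measure_phases(b, "Per2AS")["Per2"]
        d = abs(pa - pb) % 24.0
        assert min(d, 24.0 - d) < 0.05


class TestModelAttractor:
    def test_wt_attractor_is_circadian(self, wt_summary):
        assert wt_summary.oscillatory
        assert wt_summary.period == pytest.approx(23.5, abs=0.3)

    def test_wt_per2_amplitude_clears_criteria_floor(self, wt_summary):
        assert wt_summary.amplitude("Per2") > 0.5

    def test_all_species_share_one_period(self, wt, wt_pre_traj):
        periods = []
        for sp in ("Per2", "Cry", "Bmal1", "REV_n", "Per2AS"):
            T = measure_period(wt_pre_traj, sp)
            assert T is not None, sp
            periods.append(T)
        spread = (max(periods) - min(periods)) / np.mean(periods)
        assert spread < 0.005

    def test_autocorr_and_peak_periods_agree_on_model(self, wt_pre_traj):
        t_peak = measure_period(wt_pre_traj, "Per2")
        t_ac = measure_period_autocorr(wt_pre_traj, "Per2")
        assert t_ac == pytest.approx(t_peak, rel=0.01)

    def test_low_interference_converges_to_steady_state(self, wt):
        traj = simulate("pre", wt.replace(mu=0.2), t_end=900.0, transient=600.0)
        assert summarize_limit_cycle(traj).oscillatory is False

    def test_grid_refinement_consistency(self, wt):
        # on the settled attractor, halving the output grid must not move
        # the reported metrics
        m1 = summarize_limit_cycle(
            simulate("pre", wt, t_end=1700.0, transient=1500.0, dt=0.1))
        m2 = summarize_limit_cycle(
            simulate("pre", wt, t_end=1700.0, transient=1500.0, dt=0.05))
        assert m2.period == pytest.approx(m1.period, rel=1e-4)
        assert m2.amplitude("Per2") == pytest.approx(m1.amplitude("Per2"), rel=1e-3)


class TestClassification:
    def summary(self, T=24.0, amp=1.0, dphi=12.0):
        return LimitCycleSummary(
            True, T,
            {"Per2": (amp, 0.0), "Per2AS": (0.05, 0.0)},
            {"Per2AS": 0.0, "Per2": dphi},
        )

    def test_strict_interior_passes(self):
        assert classify_circadian_antiphasic(self.summary())

    @pytest.mark.parametrize("kw", [
        dict(T=26.0), dict(amp=0.3), dict(dphi=9.0),
    ])
    def test_each_violated_bound_fails(self, kw):
        assert not classify_circadian_antiphasic(self.summary(**kw))

    def test_impossible_criteria_reject_everything(self):
        impossible = RhythmCriteria(period_min=0.0, period_max=0.0)
        assert not classify_circadian_antiphasic(self.summary(), impossible)

    def test_non_oscillatory_never_classifies(self):
        s = LimitCycleSummary(False, None, {"Per2": (1.0, 1.0)}, {})
        assert not classify_circadian_antiphasic(s)

    def test_wt_is_circadian_antiphasic(self, wt_summary):
        assert classify_circadian_antiphasic(wt_summary, EQ4_CRITERIA)


class TestTrajectoryContainer:
    def test_rejects_non_finite(self):
        t = np.arange(0, 10.0, 0.1)
        states = np.ones((len(t), 20))
        states[5, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            Trajectory(t, states, ModelVariant.PRE, "bad")

    def test_csv_round_trip(self, wt_pre_traj, tmp_path):
        import pandas as pd

        path = tmp_path / "traj.csv"
        wt_pre_traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns)[0] == "time_h"
        assert len(df) == len(wt_pre_traj.times)
        np.testing.assert_allclose(df["Per2"].to_numpy(),
                                   wt_pre_traj.column("Per2"))
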