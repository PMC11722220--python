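import numpy as np
import pytest

from dlam import synth, vep
from dlam.io_core import ValidationError
from dlam.lfp import LfpTrace


class TestExtractTrials:
    def test_one_row_per_event(self, quiet_session):
        _, session, schedule, _ = quiet_session
        tr = vep.extract_trials(LfpTrace(session.samples, session.fs),
                                schedule, "monocular", 32, 400.0)
        assert tr.shape == (schedule.n_trials("monocular"), 400)

    def test_events_near_end_dropped(self):
        from dlam.io_core import Block, StimulusSchedule
        sched = StimulusSchedule([Block("a", 0, 1.0)], [[0.1, 0.99]])
        trace = LfpTrace(np.zeros((1, 1000)), 1000.0)
        tr = vep.extract_trials(trace, sched, "a", 0, 500.0)
        assert tr.shape[0] == 1

    def test_unknown_condition_raises(self, quiet_session):
        _, session, schedule, _ = quiet_session
        with pytest.raises(ValidationError, match="concordant"):
            vep.extract_trials(LfpTrace(session.samples, session.fs),
                               schedule, "concordant", 0)

    def test_mean_matches_generated_shape(self, quiet_session):
        params, session, schedule, truth = quiet_session
        ch = truth.sink_channel_index
        tr = vep.extract_trials(LfpTrace(session.samples, session.fs),
                                schedule, "monocular", ch, 350.0)
        t = np.arange(350) / 1000.0
        shape = -synth.lfp_trial_kernel(t, truth.early_gain["monocular"],
                                        truth.late_gain["monocular"])
        r = np.corrcoef(tr.mean(axis=0), shape)[0, 1]
        assert r > 0.99


class TestNormalizeAndSmooth:
    def test_constant_offset_trials_vanish(self):
        trials = np.full((5, 300), 7.0)
        wf = vep.normalize_and_smooth(trials, 1000.0)
        np.testing.assert_allclose(wf.voltage_v, 0.0, atol=1e-12)

    def test_first_10ms_mean_zero(self, quiet_session):
        params, session, schedule, truth = quiet_session
        tr = vep.extract_trials(LfpTrace(session.samples, session.fs),
                                schedule, "monocular", truth.sink_channel_index, 350.0)
        wf = vep.normalize_and_smooth(tr, 1000.0)
        assert abs(wf.voltage_v[:10].mean()) < 0.02 * np.abs(wf.voltage_v).max()

    def test_duplicated_trials_average_identically(self):
        rng = np.random.default_rng(2)
        trial = rng.standard_normal(300)
        one = vep.normalize_and_smooth(trial[None], 1000.0)
        two = vep.normalize_and_smooth(np.tile(trial, (2, 1)), 1000.0)
        np.testing.assert_allclose(one.voltage_v, two.voltage_v)

    def test_delta_spreads_to_gaussian_with_preserved_area(self):
        trials = np.zeros((1, 400))
        trials[0, 200] = 1.0
        wf = vep.normalize_and_smooth(trials, 1000.0, fwhm_ms=10.0)
        assert wf.voltage_v.sum() == pytest.approx(1.0, rel=1e-6)
        assert wf.voltage_v.max() < 0.12  # spread out, not a delta
        assert np.argmax(wf.voltage_v) == 200

    def test_too_short_trial_rejected(self):
        with pytest.raises(ValidationError):
            vep.normalize_and_smooth(np.zeros((2, 5)), 1000.0)


class TestMeasureComponents:
    def _waveform(self, neg_uv=-50.0, pos_uv=70.0, fs=1000.0):
        t = np.arange(300) / fs * 1000.0
        v = (neg_uv * 1e-6 * np.exp(-0.5 * ((t - 60) / 8) ** 2)
             + pos_uv * 1e-6 * np.exp(-0.5 * ((t - 140) / 15) ** 2))
        return vep.VepWaveform(v, fs, n_trials=1)

    def test_magnitude_is_peak_to_peak(self):
        c = vep.measure_components(self._waveform())
        assert c.magnitude_v == pytest.approx(120e-6, rel=1e-3)
        assert c.negativity_latency_ms == pytest.approx(60, abs=2)
        assert c.positivity_latency_ms == pytest.approx(140, abs=2)

    def test_flat_waveform_magnitude_zero(self):
        wf = vep.VepWaveform(np.zeros(300), 1000.0, n_trials=1)
        assert vep.measure_components(wf).magnitude_v == 0.0

    def test_positivity_constrained_after_negativity(self):
        # early bump at 30 ms must not be picked as the positivity
        t = np.arange(300)
        v = 50e-6 * np.exp(-0.5 * ((t - 70) / 8) ** 2) * -1.0
        v += 80e-6 * np.exp(-0.5 * ((t - 65) / 3) ** 2) * 0  # nothing early
        v += 30e-6 * np.exp(-0.5 * ((t - 130) / 10) ** 2)
        c = vep.measure_components(vep.VepWaveform(v, 1000.0, 1))
        assert c.positivity_latency_ms > c.negativity_latency_ms

    def test_recovers_generated_component_amplitudes(self, quiet_session):
        params, session, schedule, truth = quiet_session
        tr = vep.extract_trials(LfpTrace(session.samples, session.fs),
                                schedule, "monocular", truth.sink_channel_index, 350.0)
        wf = vep.normalize_and_smooth(tr, 1000.0)
        c = vep.measure_components(wf)
        # negativity equals the prescribed evoked amplitude (5% tolerance:
        # smoothing slightly attenuates the peak)
        assert -c.negativity_v == pytest.approx(truth.evoked_amplitude_v["monocular"],
                                                rel=0.05)

    def test_invariant_to_pre_baseline_constant(self):
        wf = self._waveform()
        trials = np.tile(wf.voltage_v, (3, 1))
        a = vep.measure_components(vep.normalize_and_smooth(trials, 1000.0))
        b = vep.measure_components(vep.normalize_and_smooth(trials + 1.23e-3, 1000.0))
        assert a.magnitude_v == pytest.approx(b.magnitude_v, abs=1e-15)


class TestNormalizeToReference:
    def test_reference_maps_to_one(self):
        out = vep.normalize_to_reference({"a": 2.0, "b": 4.0}, "a")
        assert out == {"a": 1.0, "b": 2.0}

    def test_order_invariance(self):
        m = {"x": 3.0, "y": 1.5, "z": 6.0}
        a = vep.normalize_to_reference(m, "y")
        b = vep.normalize_to_reference(dict(reversed(list(m.items()))), "y")
        assert a == b

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            vep.normalize_to_reference({"a": 0.0, "b": 1.0}, "a")


class TestConditionEffectSign:
    def test_phase_offset_negativity_smaller_than_monocular(self):
        """Generator gains g_E(phase_offset) < g_E(monocular) must show up
        as a smaller measured negativity magnitude."""
        p = synth.SessionParams(
            fs=1000.0, n_blocks_per_condition=1, block_s=60.0, interblock_s=10.0,
            conditions=("monocular", "phase_offset"))
        session, schedule, truth = synth.generate_session(p, seed=17)
        from dlam.lfp import preprocess_lfp
        out = preprocess_lfp(session)
        mags = {}
        for cond in p.conditions:
            tr = vep.extract_trials(out, schedule, cond, truth.sink_channel_index, 350.0)
            mags[cond] = vep.measure_components(
                vep.normalize_and_smooth(tr, out.fs)).negativity_v
        assert abs(mags["phase_offset"]) < abs(mags["monocular"])
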