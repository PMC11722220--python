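import numpy as np
import pytest

from dlam import csd, synth
from dlam.calcium import dff_vs_gray, neuropil_correct
from dlam.io_core import ValidationError
from dlam.units import classify_unit, trough_to_peak_ms
from dlam.vep import extract_trials
from dlam.lfp import LfpTrace


def _avg_lfp(session, schedule, condition="monocular", t_ms=350.0):
    tr = LfpTrace(session.samples, session.fs)
    return np.stack([
        extract_trials(tr, schedule, condition, ch, t_ms).mean(axis=0)
        for ch in range(session.n_channels)])


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = synth.SessionParams(fs=1000.0, n_blocks_per_condition=1, block_s=10.0,
                                interblock_s=5.0, conditions=("monocular",))
        a = synth.generate_session(p, seed=5)
        b = synth.generate_session(p, seed=5)
        np.testing.assert_array_equal(a[0].samples, b[0].samples)
        ua, _ = synth.generate_units(synth.UnitParams(n_units=4), a[1], a[2], seed=5)
        ub, _ = synth.generate_units(synth.UnitParams(n_units=4), b[1], b[2], seed=5)
        for x, y in zip(ua, ub):
            np.testing.assert_array_equal(x.spike_times_s, y.spike_times_s)

    def test_different_seed_differs(self):
        p = synth.SessionParams(fs=1000.0, n_blocks_per_condition=1, block_s=10.0,
                                interblock_s=5.0, conditions=("monocular",))
        a = synth.generate_session(p, seed=5)[0]
        b = synth.generate_session(p, seed=6)[0]
        assert not np.array_equal(a.samples, b.samples)


class TestLfpForwardModel:
    def test_zero_gain_zero_noise_is_flat(self):
        p = synth.SessionParams(
            fs=1000.0, n_blocks_per_condition=1, block_s=10.0, interblock_s=5.0,
            conditions=("monocular",), early_gain={"monocular": 0.0},
            late_gain={"monocular": 0.0}, pink_noise_v=0.0, line_noise_v=0.0)
        session, _, _ = synth.generate_session(p, seed=0)
        assert np.abs(session.samples).max() == 0.0

    def test_csd_minimum_at_prescribed_sink(self, quiet_session):
        params, session, schedule, truth = quiet_session
        cmap = csd.compute_csd(_avg_lfp(session, schedule), params.spacing_um, 1000.0)
        ch, t = np.unravel_index(np.argmin(cmap.values), cmap.values.shape)
        assert ch + cmap.channel_offset == truth.sink_channel_index
        # evoked CSD peaks near the early-kernel peak; within one smoothing width
        assert abs(cmap.time_ms[t] - 65.0) <= 20.0

    def test_evoked_amplitude_is_linear(self):
        base = dict(fs=1000.0, n_blocks_per_condition=1, block_s=10.0, interblock_s=5.0,
                    conditions=("monocular",), pink_noise_v=0.0, line_noise_v=0.0)
        a = synth.generate_session(synth.SessionParams(**base), seed=0)[0]
        b = synth.generate_session(
            synth.SessionParams(evoked_amplitude_v=300e-6, **base), seed=0)[0]
        ratio = np.abs(b.samples).max() / np.abs(a.samples).max()
        assert ratio == pytest.approx(2.0, rel=1e-3)  # quantization-limited

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValidationError):
            synth.SessionParams(n_channels=4, sink_channel=2)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValidationError):
            synth.SessionParams(early_gain={"monocular": -1.0})


class TestSpikes:
    def test_homogeneous_rate_without_gains(self):
        p = synth.SessionParams(fs=1000.0, n_blocks_per_condition=1, block_s=60.0,
                                interblock_s=5.0, conditions=("monocular",),
                                early_gain={"monocular": 0.0}, late_gain={"monocular": 0.0})
        sched = synth.generate_schedule(p, np.random.default_rng(0))
        truth = synth.GroundTruth(0, 32, 28, {}, p.early_gain, p.late_gain)
        units, truth = synth.generate_units(
            synth.UnitParams(n_units=8, base_rate_range=(5.0, 5.0)), sched, truth, seed=9)
        dur = sched.blocks[0].duration_s
        for u in units:
            n = np.sum((u.spike_times_s >= sched.blocks[0].start_s)
                       & (u.spike_times_s < sched.blocks[0].end_s))
            # 3-sigma Poisson band around base * duration
            assert abs(n - 5.0 * dur) < 3 * np.sqrt(5.0 * dur) + 1

    def test_expected_count_matches_rate_integral(self):
        """Monte-Carlo: mean spike count over repeats matches the rate integral."""
        p = synth.SessionParams(fs=1000.0, n_blocks_per_condition=1, block_s=50.0,
                                interblock_s=5.0, conditions=("monocular",),
                                early_gain={"monocular": 2.0}, late_gain={"monocular": 1.0})
        sched = synth.generate_schedule(p, np.random.default_rng(0))
        truth = synth.GroundTruth(0, 32, 28, {}, p.early_gain, p.late_gain)
        base = 6.0
        grid = np.arange(0.0, 1.0, 1e-3)
        rate = base * (1 + 2.0 * synth.early_kernel(grid) + 1.0 * synth.late_kernel(grid))
        expected = rate.sum() * 1e-3 * sched.n_trials("monocular")
        counts = []
        for r in range(50):
            units, _ = synth.generate_units(
                synth.UnitParams(n_units=1, base_rate_range=(base, base),
                                 interblock_rate_factor=0.0),
                sched, truth, seed=100 + r)
            b = sched.blocks[0]
            counts.append(np.sum((units[0].spike_times_s >= b.start_s)
                                 & (units[0].spike_times_s < b.end_s)))
        sem = np.sqrt(expected) / np.sqrt(50)
        assert abs(np.mean(counts) - expected) < 3 * sem

    def test_templates_classify_to_their_class(self, four_condition_spikes):
        _, _, units, truth = four_condition_spikes
        for u, row in zip(units, truth.unit_table):
            assert classify_unit(trough_to_peak_ms(u.waveform_mv)) == row["true_cls"]

    def test_template_trough_to_peak_is_exact(self):
        for ttp in (0.2, 0.32, 0.4, 0.6, 0.8):
            w = synth.make_template(ttp)
            assert trough_to_peak_ms(w) == pytest.approx(ttp, abs=0.021)


class TestCalcium:
    def test_zero_spikes_zero_noise_gives_zero_dff(self):
        p = synth.SessionParams(fs=1000.0, conditions=("a",), n_blocks_per_condition=2,
                                block_s=10.0, interblock_s=10.0)
        sched = synth.generate_schedule(p, np.random.default_rng(0))
        silent = [synth.SortedUnit("u0", np.empty(0), synth.make_template(0.6))]
        cp = synth.CalciumParams(shot_noise_f=0.0, neuropil_pop_fraction=0.0,
                                 neuropil_baseline_f=60.0)
        traces, _ = synth.generate_calcium(silent, cp, sched, seed=0)
        f_true = neuropil_correct(traces.F, traces.F_neuropil)
        dff = dff_vs_gray(f_true, sched, traces.frame_rate)
        np.testing.assert_allclose(dff, 0.0, atol=1e-12)

    def test_neuropil_correction_without_mixing_is_pure_background_shift(self):
        """With alpha_mix = 0 the ROI trace is uncontaminated, so correction
        subtracts exactly 0.7 * the background trace."""
        p = synth.SessionParams(fs=1000.0, conditions=("a",), n_blocks_per_condition=1,
                                block_s=10.0, interblock_s=5.0)
        sched = synth.generate_schedule(p, np.random.default_rng(0))
        u = [synth.SortedUnit("u0", np.array([1.0, 2.0]), synth.make_template(0.6))]
        cp = synth.CalciumParams(neuropil_alpha=0.0, shot_noise_f=0.0,
                                 neuropil_pop_fraction=0.0)
        traces, _ = synth.generate_calcium(u, cp, sched, seed=0)
        corrected = neuropil_correct(traces.F, traces.F_neuropil)
        np.testing.assert_allclose(traces.F - corrected, 0.7 * traces.F_neuropil)

    def test_rate_ratio_ordering_survives_pipeline(self):
        traces, sched, info = synth.generate_calcium_session(
            "excitatory", n_rois=40, n_blocks_per_condition=4, seed=4)
        f_true = neuropil_correct(traces.F, traces.F_neuropil)
        dff = dff_vs_gray(f_true, sched, traces.frame_rate)
        from dlam.calcium import condition_responses
        pop = condition_responses(dff, sched, traces.frame_rate)["population"]
        assert pop["orthogonal"] > pop["monocular"] > pop["phase_offset"]

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValidationError):
            synth.CalciumParams(tau_s=0.0)
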