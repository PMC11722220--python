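import numpy as np
import pytest

from dlam import muae, synth
from dlam.csd import assign_layers
from dlam.io_core import Block, StimulusSchedule, ValidationError


def _tone(freq, fs=25_000.0, dur=2.0, n_ch=2):
    t = np.arange(int(dur * fs)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))


class TestCommonMedianReference:
    def test_identical_channels_cancel(self):
        x = np.tile(np.sin(np.linspace(0, 10, 1000)), (4, 1))
        np.testing.assert_allclose(muae.common_median_reference(x), 0.0, atol=1e-15)

    def test_channel_offset_removed(self):
        x = np.zeros((3, 500))
        x[1] += 4.2
        out = muae.common_median_reference(x)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_matches_two_pass_median_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 1000))
        got = muae.common_median_reference(x)
        y = x.copy()
        for ch in range(8):
            y[ch] -= np.median(y[ch])
        for t in range(1000):
            y[:, t] -= np.median(y[:, t])
        np.testing.assert_allclose(got, y, atol=1e-14)

    def test_single_channel_rejected(self):
        with pytest.raises(ValidationError):
            muae.common_median_reference(np.zeros((1, 100)))


class TestNotch60:
    def test_60hz_attenuated_10db(self):
        x = _tone(60.0)
        y = muae.notch60_iir(x)
        core = slice(x.shape[1] // 4, -x.shape[1] // 4)
        assert np.abs(y[0, core]).max() < 10 ** (-10 / 20)

    def test_600hz_and_1khz_unchanged(self):
        for f in (600.0, 1000.0):
            x = _tone(f)
            y = muae.notch60_iir(x)
            core = slice(x.shape[1] // 4, -x.shape[1] // 4)
            assert np.abs(y[0, core]).max() == pytest.approx(1.0, abs=0.11)

    def test_zeros_stay_zero(self):
        np.testing.assert_array_equal(muae.notch60_iir(np.zeros((2, 1000))), 0.0)

    def test_wrong_fs_rejected(self):
        with pytest.raises(ValidationError):
            muae.notch60_iir(np.zeros((2, 100)), fs=1000.0)


class TestComputeMuae:
    def test_zeros_in_zeros_out(self):
        out = muae.compute_muae(np.zeros((2, 50_000)))
        np.testing.assert_allclose(out.envelope, 0.0, atol=1e-15)
        assert out.fs == 1000.0

    def test_envelope_nonnegative_and_sign_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 100_000)) * 1e-5
        a = muae.compute_muae(x)
        b = muae.compute_muae(-x)
        assert a.envelope.min() >= 0.0
        np.testing.assert_allclose(a.envelope, b.envelope, atol=1e-18)

    def test_out_of_band_tone_rejected(self):
        """A 100 Hz tone (below the 500-5000 Hz band) must yield a tiny
        envelope compared with an in-band tone of equal amplitude."""
        low = muae.compute_muae(_tone(100.0, dur=1.0) * 1e-4)
        mid = muae.compute_muae(_tone(1500.0, dur=1.0) * 1e-4)
        core = slice(250, 750)
        assert low.envelope[0, core].mean() < 0.1 * mid.envelope[0, core].mean()

    def test_envelope_scales_with_insertion_rate(self):
        """Doubling the inserted template rate ~doubles the mean envelope."""
        fs = 25_000.0
        rng = np.random.default_rng(2)
        w = synth.make_template(0.6) * 1e-3
        out = {}
        for rate in (10.0, 20.0):
            x = np.zeros((2, int(20 * fs)))
            times = np.sort(rng.uniform(0.2, 19.5, int(rate * 20)))
            for t in times:
                i = int(t * fs)
                x[0, i:i + w.size] += w
            env = muae.compute_muae(x)
            out[rate] = env.envelope[0].mean()
        assert out[20.0] / out[10.0] == pytest.approx(2.0, rel=0.10)


class TestZScore:
    def _sched(self):
        return StimulusSchedule([Block("a", 2.0, 6.0), Block("a", 8.0, 12.0)], [[], []])

    def test_interblock_self_check(self):
        rng = np.random.default_rng(3)
        env = muae.MuaeTrace(np.abs(rng.standard_normal((2, 14_000))), 1000.0)
        sched = self._sched()
        z = muae.zscore_interblock(env, sched)
        mask = sched.interblock_mask(14_000, 1000.0)
        np.testing.assert_allclose(z.z[:, mask].mean(axis=1), 0.0, atol=1e-6)
        np.testing.assert_allclose(z.z[:, mask].std(axis=1), 1.0, atol=1e-6)

    def test_significance_threshold_value(self):
        """A sample at mean + 1.96 SD scores exactly the z = 1.96 cutoff."""
        env_vals = np.abs(np.random.default_rng(4).standard_normal((1, 14_000)))
        env = muae.MuaeTrace(env_vals, 1000.0)
        sched = self._sched()
        z = muae.zscore_interblock(env, sched)
        probe = z.baseline_mean[0] + 1.96 * z.baseline_sd[0]
        z_probe = (probe - z.baseline_mean[0]) / z.baseline_sd[0]
        assert z_probe == pytest.approx(muae.SIGNIFICANCE_Z)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        base = np.abs(rng.standard_normal((1, 14_000)))
        sched = self._sched()
        z1 = muae.zscore_interblock(muae.MuaeTrace(base, 1000.0), sched)
        z2 = muae.zscore_interblock(muae.MuaeTrace(3.0 * base + 2.0, 1000.0), sched)
        np.testing.assert_allclose(z1.z, z2.z, atol=1e-9)

    def test_degenerate_baseline_rejected(self):
        env = muae.MuaeTrace(np.ones((1, 14_000)), 1000.0)
        with pytest.raises(ValidationError):
            muae.zscore_interblock(env, self._sched())


class TestConditionResponse:
    def _make(self, gain_by_cond):
        """Constructed z traces with known per-condition early/late structure."""
        fs = 1000.0
        blocks, events = [], []
        t0 = 1.0
        for cond in gain_by_cond:
            blocks.append(Block(cond, t0, t0 + 4.0))
            events.append(list(t0 + np.arange(0.0, 3.5, 0.5)))
            t0 += 5.0
        sched = StimulusSchedule(blocks, events)
        n = int((t0 + 1) * fs)
        z = np.zeros((8, n))
        kern_t = np.arange(0, 0.4, 1 / fs)
        for cond, (gE, gL) in gain_by_cond.items():
            kern = gE * synth.early_kernel(kern_t) + gL * synth.late_kernel(kern_t)
            for ev in sched.events_for(cond):
                i = int(ev * fs)
                z[:, i:i + kern.size] += kern
        return muae.MuaeTrace(z, fs, z=z), sched

    def test_identical_conditions_have_zero_difference(self):
        trace, sched = self._make({"monocular": (1.0, 0.0), "concordant": (1.0, 0.0)})
        al = assign_layers(4, 8, 100.0)
        resp = muae.condition_response(trace, sched, al, 400.0)
        for layer, d in resp["delta"]["concordant"].items():
            np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_encoded_gains_show_in_windows(self):
        trace, sched = self._make({
            "monocular": (1.0, 0.0), "concordant": (2.0, 0.0), "orthogonal": (1.0, 1.0)})
        al = assign_layers(4, 8, 100.0)
        resp = muae.condition_response(trace, sched, al, 400.0)
        d_conc = np.stack(list(resp["delta"]["concordant"].values()))
        d_orth = np.stack(list(resp["delta"]["orthogonal"].values()))
        e_c, l_c = muae.window_means(d_conc)
        e_o, l_o = muae.window_means(d_orth)
        assert e_c > 0 and abs(l_c) < 1e-9
        assert abs(e_o) < 1e-9 and l_o > 0

    def test_missing_condition_named(self):
        trace, sched = self._make({"concordant": (1.0, 0.0)})
        al = assign_layers(4, 8, 100.0)
        with pytest.raises(ValidationError, match="monocular"):
            muae.condition_response(trace, sched, al, 400.0)


class TestWindowMeans:
    def test_constant_one(self):
        assert muae.window_means(np.ones(500)) == (1.0, 1.0)

    def test_step_at_90ms(self):
        z = np.zeros(500)
        z[90:] = 2.0
        early, late = muae.window_means(z)
        assert early == 0.0 and late == 2.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            muae.window_means(np.ones(50))
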