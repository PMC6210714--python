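"""Conditioning chain: bad channels, FIR, PCA spatial filter, envelopes."""

import numpy as np
import pytest
from scipy import signal as sps

import emgforce as ef
from emgforce.preprocess import BAND_PASS_DEFAULT, ENVELOPE_LOWPASS_DEFAULT

FS = 1000.0


class TestReplaceBadChannels:
    def test_empty_set_is_identity(self, small_recording):
        out = ef.replace_bad_channels(small_recording.emg, set(),
                                      small_recording.grid)
        assert np.array_equal(out, small_recording.emg)

    def test_bad_channel_copies_exactly_one_neighbor(self, small_recording):
        grid = small_recording.grid
        out = ef.replace_bad_channels(small_recording.emg,
                                      small_recording.bad_channels, grid, seed=1)
        for ch in small_recording.bad_channels:
            matches = [n for n in grid.neighbors(ch)
                       if np.array_equal(out[ch], small_recording.emg[n])]
            assert len(matches) >= 1
        good = set(range(grid.n_channels)) - small_recording.bad_channels
        for ch in good:
            assert np.array_equal(out[ch], small_recording.emg[ch])

    def test_fully_surrounded_channel_rejected(self):
        grid = ef.GridSpec(3, 3)
        emg = np.random.default_rng(0).standard_normal((9, 50))
        # center (4) and all its 4-neighbors flagged
        with pytest.raises(ValueError, match="no good 4-neighbor"):
            ef.replace_bad_channels(emg, {1, 3, 4, 5, 7}, grid)


class TestFirFilter:
    def test_order_50_means_51_taps(self):
        assert BAND_PASS_DEFAULT.n_taps == 51
        assert len(BAND_PASS_DEFAULT.taps(FS)) == 51

    def test_band_pass_rejects_dc(self):
        w, h = sps.freqz(BAND_PASS_DEFAULT.taps(FS), worN=[0.0], fs=FS)
        assert abs(h[0]) < 0.01
        x = np.ones(4000)
        y = ef.fir_filter(x, BAND_PASS_DEFAULT, FS)
        assert np.abs(y[1000:-1000]).max() < 0.01

    def test_band_pass_passes_100hz(self):
        w, h = sps.freqz(BAND_PASS_DEFAULT.taps(FS), worN=[100.0], fs=FS)
        assert abs(abs(h[0]) - 1.0) < 0.05
        t = np.arange(4000) / FS
        y = ef.fir_filter(np.sin(2 * np.pi * 100 * t), BAND_PASS_DEFAULT, FS)
        assert abs(np.abs(y[1000:-1000]).max() - 1.0) < 0.05

    def test_length_preserved(self):
        x = np.random.default_rng(0).standard_normal((3, 500))
        assert ef.fir_filter(x, BAND_PASS_DEFAULT, FS).shape == x.shape

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 600))
        lhs = ef.fir_filter(2.5 * x - 1.5 * y, BAND_PASS_DEFAULT, FS)
        rhs = (2.5 * ef.fir_filter(x, BAND_PASS_DEFAULT, FS)
               - 1.5 * ef.fir_filter(y, BAND_PASS_DEFAULT, FS))
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_causal_variant_compensates_group_delay(self):
        spec = ef.FilterSpec("low_pass", (5.0,), zero_phase=False)
        x = np.zeros(800)
        x[400] = 1.0
        y = ef.fir_filter(x, spec, FS)
        assert abs(int(np.argmax(y)) - 400) <= 1

    def test_edges_must_stay_below_nyquist(self):
        spec = ef.FilterSpec("band_pass", (20.0, 500.0))
        with pytest.raises(ValueError):
            spec.taps(FS)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ef.fir_filter(np.zeros(30), BAND_PASS_DEFAULT, FS)


class TestPcaSpatialFilter:
    def test_zero_drops_reconstructs_input(self):
        x = np.random.default_rng(2).standard_normal((6, 300))
        out = ef.pca_spatial_filter(x, 0, 0)
        assert np.allclose(out, x, atol=1e-8)

    def test_projection_is_stable(self):
        # re-filtering the output while dropping only its four dead modes
        # leaves it unchanged: the retained subspace is a fixed projection
        x = np.random.default_rng(3).standard_normal((8, 400))
        once = ef.pca_spatial_filter(x, 2, 2)
        again = ef.pca_spatial_filter(once, 0, 4)
        assert np.allclose(once, again, atol=1e-8)

    def test_rank_and_variance_of_retained_modes(self):
        # 6 channels with known diagonalizable covariance
        rng = np.random.default_rng(4)
        A = rng.standard_normal((6, 6))
        x = A @ rng.standard_normal((6, 20_000))
        out = ef.pca_spatial_filter(x, 2, 2)
        outc = out - out.mean(axis=1, keepdims=True)
        cov_out = outc @ outc.T / (x.shape[1] - 1)
        evals_out = np.sort(np.linalg.eigvalsh(cov_out))[::-1]
        assert np.sum(evals_out > 1e-8 * evals_out[0]) == 2
        xc = x - x.mean(axis=1, keepdims=True)
        evals_in = np.sort(np.linalg.eigvalsh(xc @ xc.T / (x.shape[1] - 1)))[::-1]
        assert np.trace(cov_out) == pytest.approx(evals_in[2:4].sum(), rel=1e-8)

    def test_rank_deficient_warns(self):
        x = np.random.default_rng(5).standard_normal((10, 8))
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            ef.pca_spatial_filter(x, 1, 1)

    def test_too_many_drops_rejected(self):
        with pytest.raises(ValueError):
            ef.pca_spatial_filter(np.zeros((4, 100)), 2, 2)


class TestEnvelope:
    def test_constant_passes_through(self):
        env = ef.envelope(np.full(3000, 0.7), FS)
        assert abs(env[1000:-1000].mean() - 0.7) < 0.007

    def test_full_wave_symmetry(self):
        x = np.random.default_rng(6).standard_normal(2000)
        assert np.array_equal(ef.envelope(x, FS), ef.envelope(-x, FS))

    def test_rectified_sinusoid_mean(self):
        # steady-state envelope of |A sin| is 2A/pi
        t = np.arange(8000) / FS
        A = 1.3
        env = ef.envelope(A * np.sin(2 * np.pi * 100 * t), FS)
        steady = env[2000:-2000]
        assert abs(steady.mean() - 2 * A / np.pi) / (2 * A / np.pi) < 0.05

    def test_non_negative(self):
        x = np.random.default_rng(7).standard_normal(2000)
        assert ef.envelope(x, FS).min() >= 0.0


class TestNormalizePerCycle:
    BOUNDS = [(0, 50), (50, 120)]

    def test_each_cycle_max_is_one(self):
        rng = np.random.default_rng(8)
        x = np.abs(rng.standard_normal((3, 120))) + 0.1
        out = ef.normalize_per_cycle(x, self.BOUNDS)
        for s, e in self.BOUNDS:
            assert np.allclose(out[:, s:e].max(axis=1), 1.0)

    def test_zero_cycle_left_untouched(self):
        x = np.zeros(120)
        x[50:120] = 2.0
        out = ef.normalize_per_cycle(x, self.BOUNDS)
        assert np.all(out[:50] == 0.0)
        assert np.allclose(out[50:], 1.0)

    def test_cycles_scaled_independently(self):
        x = np.concatenate([np.full(50, 2.0), np.full(70, 5.0)])
        out = ef.normalize_per_cycle(x, self.BOUNDS)
        assert np.allclose(out, 1.0)
        # a ramp shows the per-cycle scale: max 2 in cycle 1, max 5 in cycle 2
        x2 = np.concatenate([np.linspace(0, 2, 50), np.linspace(0, 5, 70)])
        out2 = ef.normalize_per_cycle(x2, self.BOUNDS)
        assert np.allclose(out2[:50], x2[:50] / 2)
        assert np.allclose(out2[50:], x2[50:] / 5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        x = np.abs(rng.standard_normal(120))
        a = ef.normalize_per_cycle(x, self.BOUNDS)
        b = ef.normalize_per_cycle(3.7 * x, self.BOUNDS)
        assert np.allclose(a, b)

    def test_empty_cycle_rejected(self):
        with pytest.raises(ValueError, match="empty cycle"):
            ef.normalize_per_cycle(np.ones(10), [(3, 3)])


class TestPreprocessRecording:
    def test_output_contracts(self, mid_envelopes):
        env = mid_envelopes
        assert env.envelopes.min() >= 0.0
        for s, e in env.cycle_bounds:
            assert np.allclose(env.envelopes[:, s:e].max(axis=1), 1.0)
            assert env.force_norm[s:e].max() == pytest.approx(1.0)

    def test_envelopes_track_force_on_active_channels(self, mid_recording,
                                                      mid_envelopes):
        top = np.argsort(-mid_recording.truth_weights)[:32]
        corrs = [np.corrcoef(mid_envelopes.envelopes[ch],
                             mid_envelopes.force_norm)[0, 1] for ch in top]
        assert np.mean(corrs) > 0.9

    def test_envelope_only_config_reproduces_envelope(self, small_recording):
        cfg = ef.PreprocessConfig(replace_bad=False, apply_band_pass=False,
                                  apply_pca=False, normalize=False)
        out = ef.preprocess_recording(small_recording, cfg)
        direct = ef.envelope(small_recording.emg, small_recording.fs_hz)
        assert np.array_equal(out.envelopes, direct)
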