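import numpy as np
import pytest
from scipy import signal as sps

from delaystand import fourier
from delaystand.fourier import (
    coherence,
    coherence_limit,
    cross_covariance,
    gain,
    peak_to_peak,
    pool_participants,
    preprocess_emg,
    scale_emg,
    segment_spectra,
)

FS = 2000.0
NFFT = 2048


def coupled_pair(rng, n, kernel_delay=40, noise=0.5):
    """y = x delayed + noise: a simple coupled pair for oracle tests."""
    x = rng.standard_normal(n)
    y = np.roll(x, kernel_delay) + noise * rng.standard_normal(n)
    return x, y


class TestPreprocessEmg:
    def test_dc_killed(self):
        out = preprocess_emg(np.full(4000, 5.0), FS)
        assert np.abs(out[500:-500]).max() < 1e-6

    def test_rectified_sinusoid_mean(self):
        t = np.arange(int(4 * FS)) / FS
        a = 2.0
        # 130 Hz passes the 30 Hz high-pass untouched and is incommensurate
        # with fs, so the sample mean approaches the continuous 2A/pi
        out = preprocess_emg(a * np.sin(2 * np.pi * 130 * t), FS)
        assert out[1000:-1000].mean() == pytest.approx(2 * a / np.pi, rel=0.01)

    def test_zero_phase_at_50hz(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 50 * t)
        sos = sps.butter(3, 30.0, btype="highpass", fs=FS, output="sos")
        filtered = sps.sosfiltfilt(sos, x)
        xc = np.correlate(filtered[2000:6000], x[2000:6000], "full")
        lag = np.argmax(xc) - 3999
        assert abs(lag) == 0

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            preprocess_emg(np.zeros(100), 50.0)


class TestScaleEmg:
    def test_identity_when_equal_to_baseline(self, rng):
        quiet_theta = 0.1 * rng.standard_normal(1000)
        quiet_env = np.full(1000, 2.0)
        out = scale_emg(np.full(500, 2.0), quiet_env, quiet_theta)
        np.testing.assert_allclose(out, 1.0)

    def test_simple_division(self, rng):
        quiet_theta = 0.1 * rng.standard_normal(1000)
        out = scale_emg(np.array([5.0]), np.full(1000, 2.0), quiet_theta)
        assert out[0] == pytest.approx(2.5)

    def test_band_masks_baseline_mean(self, rng):
        quiet_theta = np.concatenate([np.zeros(500), np.full(500, 3.0)])
        quiet_env = np.concatenate([np.full(500, 2.0), np.full(500, 10.0)])
        # median is 1.5; band +-0.25 deg keeps only theta=0 samples... median
        # of half/half is 1.5 -> no samples in band; widen by re-centering
        quiet_theta = np.concatenate([np.zeros(600), np.full(400, 3.0)])
        quiet_env = np.concatenate([np.full(600, 2.0), np.full(400, 10.0)])
        out = scale_emg(np.array([4.0]), quiet_env, quiet_theta)
        assert out[0] == pytest.approx(2.0)  # baseline from in-band samples only

    def test_no_inband_samples_rejected(self):
        theta = np.array([0.0, 10.0])
        with pytest.raises(ValueError, match="0.25"):
            scale_emg(np.ones(3), np.ones(2), theta, posture_band_deg=0.25)


class TestSegmentSpectra:
    def test_frequency_resolution(self):
        s = segment_spectra(np.random.default_rng(0).standard_normal(3 * NFFT),
                            np.random.default_rng(1).standard_normal(3 * NFFT))
        assert s.df == pytest.approx(0.9766, abs=1e-4)

    def test_segment_count_80s(self):
        n = int(80 * FS)
        x = np.zeros(n)
        s = segment_spectra(x + 1e-9, x + 1e-9)
        assert s.L == 78

    def test_76_segments_span_77_82s(self):
        assert round(76 * NFFT / FS, 2) == 77.82

    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(4 * NFFT)
        s = segment_spectra(x, x)
        f, c, lim = coherence(s)
        np.testing.assert_allclose(c[1:], 1.0, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            segment_spectra(np.zeros(100), np.zeros(100))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            segment_spectra(np.zeros(NFFT), np.zeros(NFFT + 1))


class TestCoherence:
    def test_limit_L76_closed_form(self):
        assert coherence_limit(76) == pytest.approx(1 - 0.05 ** (1 / 75), abs=1e-12)
        assert coherence_limit(76) == pytest.approx(0.0392, abs=1e-4)

    def test_limit_requires_two_segments(self):
        with pytest.raises(ValueError):
            coherence_limit(1)

    def test_false_positive_rate_near_alpha(self, rng):
        fracs = []
        for _ in range(20):
            x = rng.standard_normal(76 * NFFT)
            y = rng.standard_normal(76 * NFFT)
            f, c, lim = coherence(segment_spectra(x, y))
            fracs.append(np.mean(c[1:] > lim))
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_snr_relation(self, rng):
        # y = x + noise: per-frequency SNR = 1/sigma^2, flat
        sigma = 1.0
        x = rng.standard_normal(76 * NFFT)
        y = x + sigma * rng.standard_normal(76 * NFFT)
        f, c, lim = coherence(segment_spectra(x, y))
        expected = 1.0 / (1.0 + sigma**2)
        assert np.mean(c[5:500]) == pytest.approx(expected, abs=0.05)

    def test_cauchy_schwarz_bound(self, rng):
        for _ in range(5):
            x = rng.standard_normal(6 * 256)
            y = rng.standard_normal(6 * 256)
            f, c, lim = coherence(segment_spectra(x, y, nfft=256, fs=200.0))
            assert np.nanmax(c) <= 1.0 + 1e-10
            assert np.nanmin(c) >= -1e-10

    def test_brute_force_oracle(self, rng):
        x = rng.standard_normal(5 * 128)
        y = np.roll(x, 3) + rng.standard_normal(5 * 128)
        s = segment_spectra(x, y, nfft=128, fs=200.0)
        f, c, lim = coherence(s)
        # independent brute-force per-segment computation
        pss = np.zeros(128)
        prr = np.zeros(128)
        psr = np.zeros(128, dtype=complex)
        for i in range(5):
            xs = x[i * 128:(i + 1) * 128] - x[i * 128:(i + 1) * 128].mean()
            ys = y[i * 128:(i + 1) * 128] - y[i * 128:(i + 1) * 128].mean()
            fx = np.fft.fft(xs)
            fy = np.fft.fft(ys)
            pss += np.abs(fx) ** 2
            prr += np.abs(fy) ** 2
            psr += np.conj(fx) * fy
        want = np.abs(psr[:65]) ** 2 / (pss[:65] * prr[:65])
        np.testing.assert_allclose(c, want, atol=1e-10)


class TestGain:
    def test_scalar_system_gain_three(self, rng):
        x = rng.standard_normal(10 * NFFT)
        s = segment_spectra(x, 3.0 * x)
        f, g, mask = gain(s)
        np.testing.assert_allclose(g[1:], 3.0, atol=1e-8)

    def test_known_filter_transfer_magnitude(self, rng):
        sos = sps.butter(2, 100.0, fs=FS, output="sos")
        x = rng.standard_normal(40 * NFFT)
        y = sps.sosfilt(sos, x) + 0.05 * rng.standard_normal(40 * NFFT)
        f, g, mask = gain(segment_spectra(x, y))
        w, h = sps.sosfreqz(sos, worN=f[:300], fs=FS)
        sel = mask[:300] & (f[:300] > 5)
        rel = np.abs(g[:300][sel] - np.abs(h)[sel]) / np.abs(h)[sel]
        assert np.median(rel) < 0.05
        assert rel.max() < 0.25

    def test_independent_signals_mostly_unreliable(self, rng):
        x = rng.standard_normal(76 * NFFT)
        y = rng.standard_normal(76 * NFFT)
        f, g, mask = gain(segment_spectra(x, y))
        assert np.mean(~mask) > 0.90


class TestCrossCovariance:
    def test_pure_delay_peak(self, rng):
        d = 100
        x = rng.standard_normal(20 * NFFT)
        y = np.roll(x, d)
        lags, q, ci = cross_covariance(segment_spectra(x, y))
        assert lags[np.argmax(q)] == pytest.approx(d / FS)

    def test_interval_calibration(self, rng):
        rates = []
        for _ in range(10):
            x = rng.standard_normal(76 * NFFT)
            y = rng.standard_normal(76 * NFFT)
            lags, q, ci = cross_covariance(segment_spectra(x, y))
            rates.append(np.mean(np.abs(q) > ci))
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_bootstrap_interval_agrees_with_analytic(self, rng):
        x = rng.standard_normal(20 * NFFT)
        y = rng.standard_normal(20 * NFFT)
        s = segment_spectra(x, y)
        lags, q, ci = cross_covariance(s)
        boot = fourier.bootstrap_covariance_interval(s, n_boot=50, seed=1)
        assert boot == pytest.approx(ci, rel=0.25)


class TestPeakToPeak:
    def lag_axis(self):
        return (np.arange(NFFT) - NFFT // 2) / FS

    def test_both_subthreshold_gives_zero(self):
        lags = self.lag_axis()
        q = np.zeros(NFFT)
        out = peak_to_peak(lags, q, ci95=1.0)
        assert out["amplitude"] == 0.0
        assert not out["short_significant"] and not out["medium_significant"]

    def test_arithmetic_of_significant_peaks(self):
        lags = self.lag_axis()
        q = np.zeros(NFFT)
        q[np.argmin(np.abs(lags - 0.060))] = 5.0
        q[np.argmin(np.abs(lags - 0.110))] = -4.0
        out = peak_to_peak(lags, q, ci95=1.0)
        assert out["amplitude"] == pytest.approx(9.0)

    def test_zeroing_rule_one_significant(self):
        lags = self.lag_axis()
        q = np.zeros(NFFT)
        q[np.argmin(np.abs(lags - 0.060))] = 5.0
        q[np.argmin(np.abs(lags - 0.110))] = -0.5
        out = peak_to_peak(lags, q, ci95=1.0)
        assert out["amplitude"] == pytest.approx(5.0)
        assert out["medium_value"] == 0.0


class TestPooling:
    def test_single_participant_identity(self, rng):
        x, y = coupled_pair(rng, 4 * 256)
        s = segment_spectra(x, y, nfft=256, fs=200.0)
        pooled = pool_participants([s])
        np.testing.assert_array_equal(pooled.psr, s.psr)
        assert pooled.L == s.L

    def test_equal_L_pooling_is_mean(self, rng):
        xa, ya = coupled_pair(rng, 4 * 256)
        xb, yb = coupled_pair(rng, 4 * 256)
        sa = segment_spectra(xa, ya, nfft=256, fs=200.0)
        sb = segment_spectra(xb, yb, nfft=256, fs=200.0)
        pooled = pool_participants([sa, sb])
        np.testing.assert_allclose(pooled.pss, (sa.pss + sb.pss) / 2, rtol=1e-12)
        assert pooled.L == sa.L + sb.L

    def test_pooling_lowers_coherence_limit(self, rng):
        xa, ya = coupled_pair(rng, 4 * 256)
        sa = segment_spectra(xa, ya, nfft=256, fs=200.0)
        pooled = pool_participants([sa, sa])
        assert coherence_limit(pooled.L) < coherence_limit(sa.L)

    def test_mismatched_nfft_rejected(self, rng):
        xa, ya = coupled_pair(rng, 4 * 256)
        sa = segment_spectra(xa, ya, nfft=256, fs=200.0)
        sb = segment_spectra(xa, ya, nfft=128, fs=200.0)
        with pytest.raises(ValueError, match="nfft"):
            pool_participants([sa, sb])


class TestKernelRecoveryMonotonicity:
    def test_peak_to_peak_monotone_in_coupling_gain(self):
        from delaystand.interface.trialio import TrialRecord
        from delaystand.signals import EVSConfig, VestibularCoupling, generate_emg, generate_evs
        evs = generate_evs(EVSConfig(duration_s=40.0, fs=FS, target_rms=1.5, seed=1))
        tr = TrialRecord(fs=FS, time_s=np.arange(len(evs)) / FS)
        amps = [0.0, 0.25, 0.5, 1.0]
        pps = []
        for a in amps:
            emg = generate_emg(tr, evs, VestibularCoupling(fs=FS, amplitude=a),
                               tonic=1.0, noise_std=0.15, seed=2)
            s = segment_spectra(evs, emg)
            pk = peak_to_peak(*cross_covariance(s))
            pps.append(pk["amplitude"])
        assert all(x < y for x, y in zip(pps, pps[1:]))
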