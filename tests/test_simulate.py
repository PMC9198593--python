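"""Synthetic cohort generator: stimuli, kernels, EEG and behavior."""

import numpy as np
import pytest
from scipy import signal as sps

from speechtrf import (
    CohortConfig,
    ConfigError,
    KernelParams,
    StimulusConfig,
    estimate_trf,
    generate_cohort,
    generate_envelope,
    ground_truth_kernel,
    simulate_behavior,
    synthesize_eeg,
)
from speechtrf.features import N1_WINDOW_MS, detect_peak
from speechtrf.simulate import convolve_envelope_kernel, psychometric
from speechtrf.trf import LagSpec, build_lag_matrix


class TestGenerateEnvelope:
    def test_zero_duration_rejected(self):
        with pytest.raises(ConfigError):
            StimulusConfig(duration_s=0.0)

    def test_deterministic_for_fixed_seed(self, short_stim):
        a = generate_envelope(short_stim, seed=5)
        b = generate_envelope(short_stim, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = generate_envelope(short_stim, seed=6)
        assert not np.array_equal(a.samples, c.samples)

    def test_nonnegative_with_zero_gaps(self, short_stim):
        env = generate_envelope(short_stim, seed=1)
        assert env.samples.min() >= 0.0
        assert (env.samples == 0.0).mean() > 0.2  # inter-sentence silence

    def test_syllable_rate_peak_against_periodogram(self):
        cfg = StimulusConfig(duration_s=60.0, syllable_rate_hz=3.8)
        env = generate_envelope(cfg, seed=3)
        voiced = env.samples[env.samples > 0]
        f, pxx = sps.periodogram(voiced - voiced.mean(), fs=cfg.fs_hz)
        band = (f >= 1.0) & (f <= 10.0)
        peak_hz = f[band][np.argmax(pxx[band])]
        assert abs(peak_hz - 3.8) <= 0.5

    def test_dominant_energy_in_analysis_band(self, short_stim):
        env = generate_envelope(short_stim, seed=9)
        f, pxx = sps.periodogram(env.samples - env.samples.mean(), fs=short_stim.fs_hz)
        in_band = pxx[(f >= 1.0) & (f <= 10.0)].sum()
        assert in_band / pxx[f > 0].sum() > 0.5


class TestGroundTruthKernel:
    def test_no_modulation_gives_identical_kernels(self):
        kp = KernelParams(amp_slope_per_db=0.0, lat_slope_ms_per_db=0.0)
        k_lo = ground_truth_kernel(kp, -4.0)
        k_hi = ground_truth_kernel(kp, +4.0)
        np.testing.assert_array_equal(k_lo, k_hi)

    def test_snr_modulation_scales_amplitude_and_latency(self, kernel):
        spec = LagSpec()
        k_hi = ground_truth_kernel(kernel, +4.0, spec)
        k_lo = ground_truth_kernel(kernel, -4.0, spec)
        assert abs(k_hi.min()) > abs(k_lo.min())  # larger N1 at high SNR
        lat_hi = spec.lags_ms[np.argmin(k_hi)]
        lat_lo = spec.lags_ms[np.argmin(k_lo)]
        assert lat_hi < lat_lo  # earlier N1 at high SNR

    def test_single_gaussian_identity(self):
        kp = KernelParams(n1_amplitude=-1.0, p2_amplitude=1e-12)
        spec = LagSpec()
        k = ground_truth_kernel(kp, 0.0, spec)
        i = np.argmin(k)
        assert k[i] == pytest.approx(-1.0, abs=1e-6)
        assert abs(spec.lags_ms[i] - kp.n1_latency_ms) < 1000.0 / spec.fs_hz

    def test_amplitude_floor_at_zero(self):
        kp = KernelParams(amp_slope_per_db=0.2)
        k = ground_truth_kernel(kp, -10.0)  # 1 + 0.2*(-10) < 0 -> floored
        np.testing.assert_array_equal(k, np.zeros_like(k))

    def test_zero_outside_support(self, kernel):
        spec = LagSpec()
        k = ground_truth_kernel(kernel, 0.0, spec)
        outside = (spec.lags_ms < 0.0) | (spec.lags_ms > 400.0)
        np.testing.assert_array_equal(k[outside], 0.0)


class TestSynthesizeEEG:
    def test_noiseless_channel_equals_convolution_oracle(self, short_stim, kernel):
        env = generate_envelope(short_stim, seed=2)
        cfg = CohortConfig(n_subjects=2, n_channels=1, channel_names=("C3",),
                           noise_sd=0.0)
        eeg = synthesize_eeg(env, kernel, cfg, 0.0, subject_seed=1,
                             topography=np.array([1.0]))
        spec = LagSpec()
        k = ground_truth_kernel(kernel, 0.0, spec)
        # direct time-domain oracle: r(t) = sum_tau k(tau) s(t - tau)
        n = env.n_samples
        oracle = np.zeros(n)
        for j, ell in enumerate(spec.lag_samples):
            for t in range(max(0, ell), min(n, n + ell)):
                if 0 <= t - ell < n:
                    oracle[t] += k[j] * env.samples[t - ell]
        np.testing.assert_allclose(eeg.data[0], oracle, atol=1e-10)

    def test_convolution_matches_design_matrix(self, short_stim, kernel):
        env = generate_envelope(short_stim, seed=4)
        spec = LagSpec()
        k = ground_truth_kernel(kernel, 0.0, spec)
        direct = build_lag_matrix(env.samples, spec) @ k
        fast = convolve_envelope_kernel(env.samples, k, spec)
        np.testing.assert_allclose(fast, direct, atol=1e-10)

    def test_null_kernel_gives_silence(self, short_stim):
        env = generate_envelope(short_stim, seed=2)
        kp = KernelParams(amp_slope_per_db=1.0)  # floor kills the kernel at -4 dB
        cfg = CohortConfig(n_subjects=2, n_channels=2,
                           channel_names=("C3", "CP3"), noise_sd=0.0)
        eeg = synthesize_eeg(env, kp, cfg, -4.0, subject_seed=0)
        np.testing.assert_array_equal(eeg.data, 0.0)

    def test_wrong_topography_length_rejected(self, short_stim, kernel):
        env = generate_envelope(short_stim, seed=2)
        cfg = CohortConfig(n_subjects=2, n_channels=2,
                           channel_names=("C3", "CP3"), noise_sd=0.0)
        with pytest.raises(Exception):
            synthesize_eeg(env, kernel, cfg, 0.0, 1, topography=np.ones(5))

    def test_roundtrip_recovery_noiseless(self, short_stim, kernel):
        """Noiseless EEG -> small-lambda ridge recovers the kernel and its N1."""
        env = generate_envelope(short_stim, seed=7)
        cfg = CohortConfig(n_subjects=2, n_channels=1, channel_names=("C3",),
                           noise_sd=0.0)
        eeg = synthesize_eeg(env, kernel, cfg, 0.0, 1, topography=np.array([1.0]))
        spec = LagSpec()
        est = estimate_trf(env, eeg.data[0], spec, lambda_=1e-8)
        k = ground_truth_kernel(kernel, 0.0, spec)
        mask = (spec.lags_ms >= 0.0) & (spec.lags_ms <= 400.0)
        rho = np.corrcoef(est.coefficients[mask], k[mask])[0, 1]
        assert rho >= 0.99
        peak = detect_peak(est, "negative", N1_WINDOW_MS)
        true_lat = spec.lags_ms[np.argmin(k)]
        assert abs(peak.latency_ms - true_lat) <= 1000.0 / spec.fs_hz + 1e-9

    def test_monotone_n1_amplitude_without_noise(self, short_stim, kernel):
        """amp_slope > 0, no noise: extracted N1 amplitude increases with SNR."""
        env = generate_envelope(short_stim, seed=8)
        cfg = CohortConfig(n_subjects=2, n_channels=1, channel_names=("C3",),
                           noise_sd=0.0)
        spec = LagSpec()
        amps = []
        for dsnr in cfg.delta_snr_grid_db:
            eeg = synthesize_eeg(env, kernel, cfg, dsnr, 1, topography=np.array([1.0]))
            est = estimate_trf(env, eeg.data[0], spec, lambda_=1e-8)
            amps.append(detect_peak(est, "negative", N1_WINDOW_MS).amplitude)
        assert all(b > a for a, b in zip(amps, amps[1:]))


class TestSimulateBehavior:
    def test_midpoint_is_50pct(self):
        # deterministic expectation: f(SRT_50) = 0.5 exactly
        scores = [
            simulate_behavior(-7.0, 1.462, 0.0, seed=s).intelligibility_pct
            for s in range(300)
        ]
        se = 100.0 * np.sqrt(0.25 / 100.0) / np.sqrt(300)
        assert abs(np.mean(scores) - 50.0) < 4 * se

    def test_large_sample_matches_logistic(self):
        sample = simulate_behavior(-7.0, 1.462, 2.0, n_sentences=20000,
                                   words_per_sentence=5, seed=1)
        expected = 100.0 * psychometric(2.0, 1.462)
        assert abs(sample.intelligibility_pct - expected) < 1.0

    def test_denominator_is_100_words(self):
        sample = simulate_behavior(-7.0, 1.462, 0.5, seed=3)
        assert sample.n_words == 100
        # with 100 words every observable score is an integer percentage
        assert sample.intelligibility_pct == int(sample.intelligibility_pct)

    def test_mean_scores_track_psychometric(self):
        for dsnr in (-4.0, -0.5, 2.0):
            scores = [
                simulate_behavior(-7.0, 1.462, dsnr, seed=s).intelligibility_pct
                for s in range(400)
            ]
            p = float(psychometric(dsnr, 1.462))
            se = 100.0 * np.sqrt(p * (1 - p) / 100.0) / np.sqrt(400)
            assert abs(np.mean(scores) - 100.0 * p) < 4 * se + 1e-9

    def test_invalid_slope_rejected(self):
        with pytest.raises(ConfigError):
            simulate_behavior(-7.0, 0.0, 0.0)


class TestGenerateCohort:
    def test_srt_distribution(self):
        cfg = CohortConfig(n_subjects=500, n_channels=2,
                           channel_names=("C3", "CP3"), seed=42)
        cohort = generate_cohort(cfg, StimulusConfig(duration_s=5.0), with_eeg=False)
        srts = [s.srt50_db for s in cohort]
        assert abs(np.mean(srts) - (-7.0)) < 0.2
        assert 0.5 < np.std(srts) < 1.3

    def test_same_seed_identical_dataset(self, small_cohort_cfg, kernel):
        stim = StimulusConfig(duration_s=20.0)
        a = generate_cohort(small_cohort_cfg, stim, kernel)
        b = generate_cohort(small_cohort_cfg, stim, kernel)
        for sa, sb in zip(a, b):
            assert sa.srt50_db == sb.srt50_db
            for d in sa.conditions:
                np.testing.assert_array_equal(sa.envelopes[d].samples,
                                              sb.envelopes[d].samples)
                np.testing.assert_array_equal(sa.eeg[d].data, sb.eeg[d].data)
                assert (sa.behavior[d].intelligibility_pct
                        == sb.behavior[d].intelligibility_pct)

    def test_default_shape_counts(self):
        cfg = CohortConfig(seed=1)  # 18 subjects, 6 conditions, 32 channels
        cohort = generate_cohort(cfg, StimulusConfig(duration_s=15.0))
        assert cohort.n_subjects == 18
        for sub in cohort:
            assert len(sub.conditions) == 6
            for d in sub.conditions:
                assert sub.eeg[d].n_channels == 32
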