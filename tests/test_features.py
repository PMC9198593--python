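"""Peak detection, windowed RMS, window optimization and RMS_sum."""

import numpy as np
import pandas as pd
import pytest

from speechtrf import (
    ConfigError,
    DataError,
    LagSpec,
    WindowSpec,
    compute_rms_sum,
    detect_peak,
    extract_feature_table,
    optimize_rms_windows,
    windowed_rms,
)
from speechtrf.features import N1_WINDOW_MS, P2_WINDOW_MS
from speechtrf.trf import TRFSet

SPEC = LagSpec()
LAGS = SPEC.lags_ms


def _gauss(mu, width, amp):
    return amp * np.exp(-0.5 * ((LAGS - mu) / width) ** 2)


def _trf_set(coefs, subject="S01", condition=0.0, channels=("C3",)):
    coefs = np.atleast_2d(coefs)
    return TRFSet(coefficients=coefs, lags_ms=LAGS, lambda_=1.0,
                  costs=np.zeros(coefs.shape[0]), channel_names=list(channels),
                  subject=subject, condition=condition)


class TestDetectPeak:
    def test_single_gaussian_minimum(self):
        peak = detect_peak(_gauss(100.0, 20.0, -0.8), "negative", N1_WINDOW_MS,
                           lags_ms=LAGS)
        assert peak.found
        assert abs(peak.latency_ms - 100.0) <= 1000.0 / 120.0
        assert peak.amplitude == pytest.approx(0.8, rel=1e-3)

    def test_flat_trf_fallback(self):
        peak = detect_peak(np.zeros_like(LAGS), "negative", N1_WINDOW_MS,
                           lags_ms=LAGS)
        assert not peak.found
        assert peak.amplitude == 0.0
        assert peak.latency_ms == 175.0

    def test_first_of_two_minima_returned(self):
        y = _gauss(90.0, 8.0, -1.0) + _gauss(150.0, 8.0, -1.5)
        peak = detect_peak(y, "negative", N1_WINDOW_MS, lags_ms=LAGS)
        assert abs(peak.latency_ms - 90.0) <= 1000.0 / 120.0

    def test_wrong_sign_extremum_skipped(self):
        # a positive-valued dip is not an N1; fallback applies
        y = 1.0 + _gauss(120.0, 15.0, -0.3)
        peak = detect_peak(y, "negative", N1_WINDOW_MS, lags_ms=LAGS)
        assert not peak.found

    def test_positive_polarity_p2(self):
        y = _gauss(100.0, 15.0, -1.0) + _gauss(210.0, 25.0, 0.7)
        peak = detect_peak(y, "positive", P2_WINDOW_MS, lags_ms=LAGS)
        assert peak.found
        assert abs(peak.latency_ms - 210.0) <= 1000.0 / 120.0

    def test_scaling_invariance_of_latency(self):
        y = _gauss(110.0, 18.0, -0.5)
        p1 = detect_peak(y, "negative", N1_WINDOW_MS, lags_ms=LAGS)
        p2 = detect_peak(3.7 * y, "negative", N1_WINDOW_MS, lags_ms=LAGS)
        assert p1.latency_ms == p2.latency_ms
        assert p2.amplitude == pytest.approx(3.7 * p1.amplitude, rel=1e-12)

    def test_window_outside_lags_rejected(self):
        with pytest.raises(ConfigError):
            detect_peak(np.zeros_like(LAGS), "negative", (400.0, 600.0),
                        lags_ms=LAGS)


class TestWindowedRMS:
    def test_constant_trf(self):
        y = np.full_like(LAGS, 0.5)
        assert windowed_rms(y, WindowSpec(83.0, 133.0), lags_ms=LAGS) == \
            pytest.approx(0.5)

    def test_hand_computed_two_samples(self):
        # window holding exactly the samples 3 and 4: sqrt((9+16)/2)
        y = np.zeros_like(LAGS)
        i = np.where(np.isclose(LAGS, 100.0))[0][0]
        y[i], y[i + 1] = 3.0, 4.0
        lo, hi = LAGS[i], LAGS[i + 1]
        val = windowed_rms(y, WindowSpec(lo - 1e-9, hi + 1e-9), lags_ms=LAGS)
        assert val == pytest.approx(np.sqrt(12.5), rel=1e-12)

    def test_homogeneity(self, rng):
        y = rng.standard_normal(LAGS.size)
        w = WindowSpec(50.0, 150.0)
        assert windowed_rms(-2.0 * y, w, lags_ms=LAGS) == \
            pytest.approx(2.0 * windowed_rms(y, w, lags_ms=LAGS), rel=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ConfigError):
            windowed_rms(np.zeros_like(LAGS), WindowSpec(101.0, 102.0),
                         lags_ms=LAGS)


class TestOptimizeWindows:
    GRID = np.array([-4.0, -2.0, -0.5, 0.5, 2.0, 4.0])

    def test_recovers_informative_band(self, rng):
        """Only lags 80-130 ms carry SNR-dependent signal; rest is noise."""
        n_subj = 8
        band = (LAGS >= 80.0) & (LAGS <= 130.0)
        coefs = 0.05 * rng.standard_normal((n_subj, self.GRID.size, LAGS.size))
        for j, d in enumerate(self.GRID):
            coefs[:, j, band] += 0.6 + 0.1 * d
        win, crit = optimize_rms_windows(coefs, LAGS, self.GRID)
        assert crit >= 0.9
        assert win.lower_ms <= 130.0 and win.upper_ms >= 108.0
        assert min(win.upper_ms, 130.0) - max(win.lower_ms, 80.0) > 0

    def test_grid_bounds_honored(self, rng):
        coefs = rng.standard_normal((4, self.GRID.size, LAGS.size))
        coefs[:, :, :] += np.linspace(0, 1, self.GRID.size)[None, :, None]
        win, _ = optimize_rms_windows(coefs, LAGS, self.GRID)
        assert 0.0 <= win.lower_ms <= 100.0
        assert 108.0 <= win.upper_ms <= 200.0

    def test_tie_broken_by_narrowest_then_lowest(self):
        # constant across lags: every window scores identically
        levels = np.arange(1.0, 7.0)  # monotone in condition, integer-exact
        coefs = np.tile(levels[None, :, None], (3, 1, LAGS.size))
        win, crit = optimize_rms_windows(coefs, LAGS, self.GRID)
        assert crit == pytest.approx(1.0)
        assert win.lower_ms == pytest.approx(100.0)
        # narrowest admissible upper edge right above 108 ms
        assert win.upper_ms == pytest.approx(13 * 1000.0 / 120.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        coefs = np.abs(rng.standard_normal((5, self.GRID.size, LAGS.size))) + 0.1
        w1, c1 = optimize_rms_windows(coefs, LAGS, self.GRID)
        w2, c2 = optimize_rms_windows(3.0 * coefs, LAGS, self.GRID)
        assert (w1, c1) == (w2, pytest.approx(c1))

    def test_constant_features_rejected(self):
        coefs = np.ones((3, self.GRID.size, LAGS.size))
        with pytest.raises(DataError):
            optimize_rms_windows(coefs, LAGS, self.GRID)


class TestFeatureTable:
    def _sets(self, n_subjects, n_conditions, channels):
        rng = np.random.default_rng(0)
        return [
            _trf_set(rng.standard_normal((len(channels), LAGS.size)),
                     subject=f"S{s:02d}", condition=float(c), channels=channels)
            for s in range(n_subjects) for c in range(n_conditions)
        ]

    def test_full_cohort_row_count(self):
        channels = [f"ch{i}" for i in range(32)]
        sets = self._sets(18, 6, channels)
        table = extract_feature_table(sets, WindowSpec(83.0, 133.0))
        assert len(table) == 3456

    def test_single_subject_row_count(self):
        channels = [f"ch{i}" for i in range(32)]
        sets = self._sets(1, 6, channels)
        assert len(extract_feature_table(sets, WindowSpec(83.0, 133.0))) == 192

    def test_all_zero_trfs_fallback_features(self):
        sets = [_trf_set(np.zeros((1, LAGS.size)))]
        table = extract_feature_table(sets, WindowSpec(83.0, 133.0))
        row = table.iloc[0]
        assert row["rms"] == 0.0
        assert row["n1_amp"] == 0.0 and row["n1_lat_ms"] == 175.0
        assert row["p2_amp"] == 0.0 and row["p2_lat_ms"] == 300.0


class TestRMSSum:
    def _features(self, rms_by_electrode):
        return pd.DataFrame(
            [
                {"subject": "S01", "condition": 0.0, "electrode": e, "rms": v}
                for e, v in rms_by_electrode.items()
            ]
        )

    def test_three_electrodes_sum(self):
        feats = self._features({"C3": 0.1, "CP3": 0.1, "CPz": 0.1, "Pz": 9.0})
        out = compute_rms_sum(feats)
        assert out["rms_sum"].iloc[0] == pytest.approx(0.3)

    def test_default_set_has_three_addends(self):
        feats = self._features({e: 1.0 for e in
                                ("C3", "CP3", "CPz", "Pz", "Fz", "Cz")})
        out = compute_rms_sum(feats)
        assert out["rms_sum"].iloc[0] == pytest.approx(3.0)

    def test_missing_electrode_rejected(self):
        with pytest.raises(DataError):
            compute_rms_sum(self._features({"C3": 0.1}))

    def test_empty_electrode_set_rejected(self):
        with pytest.raises(DataError):
            compute_rms_sum(self._features({"C3": 0.1}), electrodes=())
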