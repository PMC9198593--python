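"""TRF morphology features: N1/P2 peaks, windowed RMS and RMS_sum.

Five features are extracted per TRF: absolute amplitude and latency of
the N1 deflection (first local minimum with negative value in 75–175 ms),
amplitude and latency of P2 (first local maximum with positive value in
175–300 ms), and the root mean square of the TRF inside a per-electrode
latency window.  Window limits are optimized on a grid (lower 0–100 ms,
upper 108–200 ms, lag-sample resolution) to maximize the mean over
subjects of the per-subject Spearman correlation between ΔSNR and the
windowed RMS.  RMS values of a small electrode subset (default C3, CP3,
CPz) are summed into the RMS_sum composite used for threshold prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._errors import ConfigError, DataError
from .trf import TRFEstimate

log = logging.getLogger("speechtrf.features")

N1_WINDOW_MS = (75.0, 175.0)
P2_WINDOW_MS = (175.0, 300.0)
RMS_LOWER_GRID_MS = (0.0, 100.0)
RMS_UPPER_GRID_MS = (108.0, 200.0)
DEFAULT_RMS_ELECTRODES = ("C3", "CP3", "CPz")

_EPS_MS = 1e-6  # tolerance when matching window edges to the lag grid


@dataclass(frozen=True)
class PeakResult:
    """Detected (or fallback) TRF peak.

    When no peak of the requested polarity exists in the search window,
    ``found`` is False, amplitude is 0 and latency sits at the window
    maximum — the conservative fallback for degraded responses.
    """

    amplitude: float
    latency_ms: float
    found: bool


@dataclass(frozen=True)
class WindowSpec:
    """Per-electrode RMS window limits in ms (inclusive endpoints)."""

    lower_ms: float
    upper_ms: float

    def __post_init__(self) -> None:
        if not self.lower_ms < self.upper_ms:
            raise ConfigError("window lower edge must lie below the upper edge")


def _coerce(trf, lags_ms=None):
    if isinstance(trf, TRFEstimate):
        return trf.coefficients, trf.lags_ms
    if lags_ms is None:
        raise DataError("raw coefficient arrays need an explicit lag grid")
    return np.asarray(trf, dtype=float), np.asarray(lags_ms, dtype=float)


def detect_peak(
    trf,
    polarity: str,
    window_ms: tuple[float, float],
    lags_ms: np.ndarray | None = None,
) -> PeakResult:
    """First local extremum of the requested polarity inside the window.

    Extrema are sign changes of the discrete first derivative scanned in
    ascending latency (a plateau counts at its first sample); an extremum
    whose TRF value has the wrong sign (e.g. a positive-valued "minimum"
    when searching for N1) is skipped.  Amplitude is reported as |value|.
    """
    coefs, lags = _coerce(trf, lags_ms)
    if polarity not in ("negative", "positive"):
        raise ConfigError("polarity must be 'negative' or 'positive'")
    lo, hi = window_ms
    if lo < lags[0] - _EPS_MS or hi > lags[-1] + _EPS_MS:
        raise ConfigError(
            f"window {window_ms} ms outside the lag span "
            f"[{lags[0]:.1f}, {lags[-1]:.1f}] ms"
        )
    idx = np.where((lags >= lo - _EPS_MS) & (lags <= hi + _EPS_MS))[0]
    sign = -1.0 if polarity == "negative" else 1.0
    # work on the sign-flipped series so both polarities search for minima
    y = sign * coefs
    d = np.diff(y)
    for i in idx:
        if i == 0 or i == coefs.size - 1:
            continue  # need both neighbours for a derivative sign change
        left = d[i - 1]
        right = d[i]
        # first sample of a maximum or of a plateau that tops out here
        if left > 0 and right <= 0 and y[i] > 0:
            return PeakResult(
                amplitude=float(abs(coefs[i])),
                latency_ms=float(lags[i]),
                found=True,
            )
    return PeakResult(amplitude=0.0, latency_ms=float(hi), found=False)


def windowed_rms(
    trf,
    window: WindowSpec,
    lags_ms: np.ndarray | None = None,
) -> float:
    """RMS of the TRF over lags in [lower, upper] ms, endpoints inclusive."""
    coefs, lags = _coerce(trf, lags_ms)
    mask = (lags >= window.lower_ms - _EPS_MS) & (lags <= window.upper_ms + _EPS_MS)
    if not mask.any():
        raise ConfigError(
            f"window [{window.lower_ms}, {window.upper_ms}] ms contains no lag samples"
        )
    return float(np.sqrt(np.mean(coefs[mask] ** 2)))


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return sstats.rankdata(a, axis=axis)


def _mean_subject_spearman(rms: np.ndarray, dsnr: np.ndarray) -> float:
    """Mean over subjects of Spearman ρ(ΔSNR, rms); rms is (n_subj, n_cond)."""
    cond_rank = _rank(dsnr)
    feat_rank = _rank(rms, axis=1)
    fr = feat_rank - feat_rank.mean(axis=1, keepdims=True)
    cr = cond_rank - cond_rank.mean()
    denom = np.sqrt(np.sum(fr**2, axis=1) * np.sum(cr**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (fr @ cr) / denom, 0.0)
    return float(rho.mean())


def optimize_rms_windows(
    trf_coefs: np.ndarray,
    lags_ms: np.ndarray,
    delta_snr_db,
    grid_step_samples: int = 1,
) -> tuple[WindowSpec, float]:
    """Exhaustive window grid search for one electrode.

    ``trf_coefs`` is (n_subjects, n_conditions, n_lags) for a single
    electrode; the criterion is the mean over subjects of the per-subject
    Spearman ρ between ΔSNR and the windowed RMS.  Ties are broken by the
    narrowest window, then by the smallest lower edge.  Returns the best
    window together with its criterion value.
    """
    trf_coefs = np.asarray(trf_coefs, dtype=float)
    lags_ms = np.asarray(lags_ms, dtype=float)
    dsnr = np.asarray(delta_snr_db, dtype=float)
    if trf_coefs.ndim != 3 or trf_coefs.shape[1] != dsnr.size:
        raise DataError("expected (n_subjects, n_conditions, n_lags) coefficients")
    if dsnr.size < 2:
        raise DataError("window optimization needs at least two conditions")
    lower_idx = np.where(
        (lags_ms >= RMS_LOWER_GRID_MS[0] - _EPS_MS)
        & (lags_ms <= RMS_LOWER_GRID_MS[1] + _EPS_MS)
    )[0][::grid_step_samples]
    upper_idx = np.where(
        (lags_ms >= RMS_UPPER_GRID_MS[0] - _EPS_MS)
        & (lags_ms <= RMS_UPPER_GRID_MS[1] + _EPS_MS)
    )[0][::grid_step_samples]
    if lower_idx.size == 0 or upper_idx.size == 0:
        raise ConfigError("lag grid does not cover the window search ranges")

    csum = np.concatenate(
        [np.zeros(trf_coefs.shape[:2] + (1,)), np.cumsum(trf_coefs**2, axis=2)],
        axis=2,
    )
    best = None  # (criterion, width, lower, WindowSpec)
    for li in lower_idx:
        for ui in upper_idx:
            if ui <= li:
                continue
            n_in = ui - li + 1
            rms = np.sqrt((csum[:, :, ui + 1] - csum[:, :, li]) / n_in)
            if np.ptp(rms) == 0:
                continue  # degenerate: constant feature carries no ranking
            crit = _mean_subject_spearman(rms, dsnr)
            width = lags_ms[ui] - lags_ms[li]
            key = (-crit, width, lags_ms[li])
            if best is None or key < best[0]:
                best = (key, WindowSpec(float(lags_ms[li]), float(lags_ms[ui])), crit)
    if best is None:
        raise DataError("all candidate windows gave constant features")
    log.info(
        "optimal RMS window [%g, %g] ms (mean Spearman rho = %.3f)",
        best[1].lower_ms, best[1].upper_ms, best[2],
    )
    return best[1], float(best[2])


def extract_feature_table(
    trf_sets,
    windows: dict[str, WindowSpec] | WindowSpec,
    n1_window_ms: tuple[float, float] = N1_WINDOW_MS,
    p2_window_ms: tuple[float, float] = P2_WINDOW_MS,
) -> pd.DataFrame:
    """One row of the five features per (subject, condition, electrode).

    ``trf_sets`` is an iterable of :class:`speechtrf.trf.TRFSet`;
    ``windows`` maps electrode label to its RMS :class:`WindowSpec`
    (a single spec is broadcast to every electrode).
    """
    rows = []
    for ts in trf_sets:
        for ci, electrode in enumerate(ts.channel_names):
            coefs = ts.coefficients[ci]
            win = windows if isinstance(windows, WindowSpec) else windows.get(electrode)
            if win is None:
                raise ConfigError(f"no RMS window configured for electrode {electrode}")
            n1 = detect_peak(coefs, "negative", n1_window_ms, lags_ms=ts.lags_ms)
            p2 = detect_peak(coefs, "positive", p2_window_ms, lags_ms=ts.lags_ms)
            rows.append(
                {
                    "subject": ts.subject,
                    "condition": ts.condition,
                    "electrode": electrode,
                    "n1_amp": n1.amplitude,
                    "n1_lat_ms": n1.latency_ms,
                    "n1_found": n1.found,
                    "p2_amp": p2.amplitude,
                    "p2_lat_ms": p2.latency_ms,
                    "p2_found": p2.found,
                    "rms": windowed_rms(coefs, win, lags_ms=ts.lags_ms),
                    "window_lower_ms": win.lower_ms,
                    "window_upper_ms": win.upper_ms,
                }
            )
    return pd.DataFrame(rows)


def compute_rms_sum(
    features: pd.DataFrame,
    electrodes=DEFAULT_RMS_ELECTRODES,
) -> pd.DataFrame:
    """Sum of per-electrode windowed RMS over the configured subset.

    Returns a table with one ``rms_sum`` row per (subject, condition).
    """
    electrodes = list(electrodes)
    if not electrodes:
        raise DataError("electrode subset for RMS_sum is empty")
    present = set(features["electrode"])
    missing = [e for e in electrodes if e not in present]
    if missing:
        raise DataError(f"electrodes missing from feature table: {missing}")
    sel = features[features["electrode"].isin(electrodes)]
    out = (
        sel.groupby(["subject", "condition"], as_index=False)["rms"]
        .sum()
        .rename(columns={"rms": "rms_sum"})
    )
    return out
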