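"""Behavioral and EEG-feature intelligibility models; SRT_50 prediction.

Two models are fitted by nonlinear least squares:

* the logistic psychometric function
  ``100 / (1 + exp(−(SNR − SRT_50)/s))`` for the behavioral scores, and
* the saturating exponential
  ``Intelligibility = 100 · (1 − exp(−b · RMS_sum)) %`` mapping the
  RMS_sum EEG feature to intelligibility.

The RMS_sum value corresponding to 50% intelligibility is
``RMS_50 = ln 2 / b``.  A subject's SRT_50 is predicted leave-one-out:
``b`` (hence RMS_50) is fitted on all other subjects, and the predicted
SRT is the first ΔSNR condition, scanned in ascending order, at which the
subject's RMS_sum reaches RMS_50.  Because the condition grid is defined
relative to the behavioral SRT_50, the prediction error in dB is simply
the predicted ΔSNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from ._errors import DataError, FitError

log = logging.getLogger("speechtrf.intelligibility")


@dataclass(frozen=True)
class PsychometricFit:
    srt50_db: float
    slope_s_db: float
    rmse_pct: float


@dataclass(frozen=True)
class ExponentialFit:
    b: float
    b_ci_low: float
    b_ci_high: float
    rms50: float
    rmse_pct: float


@dataclass(frozen=True)
class PredictionResult:
    subject: str
    predicted_srt_delta_db: float | None
    crossed: bool
    deviation_db: float | None
    rms50: float


def logistic_pct(snr_db, srt50_db: float, slope_s_db: float):
    """Intelligibility in % under the logistic psychometric function."""
    return 100.0 / (1.0 + np.exp(-(np.asarray(snr_db, dtype=float) - srt50_db) / slope_s_db))


def exponential_pct(rms_sum, b: float):
    """Intelligibility in % under the saturating exponential model."""
    return 100.0 * (1.0 - np.exp(-b * np.asarray(rms_sum, dtype=float)))


def fit_psychometric(snr_db, scores_pct) -> PsychometricFit:
    """Nonlinear least-squares logistic fit to intelligibility scores.

    Initialization is deterministic: SRT starts at the SNR whose score is
    nearest 50%, the slope at 1.5 dB; a small multi-start ladder over the
    slope guards against poor convergence.
    """
    x = np.asarray(snr_db, dtype=float)
    y = np.asarray(scores_pct, dtype=float)
    if np.unique(x).size < 3:
        raise DataError("psychometric fit needs at least 3 distinct SNRs")
    srt0 = float(x[np.argmin(np.abs(y - 50.0))])
    best = None
    for s0 in (1.5, 0.75, 3.0, 6.0):
        try:
            popt, _ = optimize.curve_fit(
                logistic_pct, x, y, p0=[srt0, s0],
                bounds=([x.min() - 20.0, 1e-3], [x.max() + 20.0, 50.0]),
                maxfev=10000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = y - logistic_pct(x, *popt)
        sse = float(np.sum(resid**2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError("psychometric fit did not converge from any start")
    sse, (srt50, slope) = best
    rmse = float(np.sqrt(sse / x.size))
    log.info("psychometric fit: SRT50=%.3f dB, s=%.3f dB, RMSE=%.2f%%", srt50, slope, rmse)
    return PsychometricFit(srt50_db=float(srt50), slope_s_db=float(slope), rmse_pct=rmse)


def fit_exponential(rms_sum, scores_pct, confidence: float = 0.95) -> ExponentialFit:
    """Single-parameter least-squares fit of the exponential model.

    The confidence interval for ``b`` comes from the linearized
    (Jacobian) standard error with normal quantiles.
    """
    x = np.asarray(rms_sum, dtype=float)
    y = np.asarray(scores_pct, dtype=float)
    if x.size < 3:
        raise DataError("exponential fit needs at least 3 (RMS_sum, score) pairs")
    if np.any(x < 0):
        raise DataError("RMS_sum values must be non-negative")
    if np.all(y == 0):
        raise FitError("all intelligibility scores are zero; b is unidentifiable")
    mean_x = float(np.mean(x[x > 0])) if np.any(x > 0) else 1.0
    b0 = np.log(2.0) / mean_x  # curve through ~50% at the mean feature value
    try:
        popt, pcov = optimize.curve_fit(
            exponential_pct, x, y, p0=[b0], bounds=(1e-9, np.inf), maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    b = float(popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    z = sstats.norm.ppf(0.5 + confidence / 2.0)
    resid = y - exponential_pct(x, b)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ExponentialFit(
        b=b, b_ci_low=b - z * se, b_ci_high=b + z * se,
        rms50=rms50_from_b(b), rmse_pct=rmse,
    )


def rms50_from_b(b: float) -> float:
    """RMS_sum at 50% intelligibility: solves 100·(1 − e^{−b·x}) = 50."""
    if b <= 0:
        raise DataError("rate parameter b must be positive")
    return float(np.log(2.0) / b)


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")


def predict_srt_loo(cohort_features: pd.DataFrame) -> list[PredictionResult]:
    """Leave-one-out SRT_50 prediction for every subject.

    ``cohort_features`` needs columns subject, delta_snr_db, rms_sum,
    intelligibility_pct.  For each subject the exponential model is
    fitted on all *other* subjects' pairs; the subject's conditions are
    scanned in ascending ΔSNR and the first with RMS_sum ≥ RMS_50 is the
    predicted SRT (no interpolation between grid points).
    """
    _require_columns(
        cohort_features, ["subject", "delta_snr_db", "rms_sum", "intelligibility_pct"]
    )
    subjects = list(pd.unique(cohort_features["subject"]))
    if len(subjects) < 2:
        raise DataError("leave-one-out prediction needs at least 2 subjects")
    results = []
    for subject in subjects:
        train = cohort_features[cohort_features["subject"] != subject]
        fit = fit_exponential(train["rms_sum"], train["intelligibility_pct"])
        own = cohort_features[cohort_features["subject"] == subject].sort_values(
            "delta_snr_db"
        )
        crossing = own[own["rms_sum"] >= fit.rms50]
        if len(crossing):
            pred = float(crossing["delta_snr_db"].iloc[0])
            results.append(
                PredictionResult(
                    subject=subject, predicted_srt_delta_db=pred, crossed=True,
                    deviation_db=pred, rms50=fit.rms50,
                )
            )
        else:
            results.append(
                PredictionResult(
                    subject=subject, predicted_srt_delta_db=None, crossed=False,
                    deviation_db=None, rms50=fit.rms50,
                )
            )
    n_crossed = sum(r.crossed for r in results)
    log.info("LOO prediction: %d/%d subjects crossed RMS_50", n_crossed, len(results))
    return results


def evaluate_predictions(results) -> dict:
    """Summary of LOO predictions over subjects whose RMS_sum crossed RMS_50.

    Reports mean |deviation|, the deviation range, counts within ±1 and
    ±2 dB, and how many subjects never crossed the threshold.
    """
    results = list(results)
    crossed = [r for r in results if r.crossed]
    if not crossed:
        raise DataError("no subject crossed the RMS_50 threshold")
    dev = np.array([r.deviation_db for r in crossed], dtype=float)
    return {
        "n_subjects": len(results),
        "n_crossed": len(crossed),
        "n_uncrossed": len(results) - len(crossed),
        "mean_abs_deviation_db": float(np.mean(np.abs(dev))),
        "min_deviation_db": float(dev.min()),
        "max_deviation_db": float(dev.max()),
        "n_within_1db": int(np.sum(np.abs(dev) <= 1.0)),
        "n_within_2db": int(np.sum(np.abs(dev) <= 2.0)),
    }


def feature_intelligibility_correlation(cohort_features: pd.DataFrame) -> float:
    """Pooled Spearman ρ between RMS_sum and intelligibility."""
    _require_columns(cohort_features, ["rms_sum", "intelligibility_pct"])
    return float(
        sstats.spearmanr(
            cohort_features["rms_sum"], cohort_features["intelligibility_pct"]
        ).statistic
    )
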