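"""End-to-end driver: simulate-or-load → preprocess → TRF → features →
stats → SRT prediction → report bundle.

Subjects are processed one at a time so EEG for only one subject is held
in memory; the retained per-subject products (TRF coefficient arrays and
behavior) are small.  With fixed seeds the full run is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError
from .config import PipelineConfig
from .containers import Cohort, SubjectData
from .features import (
    WindowSpec,
    compute_rms_sum,
    extract_feature_table,
    optimize_rms_windows,
)
from .intelligibility import (
    evaluate_predictions,
    feature_intelligibility_correlation,
    fit_exponential,
    fit_psychometric,
    predict_srt_loo,
)
from .io import read_dataset
from .preprocess import preprocess_eeg, preprocess_envelope
from .simulate import generate_cohort
from .stats import electrode_stat_map, spearman_monotonicity
from .trf import TRFSet, estimate_trf_multichannel

log = logging.getLogger("speechtrf.pipeline")

PEAK_FEATURES = ("n1_amp", "n1_lat_ms", "p2_amp", "p2_lat_ms", "rms")


@dataclass
class PipelineReport:
    """All tabular and scalar products of one pipeline run."""

    config: PipelineConfig
    trf_long: pd.DataFrame  # subject, condition, electrode, lag_ms, coefficient
    windows: pd.DataFrame  # electrode, lower_ms, upper_ms, criterion_rho
    features: pd.DataFrame
    rms_sum: pd.DataFrame
    stat_tables: pd.DataFrame
    posthoc: pd.DataFrame
    behavior: pd.DataFrame
    predictions: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trf_long.to_csv(out / "trf.csv", index=False)
        self.windows.to_csv(out / "rms_windows.csv", index=False)
        self.features.to_csv(out / "features.csv", index=False)
        self.rms_sum.to_csv(out / "rms_sum.csv", index=False)
        self.stat_tables.to_csv(out / "stats.csv", index=False)
        self.posthoc.to_csv(out / "posthoc.csv", index=False)
        self.behavior.to_csv(out / "behavior.csv", index=False)
        self.predictions.to_csv(out / "predictions.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=1, default=float)
        log.info("report bundle written to %s", out)
        return out


def estimate_all_trfs(cohort: Cohort, cfg: PipelineConfig) -> list[TRFSet]:
    """Preprocess and fit TRFs for every subject × condition."""
    trf_sets = []
    for sub in cohort:
        for dsnr in sub.conditions:
            if dsnr not in sub.eeg:
                raise DataError(
                    f"subject {sub.subject_id} has no EEG for condition {dsnr}"
                )
            env = sub.envelopes[dsnr]
            if not env.filtered:
                env = preprocess_envelope(env, cfg.filter)
            eeg = preprocess_eeg(
                sub.eeg[dsnr], cfg.filter,
                target_fs_hz=cfg.lags.fs_hz,
                artifact_method=cfg.artifact_method,
            )
            trf_sets.append(
                estimate_trf_multichannel(
                    env, eeg.data, eeg.channel_names,
                    spec=cfg.lags, lambda_=cfg.lambda_,
                    subject=sub.subject_id, condition=dsnr,
                )
            )
        log.info("TRFs estimated for subject %s", sub.subject_id)
    return trf_sets


def trf_sets_to_long(trf_sets: list[TRFSet]) -> pd.DataFrame:
    rows = []
    for ts in trf_sets:
        for ci, electrode in enumerate(ts.channel_names):
            rows.append(
                pd.DataFrame(
                    {
                        "subject": ts.subject,
                        "condition": ts.condition,
                        "electrode": electrode,
                        "lag_ms": ts.lags_ms,
                        "coefficient": ts.coefficients[ci],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def optimize_windows_per_electrode(
    trf_sets: list[TRFSet], grid: list[float]
) -> tuple[dict[str, WindowSpec], pd.DataFrame]:
    """Run the RMS window grid search independently for each electrode."""
    channels = trf_sets[0].channel_names
    lags_ms = trf_sets[0].lags_ms
    subjects = sorted({ts.subject for ts in trf_sets})
    by_key = {(ts.subject, ts.condition): ts for ts in trf_sets}
    windows: dict[str, WindowSpec] = {}
    rows = []
    for ci, electrode in enumerate(channels):
        stack = np.array(
            [
                [by_key[(s, d)].coefficients[ci] for d in grid]
                for s in subjects
            ]
        )
        win, crit = optimize_rms_windows(stack, lags_ms, grid)
        windows[electrode] = win
        rows.append(
            {
                "electrode": electrode,
                "lower_ms": win.lower_ms,
                "upper_ms": win.upper_ms,
                "criterion_rho": crit,
            }
        )
    return windows, pd.DataFrame(rows)


def behavior_table(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for sub in cohort:
        for dsnr, b in sorted(sub.behavior.items()):
            rows.append(
                {
                    "subject": sub.subject_id,
                    "srt50_db": sub.srt50_db,
                    "delta_snr_db": dsnr,
                    "intelligibility_pct": b.intelligibility_pct,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig | None = None, out_dir: str | Path | None = None) -> PipelineReport:
    """Execute the full analysis; optionally write the report bundle.

    With fewer than three conditions the rank statistics and threshold
    prediction are undefined and those stages are skipped with a warning
    (the TRF and feature products are still returned).
    """
    cfg = cfg or PipelineConfig()
    if cfg.dataset_path:
        cohort = read_dataset(cfg.dataset_path)
        log.info("loaded dataset from %s", cfg.dataset_path)
    else:
        cohort = generate_cohort(cfg.cohort, cfg.stimulus, cfg.kernel)
        log.info(
            "simulated cohort: %d subjects x %d conditions x %d channels",
            cfg.cohort.n_subjects, len(cfg.cohort.delta_snr_grid_db),
            cfg.cohort.n_channels,
        )
    grid = list(cohort.delta_snr_grid_db)
    trf_sets = estimate_all_trfs(cohort, cfg)
    full_stats = len(grid) >= 3

    if full_stats:
        windows, window_table = optimize_windows_per_electrode(trf_sets, grid)
    else:
        log.warning("fewer than 3 conditions: default RMS window, no stats")
        default = WindowSpec(83.0, 133.0)
        windows = {ch: default for ch in trf_sets[0].channel_names}
        window_table = pd.DataFrame(
            [
                {"electrode": ch, "lower_ms": default.lower_ms,
                 "upper_ms": default.upper_ms, "criterion_rho": np.nan}
                for ch in trf_sets[0].channel_names
            ]
        )

    features = extract_feature_table(
        trf_sets, windows, n1_window_ms=cfg.n1_window_ms, p2_window_ms=cfg.p2_window_ms
    )
    rms_sum = compute_rms_sum(features, cfg.rms_electrodes)
    behavior = behavior_table(cohort)
    summary: dict = {
        "n_subjects": cohort.n_subjects,
        "n_conditions": len(grid),
        "n_trfs": len(features),
        "mean_srt50_db": float(np.mean([s.srt50_db for s in cohort])),
        "lambda": cfg.lambda_,
    }

    stat_tables = pd.DataFrame()
    posthoc = pd.DataFrame()
    predictions = pd.DataFrame()
    if full_stats:
        maps = [
            electrode_stat_map(features, feat, grid) for feat in PEAK_FEATURES
        ]
        stat_tables = pd.concat([m.table for m in maps], ignore_index=True)
        posthoc = pd.concat([m.posthoc for m in maps], ignore_index=True)

        pivot = rms_sum.pivot(index="subject", columns="condition", values="rms_sum")
        _, rho_rms_sum = spearman_monotonicity(pivot.to_numpy(), grid)
        summary["rms_sum_mean_rho"] = rho_rms_sum

        if len(behavior):
            psych = fit_psychometric(
                behavior["delta_snr_db"], behavior["intelligibility_pct"]
            )
            summary["psychometric"] = {
                "srt50_delta_db": psych.srt50_db,
                "slope_s_db": psych.slope_s_db,
                "rmse_pct": psych.rmse_pct,
            }
            merged = rms_sum.rename(columns={"condition": "delta_snr_db"}).merge(
                behavior, on=["subject", "delta_snr_db"]
            )
            expfit = fit_exponential(
                merged["rms_sum"], merged["intelligibility_pct"]
            )
            summary["exponential"] = {
                "b": expfit.b, "b_ci_low": expfit.b_ci_low,
                "b_ci_high": expfit.b_ci_high, "rms50": expfit.rms50,
                "rmse_pct": expfit.rmse_pct,
            }
            summary["rms_sum_intelligibility_rho"] = (
                feature_intelligibility_correlation(merged)
            )
            results = predict_srt_loo(merged)
            predictions = pd.DataFrame(
                [
                    {
                        "subject": r.subject,
                        "predicted_srt_delta_db": r.predicted_srt_delta_db,
                        "crossed": r.crossed,
                        "deviation_db": r.deviation_db,
                        "rms50_loo": r.rms50,
                    }
                    for r in results
                ]
            )
            summary["prediction"] = evaluate_predictions(results)

    report = PipelineReport(
        config=cfg,
        trf_long=trf_sets_to_long(trf_sets),
        windows=window_table,
        features=features,
        rms_sum=rms_sum,
        stat_tables=stat_tables,
        posthoc=posthoc,
        behavior=behavior,
        predictions=predictions,
        summary=summary,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
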