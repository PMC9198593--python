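"""Electrode-wise monotonicity and group-difference statistics.

For each electrode and feature: (1) Spearman's ρ between ΔSNR and the
feature, computed per subject and averaged over subjects, quantifies
monotonicity; (2) a Kruskal–Wallis test asks whether the ΔSNR conditions
share a common location; (3) when it rejects, Dunn z tests with a
Bonferroni correction compare the conditions pairwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._errors import DataError

log = logging.getLogger("speechtrf.stats")


def spearman_monotonicity(
    feature_values: np.ndarray,
    delta_snr_db,
    constant_policy: str = "zero",
) -> tuple[np.ndarray, float]:
    """Per-subject Spearman ρ of feature vs ΔSNR, and the mean over subjects.

    ``feature_values`` is (n_subjects, n_conditions), conditions ordered
    by ΔSNR.  A constant feature vector has no defined rank correlation;
    by default it contributes ρ = 0 (with a warning) so the electrode map
    stays total, or NaN under ``constant_policy='nan'``.
    """
    x = np.atleast_2d(np.asarray(feature_values, dtype=float))
    dsnr = np.asarray(delta_snr_db, dtype=float)
    if dsnr.size < 3:
        raise DataError("Spearman monotonicity needs at least 3 conditions")
    if x.shape[1] != dsnr.size:
        raise DataError("feature columns must match the condition grid")
    rhos = np.empty(x.shape[0])
    for i, row in enumerate(x):
        if np.ptp(row) == 0:
            warnings.warn(
                f"constant feature for subject index {i}; Spearman rho set by "
                f"'{constant_policy}' policy", stacklevel=2,
            )
            rhos[i] = 0.0 if constant_policy == "zero" else np.nan
        else:
            rhos[i] = sstats.spearmanr(dsnr, row).statistic
    return rhos, float(np.nanmean(rhos))


def kruskal_wallis(groups) -> tuple[float, float, int]:
    """Kruskal–Wallis H with midrank tie correction: (chi2, p, df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise DataError("need at least two non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0, df  # all observations identical: no evidence
    h, p = sstats.kruskal(*groups)
    return float(h), float(p), df


def dunn_bonferroni_posthoc(groups) -> np.ndarray:
    """Pairwise Dunn z tests on midranks, Bonferroni-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the
    tie term T = Σ(t³ − t) / (12(N − 1)); two-sided normal p-values are
    multiplied by the number of pairs and clipped at 1.  Returns the
    symmetric adjusted p matrix with unit diagonal.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise DataError("need at least two non-empty groups")
    k = len(groups)
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sstats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    mean_ranks = np.array(mean_ranks)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    n_pairs = k * (k - 1) // 2
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = min(1.0, 2.0 * sstats.norm.sf(abs(z)) * n_pairs)
            pmat[i, j] = pmat[j, i] = p
    return pmat


@dataclass
class ElectrodeStatMap:
    """Per-electrode statistics for one feature."""

    feature: str
    table: pd.DataFrame  # electrode, mean_rho, kw_chi2, kw_p
    posthoc: pd.DataFrame  # electrode, cond_a, cond_b, p_adj


def electrode_stat_map(
    features: pd.DataFrame,
    feature: str,
    delta_snr_grid_db,
    alpha: float = 0.05,
) -> ElectrodeStatMap:
    """Monotonicity and group statistics for every electrode of one feature.

    ``features`` is the long table from
    :func:`speechtrf.features.extract_feature_table`.  Dunn–Bonferroni
    post-hoc comparisons are reported for electrodes where the
    Kruskal–Wallis test rejects at ``alpha``.
    """
    grid = list(delta_snr_grid_db)
    rows = []
    posthoc_rows = []
    for electrode, sub in features.groupby("electrode"):
        pivot = sub.pivot_table(index="subject", columns="condition", values=feature)
        pivot = pivot.reindex(columns=grid)
        if pivot.isna().any().any():
            raise DataError(f"missing conditions for electrode {electrode}")
        values = pivot.to_numpy()
        _, mean_rho = spearman_monotonicity(values, grid)
        groups = [values[:, j] for j in range(len(grid))]
        chi2, p, _ = kruskal_wallis(groups)
        rows.append(
            {"electrode": electrode, "feature": feature,
             "mean_rho": mean_rho, "kw_chi2": chi2, "kw_p": p}
        )
        if p < alpha:
            pmat = dunn_bonferroni_posthoc(groups)
            for a in range(len(grid)):
                for b in range(a + 1, len(grid)):
                    posthoc_rows.append(
                        {"electrode": electrode, "feature": feature,
                         "cond_a": grid[a], "cond_b": grid[b],
                         "p_adj": pmat[a, b]}
                    )
    table = pd.DataFrame(rows).sort_values("electrode", ignore_index=True)
    posthoc = pd.DataFrame(
        posthoc_rows, columns=["electrode", "feature", "cond_a", "cond_b", "p_adj"]
    )
    log.info(
        "stat map for %s: max |mean_rho| = %.3f", feature,
        table["mean_rho"].abs().max() if len(table) else float("nan"),
    )
    return ElectrodeStatMap(feature=feature, table=table, posthoc=posthoc)
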