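"""Forward (encoding) model: ridge-regularized temporal response functions.

A TRF is the linear impulse response mapping the speech envelope s(t) to
the EEG r(t) at one electrode,

    r̂(t) = Σ_τ TRF(τ) · s(t − τ),

estimated over lags τ from −200 to 500 ms by regularized least squares on
the lagged design matrix S,

    TRF = (SᵀS + λI)⁻¹ Sᵀ r,

with a single fixed regularization parameter (default λ = 2¹⁵) so that
TRF amplitudes are comparable across SNR conditions and subjects.  The
penalty is applied to the raw normal equations — no eigenvalue rescaling
and no per-condition envelope renormalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigError, DataError
from .containers import Envelope

log = logging.getLogger("speechtrf.trf")

DEFAULT_LAMBDA = 2.0**15


@dataclass(frozen=True)
class LagSpec:
    """Lag window for the design matrix, in ms, on the pipeline sample grid.

    Positive lag means the envelope sample precedes the EEG sample
    (causal response); the negative lags down to −200 ms act as a sanity
    floor that should carry no structure.
    """

    lag_min_ms: float = -200.0
    lag_max_ms: float = 500.0
    fs_hz: float = 120.0

    def __post_init__(self) -> None:
        if self.lag_min_ms >= self.lag_max_ms:
            raise ConfigError("lag_min_ms must be below lag_max_ms")
        if self.fs_hz <= 0:
            raise ConfigError("fs_hz must be positive")

    @property
    def lag_samples(self) -> np.ndarray:
        lo = int(round(self.lag_min_ms * self.fs_hz / 1000.0))
        hi = int(round(self.lag_max_ms * self.fs_hz / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lag_samples * 1000.0 / self.fs_hz

    @property
    def n_lags(self) -> int:
        return self.lag_samples.size


@dataclass
class TRFEstimate:
    """Per-lag impulse-response coefficients for one electrode."""

    coefficients: np.ndarray
    lags_ms: np.ndarray
    lambda_: float
    cost: float  # residual sum of squares of the fit
    fs_hz: float = 120.0
    electrode: str | None = None
    condition: float | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        if self.coefficients.shape != self.lags_ms.shape:
            raise DataError("coefficient vector length must equal lag count")


@dataclass
class TRFSet:
    """TRFs for all electrodes of one (subject, condition) recording."""

    coefficients: np.ndarray  # (n_channels, n_lags)
    lags_ms: np.ndarray
    lambda_: float
    costs: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    condition: float | None = None
    subject: str | None = None

    def __getitem__(self, electrode: str) -> TRFEstimate:
        i = self.channel_names.index(electrode)
        return TRFEstimate(
            coefficients=self.coefficients[i],
            lags_ms=self.lags_ms,
            lambda_=self.lambda_,
            cost=float(self.costs[i]),
            electrode=electrode,
            condition=self.condition,
            subject=self.subject,
        )


def build_lag_matrix(env: Envelope | np.ndarray, spec: LagSpec) -> np.ndarray:
    """Design matrix S whose column for lag τ holds s(t − τ).

    Out-of-range samples are zero-filled, so row count equals the
    envelope length regardless of the lag span.
    """
    s = env.samples if isinstance(env, Envelope) else np.asarray(env, dtype=float)
    n = s.size
    lags = spec.lag_samples
    if n <= lags.max() - lags.min():
        raise DataError(
            f"envelope of {n} samples is shorter than the lag span "
            f"({lags.max() - lags.min() + 1} samples)"
        )
    S = np.zeros((n, lags.size))
    for j, ell in enumerate(lags):
        if ell >= 0:
            S[ell:, j] = s[: n - ell] if ell else s
        else:
            S[:ell, j] = s[-ell:]
    return S


def _solve_ridge(S: np.ndarray, R: np.ndarray, lambda_: float) -> np.ndarray:
    """Solve (SᵀS + λI) W = Sᵀ R for W; raises on a singular system."""
    G = S.T @ S
    G[np.diag_indices_from(G)] += lambda_
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        raise DataError(
            "normal equations are numerically singular; "
            "increase lambda or provide a richer envelope"
        )
    return np.linalg.solve(G, S.T @ R)


def estimate_trf(
    env: Envelope | np.ndarray,
    response: np.ndarray,
    spec: LagSpec | None = None,
    lambda_: float = DEFAULT_LAMBDA,
    **meta,
) -> TRFEstimate:
    """Exact regularized least-squares TRF for one electrode.

    ``cost`` on the returned estimate is the residual sum of squares
    Σ_t (r(t) − r̂(t))² of the regularized solution.
    """
    spec = spec or LagSpec()
    if lambda_ < 0:
        raise ConfigError("lambda must be non-negative")
    r = np.asarray(response, dtype=float)
    s = env.samples if isinstance(env, Envelope) else np.asarray(env, dtype=float)
    if r.shape != s.shape:
        raise DataError(
            f"envelope ({s.size}) and response ({r.size}) lengths differ"
        )
    S = build_lag_matrix(s, spec)
    w = _solve_ridge(S, r, lambda_)
    cost = float(np.sum((r - S @ w) ** 2))
    return TRFEstimate(
        coefficients=w, lags_ms=spec.lags_ms, lambda_=lambda_, cost=cost,
        fs_hz=spec.fs_hz, **meta,
    )


def estimate_trf_multichannel(
    env: Envelope | np.ndarray,
    eeg_data: np.ndarray,
    channel_names: list[str],
    spec: LagSpec | None = None,
    lambda_: float = DEFAULT_LAMBDA,
    subject: str | None = None,
    condition: float | None = None,
) -> TRFSet:
    """All electrodes of one recording in a single factorized solve."""
    spec = spec or LagSpec()
    if lambda_ < 0:
        raise ConfigError("lambda must be non-negative")
    R = np.asarray(eeg_data, dtype=float).T  # (n_samples, n_channels)
    s = env.samples if isinstance(env, Envelope) else np.asarray(env, dtype=float)
    if R.shape[0] != s.size:
        raise DataError("envelope and EEG lengths differ")
    S = build_lag_matrix(s, spec)
    W = _solve_ridge(S, R, lambda_)
    costs = np.sum((R - S @ W) ** 2, axis=0)
    log.info(
        "estimated %d TRFs (lambda=%g, %d lags, %d samples)",
        R.shape[1], lambda_, spec.n_lags, s.size,
    )
    return TRFSet(
        coefficients=W.T, lags_ms=spec.lags_ms, lambda_=lambda_,
        costs=costs, channel_names=list(channel_names),
        condition=condition, subject=subject,
    )


def predict_response(trf: TRFEstimate, env: Envelope | np.ndarray) -> np.ndarray:
    """Predicted EEG r̂ = S · TRF, same boundary convention as the fit."""
    if isinstance(env, Envelope):
        if env.fs_hz != trf.fs_hz:
            raise ConfigError(
                f"envelope fs {env.fs_hz} Hz != TRF fs {trf.fs_hz} Hz"
            )
        s = env.samples
    else:
        s = np.asarray(env, dtype=float)
    lag_min = trf.lags_ms[0]
    lag_max = trf.lags_ms[-1]
    spec = LagSpec(lag_min_ms=lag_min, lag_max_ms=lag_max, fs_hz=trf.fs_hz)
    return build_lag_matrix(s, spec) @ trf.coefficients


def prediction_correlation(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Pearson correlation between predicted and measured EEG."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.size < 3:
        raise DataError("signals must share a length of at least 3")
    if np.ptp(p) == 0 or np.ptp(m) == 0:
        raise DataError("correlation undefined for a constant signal")
    return float(np.corrcoef(p, m)[0, 1])
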