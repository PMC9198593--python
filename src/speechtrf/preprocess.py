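"""Signal conditioning for EEG and stimulus envelopes.

Both the EEG and the envelope pass through the same zero-phase band-pass
(1–10 Hz, Hamming windowed-sinc FIR) after downsampling to the 120 Hz
pipeline rate.  "Zero phase" is realized as a single linear-phase FIR pass
with exact group-delay compensation, not forward-backward filtering: the
designed filter has odd length, symmetric taps and an integer delay of
(n_taps − 1)/2 samples which is removed after convolution.  Edges are
zero-padded so output length always equals input length.

Envelope extraction order is fixed: rectify, power-law compress (|x|^0.6),
resample to 120 Hz, band-pass — the same order for every dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import gcd

import numpy as np
from scipy import signal as sps

from ._errors import ConfigError, DataError
from .containers import PIPELINE_FS_HZ, EEGRecording, Envelope

log = logging.getLogger("speechtrf.preprocess")


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass FIR specification.

    ``order`` counts the filter taps of the windowed-sinc design; an odd
    tap count (type-I linear phase) keeps the group delay at an integer
    (order − 1)/2 samples.  Band edges are the −6 dB cutoffs of the
    design, the standard convention for windowed-sinc filters.
    """

    low_hz: float = 1.0
    high_hz: float = 10.0
    order: int = 397
    window: str = "hamming"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigError("need 0 < low_hz < high_hz")
        if self.order < 3 or self.order % 2 == 0:
            raise ConfigError("filter order (tap count) must be odd and >= 3")

    def taps(self, fs_hz: float) -> np.ndarray:
        if self.high_hz >= fs_hz / 2:
            raise ConfigError(
                f"high cutoff {self.high_hz} Hz >= Nyquist ({fs_hz / 2} Hz)"
            )
        return sps.firwin(
            self.order,
            [self.low_hz, self.high_hz],
            pass_zero=False,
            window=self.window,
            fs=fs_hz,
        )


def bandpass_filter(
    x: np.ndarray, fs_hz: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase band-pass along the last axis; output length = input length.

    The signal is zero-padded by half the filter length on both ends, the
    linear-phase FIR is applied in one pass, and the integer group delay
    is trimmed, leaving zero phase shift in the passband.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n <= spec.order:
        raise DataError(
            f"signal of {n} samples is shorter than the {spec.order}-tap filter"
        )
    h = spec.taps(fs_hz)
    delay = (spec.order - 1) // 2
    y = sps.fftconvolve(x, h[np.newaxis, :] if x.ndim == 2 else h, axes=-1, mode="full")
    out = y[..., delay : delay + n]
    log.info(
        "bandpass %g-%g Hz, %d taps, fs=%g Hz, n=%d", spec.low_hz,
        spec.high_hz, spec.order, fs_hz, n,
    )
    return out


def resample_signal(x: np.ndarray, fs_in_hz: float, fs_out_hz: float) -> np.ndarray:
    """Anti-aliased downsampling (polyphase) along the last axis."""
    if fs_out_hz > fs_in_hz:
        raise ConfigError("upsampling is not supported in this pipeline")
    if fs_in_hz == fs_out_hz:
        return np.asarray(x, dtype=float)
    # rational rate conversion; pipeline rates are integral so this is exact
    fi, fo = int(round(fs_in_hz)), int(round(fs_out_hz))
    if not (np.isclose(fi, fs_in_hz) and np.isclose(fo, fs_out_hz)):
        raise ConfigError("sampling rates must be integral Hz")
    g = gcd(fi, fo)
    up, down = fo // g, fi // g
    y = sps.resample_poly(np.asarray(x, dtype=float), up, down, axis=-1)
    log.info("resampled %g -> %g Hz (%d -> %d samples)",
             fs_in_hz, fs_out_hz, np.shape(x)[-1], y.shape[-1])
    return y


def extract_envelope(
    audio: np.ndarray,
    audio_fs_hz: float,
    spec: FilterSpec | None = None,
    compression_exponent: float = 0.6,
    target_fs_hz: float = PIPELINE_FS_HZ,
) -> Envelope:
    """Broadband envelope: |x|^0.6 → resample to 120 Hz → band-pass."""
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise DataError("audio waveform is empty")
    if not np.all(np.isfinite(audio)):
        raise DataError("audio contains non-finite samples")
    env = np.abs(audio) ** compression_exponent
    env = resample_signal(env, audio_fs_hz, target_fs_hz)
    env = bandpass_filter(env, target_fs_hz, spec)
    return Envelope(
        samples=env, fs_hz=target_fs_hz,
        compression_exponent=compression_exponent, filtered=True,
    )


def preprocess_envelope(
    env: Envelope, spec: FilterSpec | None = None
) -> Envelope:
    """Band-pass an already rate-matched envelope with the EEG filter."""
    out = bandpass_filter(env.samples, env.fs_hz, spec)
    return Envelope(
        samples=out, fs_hz=env.fs_hz,
        compression_exponent=env.compression_exponent,
        condition=env.condition, filtered=True,
    )


def preprocess_eeg(
    eeg: EEGRecording,
    spec: FilterSpec | None = None,
    target_fs_hz: float = PIPELINE_FS_HZ,
    artifact_method: str = "none",
) -> EEGRecording:
    """Downsample to the pipeline rate, band-pass, then the artifact hook."""
    data = eeg.data
    fs = eeg.fs_hz
    if fs > target_fs_hz:
        data = resample_signal(data, fs, target_fs_hz)
        fs = target_fs_hz
    elif fs < target_fs_hz:
        raise ConfigError(
            f"EEG rate {fs} Hz below pipeline rate {target_fs_hz} Hz"
        )
    data = bandpass_filter(data, fs, spec)
    out = EEGRecording(
        data=data, fs_hz=fs, channel_names=list(eeg.channel_names),
        condition=eeg.condition,
    )
    return remove_artifacts(out, method=artifact_method)


# Artifact removal is a pluggable hook: the synthetic path needs none and a
# full ICA is out of scope, but real-data users can register a callable.
_ARTIFACT_METHODS: dict[str, object] = {"none": None}


def register_artifact_method(name: str, func) -> None:
    """Register ``func(EEGRecording) -> EEGRecording`` under ``name``."""
    _ARTIFACT_METHODS[name] = func


def remove_artifacts(eeg: EEGRecording, method: str = "none") -> EEGRecording:
    """Apply a registered artifact-removal hook; ``none`` is the identity.

    The hook contract is enforced: same channel count, labels and rate.
    """
    if method not in _ARTIFACT_METHODS:
        raise ConfigError(
            f"unknown artifact method {method!r}; "
            f"registered: {sorted(_ARTIFACT_METHODS)}"
        )
    func = _ARTIFACT_METHODS[method]
    if func is None:
        return eeg
    out = func(eeg)
    if not isinstance(out, EEGRecording):
        raise DataError("artifact hook must return an EEGRecording")
    if (
        out.data.shape != eeg.data.shape
        or out.channel_names != eeg.channel_names
        or out.fs_hz != eeg.fs_hz
    ):
        raise DataError(
            "artifact hook changed the recording shape, labels or rate"
        )
    return out
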