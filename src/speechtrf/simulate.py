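"""Synthetic speech-in-noise EEG cohorts.

The generator emulates a matrix-sentence (OLSa-style) passive-listening
experiment: per ΔSNR condition a ~9 min stream of sentence-shaped envelope
bursts (raised-cosine syllable modulation at 3.8 Hz) separated by silent
gaps of 0.9–1.8 s, EEG formed by convolving that envelope with a
ground-truth N1/P2 kernel scaled by a centro-parietal topography plus 1/f
background noise, and word-recognition scores drawn binomially from a
logistic psychometric function anchored at the subject's SRT_50.

SNR dependence lives on the kernel, not on the stimulus: amplitudes shrink
and latencies grow as ΔSNR decreases, mirroring how evoked-response
morphology degrades in noise, while the clean-speech envelope stays the
regressor at every condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._errors import ConfigError, DataError
from .containers import (
    PIPELINE_FS_HZ,
    BehavioralSample,
    Cohort,
    EEGRecording,
    Envelope,
    SubjectData,
)
from .montage import CHANNELS_32, default_topography
from .trf import LagSpec

log = logging.getLogger("speechtrf.simulate")

#: Study condition grid: ΔSNR relative to the behavioral SRT_50, in dB.
DELTA_SNR_GRID_DB = (-4.0, -2.0, -0.5, 0.5, 2.0, 4.0)

#: Logistic slope (dB) of the matrix-test psychometric function; reproduces
#: the expected recognition rates 94/80/59/41/20/6 % on the grid above.
DEFAULT_SLOPE_S_DB = 1.462

# stream tags for deterministic seed derivation
_STREAM_SRT = 0
_STREAM_GAIN = 1
_STREAM_ENV = 2
_STREAM_EEG = 3
_STREAM_BEHAVIOR = 4


@dataclass(frozen=True)
class StimulusConfig:
    """Envelope stream parameters for one condition.

    ``speech_level_db`` is presentation-level metadata only (the level is
    fixed across conditions so stimulus intensity cannot confound the TRF).
    """

    duration_s: float = 540.0  # ~9 min per condition
    syllable_rate_hz: float = 3.8
    gap_mean_s: float = 1.4
    gap_range_s: tuple[float, float] = (0.9, 1.8)
    syllables_per_sentence: int = 8  # ≈2.1 s five-word sentences at 3.8 Hz
    speech_level_db: float = 60.0
    fs_hz: float = PIPELINE_FS_HZ

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.syllable_rate_hz <= 0:
            raise ConfigError("syllable_rate_hz must be positive")
        lo, hi = self.gap_range_s
        if not (0 < lo <= self.gap_mean_s <= hi):
            raise ConfigError("gap_mean_s must lie within gap_range_s")
        if self.syllables_per_sentence < 1:
            raise ConfigError("need at least one syllable per sentence")


@dataclass(frozen=True)
class KernelParams:
    """Ground-truth TRF kernel: two Gaussians (N1 negative, P2 positive).

    At ΔSNR = d the amplitudes are scaled by max(0, 1 + amp_slope_per_db·d)
    (a negative-gain kernel is physiologically meaningless, hence the
    floor) and latencies shift by −lat_slope_ms_per_db·d, so higher SNR
    gives larger, earlier peaks.  Support is clipped to 0–400 ms.
    """

    n1_latency_ms: float = 100.0
    n1_amplitude: float = -1.0
    n1_width_ms: float = 22.0
    p2_latency_ms: float = 200.0
    p2_amplitude: float = 0.6
    p2_width_ms: float = 35.0
    amp_slope_per_db: float = 0.12
    lat_slope_ms_per_db: float = 3.0
    support_ms: tuple[float, float] = (0.0, 400.0)

    def __post_init__(self) -> None:
        if not (self.n1_amplitude < 0 < self.p2_amplitude):
            raise ConfigError("need n1_amplitude < 0 < p2_amplitude")
        if self.n1_width_ms <= 0 or self.p2_width_ms <= 0:
            raise ConfigError("kernel widths must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Study-level parameters of the synthetic cohort."""

    n_subjects: int = 18
    srt_mean_db: float = -7.0
    srt_sd_db: float = 0.9
    delta_snr_grid_db: tuple[float, ...] = DELTA_SNR_GRID_DB
    n_channels: int = 32
    channel_names: tuple[str, ...] = CHANNELS_32
    slope_s_db: float = DEFAULT_SLOPE_S_DB
    # 13 a.u. of 1/f noise puts the stimulus-driven signal ~10 dB below the
    # background in the 1-10 Hz analysis band at the best electrode, the
    # typical in-band SNR of cortical evoked responses
    noise_sd: float = 13.0
    noise_color: str = "pink"  # "white" available for oracle tests
    subject_gain_sd: float = 0.1  # log-normal spread of per-subject response gain
    n_sentences: int = 20
    words_per_sentence: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("need at least two subjects")
        grid = np.asarray(self.delta_snr_grid_db, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ConfigError("delta_snr_grid_db must be strictly increasing")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if len(self.channel_names) != self.n_channels:
            raise ConfigError(
                f"{len(self.channel_names)} labels for {self.n_channels} channels"
            )
        if self.slope_s_db <= 0:
            raise ConfigError("slope_s_db must be positive")
        if self.noise_color not in ("pink", "white"):
            raise ConfigError("noise_color must be 'pink' or 'white'")


def derive_seed(master: int, *key: int) -> int:
    """Deterministic child seed (< 2^31) from a master seed and offsets."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *[int(k) & 0x7FFFFFFF for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *key))


def generate_envelope(cfg: StimulusConfig, seed: int) -> Envelope:
    """Sentence-burst envelope at the 120 Hz pipeline rate.

    Each sentence is a raised-cosine syllable modulation at
    ``syllable_rate_hz`` under a gentle onset/offset ramp; sentences are
    separated by zero-valued gaps drawn uniformly from ``gap_range_s``.
    """
    rng = _rng(seed)
    fs = cfg.fs_hz
    n_total = int(round(cfg.duration_s * fs))
    sent_dur_s = cfg.syllables_per_sentence / cfg.syllable_rate_hz
    n_sent = int(round(sent_dur_s * fs))
    t_sent = np.arange(n_sent) / fs
    # raised-cosine syllable modulation, 0..1, one hump per syllable
    syllables = 0.5 * (1.0 - np.cos(2.0 * np.pi * cfg.syllable_rate_hz * t_sent))
    # sentence-level onset/offset ramp (100 ms raised cosine)
    ramp_n = max(1, int(round(0.1 * fs)))
    window = np.ones(n_sent)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    window[:ramp_n] = ramp
    window[n_sent - ramp_n :] = ramp[::-1]
    sentence = syllables * window

    env = np.zeros(n_total)
    lo, hi = cfg.gap_range_s
    pos = int(round(rng.uniform(lo, hi) * fs))  # leading gap
    while pos + n_sent <= n_total:
        amp = rng.uniform(0.7, 1.0)  # per-sentence level variation
        env[pos : pos + n_sent] = amp * sentence
        pos += n_sent + int(round(rng.uniform(lo, hi) * fs))
    if not env.any():
        raise ConfigError(
            f"duration {cfg.duration_s} s too short for a single sentence"
        )
    return Envelope(samples=env, fs_hz=fs)


def _gauss(t_ms: np.ndarray, mu_ms: float, width_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - mu_ms) / width_ms) ** 2)


def ground_truth_kernel(
    kp: KernelParams,
    delta_snr_db: float = 0.0,
    spec: LagSpec | None = None,
) -> np.ndarray:
    """Evaluate the N1/P2 kernel on the lag grid for one ΔSNR."""
    spec = spec or LagSpec()
    scale = max(0.0, 1.0 + kp.amp_slope_per_db * delta_snr_db)
    shift = -kp.lat_slope_ms_per_db * delta_snr_db
    t = spec.lags_ms
    k = (
        kp.n1_amplitude * scale * _gauss(t, kp.n1_latency_ms + shift, kp.n1_width_ms)
        + kp.p2_amplitude * scale * _gauss(t, kp.p2_latency_ms + shift, kp.p2_width_ms)
    )
    lo, hi = kp.support_ms
    k[(t < lo) | (t > hi)] = 0.0
    return k


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    if n > 1:
        f[0] = f[1]  # avoid the DC singularity
    else:
        return white
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def convolve_envelope_kernel(
    env_samples: np.ndarray, kernel: np.ndarray, spec: LagSpec
) -> np.ndarray:
    """Clean response Σ_τ k(τ) s(t−τ) with the design-matrix boundary rule.

    Matches ``build_lag_matrix(env, spec) @ kernel`` exactly (the envelope
    is treated as zero outside its support), at convolution cost.
    """
    n = env_samples.size
    full = np.convolve(env_samples, kernel)  # full[m] = Σ_j k_j s[m-j]
    lag0 = int(spec.lag_samples[0])
    # clean[t] = full[t - lag0]; indices below zero are zero-filled
    if lag0 <= 0:
        return full[-lag0 : -lag0 + n]
    out = np.zeros(n)
    out[lag0:] = full[: n - lag0]
    return out


def synthesize_eeg(
    env: Envelope,
    kp: KernelParams,
    cohort: CohortConfig,
    delta_snr_db: float,
    subject_seed: int,
    topography: np.ndarray | None = None,
    gain: float = 1.0,
    spec: LagSpec | None = None,
) -> EEGRecording:
    """EEG = gain · topography[c] · (envelope ⊛ kernel) + noise_sd · 1/f noise.

    Noise is independent per channel, seeded from ``subject_seed`` and the
    condition, so a cohort regenerates byte-identically.
    """
    if env.fs_hz != PIPELINE_FS_HZ:
        raise ConfigError("synthetic EEG requires the 120 Hz envelope")
    spec = spec or LagSpec()
    topo = (
        default_topography(cohort.channel_names)
        if topography is None
        else np.asarray(topography, dtype=float)
    )
    if topo.size != cohort.n_channels:
        raise DataError(
            f"topography has {topo.size} gains for {cohort.n_channels} channels"
        )
    kernel = ground_truth_kernel(kp, delta_snr_db, spec)
    clean = convolve_envelope_kernel(env.samples, kernel, spec)
    n = env.n_samples
    cond_key = int(round(delta_snr_db * 10.0))
    data = np.empty((cohort.n_channels, n))
    for c in range(cohort.n_channels):
        data[c] = gain * topo[c] * clean
        if cohort.noise_sd > 0:
            rng = _rng(subject_seed, _STREAM_EEG, cond_key, c)
            noise = (
                pink_noise(n, rng)
                if cohort.noise_color == "pink"
                else rng.standard_normal(n)
            )
            data[c] += cohort.noise_sd * noise
    return EEGRecording(
        data=data, fs_hz=env.fs_hz,
        channel_names=list(cohort.channel_names), condition=delta_snr_db,
    )


def psychometric(delta_snr_db, slope_s_db: float):
    """Word-recognition probability f = 1 / (1 + exp(−ΔSNR / s)).

    ΔSNR is the presentation SNR relative to SRT_50, so f(0) = 0.5 by
    construction.
    """
    return 1.0 / (1.0 + np.exp(-np.asarray(delta_snr_db, dtype=float) / slope_s_db))


def simulate_behavior(
    srt50_db: float,
    slope_s_db: float,
    delta_snr_db: float,
    n_sentences: int = 20,
    words_per_sentence: int = 5,
    seed: int = 0,
) -> BehavioralSample:
    """Binomial word score at SNR = SRT_50 + ΔSNR.

    With the default 20 sentences of 5 words the denominator is 100
    words per condition, so scores land on integer percentages.
    """
    if slope_s_db <= 0:
        raise ConfigError("slope_s_db must be positive")
    if n_sentences <= 0 or words_per_sentence <= 0:
        raise DataError("sentence and word counts must be positive")
    # (SNR − SRT_50)/s reduces to ΔSNR/s: srt50_db cancels by construction
    p = float(psychometric(delta_snr_db, slope_s_db))
    n_words = n_sentences * words_per_sentence
    rng = _rng(seed)
    correct = int(rng.binomial(n_words, p))
    return BehavioralSample(
        delta_snr_db=delta_snr_db,
        intelligibility_pct=100.0 * correct / n_words,
        n_sentences=n_sentences,
        words_per_sentence=words_per_sentence,
    )


def generate_cohort(
    cohort: CohortConfig,
    stim: StimulusConfig | None = None,
    kernel: KernelParams | None = None,
    with_eeg: bool = True,
) -> Cohort:
    """Full synthetic dataset: per subject an SRT_50, and per condition an
    envelope, an EEG recording and a behavioral score.

    Every random stream derives deterministically from ``cohort.seed``
    (subject index and condition index as counter offsets), so the same
    configuration regenerates byte-identically.  ``with_eeg=False`` skips
    the expensive EEG synthesis when only stimuli/behavior are needed.
    """
    stim = stim or StimulusConfig()
    kernel = kernel or KernelParams()
    topo = default_topography(cohort.channel_names)
    srt50 = _rng(cohort.seed, _STREAM_SRT).normal(
        cohort.srt_mean_db, cohort.srt_sd_db, cohort.n_subjects
    )
    gains = np.exp(
        _rng(cohort.seed, _STREAM_GAIN).normal(
            0.0, cohort.subject_gain_sd, cohort.n_subjects
        )
    )
    subjects = []
    for i in range(cohort.n_subjects):
        sub = SubjectData(subject_id=f"S{i + 1:02d}", srt50_db=float(srt50[i]))
        subject_seed = derive_seed(cohort.seed, 10, i)
        for j, dsnr in enumerate(cohort.delta_snr_grid_db):
            env = generate_envelope(stim, seed=derive_seed(cohort.seed, _STREAM_ENV, i, j))
            env.condition = dsnr
            sub.envelopes[dsnr] = env
            if with_eeg:
                sub.eeg[dsnr] = synthesize_eeg(
                    env, kernel, cohort, dsnr,
                    subject_seed=subject_seed,
                    topography=topo, gain=float(gains[i]),
                )
            sub.behavior[dsnr] = simulate_behavior(
                sub.srt50_db, cohort.slope_s_db, dsnr,
                cohort.n_sentences, cohort.words_per_sentence,
                seed=derive_seed(cohort.seed, _STREAM_BEHAVIOR, i, j),
            )
        subjects.append(sub)
        log.info("generated subject %s (SRT_50 = %.2f dB)", sub.subject_id, sub.srt50_db)
    return Cohort(subjects=subjects, delta_snr_grid_db=list(cohort.delta_snr_grid_db))
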