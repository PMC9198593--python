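"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import DataError

PIPELINE_FS_HZ = 120.0


@dataclass
class Envelope:
    """Single-channel stimulus envelope aligned to the EEG clock.

    ``samples`` is non-negative as produced by rectification + power-law
    compression; after band-pass filtering it becomes zero-mean (the
    ``filtered`` flag tracks which state it is in).
    """

    samples: np.ndarray
    fs_hz: float = PIPELINE_FS_HZ
    compression_exponent: float = 0.6
    condition: float | None = None  # ΔSNR in dB, if tied to a condition
    filtered: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise DataError("envelope must be a 1-D time series")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is (n_channels, n_samples)."""

    data: np.ndarray
    fs_hz: float
    channel_names: list[str]
    condition: float | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_names):
            raise DataError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel labels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class BehavioralSample:
    """Word-recognition score observed at one ΔSNR condition."""

    delta_snr_db: float
    intelligibility_pct: float
    n_sentences: int = 20
    words_per_sentence: int = 5

    def __post_init__(self) -> None:
        if self.n_sentences <= 0 or self.words_per_sentence <= 0:
            raise DataError("sentence and word counts must be positive")
        if not 0.0 <= self.intelligibility_pct <= 100.0:
            raise DataError("intelligibility must lie in [0, 100] %")

    @property
    def n_words(self) -> int:
        return self.n_sentences * self.words_per_sentence


@dataclass
class SubjectData:
    """One synthetic or imported subject: stimuli, EEG and behavior per ΔSNR."""

    subject_id: str
    srt50_db: float
    envelopes: dict[float, Envelope] = field(default_factory=dict)
    eeg: dict[float, EEGRecording] = field(default_factory=dict)
    behavior: dict[float, BehavioralSample] = field(default_factory=dict)

    @property
    def conditions(self) -> list[float]:
        return sorted(self.envelopes)


@dataclass
class Cohort:
    """A full dataset: one entry per subject, common condition grid."""

    subjects: list[SubjectData]
    delta_snr_grid_db: list[float]

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)
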