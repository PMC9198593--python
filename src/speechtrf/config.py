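"""Pipeline configuration: a single source of truth for every constant.

The ``defaults`` profile reproduces the study conditions: 120 Hz pipeline
rate, 1–10 Hz band-pass (397-tap Hamming windowed-sinc), lags −200…500 ms,
λ = 2¹⁵, N1 search 75–175 ms, P2 search 175–300 ms, RMS window grids
0–100 / 108–200 ms, RMS_sum electrodes {C3, CP3, CPz} and the ΔSNR grid
±0.5, ±2, ±4 dB.  Everything is overridable from a YAML file or CLI flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from ._errors import ConfigError
from .features import DEFAULT_RMS_ELECTRODES, N1_WINDOW_MS, P2_WINDOW_MS
from .preprocess import FilterSpec
from .simulate import CohortConfig, KernelParams, StimulusConfig
from .trf import DEFAULT_LAMBDA, LagSpec


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    kernel: KernelParams = field(default_factory=KernelParams)
    filter: FilterSpec = field(default_factory=FilterSpec)
    lags: LagSpec = field(default_factory=LagSpec)
    lambda_: float = DEFAULT_LAMBDA
    n1_window_ms: tuple[float, float] = N1_WINDOW_MS
    p2_window_ms: tuple[float, float] = P2_WINDOW_MS
    rms_electrodes: tuple[str, ...] = DEFAULT_RMS_ELECTRODES
    artifact_method: str = "none"
    dataset_path: str | None = None  # load instead of simulating when set

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "stimulus": StimulusConfig,
    "kernel": KernelParams,
    "filter": FilterSpec,
    "lags": LagSpec,
}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a (possibly partial) nested mapping."""
    kwargs = {}
    known = {f.name for f in fields(PipelineConfig)}
    for key, value in (data or {}).items():
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            section = dict(value or {})
            for name, v in section.items():
                if isinstance(v, list):
                    section[name] = tuple(v)
            try:
                kwargs[key] = cls(**section)
            except TypeError as exc:
                raise ConfigError(f"bad {key} section: {exc}") from exc
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a YAML config file; ``None`` gives the defaults profile."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    return config_from_dict(data)
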