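"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
FitError -> 4.  Library callers catch them like any other ValueError.
"""


class SpeechTRFError(ValueError):
    """Base class for all errors raised by this package."""


class ConfigError(SpeechTRFError):
    """Invalid configuration value, window, filter spec or method name."""


class DataError(SpeechTRFError):
    """Malformed, missing or dimensionally inconsistent data."""


class FitError(SpeechTRFError):
    """A model fit failed to converge or is degenerate."""
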