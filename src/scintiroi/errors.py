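"""Exception hierarchy shared across the pipeline."""


class ScintiroiError(Exception):
    """Base class for all package errors."""


class FormatError(ScintiroiError):
    """Malformed or inconsistent on-disk series/sidecar data."""


class ConfigError(ScintiroiError, ValueError):
    """Invalid configuration or parameter values."""


class AnalysisError(ScintiroiError):
    """A computation cannot proceed on this input (empty mask, flat map, ...)."""


class UnsuitableCurveError(AnalysisError):
    """The time-activity curve does not show the peak morphology the target
    method requires (e.g. slow-injection bolus, missing second peak)."""
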