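"""Exception hierarchy shared across the pipeline stages."""


class SleepOnsetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SleepOnsetError):
    """A configuration value is invalid (bad filter edge, non-stochastic matrix, ...)."""


class ValidationError(SleepOnsetError):
    """An input violates a precondition (NaN samples, length mismatch, bad label, ...)."""


class ChannelMapError(SleepOnsetError):
    """A required channel is missing from a recording file."""


class DegenerateInputError(SleepOnsetError):
    """The input is degenerate for the requested quantity (zero variance, zero band energy)."""
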