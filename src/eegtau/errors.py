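"""Exception types shared across the pipeline."""


class EegTauError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EegTauError):
    """A parameter combination is invalid (bad band, fs too low, ...)."""


class StabilityError(ConfigurationError):
    """An AR pole radius lies outside (0, 1)."""


class FormatError(EegTauError):
    """A file could not be parsed into a Recording or EventList."""


class MontageError(EegTauError):
    """A bipolar pair references a channel that is not present."""


class WindowingError(EegTauError):
    """A window specification is incompatible with the epoch span."""


class DegenerateWindowError(EegTauError):
    """A window has zero variance; its autocorrelation is undefined."""


class EmptySetError(EegTauError):
    """An operation received no usable trials/events/curves."""


class BaselineError(EegTauError):
    """The ERD baseline power is non-positive."""
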