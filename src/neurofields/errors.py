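"""Exception types shared across the package."""


class NeurofieldsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NeurofieldsError, ValueError):
    """A numeric argument violates its precondition."""


class FormatError(NeurofieldsError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class SingularEvaluationError(NeurofieldsError, ValueError):
    """A field was requested at (or too close to) a source location."""


class UndefinedCountError(NeurofieldsError, ValueError):
    """Sign-reversal counting on a profile entirely below the noise floor."""


class NoBoundaryError(NeurofieldsError, ValueError):
    """Boundary estimation requested on single-polarity input."""
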