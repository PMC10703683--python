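"""Exception hierarchy.

All errors raised by the library derive from :class:`EsrrfError` so callers
can catch one type; subclasses mirror the distinct failure contracts
(invalid data, invalid parameters, too few frames, low-confidence
registration, unreadable files).
"""


class EsrrfError(ValueError):
    """Base class for all errors raised by this package."""


class InvalidInputError(EsrrfError):
    """Input data violates a precondition (non-finite, wrong shape, ...)."""


class InvalidParameterError(EsrrfError):
    """A parameter value is outside its admissible range."""


class InsufficientFramesError(EsrrfError):
    """Too few frames for the requested temporal operation."""


class UndefinedCorrelationError(EsrrfError):
    """Correlation against a constant (zero-variance) reference."""


class LowConfidenceError(EsrrfError):
    """Registration correlation peak is not distinguishable from background."""


class FormatError(EsrrfError):
    """File could not be read/interpreted; message carries a remediation hint."""
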