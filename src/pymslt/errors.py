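"""Exception hierarchy used across the package."""


class PymsltError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PymsltError):
    """Invalid configuration value (scale, share, window, rate settings...)."""


class DomainError(PymsltError):
    """Argument outside the mathematical domain of an operation."""


class NumericError(PymsltError):
    """Numerical failure: non-convergent integral, proportion outside [0, 1]."""


class SchemaError(PymsltError):
    """Dataset file missing, or with missing/unexpected columns."""


class FitError(PymsltError):
    """Moments incompatible with the requested distribution family."""


class UndefinedICERError(PymsltError):
    """ICER requested for a zero QALY difference."""
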