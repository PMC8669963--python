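"""Exception hierarchy for the simulator."""


class DbsKuramotoError(Exception):
    """Base class for all package errors."""


class InvalidNetworkError(DbsKuramotoError, ValueError):
    """Raised when a network is too small or otherwise malformed."""


class ConfigurationError(DbsKuramotoError, ValueError):
    """Raised on invalid configuration values, unknown keys, or dimension mismatch."""


class NumericalOverflowError(DbsKuramotoError, FloatingPointError):
    """Raised when integration produces non-finite or absurdly large phases."""


class InvalidInputError(DbsKuramotoError, ValueError):
    """Raised when a metric receives malformed input (length mismatch, empty, non-finite)."""


class DegenerateBaselineError(DbsKuramotoError, ZeroDivisionError):
    """Raised when a percent-change baseline value is zero (or negative)."""
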