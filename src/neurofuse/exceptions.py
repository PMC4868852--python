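"""Exception hierarchy.

``ConfigurationError`` flags invalid user-supplied parameters,
``InputDataError`` flags invalid data passed to an operation, and
``NumericalError`` flags numerically infeasible fits (e.g. a singular
unregularized covariance).  All derive from :class:`NeurofuseError` so
callers can catch package errors with one clause.
"""


class NeurofuseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeurofuseError, ValueError):
    """An invalid parameter or configuration value, naming the field."""


class InputDataError(NeurofuseError, ValueError):
    """Invalid input data (shape mismatch, non-finite values, ...)."""


class NumericalError(NeurofuseError, RuntimeError):
    """A numerically infeasible computation with advice on how to fix it."""
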