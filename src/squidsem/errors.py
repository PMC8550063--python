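"""Exception types shared across the package."""


class SquidsemError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SquidsemError, ValueError):
    """A model parameter violates its documented invariant."""


class InvalidInputError(SquidsemError, ValueError):
    """A state variable or series passed to an operation is out of range."""


class ConfigurationError(SquidsemError, ValueError):
    """A run configuration is inconsistent (missing years, files, labels)."""


class UndefinedStatisticError(SquidsemError, ValueError):
    """A summary statistic is undefined for the given input (e.g. constant
    observations in an r-squared, no valid years in a price gap)."""


class CalibrationFailureError(SquidsemError, RuntimeError):
    """Every Monte-Carlo draw produced a degenerate trajectory."""
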