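"""Exception hierarchy for the newssdt pipeline.

All errors raised by the package derive from :class:`NewsSDTError` so callers
can catch pipeline failures with a single except clause while still
distinguishing schema problems from numerical ones.
"""


class NewsSDTError(Exception):
    """Base class for all newssdt errors."""


class SchemaError(NewsSDTError, ValueError):
    """A required column or field is missing from an input file."""


class ValidationError(NewsSDTError, ValueError):
    """Input data violate the ratings-table contract (bad value, bad group)."""


class ConfigurationError(NewsSDTError, ValueError):
    """An operation was requested with inconsistent or missing configuration."""


class ComputationError(NewsSDTError, ValueError):
    """A statistic cannot be computed for an identified group of records."""


class DegenerateDataError(NewsSDTError, ValueError):
    """Sample data are degenerate in a way that leaves a statistic undefined."""


class NumericalError(NewsSDTError, ArithmeticError):
    """A quadrature or optimisation routine failed to converge."""
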