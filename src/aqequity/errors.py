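"""Exception hierarchy.

Every error raised by the package derives from :class:`AQEquityError` so
callers can catch pipeline failures with a single except clause while tests
can assert the precise failure mode.
"""


class AQEquityError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AQEquityError, ValueError):
    """An invalid configuration field; the message names the field."""


class DomainError(AQEquityError, ValueError):
    """An input outside a function's mathematical domain."""


class ImputationError(AQEquityError):
    """No same-category neighbour available for stack-layer imputation."""


class AllocationError(AQEquityError, ValueError):
    """Area-source surrogate weights cannot allocate mass (e.g. all zero)."""


class ScalingError(AQEquityError, LookupError):
    """A (region, category) pair in the inventory has no scaling factor."""


class CoverageError(AQEquityError, LookupError):
    """A (pollutant, layer) combination is missing from the SRM."""


class LabelError(AQEquityError, LookupError):
    """An unknown sector / group / region label."""


class ShapeError(AQEquityError, ValueError):
    """Grid or array shape mismatch between operands."""


class UndefinedMetricError(AQEquityError, ZeroDivisionError):
    """Exposure or disparity undefined (zero population or zero exposure)."""


class InfeasibleError(AQEquityError):
    """An optimization target outside the feasible range; names the group."""


class AlignmentError(AQEquityError, ValueError):
    """Two inventories or a scenario/inventory pair on different source sets."""


class SchemaError(AQEquityError, ValueError):
    """A file is missing required columns."""


class ValidationError(AQEquityError, ValueError):
    """A file row violates a value constraint; the message names the row."""
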