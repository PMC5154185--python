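"""Exception hierarchy shared across the package."""


class RamForageError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(RamForageError):
    """Invalid flower-array geometry (too few flowers, non-positive radius...)."""


class UndefinedDirectionError(RamForageError):
    """Travel direction requested between two identical points."""


class MalformedRecordError(RamForageError):
    """A visit record violates the schema (e.g. flower id out of range)."""


class PolicyConfigError(RamForageError):
    """An agent policy is internally inconsistent (e.g. stereotyped without a matrix)."""


class NoDataError(RamForageError):
    """An operation received an empty input where data is required."""


class InsufficientDataError(RamForageError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(RamForageError):
    """Rank correlation requested on a constant vector."""


class SchemaError(RamForageError):
    """A CSV table does not match its declared schema."""


class NoEventsError(RamForageError):
    """Survival fit requested on data with no observed events."""
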