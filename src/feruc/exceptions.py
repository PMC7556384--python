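"""Exception hierarchy.

All library-specific failures derive from :class:`FerucError` so callers
(and the CLI) can catch one base class.
"""


class FerucError(Exception):
    """Base class for all feruc errors."""


class BinCountError(FerucError, ValueError):
    """Requested bin count is impossible for the given response vector."""


class EmptyBinError(FerucError, ValueError):
    """A discretizer produced (or would produce) an empty bin."""


class DegenerateClassError(FerucError, ValueError):
    """A resampler was given a one-class (or non-binary) label vector."""


class FitError(FerucError, RuntimeError):
    """Ensemble fitting failed (e.g. a bin is below minimum occupancy)."""


class ContractViolationError(FerucError, ValueError):
    """A value violated an interface contract (e.g. probability outside [0, 1])."""


class UndefinedMetricError(FerucError, ZeroDivisionError):
    """A metric's denominator is undefined (e.g. constant observed vector)."""


class DegenerateTestError(FerucError, ValueError):
    """A statistical test is undefined for the given inputs."""


class ValidationError(FerucError, ValueError):
    """A parameter object failed validation; message lists the offending fields."""


class TableFormatError(FerucError, ValueError):
    """A tabular input file could not be parsed into a Dataset."""


class MissingColumnError(TableFormatError):
    """A named target column is absent from the input table."""


class NonNumericCellError(TableFormatError):
    """A cell that must be numeric is not; message cites row and column."""
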