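"""Exception hierarchy.

Everything derives from :class:`FckiError` so callers can catch the package's
failures with one clause; the finer-grained classes mirror the distinct
failure modes of parsing, amputation specs, donor-pool construction and
metric evaluation.
"""


class FckiError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(FckiError):
    """A CSV cell could not be parsed as a number; carries row/column."""

    def __init__(self, message: str, row: int | None = None, col: int | None = None):
        super().__init__(message)
        self.row = row
        self.col = col


class ShapeError(FckiError):
    """Ragged rows, mismatched lengths, or incompatible matrix shapes."""


class EmptyInputError(FckiError):
    """An input file or dataset contained no data."""


class SpecError(FckiError, ValueError):
    """An amputation/clustering/imputation parameter is out of range."""


class PrefilledInputError(FckiError):
    """An amputation input already contains missing cells."""


class PoolTooSmallError(FckiError):
    """Donor pool too small for the automatic-k search (fewer than 3 rows)."""


class NoComparableDonorsError(FckiError):
    """Every candidate donor is at infinite partial distance from the query."""


class ColumnAllMissingError(FckiError):
    """A column has no observed value, so no estimate of it exists."""


class SubsetTooSmallError(FckiError):
    """Round-robin regression needs at least two rows."""


class DegenerateRangeError(FckiError):
    """Observed values span zero range; NRMSE is undefined."""


class EmptyMaskError(FckiError):
    """Evaluation requested over a mask with no masked cells."""
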