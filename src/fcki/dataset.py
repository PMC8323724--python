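"""Rectangular numeric datasets with an explicit missingness model.

A :class:`NumericDataset` is an N×M float matrix with row and column labels;
missing cells are ``NaN``. A :class:`MaskedDataset` couples an amputed
dataset with the boolean mask that produced it, the pre-amputation truth and
the generator provenance, so downstream evaluation can score imputations on
exactly the cells that were removed.

CSV is the only file format: comma-separated, optional header row, missing
cells written as a configurable token (default ``NaN``) and read back from a
configurable token set (default ``{"", "NaN", "nan", "NA"}``).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import EmptyInputError, ParseError, ShapeError

DEFAULT_MISSING_TOKENS = ("", "NaN", "nan", "NA")


@dataclass
class NumericDataset:
    """An N×M real matrix with row/column identity; NaN marks missing.

    Parameters
    ----------
    values : ndarray of shape (N, M)
        Float matrix. Cells are finite reals or NaN (the missing marker);
        infinities are rejected.
    row_ids : sequence of str, optional
        Unique record labels; defaults to ``"r0".."r{N-1}"``.
    col_names : sequence of str, optional
        Unique attribute labels; defaults to ``"x0".."x{M-1}"``.
    """

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise EmptyInputError(f"dataset must be at least 1x1, got {n}x{m}")
        if np.isinf(self.values).any():
            raise ParseError("dataset contains infinities; cells must be finite or NaN")
        if not self.row_ids:
            self.row_ids = [f"r{i}" for i in range(n)]
        if not self.col_names:
            self.col_names = [f"x{j}" for j in range(m)]
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_names = [str(c) for c in self.col_names]
        if len(self.row_ids) != n:
            raise ShapeError(f"{len(self.row_ids)} row ids for {n} rows")
        if len(self.col_names) != m:
            raise ShapeError(f"{len(self.col_names)} column names for {m} columns")
        if len(set(self.row_ids)) != n:
            raise ShapeError("row ids are not unique")
        if len(set(self.col_names)) != m:
            raise ShapeError("column names are not unique")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_flags(self) -> np.ndarray:
        """Boolean N×M matrix, True where the cell is missing."""
        return np.isnan(self.values)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def copy(self) -> "NumericDataset":
        return NumericDataset(self.values.copy(), list(self.row_ids), list(self.col_names))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_names)


@dataclass
class MissingMask:
    """Boolean missingness mask plus its summary counts.

    ``mv_count`` is the number of masked cells MV and ``ratio_percent`` the
    achieved ratio 100·MV/(N·M).
    """

    flags: np.ndarray
    mv_count: int = -1
    ratio_percent: float = -1.0

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ShapeError("mask must be 2-D")
        mv = int(self.flags.sum())
        if self.mv_count < 0:
            self.mv_count = mv
        elif self.mv_count != mv:
            raise ShapeError(f"mv_count={self.mv_count} but mask has {mv} set flags")
        ratio = 100.0 * mv / self.flags.size
        if self.ratio_percent < 0:
            self.ratio_percent = ratio
        elif not math.isclose(self.ratio_percent, ratio, abs_tol=1e-9):
            raise ShapeError(f"ratio_percent={self.ratio_percent} inconsistent with mask ({ratio})")


@dataclass
class Provenance:
    """How a mask was generated: mechanism name, target ratio, NA, seed."""

    mechanism: str
    mdr_percent: float
    na: int | None
    seed: int | None


@dataclass
class MaskedDataset:
    """An amputed dataset joined to its mask, ground truth and provenance."""

    data: NumericDataset
    mask: MissingMask
    truth: NumericDataset | None = None
    provenance: Provenance | None = None

    def __post_init__(self) -> None:
        if self.mask.flags.shape != self.data.shape:
            raise ShapeError("mask shape does not match data shape")
        if not np.isnan(self.data.values[self.mask.flags]).all():
            raise ShapeError("some masked cells of data do not carry the missing marker")
        if self.truth is not None:
            if self.truth.shape != self.data.shape:
                raise ShapeError("truth shape does not match data shape")
            obs = ~self.mask.flags
            d, t = self.data.values[obs], self.truth.values[obs]
            same = (d == t) | (np.isnan(d) & np.isnan(t))
            if not same.all():
                raise ShapeError("data and truth disagree on a non-masked cell")


def read_csv(
    path,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    has_header: bool = True,
) -> NumericDataset:
    """Read a numeric CSV into a :class:`NumericDataset`.

    Cells matching any entry of ``missing_tokens`` (case-insensitive, after
    stripping surrounding whitespace) become NaN. Raises
    :class:`~fcki.exceptions.ParseError` on a non-numeric cell (naming its
    row and column), :class:`~fcki.exceptions.ShapeError` on ragged rows and
    :class:`~fcki.exceptions.EmptyInputError` on an empty file.
    """
    tokens = {t.strip().lower() for t in missing_tokens}
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        raise EmptyInputError(f"{path}: empty file")
    col_names: list[str] = []
    if has_header:
        col_names = [c.strip() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise EmptyInputError(f"{path}: header but no data rows")
    m = len(rows[0])
    values = np.empty((len(rows), m), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != m:
            raise ShapeError(f"{path}: row {i} has {len(row)} cells, expected {m}")
        for j, cell in enumerate(row):
            text = cell.strip()
            if text.lower() in tokens:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(text)
            except ValueError:
                raise ParseError(
                    f"{path}: cell at row {i}, column {j} is not numeric: {text!r}",
                    row=i,
                    col=j,
                ) from None
            if np.isinf(values[i, j]):
                raise ParseError(f"{path}: infinite value at row {i}, column {j}", row=i, col=j)
    return NumericDataset(values, col_names=col_names or [])


def write_csv(data: NumericDataset, path, missing_token: str = "NaN") -> None:
    """Write a dataset as CSV with a header row.

    Numeric cells use ``repr`` (shortest round-trippable form), so a
    ``write_csv``/``read_csv`` round trip is value-exact.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(data.col_names)
        for row in data.values:
            writer.writerow([missing_token if np.isnan(v) else repr(float(v)) for v in row])


def missing_profile(data: NumericDataset) -> tuple[dict[str, int], float]:
    """Per-column missing counts and the overall missing ratio in percent."""
    flags = data.missing_flags()
    counts = {name: int(flags[:, j].sum()) for j, name in enumerate(data.col_names)}
    ratio = 100.0 * flags.sum() / flags.size
    return counts, float(ratio)


def as_dataset(x) -> NumericDataset:
    """Coerce an array-like / DataFrame / NumericDataset to a NumericDataset."""
    if isinstance(x, NumericDataset):
        return x
    try:
        import pandas as pd

        if isinstance(x, pd.DataFrame):
            return NumericDataset(
                x.to_numpy(dtype=float),
                row_ids=[str(i) for i in x.index],
                col_names=[str(c) for c in x.columns],
            )
    except ImportError:  # pragma: no cover
        pass
    return NumericDataset(np.asarray(x, dtype=float))
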