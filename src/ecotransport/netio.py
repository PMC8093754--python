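"""Reading, writing and normalizing labeled bipartite interaction data.

All matrices follow one fixed orientation: rows are the top level *A*
(n species, e.g. animals), columns are the bottom level *B* (m species,
e.g. plants).  Files are delimited text with a header row of column
labels and a first column of row labels; the delimiter (comma or tab) is
auto-detected and can be overridden.  Forbidden links in utility-matrix
files are written as the literal token ``-inf``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InteractionCounts",
    "Coupling",
    "ValidationError",
    "ParseError",
    "read_counts",
    "write_counts",
    "read_matrix",
    "write_matrix",
    "read_abundance",
    "write_abundance",
    "normalize_counts",
]


class ValidationError(ValueError):
    """Input data violates a structural contract (negative count, bad labels...)."""


class ParseError(ValueError):
    """A file could not be parsed as a labeled matrix."""


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_labeled_frame(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path, delimiter)
    # pandas pads/raises inconsistently on ragged rows; check explicitly so the
    # error can name the offending line.
    with open(path, "r") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split(sep)
    width = len(header)
    _check_unique(header[1:], "column")
    for lineno, ln in enumerate(lines[1:], start=2):
        if len(ln.split(sep)) != width:
            raise ParseError(
                f"{path}: line {lineno} has {len(ln.split(sep))} fields, expected {width}"
            )
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _check_unique(labels, axis: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {axis} label: {lab!r}")
        seen.add(lab)


@dataclass
class InteractionCounts:
    """Observed integer interaction/visit matrix Y with species labels.

    ``total_count`` is L = sum of all entries.  (The source framework's
    notation calls this quantity the connectance, although it is a total
    count, not a link density.)
    """

    matrix: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("count matrix must be two-dimensional")
        n, m = self.matrix.shape
        if len(self.row_labels) != n or len(self.col_labels) != m:
            raise ValidationError("label lengths do not match matrix shape")
        _check_unique(self.row_labels, "row")
        _check_unique(self.col_labels, "column")
        bad = np.argwhere(self.matrix < 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"negative count at row {self.row_labels[i]!r}, "
                f"column {self.col_labels[j]!r}: {self.matrix[i, j]}"
            )
        if not np.allclose(self.matrix, np.round(self.matrix)):
            i, j = np.argwhere(~np.isclose(self.matrix, np.round(self.matrix)))[0]
            raise ValidationError(
                f"non-integral count at row {self.row_labels[i]!r}, "
                f"column {self.col_labels[j]!r}: {self.matrix[i, j]}"
            )
        self.matrix = np.round(self.matrix)

    @property
    def total_count(self) -> float:
        """L, the total number of observed interactions."""
        return float(self.matrix.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class Coupling:
    """A joint distribution over (top, bottom) species pairs.

    ``matrix`` sums to one; ``row_marginal`` (a) and ``col_marginal`` (b)
    are its row and column sums.  ``kind`` distinguishes an observed
    coupling P (normalized counts) from a modeled coupling Q (solution of
    a transport problem).
    """

    matrix: np.ndarray
    row_marginal: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_marginal: np.ndarray = field(default=None)  # type: ignore[assignment]
    kind: str = "observed"
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("coupling must be two-dimensional")
        if (self.matrix < 0).any():
            raise ValidationError("coupling has negative entries")
        total = self.matrix.sum()
        if not np.isclose(total, 1.0, atol=1e-10):
            raise ValidationError(f"coupling entries sum to {total}, expected 1")
        if self.row_marginal is None:
            self.row_marginal = self.matrix.sum(axis=1)
        else:
            self.row_marginal = np.asarray(self.row_marginal, dtype=float)
        if self.col_marginal is None:
            self.col_marginal = self.matrix.sum(axis=0)
        else:
            self.col_marginal = np.asarray(self.col_marginal, dtype=float)
        if self.kind not in ("observed", "modeled"):
            raise ValidationError(f"unknown coupling kind: {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def read_counts(path: str | Path, delimiter: str | None = None) -> InteractionCounts:
    """Read a labeled count matrix (header row + label column)."""
    df = _read_labeled_frame(path, delimiter)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric entry ({exc})") from exc
    return InteractionCounts(values, list(df.index), list(df.columns))


def write_counts(counts: InteractionCounts, path: str | Path,
                 delimiter: str = ",") -> None:
    df = pd.DataFrame(
        counts.matrix.astype(int), index=counts.row_labels, columns=counts.col_labels
    )
    df.to_csv(path, sep=delimiter)


def read_matrix(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a labeled real-valued matrix (utility M or coupling P/Q).

    ``-inf`` tokens are preserved as ``-numpy.inf`` (forbidden links).
    """
    df = _read_labeled_frame(path, delimiter)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric entry ({exc})") from exc
    return df


def write_matrix(matrix: np.ndarray, path: str | Path,
                 row_labels=None, col_labels=None, delimiter: str = ",") -> None:
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    df = pd.DataFrame(
        matrix,
        index=row_labels if row_labels is not None else [f"A{i+1}" for i in range(n)],
        columns=col_labels if col_labels is not None else [f"B{j+1}" for j in range(m)],
    )
    df.to_csv(path, sep=delimiter)


def read_abundance(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Read a one-column labeled abundance vector."""
    df = _read_labeled_frame(path, delimiter)
    if df.shape[1] != 1:
        raise ParseError(f"{path}: expected one value column, found {df.shape[1]}")
    series = df.iloc[:, 0].astype(float)
    if (series < 0).any():
        lab = series.index[series.to_numpy() < 0][0]
        raise ValidationError(f"negative abundance for species {lab!r}")
    return series


def write_abundance(values: np.ndarray, path: str | Path,
                    labels=None, name: str = "abundance",
                    delimiter: str = ",") -> None:
    values = np.asarray(values, dtype=float)
    idx = labels if labels is not None else [f"S{i+1}" for i in range(len(values))]
    pd.Series(values, index=idx, name=name).to_csv(path, sep=delimiter)


def normalize_counts(counts: InteractionCounts) -> Coupling:
    """Observed coupling P = Y / L with marginals a (rows) and b (columns).

    Species with zero observed interactions are retained with zero
    marginal (a warning is issued); transport solvers drop and re-insert
    them.
    """
    L = counts.total_count
    if L == 0:
        raise ValidationError("cannot normalize a count matrix with total count 0")
    P = counts.matrix / L
    a = P.sum(axis=1)
    b = P.sum(axis=0)
    if (a == 0).any() or (b == 0).any():
        zero_rows = [counts.row_labels[i] for i in np.flatnonzero(a == 0)]
        zero_cols = [counts.col_labels[j] for j in np.flatnonzero(b == 0)]
        warnings.warn(
            "species with zero observed interactions retained with zero "
            f"marginal: rows {zero_rows}, columns {zero_cols}",
            stacklevel=2,
        )
    return Coupling(P, a, b, kind="observed",
                    row_labels=list(counts.row_labels),
                    col_labels=list(counts.col_labels))
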