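"""Q-matrix container and delimited-text I/O.

A Q matrix is the standard output of model-based population-structure
inference (STRUCTURE, ADMIXTURE, baps, ...): one row per individual, one
column per statistical cluster, entry ``q[i, k]`` giving the proportion of
individual *i*'s ancestry assigned to cluster *k*.  Rows are probability
vectors and sum to 1.

Supported on-disk dialects are plain delimited text: the ADMIXTURE ``.Q``
dialect (whitespace-delimited, headerless, no labels) and CSV/TSV with an
optional single header row of cluster labels and an optional leading
row-label column.  Full STRUCTURE output files (header blocks, per-individual
metadata) are deliberately not parsed; extract the numeric block or use
``skip_cols``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QMatrix",
    "QMatrixError",
    "QMatrixParseError",
    "QMatrixValidationError",
    "read_q",
    "write_q",
    "normalize_rows",
    "DEFAULT_ROW_SUM_TOL",
]

#: Default slack accepted on row sums before renormalization.  STRUCTURE and
#: ADMIXTURE print 3-6 decimals per coefficient, so printed rows can miss 1
#: by up to ~5e-4 per entry; 1e-3 accepts rounding while still catching rows
#: that are genuinely not probability vectors.
DEFAULT_ROW_SUM_TOL = 1e-3


class QMatrixError(ValueError):
    """Base class for Q-matrix input problems."""


class QMatrixParseError(QMatrixError):
    """A cell could not be parsed as a number, or the file is empty."""


class QMatrixValidationError(QMatrixError):
    """Parsed numbers violate the Q-matrix invariants."""


@dataclass(frozen=True)
class QMatrix:
    """An I x K matrix of ancestry membership coefficients.

    Parameters
    ----------
    values
        Nonnegative floats with unit row sums; coerced to a C-contiguous
        float64 array and validated on construction.
    row_labels
        Optional individual identifiers (length I).
    col_labels
        Optional cluster identifiers (length K).
    group
        Optional group/population tag used to label bootstrap distributions.
    row_sum_tol
        Accepted deviation of raw row sums from 1 before renormalization.
    """

    values: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None
    group: str | None = None
    row_sum_tol: float = field(default=DEFAULT_ROW_SUM_TOL, repr=False)

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise QMatrixValidationError(
                f"Q matrix must be 2-D with at least one row and one column, "
                f"got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise QMatrixValidationError("Q matrix contains non-finite entries")
        if np.any(arr < 0):
            bad = np.argwhere(arr < 0)[0]
            raise QMatrixValidationError(
                f"negative membership coefficient at row {bad[0] + 1}, "
                f"column {bad[1] + 1}"
            )
        arr = _renormalized(arr, self.row_sum_tol)
        object.__setattr__(self, "values", arr)
        if self.row_labels is not None:
            object.__setattr__(self, "row_labels", tuple(map(str, self.row_labels)))
            if len(self.row_labels) != arr.shape[0]:
                raise QMatrixValidationError(
                    f"{len(self.row_labels)} row labels for {arr.shape[0]} rows"
                )
        if self.col_labels is not None:
            object.__setattr__(self, "col_labels", tuple(map(str, self.col_labels)))
            if len(self.col_labels) != arr.shape[1]:
                raise QMatrixValidationError(
                    f"{len(self.col_labels)} column labels for {arr.shape[1]} columns"
                )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_group(self, group: str) -> "QMatrix":
        return replace(self, group=group)

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.col_labels or [f"cluster{k + 1}" for k in range(self.n_clusters)]
        idx = list(self.row_labels) if self.row_labels is not None else None
        return pd.DataFrame(self.values, columns=list(cols), index=idx)

    def __eq__(self, other: object) -> bool:  # value equality, labels ignored
        if not isinstance(other, QMatrix):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.values.tobytes()))


def _renormalized(arr: np.ndarray, tol: float) -> np.ndarray:
    sums = arr.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        listed = ", ".join(
            f"row {i + 1} (sum {sums[i]:.6g})" for i in bad[:10]
        )
        more = "" if bad.size <= 10 else f" and {bad.size - 10} more"
        raise QMatrixValidationError(
            f"row sums outside 1 +/- {tol:g}: {listed}{more}"
        )
    if np.any(sums == 0):
        raise QMatrixValidationError("row of all zeros")
    # single division pass; rows whose float sum is already exactly 1 are
    # left untouched, so renormalization is idempotent to within one ulp
    rows = np.flatnonzero(sums != 1.0)
    if rows.size:
        arr = arr.copy()
        arr[rows] = arr[rows] / sums[rows, None]
    return arr


def normalize_rows(q: QMatrix, tol: float = DEFAULT_ROW_SUM_TOL) -> QMatrix:
    """Return a copy of ``q`` with rows rescaled to sum exactly to 1.

    Rows whose raw sum deviates from 1 by more than ``tol`` raise
    :class:`QMatrixValidationError`; an all-zero row is always an error.
    Idempotent to working precision: renormalizing a normalized matrix
    changes no entry by more than one unit in the last place.
    """
    return replace(q, values=_renormalized(q.values, tol), row_sum_tol=tol)


_SEPS = {"whitespace": r"\s+", "csv": ",", "tsv": "\t"}


def _sniff_dialect(path: Path) -> str:
    for line in path.read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if "\t" in s:
            return "tsv"
        if "," in s:
            return "csv"
        return "whitespace"
    raise QMatrixParseError(f"{path}: file is empty")


def read_q(
    path: str | Path,
    dialect: str = "auto",
    skip_cols: int = 0,
    has_header: bool = False,
    row_labels: bool = False,
    tol: float = DEFAULT_ROW_SUM_TOL,
    group: str | None = None,
) -> QMatrix:
    """Read a Q matrix from a delimited text file.

    Parameters
    ----------
    path
        File to read.  Lines starting with ``#`` are ignored.
    dialect
        ``"whitespace"`` (ADMIXTURE ``.Q``), ``"csv"``, ``"tsv"``, or
        ``"auto"`` to sniff the separator from the first non-comment line.
    skip_cols
        Number of leading metadata columns to drop before parsing numbers.
        Metadata columns are never guessed; silent misparsing of a label
        column as ancestry is worse than an error.
    has_header
        First non-comment line holds cluster labels.
    row_labels
        First remaining column (after ``skip_cols``) holds individual
        identifiers.
    tol
        Row-sum tolerance passed to validation; rows are renormalized to
        exact unit sums afterwards.
    group
        Optional group tag to attach.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    if dialect not in _SEPS:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path,
            sep=_SEPS[dialect],
            header=0 if has_header else None,
            comment="#",
            dtype=str,
            skip_blank_lines=True,
            engine="python",
        )
    except pd.errors.EmptyDataError:
        raise QMatrixParseError(f"{path}: file is empty") from None
    if df.shape[0] == 0:
        raise QMatrixParseError(f"{path}: no data rows")

    col_labels = [str(c) for c in df.columns] if has_header else None
    if skip_cols:
        if skip_cols >= df.shape[1]:
            raise QMatrixParseError(
                f"{path}: skip_cols={skip_cols} leaves no data columns"
            )
        df = df.iloc[:, skip_cols:]
        if col_labels:
            col_labels = col_labels[skip_cols:]
    rlabels: tuple[str, ...] | None = None
    if row_labels:
        if df.shape[1] < 2:
            raise QMatrixParseError(f"{path}: row_labels leaves no data columns")
        rlabels = tuple(df.iloc[:, 0].astype(str))
        df = df.iloc[:, 1:]
        if col_labels:
            col_labels = col_labels[1:]

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise QMatrixParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at data row {i + 1}, "
            f"column {j + 1}"
        )
    return QMatrix(
        numeric.to_numpy(dtype=np.float64),
        row_labels=rlabels,
        col_labels=tuple(col_labels) if col_labels else None,
        group=group,
        row_sum_tol=tol,
    )


def write_q(
    q: QMatrix,
    path: str | Path,
    dialect: str = "whitespace",
    precision: int = 17,
) -> None:
    """Write a Q matrix as delimited text.

    ``whitespace`` emits the headerless ADMIXTURE ``.Q`` layout; ``csv`` and
    ``tsv`` emit a header row when the matrix carries column labels and a
    leading label column when it carries row labels.  The default precision
    (17 significant digits) makes write -> read the identity on float64
    values.
    """
    if dialect not in _SEPS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = " " if dialect == "whitespace" else _SEPS[dialect]
    fmt = f"{{:.{precision}g}}"
    buf = io.StringIO()
    if dialect != "whitespace" and q.col_labels is not None:
        header = list(q.col_labels)
        if q.row_labels is not None:
            header = ["id"] + header
        buf.write(sep.join(header) + "\n")
    for i, row in enumerate(q.values):
        fields = [fmt.format(v) for v in row]
        if dialect != "whitespace" and q.row_labels is not None:
            fields = [q.row_labels[i]] + fields
        buf.write(sep.join(fields) + "\n")
    Path(path).write_text(buf.getvalue())
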