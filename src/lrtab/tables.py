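"""Observed-count tables and expected-value models.

A :class:`ContingencyTable` holds validated non-negative integer counts with
margins recomputed from the cells.  An :class:`ExpectedModel` holds the
expected cell values used by every test statistic, tagged with where those
values came from: the table's own margins, an externally specified
probability matrix, or fixed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "ExpectedModel",
    "DegenerateTableError",
    "make_table",
    "expected_from_margins",
    "expected_from_probabilities",
    "expected_from_counts",
    "read_counts_csv",
    "read_probabilities_csv",
    "write_counts_csv",
]

_PROB_SUM_TOL = 1e-9


class DegenerateTableError(ValueError):
    """Raised when an operation requires a table with positive grand total."""


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer counts, r x c with r, c >= 2.

    Margins and the grand total are always recomputed from the cells;
    they are never accepted from input.
    """

    counts: np.ndarray
    row_totals: np.ndarray = field(init=False)
    col_totals: np.ndarray = field(init=False)
    grand_total: int = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError(f"counts must be a 2-D matrix, got ndim={arr.ndim}")
        r, c = arr.shape
        if r < 2 or c < 2:
            raise ValueError(f"table must be at least 2x2, got {r}x{c}")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(np.asarray(arr, dtype=float))
            if not np.allclose(arr, rounded, rtol=0, atol=1e-9):
                raise ValueError("counts must be integral")
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(f"negative count {arr[i, j]} at cell ({i}, {j})")
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "row_totals", arr.sum(axis=1))
        object.__setattr__(self, "col_totals", arr.sum(axis=0))
        object.__setattr__(self, "grand_total", int(arr.sum()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def is_empty(self) -> bool:
        """True when the grand total is zero (accepted but degenerate)."""
        return self.grand_total == 0

    @property
    def row_proportions(self) -> np.ndarray:
        """Proportion of each row's count falling in each column."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / self.row_totals[:, None]

    @property
    def col_proportions(self) -> np.ndarray:
        """Proportion of each column's count falling in each row."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / self.col_totals[None, :]

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.tolist(),
            "row_totals": self.row_totals.tolist(),
            "col_totals": self.col_totals.tolist(),
            "grand_total": self.grand_total,
        }


@dataclass(frozen=True)
class ExpectedModel:
    """Expected cell values E_ij plus their provenance.

    source is one of ``margins`` (null model fitted from the observed
    table's marginal totals), ``probabilities`` (externally specified cell
    probabilities times N), or ``fixed_counts`` (expected counts given
    directly).  df defaults to (r-1)(c-1) and may be overridden for
    goodness-of-fit style uses.
    """

    expected: np.ndarray
    source: str
    df: int
    probabilities: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        exp = np.asarray(self.expected, dtype=float)
        if exp.ndim != 2 or exp.shape[0] < 2 or exp.shape[1] < 2:
            raise ValueError("expected must be an r x c matrix with r, c >= 2")
        if (exp < 0).any():
            raise ValueError("expected values must be non-negative")
        if self.source not in ("margins", "probabilities", "fixed_counts"):
            raise ValueError(f"unknown expected-value source {self.source!r}")
        if self.df < 1:
            raise ValueError("df must be a positive integer")
        exp.setflags(write=False)
        object.__setattr__(self, "expected", exp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.expected.shape

    def to_dict(self) -> dict:
        return {
            "expected": self.expected.tolist(),
            "source": self.source,
            "df": self.df,
            "degenerate": self.degenerate,
        }


def make_table(counts) -> ContingencyTable:
    """Build a validated table from any rectangular integer matrix."""
    return ContingencyTable(np.asarray(counts))


def default_df(shape: tuple[int, int]) -> int:
    r, c = shape
    return (r - 1) * (c - 1)


def expected_from_margins(table: ContingencyTable) -> ExpectedModel:
    """Null-model expected values E_ij = row_i * col_j / N.

    A zero row or column total yields zero expected cells along that line
    and a degenerate flag; every statistic on such a model is defined as 0.
    N = 0 raises :class:`DegenerateTableError`.
    """
    if table.grand_total == 0:
        raise DegenerateTableError("cannot fit margins: table total is 0")
    expected = np.outer(table.row_totals, table.col_totals) / table.grand_total
    degenerate = bool((table.row_totals == 0).any() or (table.col_totals == 0).any())
    return ExpectedModel(
        expected=expected,
        source="margins",
        df=default_df(table.shape),
        degenerate=degenerate,
    )


def expected_from_probabilities(
    probs, N: int, df: int | None = None
) -> ExpectedModel:
    """Expected values from an externally specified cell-probability matrix.

    probs must be non-negative and sum to 1 within 1e-9.  df defaults to
    (r-1)(c-1); pass df explicitly for goodness-of-fit uses (k-1).
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] < 2:
        raise ValueError("probabilities must be an r x c matrix with r, c >= 2")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    total = float(p.sum())
    if abs(total - 1.0) > _PROB_SUM_TOL:
        raise ValueError(f"probabilities must sum to 1, got sum = {total}")
    if N < 0:
        raise ValueError("N must be non-negative")
    return ExpectedModel(
        expected=p * N,
        source="probabilities",
        df=default_df(p.shape) if df is None else df,
        probabilities=p,
        degenerate=N == 0,
    )


def expected_from_counts(expected, df: int | None = None) -> ExpectedModel:
    """Expected values given directly as (real-valued) counts."""
    exp = np.asarray(expected, dtype=float)
    return ExpectedModel(
        expected=exp,
        source="fixed_counts",
        df=default_df(exp.shape) if df is None else df,
        degenerate=bool(exp.sum() == 0),
    )


def _read_matrix(path: Union[str, Path], sep: str | None) -> pd.DataFrame:
    """Read a CSV/TSV matrix, auto-detecting a header row and label column."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if raw.empty:
        raise ValueError(f"{path}: empty file")

    def numeric(s):
        return pd.to_numeric(s, errors="coerce")

    # Header row present when the first row fails to parse as numbers.
    has_header = numeric(raw.iloc[0]).isna().any()
    body = raw.iloc[1:] if has_header else raw
    # Label column present when the first column fails to parse.
    first_col = numeric(body.iloc[:, 0])
    has_labels = first_col.isna().any()
    if has_labels:
        body = body.iloc[:, 1:]
    values = body.apply(numeric)
    if values.isna().any().any():
        raise ValueError(f"{path}: non-numeric cell values")
    return values.reset_index(drop=True)


def read_counts_csv(path: Union[str, Path], sep: str | None = None) -> ContingencyTable:
    """Read a count table from CSV/TSV (header/labels auto-detected)."""
    values = _read_matrix(path, sep)
    arr = values.to_numpy(dtype=float)
    if not np.allclose(arr, np.rint(arr), rtol=0, atol=1e-9):
        raise ValueError(f"{path}: count cells must be integers")
    return make_table(np.rint(arr).astype(np.int64))


def read_probabilities_csv(
    path: Union[str, Path], N: int, sep: str | None = None, df: int | None = None
) -> ExpectedModel:
    """Read a cell-probability matrix and scale it by N."""
    values = _read_matrix(path, sep)
    return expected_from_probabilities(values.to_numpy(dtype=float), N, df=df)


def write_counts_csv(table: ContingencyTable, path: Union[str, Path]) -> None:
    """Write bare comma-separated counts (no header, no labels)."""
    pd.DataFrame(table.counts).to_csv(path, header=False, index=False)
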