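"""Core test statistics for contingency tables.

Two families of tests on the same observed/expected pair:

* equality of proportions — the support S = sum O*ln(O/E) and its
  chi-squared form, the likelihood-ratio test statistic 2S (the G-test);
* model variance — Pearson's X2 = sum (O-E)^2/E read against the *left*
  tail (small X2 means the data fit the model suspiciously well), and the
  support Svar for the best-fitting variance-inflation factor.

Both conventions 0*ln 0 = 0 and 0/0 = 0 apply throughout, so tables with
empty cells or degenerate margins always yield finite, well-defined
results — except O > 0 against E = 0, which gives infinite support
(the model calls an observed event impossible) and is flagged rather
than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincc, xlogy

from .evidence import EvidenceGrade, grade_support
from .tables import ContingencyTable, ExpectedModel, expected_from_margins

__all__ = [
    "TestResult",
    "SupportResult",
    "ExpansionDiagnostic",
    "chi2_sf",
    "chi2_cdf",
    "pearson_x2",
    "support_s",
    "lrt",
    "closed_form_log_lr",
    "expansion_diagnostic",
    "variance_x2_test",
    "svar",
    "williams_corrected_lrt",
    "signed_root_x",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its reference distribution and tail."""

    name: str
    statistic: float
    df: int
    p_value: float
    tail: str  # "right" or "left"
    degenerate: bool = False
    infinite: bool = False

    def __post_init__(self) -> None:
        if self.tail not in ("right", "left"):
            raise ValueError(f"tail must be 'right' or 'left', got {self.tail!r}")
        if self.tail == "left" and self.name != "variance_x2":
            raise ValueError("left-tail reading is reserved for the variance test")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "tail": self.tail,
            "degenerate": self.degenerate,
            "infinite": self.infinite,
        }


@dataclass(frozen=True)
class SupportResult:
    """A support (log likelihood-ratio) value with its evidence grade.

    kind="proportions": S compares the unrestricted fit to the expected
    model.  kind="variance": S is the support for the best-fitting
    variance-inflation factor v^2 against v^2 = 1; best_v2 then holds the
    best-supported value (the X2 statistic itself, scaled by df).
    """

    S: float
    kind: str  # "proportions" or "variance"
    df: int
    grade: EvidenceGrade = field(compare=False)
    best_v2: float | None = None
    degenerate: bool = False
    infinite: bool = False

    def as_chi2(self) -> TestResult:
        """Express 2S as a chi-squared statistic (right tail)."""
        name = "svar_x2" if self.kind == "variance" else "lrt"
        stat = 2.0 * self.S
        return TestResult(
            name=name,
            statistic=stat,
            df=self.df,
            p_value=chi2_sf(stat, self.df),
            tail="right",
            degenerate=self.degenerate,
            infinite=self.infinite,
        )

    def to_dict(self) -> dict:
        d = {
            "S": self.S,
            "kind": self.kind,
            "df": self.df,
            "grade": self.grade.to_dict(),
            "degenerate": self.degenerate,
            "infinite": self.infinite,
        }
        if self.best_v2 is not None:
            d["best_v2"] = self.best_v2
        return d


@dataclass(frozen=True)
class ExpansionDiagnostic:
    """Per-order terms of the series expansion of S around X2/2.

    terms[m-2] is the summed order-m term; valid is True iff |O-E| < E
    strictly in every cell, the condition for the expansion to converge.
    """

    terms: tuple[float, ...]
    valid: bool
    offending_cells: tuple[tuple[int, int], ...]

    @property
    def partial_sums(self) -> tuple[float, ...]:
        out, acc = [], 0.0
        for t in self.terms:
            acc += t
            out.append(acc)
        return tuple(out)


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail chi-squared probability via the incomplete gamma function."""
    if math.isinf(x):
        return 0.0
    return float(gammaincc(df / 2.0, x / 2.0))


def chi2_cdf(x: float, df: int) -> float:
    """Lower-tail chi-squared probability via the incomplete gamma function."""
    if math.isinf(x):
        return 1.0
    return float(gammainc(df / 2.0, x / 2.0))


def _check_shapes(table: ContingencyTable, expected: ExpectedModel) -> None:
    if table.shape != expected.shape:
        raise ValueError(
            f"observed {table.shape} and expected {expected.shape} shapes differ"
        )


def _x2_statistic(observed: np.ndarray, expected: np.ndarray) -> tuple[float, bool]:
    """Sum of (O-E)^2/E with 0/0 := 0; returns (statistic, hit_infinity)."""
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    impossible = (E == 0) & (O > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(E > 0, (O - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
    if impossible.any():
        return math.inf, True
    return float(terms.sum()), False


def _support_statistic(observed: np.ndarray, expected: np.ndarray) -> tuple[float, bool]:
    """Sum of O*ln(O/E) with 0*ln 0 := 0; returns (S, hit_infinity)."""
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if ((E == 0) & (O > 0)).any():
        return math.inf, True
    return float(np.sum(xlogy(O, O) - xlogy(O, E))), False


def pearson_x2(table: ContingencyTable, expected: ExpectedModel) -> TestResult:
    """Pearson X2 = sum (O-E)^2/E, referred to the right tail by default.

    Note: in this framework the right-tail reading tests the model
    *variance* direction conventionally used for proportions; prefer
    :func:`lrt` for proportions and :func:`variance_x2_test` for variance.
    """
    _check_shapes(table, expected)
    if expected.degenerate:
        return TestResult("pearson_x2", 0.0, expected.df, 1.0, "right", degenerate=True)
    stat, infinite = _x2_statistic(table.counts, expected.expected)
    return TestResult(
        name="pearson_x2",
        statistic=stat,
        df=expected.df,
        p_value=chi2_sf(stat, expected.df),
        tail="right",
        infinite=infinite,
    )


def support_s(table: ContingencyTable, expected: ExpectedModel) -> SupportResult:
    """Support S = sum O*ln(O/E) for the proportions comparison."""
    _check_shapes(table, expected)
    if expected.degenerate:
        return SupportResult(
            S=0.0, kind="proportions", df=expected.df,
            grade=grade_support(0.0), degenerate=True,
        )
    S, infinite = _support_statistic(table.counts, expected.expected)
    return SupportResult(
        S=S, kind="proportions", df=expected.df,
        grade=grade_support(S), infinite=infinite,
    )


def lrt(table: ContingencyTable, expected: ExpectedModel) -> TestResult:
    """Likelihood-ratio (G) test: 2S against the right chi-squared tail."""
    sup = support_s(table, expected)
    stat = 2.0 * sup.S
    return TestResult(
        name="lrt",
        statistic=stat,
        df=expected.df,
        p_value=chi2_sf(stat, expected.df),
        tail="right",
        degenerate=sup.degenerate,
        infinite=sup.infinite,
    )


def closed_form_log_lr(table: ContingencyTable) -> float:
    """ln LR for a 2x2 table from the closed-form product of powers.

    ln LR = a ln a + b ln b + c ln c + d ln d + N ln N
          - sum over the four marginal totals of (margin) ln (margin),
    with 0 ln 0 := 0.  Equals support_s against the margin-fitted expected
    model; kept separate as an internal oracle.
    """
    if table.shape != (2, 2):
        raise ValueError(f"closed form requires a 2x2 table, got {table.shape}")
    cells = table.counts.astype(float).ravel()
    margins = np.concatenate(
        [table.row_totals, table.col_totals]
    ).astype(float)
    N = float(table.grand_total)
    return float(
        np.sum(xlogy(cells, cells)) + xlogy(N, N) - np.sum(xlogy(margins, margins))
    )


def expansion_diagnostic(
    table: ContingencyTable, expected: ExpectedModel, max_order: int = 4
) -> ExpansionDiagnostic:
    """Alternating series terms (O-E)^m / (m(m-1) E^(m-1)), orders 2..max.

    The expansion of S is valid only when |O - E| < E strictly in every
    cell; offending cells are listed.  Cells with E = 0 are offending
    unless O = 0 there too (those contribute nothing).
    """
    if max_order < 2:
        raise ValueError("max_order must be >= 2")
    _check_shapes(table, expected)
    O = table.counts.astype(float)
    E = expected.expected
    diff = O - E
    offending = [
        (int(i), int(j))
        for i, j in np.argwhere(~(np.abs(diff) < E) & ~((O == 0) & (E == 0)))
    ]
    active = E > 0
    terms = []
    for m in range(2, max_order + 1):
        sign = 1.0 if m % 2 == 0 else -1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            cell_terms = np.where(
                active,
                sign * diff**m / (m * (m - 1) * np.where(active, E, 1.0) ** (m - 1)),
                0.0,
            )
        terms.append(float(cell_terms.sum()))
    return ExpansionDiagnostic(
        terms=tuple(terms),
        valid=not offending,
        offending_cells=tuple(offending),
    )


def variance_x2_test(table: ContingencyTable, expected: ExpectedModel) -> TestResult:
    """X2 read against the *left* tail: small p flags too-low variance.

    A small left-tail p means the observed counts match the expected
    values more closely than sampling variation allows ("too good to be
    true").  Observed exactly equal to expected gives X2 = 0, p = 0.
    """
    base = pearson_x2(table, expected)
    return TestResult(
        name="variance_x2",
        statistic=base.statistic,
        df=base.df,
        p_value=chi2_cdf(base.statistic, base.df),
        tail="left",
        degenerate=base.degenerate,
        infinite=base.infinite,
    )


def svar(x2: float, df: int = 1) -> SupportResult:
    """Support for the best-fitting variance inflation against the null.

    Svar = (df/2) ln(df/X2) - (df - X2)/2.  Zero at X2 = df (observed
    variance exactly as expected), infinite at X2 = 0 (perfect fit), and
    positive everywhere else.  2*Svar may be referred to the right
    chi-squared tail via :meth:`SupportResult.as_chi2`.
    """
    if x2 < 0:
        raise ValueError(f"X2 must be non-negative, got {x2}")
    if df < 1:
        raise ValueError("df must be a positive integer")
    if x2 == 0:
        S, infinite = math.inf, True
    else:
        S = (df / 2.0) * math.log(df / x2) - 0.5 * (df - x2)
        infinite = False
    return SupportResult(
        S=S, kind="variance", df=df, grade=grade_support(S),
        best_v2=x2, infinite=infinite,
    )


def williams_corrected_lrt(table: ContingencyTable) -> TestResult:
    """LRT with Williams's small-sample correction (2x2, margin expected).

    The statistic 2S is divided by
    q = 1 + (N/r1 + N/r2 - 1)(N/c1 + N/c2 - 1) / (6N).
    Correction formula sourced from the standard literature; it shrinks
    the statistic and its effect is negligible at moderate N.
    """
    if table.shape != (2, 2):
        raise ValueError("Williams-corrected LRT is defined for 2x2 tables")
    expected = expected_from_margins(table)
    base = lrt(table, expected)
    if base.degenerate:
        return TestResult("lrt_williams", 0.0, base.df, 1.0, "right", degenerate=True)
    N = table.grand_total
    r1, r2 = (float(t) for t in table.row_totals)
    c1, c2 = (float(t) for t in table.col_totals)
    q = 1.0 + (N / r1 + N / r2 - 1.0) * (N / c1 + N / c2 - 1.0) / (6.0 * N)
    stat = base.statistic / q
    return TestResult(
        name="lrt_williams",
        statistic=stat,
        df=base.df,
        p_value=chi2_sf(stat, base.df),
        tail="right",
        infinite=base.infinite,
    )


def signed_root_x(table: ContingencyTable, expected: ExpectedModel) -> float:
    """sign(O11 - E11) * sqrt(X2): the X2 root carrying effect direction.

    Sign convention: positive when the top-left cell exceeds its
    expectation.  Swapping the two rows flips the sign.
    """
    if table.shape != (2, 2):
        raise ValueError("signed root X is defined for 2x2 tables")
    result = pearson_x2(table, expected)
    if result.degenerate:
        return 0.0
    sign = math.copysign(1.0, float(table.counts[0, 0]) - expected.expected[0, 0])
    if table.counts[0, 0] == expected.expected[0, 0]:
        sign = 0.0 if result.statistic == 0 else sign
    return sign * math.sqrt(result.statistic)
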