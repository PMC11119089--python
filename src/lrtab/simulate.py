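"""Fixed-margin statistic scans and Monte Carlo type-I/II error rates.

The scan fixes all four margins of a 2x2 table to the same value m, so
that choosing the top-left cell a forces b = c = m - a and d = a, and
traces the three statistics (LRT 2S, Pearson X2, 2*Svar) as a moves
across its admissible range.

The error-rate simulation uses the product-binomial scheme of randomized
trials: each row total is fixed at n and the first cell of row i is drawn
Binomial(n, p_i).  Rejection uses the critical-value form
statistic > chi2 upper-alpha quantile at 1 df, with expected values
fitted from each draw's margins.  Draws with a zero column margin are
degenerate: both statistics are 0 there, so they count as non-rejections;
the tally is reported for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2 as _chi2

from .tables import ContingencyTable, make_table

__all__ = [
    "ScanResult",
    "SimConfig",
    "ErrorRateResult",
    "scan_fixed_margins",
    "generate_product_binomial_table",
    "monte_carlo_error_rates",
    "error_rate_curve",
]


@dataclass(frozen=True)
class ScanResult:
    """Statistics traced over the admissible top-left cell values."""

    observed_a: np.ndarray
    lrt_stat: np.ndarray
    x2_stat: np.ndarray
    two_svar_stat: np.ndarray
    expected_a: float
    margin: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed_a": self.observed_a,
                "lrt": self.lrt_stat,
                "x2": self.x2_stat,
                "two_svar": self.two_svar_stat,
            }
        )


@dataclass(frozen=True)
class SimConfig:
    """Product-binomial simulation settings."""

    p1: float
    p2: float
    n_per_row: int = 100
    reps: int = 50_000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, p in (("p1", self.p1), ("p2", self.p2)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n_per_row < 1:
            raise ValueError("n_per_row must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "p1": self.p1,
            "p2": self.p2,
            "n_per_row": self.n_per_row,
            "reps": self.reps,
            "alpha": self.alpha,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ErrorRateResult:
    """Rejection rates of both tests under one generating model.

    When p1 == p2 the rejection rate is the type I error rate; when
    p1 != p2 the type II error rate is 1 minus the rejection rate.
    """

    rejection_rate_lrt: float
    rejection_rate_x2: float
    n_degenerate: int
    config: SimConfig

    @property
    def se_lrt(self) -> float:
        r = self.rejection_rate_lrt
        return float(np.sqrt(r * (1.0 - r) / self.config.reps))

    @property
    def se_x2(self) -> float:
        r = self.rejection_rate_x2
        return float(np.sqrt(r * (1.0 - r) / self.config.reps))

    @property
    def type_ii_rate_lrt(self) -> float:
        return 1.0 - self.rejection_rate_lrt

    @property
    def type_ii_rate_x2(self) -> float:
        return 1.0 - self.rejection_rate_x2

    def to_dict(self) -> dict:
        return {
            "rejection_rate_lrt": self.rejection_rate_lrt,
            "rejection_rate_x2": self.rejection_rate_x2,
            "se_lrt": self.se_lrt,
            "se_x2": self.se_x2,
            "n_degenerate": self.n_degenerate,
            "config": self.config.to_dict(),
        }


def scan_fixed_margins(
    margin: int,
    expected_a: float,
    a_range: range | None = None,
) -> ScanResult:
    """Trace LRT, X2 and 2*Svar over a with all four margins fixed.

    With all margins equal to `margin` and N = 2*margin, fixing cell a
    forces b = c = margin - a and d = a; the expected table is completed
    from expected_a the same way.  At a == expected_a the LRT and X2 are
    0 and 2*Svar is infinite.
    """
    if margin < 1:
        raise ValueError("margin must be >= 1")
    if not 0.0 < expected_a < margin:
        raise ValueError(f"expected_a must lie strictly inside (0, {margin})")
    if a_range is None:
        a_range = range(1, margin)
    a = np.asarray(list(a_range), dtype=float)
    if a.size == 0:
        raise ValueError("a_range is empty")
    if (a < 0).any() or (a > margin).any():
        raise ValueError(f"a values must lie in [0, {margin}] to keep cells >= 0")

    e = float(expected_a)
    O = np.stack([a, margin - a, margin - a, a], axis=1)  # a, b, c, d
    E = np.array([e, margin - e, margin - e, e])[None, :]

    x2 = ((O - E) ** 2 / E).sum(axis=1)
    two_s = 2.0 * (xlogy(O, O) - xlogy(O, E)).sum(axis=1)
    with np.errstate(divide="ignore"):
        two_svar = np.where(
            x2 > 0, np.log(1.0 / x2) - (1.0 - x2), np.inf
        )
    return ScanResult(
        observed_a=a.astype(np.int64) if np.allclose(a, np.rint(a)) else a,
        lrt_stat=two_s,
        x2_stat=x2,
        two_svar_stat=two_svar,
        expected_a=e,
        margin=int(margin),
    )


def generate_product_binomial_table(
    config: SimConfig, rng: np.random.Generator
) -> ContingencyTable:
    """Draw one 2x2 table: row i is (k_i, n - k_i), k_i ~ Binomial(n, p_i)."""
    n = config.n_per_row
    k1 = int(rng.binomial(n, config.p1))
    k2 = int(rng.binomial(n, config.p2))
    return make_table([[k1, n - k1], [k2, n - k2]])


def _batch_statistics(
    k1: np.ndarray, k2: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized X2 and 2S with margin-fitted expected for many draws.

    Returns (x2, two_s, degenerate).  Degenerate draws (a zero column
    margin) get statistic 0, matching the scalar-path convention.
    """
    a = k1.astype(float)
    c = k2.astype(float)
    b = n - a
    d = n - c
    N = 2.0 * n
    col1 = a + c
    col2 = b + d
    degenerate = (col1 == 0) | (col2 == 0)

    # E_ij = n * col_j / N = col_j / 2 for both rows (row totals equal n)
    e1 = col1 / 2.0
    e2 = col2 / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = np.where(e1 > 0, (a - e1) ** 2 / e1 + (c - e1) ** 2 / e1, 0.0) + np.where(
            e2 > 0, (b - e2) ** 2 / e2 + (d - e2) ** 2 / e2, 0.0
        )
        two_s = 2.0 * (
            (xlogy(a, a) - xlogy(a, e1))
            + (xlogy(c, c) - xlogy(c, e1))
            + (xlogy(b, b) - xlogy(b, e2))
            + (xlogy(d, d) - xlogy(d, e2))
        )
    x2 = np.where(degenerate, 0.0, x2)
    two_s = np.where(degenerate, 0.0, two_s)
    return x2, two_s, degenerate


def monte_carlo_error_rates(config: SimConfig) -> ErrorRateResult:
    """Rejection rates of LRT and X2 over `reps` product-binomial draws.

    Deterministic given config.seed: the same config reproduces the
    result bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_row
    k1 = rng.binomial(n, config.p1, size=config.reps)
    k2 = rng.binomial(n, config.p2, size=config.reps)
    x2, two_s, degenerate = _batch_statistics(k1, k2, n)
    critical = float(_chi2.isf(config.alpha, df=1))
    return ErrorRateResult(
        rejection_rate_lrt=float(np.mean(two_s > critical)),
        rejection_rate_x2=float(np.mean(x2 > critical)),
        n_degenerate=int(degenerate.sum()),
        config=config,
    )


def error_rate_curve(
    p1_values,
    p2_values,
    n_per_row: int = 100,
    reps: int = 50_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sweep (p1, p2) pairs; independent reproducible substream per point.

    Returns a tidy frame with one row per point (columns: p1, p2, n, reps,
    seed, rate_lrt, rate_x2, se_lrt, se_x2, n_degenerate).
    """
    pairs = list(zip(p1_values, p2_values, strict=True))
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (p1, p2), child in zip(pairs, children):
        cfg = SimConfig(
            p1=p1, p2=p2, n_per_row=n_per_row, reps=reps, alpha=alpha,
            seed=child.entropy if isinstance(child.entropy, int) else None,
        )
        rng = np.random.default_rng(child)
        k1 = rng.binomial(n_per_row, p1, size=reps)
        k2 = rng.binomial(n_per_row, p2, size=reps)
        x2, two_s, degenerate = _batch_statistics(k1, k2, n_per_row)
        critical = float(_chi2.isf(alpha, df=1))
        r_lrt = float(np.mean(two_s > critical))
        r_x2 = float(np.mean(x2 > critical))
        rows.append(
            {
                "p1": p1,
                "p2": p2,
                "n": n_per_row,
                "reps": reps,
                "seed": seed,
                "rate_lrt": r_lrt,
                "rate_x2": r_x2,
                "se_lrt": float(np.sqrt(r_lrt * (1 - r_lrt) / reps)),
                "se_x2": float(np.sqrt(r_x2 * (1 - r_x2) / reps)),
                "n_degenerate": int(degenerate.sum()),
            }
        )
    return pd.DataFrame(rows)
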