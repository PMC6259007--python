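"""Summary-statistic group tests: Welch t, Yates chi-square, variance-ratio F.

These operate on *printed* summaries (means, SDs, counts) rather than raw
data, so published demographic tables can be re-tested without case-level
access.  Conventions: the Welch t statistic is (mean2 - mean1)/SE with
Welch-Satterthwaite degrees of freedom; the 2x2 chi-square applies the
Yates continuity correction; the variance-ratio F places the larger
variance in the numerator and doubles the smaller tail probability.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import ValidationError

__all__ = ["GroupSummary", "TestResult", "welch_t", "chi2_2x2", "variance_ratio_f"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and size of one group, as printed in a summary table."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float


def welch_t(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Welch's unequal-variance t test from group summaries.

    The statistic is (g2.mean - g1.mean)/SE, i.e. positive when the
    second-listed group has the larger mean; swap the arguments to flip the
    sign (the p-value is unchanged).
    """
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    se = np.sqrt(v1 + v2)
    if se == 0:
        return TestResult(0.0, float(g1.n + g2.n - 2), 1.0)
    t = (g2.mean - g1.mean) / se
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)))


def chi2_2x2(a: int, b: int, c: int, d: int, correction: bool = True) -> TestResult:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], with the Yates
    continuity correction by default (|O-E| reduced by 0.5, floored at 0)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.rint(table)):
        raise ValidationError("cell counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("2x2 table has a zero margin")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    dev = np.abs(table - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    p = float(stats.chi2.sf(chi2, 1))
    return TestResult(chi2, 1.0, p)


def variance_ratio_f(sd1: float, n1: int, sd2: float, n2: int) -> TestResult:
    """Two-sided variance-ratio F test from summary SDs.

    F = larger variance / smaller variance, df = (n_larger - 1, n_smaller - 1),
    p = 2 * min(tail probabilities); invariant to group order.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("sds must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValidationError("n must be >= 2")
    v1, v2 = sd1**2, sd2**2
    if v1 >= v2:
        f, dfn, dfd = v1 / v2, n1 - 1, n2 - 1
    else:
        f, dfn, dfd = v2 / v1, n2 - 1, n1 - 1
    if f == 1.0:
        p = 1.0
    else:
        p = 2.0 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
    return TestResult(float(f), (float(dfn), float(dfd)), float(min(p, 1.0)))
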