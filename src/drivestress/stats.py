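"""Summary statistics and the study's group-comparison tests.

Reproduces the arithmetic behind the report tables: M (SD) summaries with the
n-1 sample standard deviation, the equal-variance (pooled) two-sample t-test
with df = n1 + n2 - 2 (a Welch variant is available), and Pearson's
product-moment correlation. p-values are two-sided. Heavy lifting is
delegated to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize",
    "t_test_from_summaries",
    "t_test",
    "pearson",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    #: True when the SD is reported as 0 only because n = 1
    sd_degenerate: bool = False


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: Literal["pooled", "welch"]


def summarize(values: Sequence[float]) -> GroupSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of a value list."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty list")
    if v.size == 1:
        return GroupSummary(n=1, mean=float(v[0]), sd=0.0, sd_degenerate=True)
    return GroupSummary(n=int(v.size), mean=float(v.mean()), sd=float(v.std(ddof=1)))


def t_test_from_summaries(
    g1: GroupSummary, g2: GroupSummary, variant: Literal["pooled", "welch"] = "pooled"
) -> TTestResult:
    """Two-sample t-test computed from group summaries alone.

    Pooled (equal-variance) by default:
    ``t = (m1 - m2) / (sp * sqrt(1/n1 + 1/n2))`` with
    ``sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)``.
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("both groups need n >= 2")
    if g1.sd < 0 or g2.sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if g1.sd == 0 and g2.sd == 0:
        df = g1.n + g2.n - 2
        if g1.mean == g2.mean:
            return TTestResult(t=0.0, df=df, p=1.0, variant=variant)
        t = np.inf if g1.mean > g2.mean else -np.inf
        return TTestResult(t=float(t), df=df, p=0.0, variant=variant)
    t, p = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(g1.n + g2.n - 2)
    else:
        a, b = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (a + b) ** 2 / (a**2 / (g1.n - 1) + b**2 / (g2.n - 1))
    return TTestResult(t=float(t), df=df, p=float(p), variant=variant)


def t_test(
    x: Sequence[float], y: Sequence[float], variant: Literal["pooled", "welch"] = "pooled"
) -> TTestResult:
    """Two-sample t-test on raw value lists (group 1 minus group 2)."""
    return t_test_from_summaries(summarize(x), summarize(y), variant=variant)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired lists must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)
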