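"""Statistical comparisons for partitioning data and screen tallies.

Thin, explicitly specified wrappers around established routines: two-sided
Fisher's exact test on 2x2 tables (probability-mass definition), the
Kruskal-Wallis k-sample rank test with tie correction, the Wilcoxon rank-sum
(Mann-Whitney) test (exact for small tie-free samples, otherwise a
continuity-corrected normal approximation), Wilson or Clopper-Pearson
binomial proportion confidence intervals, and median/quartile summaries.
No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = condition, columns = category vs rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("grand total must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    odds_ratio: float | None = None


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]],
                     alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p-value sums, over all tables with the observed margins,
    the hypergeometric probabilities not exceeding that of the observed table
    (with a 1+1e-7 relative tolerance for floating-point ties).  The reported
    odds ratio is the sample ratio a*d / (b*c); 0/0 is undefined (NaN).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    arr = table.as_array()
    _, p = sps.fisher_exact(arr, alternative=alternative)
    num, den = table.a * table.d, table.b * table.c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    return TestResult(statistic=odds, p_value=float(p),
                      method=f"fisher_exact_{alternative}",
                      n_per_group=(table.a + table.b, table.c + table.d),
                      odds_ratio=odds)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    H uses midranks with tie correction; the p-value comes from the
    chi-square distribution with k-1 degrees of freedom.  When every pooled
    value is identical there is no evidence of any difference: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(groups)
    ns = tuple(len(g) for g in groups)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "kruskal_wallis", ns)
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal_wallis", ns)


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when the smaller sample has at most 8 observations and
    the pooled data are tie-free; otherwise the normal approximation with
    tie-corrected variance and continuity correction.  The method actually
    used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"wilcoxon_ranksum_{method}", (int(x.size), int(y.size)))


def proportion_ci(successes: int, n: int, level: float = 0.95,
                  method: str = "wilson") -> tuple[float, float]:
    """Confidence interval for a binomial proportion.

    Wilson score by default (well-behaved at 0% and 100%, where its relevant
    bound is exactly 0 or 1); ``method="clopper-pearson"`` gives the exact
    beta-quantile interval.  Bounds are clipped to [0, 1].
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError("require 0 <= successes <= n and n >= 1")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method=sm_method)
    lo = 0.0 if np.isnan(lo) else float(lo)  # beta interval at the boundary
    hi = 1.0 if np.isnan(hi) else float(hi)
    return (max(lo, 0.0), min(hi, 1.0))


@dataclass(frozen=True)
class Summary:
    median: float
    q1: float
    q3: float
    n: int


def summarize(values: Sequence[float]) -> Summary:
    """Median and quartiles (linear interpolation) of a sample."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return Summary(float(med), float(q1), float(q3), int(values.size))
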