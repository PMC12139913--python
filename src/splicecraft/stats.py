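"""Exact and chi-square tests used by the enrichment reports.

Conventions, chosen to match how such results are customarily printed:

* the two-sided exact binomial test on an up/down count pair uses p = 0.5
  and sums all outcome probabilities not exceeding the observed one;
* Fisher's exact test reports the sample cross-product odds ratio
  (a*d)/(b*c) — the conditional-MLE estimate is available behind a flag;
* 2x2 chi-square tests apply the Yates continuity correction, r x c tests
  are plain Pearson;
* multiple comparisons are Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class Table2x2:
    """Counts with rows = affected/unaffected, columns = category1/category2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class TestResult:
    method: str
    p: float
    statistic: float | None = None
    df: int | None = None
    odds_ratio: float | None = None
    corrected: bool = False


def binomial_two_sided(k_up: int, k_down: int) -> TestResult:
    """Exact two-sided binomial test of up/down imbalance at p = 0.5."""
    n = k_up + k_down
    if n < 1:
        raise ValueError("need at least one up- or down-regulated count")
    p = float(sps.binomtest(k_up, n, 0.5, alternative="two-sided").pvalue)
    return TestResult(method="binomial_exact", p=p)


def fisher_2x2(t: Table2x2, *, conditional_mle: bool = False) -> TestResult:
    """Two-sided Fisher exact test with the cross-product odds ratio."""
    arr = t.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("odds ratio undefined: table has a zero margin")
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    if conditional_mle:
        odds = float(sps.contingency.odds_ratio(arr, kind="conditional").statistic)
    else:
        num, den = t.a * t.d, t.b * t.c
        odds = float("inf") if den == 0 else num / den
    return TestResult(method="fisher_exact", p=float(p), odds_ratio=odds)


def chi2_2x2_yates(t: Table2x2) -> TestResult:
    """Yates-corrected chi-square on a 2x2 table (df = 1)."""
    arr = t.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: table has a zero margin")
    res = sps.chi2_contingency(arr, correction=True)
    return TestResult(
        method="chi2_yates", p=float(res.pvalue), statistic=float(res.statistic),
        df=1, corrected=True,
    )


def chi2_rxc(table) -> TestResult:
    """Plain Pearson chi-square on an r x c table, df = (r-1)(c-1)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    expected = sps.contingency.expected_freq(arr)
    zeros = np.argwhere(expected == 0)
    if len(zeros):
        r, c = zeros[0]
        raise ValueError(f"expected count of 0 in cell ({r}, {c})")
    res = sps.chi2_contingency(arr, correction=False)
    return TestResult(
        method="chi2_pearson", p=float(res.pvalue), statistic=float(res.statistic),
        df=int(res.dof),
    )


def bonferroni(pvalues, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p * m) elementwise."""
    pvals = list(pvalues)
    if m is None:
        m = len(pvals)
    if m < len(pvals):
        raise ValueError("m must be at least the number of p-values")
    return [min(1.0, p * m) for p in pvals]
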