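"""Univariate statistical toolkit with an adaptive two-group test policy.

The two-group policy is: Student's t (pooled variance) when both samples look
normal (Shapiro-Wilk) *and* variances look equal (F-test); otherwise the
Mann-Whitney U test. Heteroscedastic-but-normal data therefore go to the rank
test, not to Welch's t; a ``force=`` argument overrides the policy when a fixed
branch is wanted. Every result records which test actually ran, so adaptive
analyses stay auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "auto_two_sample_test",
    "anova_tukey",
    "chi_square_test",
    "correlate",
]


@dataclass
class TestResult:
    """Outcome of a single statistical test."""

    statistic: float
    p_value: float
    test_used: str  # student_t | mann_whitney_u | anova_f | tukey_hsd | chi_square | pearson | spearman
    df: Optional[float] = None
    n: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and np.isnan(arr).any():
        arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError(f"sample {name!r} is empty after removing missing values")
    return arr


def _looks_normal(x: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk screen; constant samples are never 'normal'."""
    if np.ptp(x) == 0.0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sps.shapiro(x).pvalue
    return bool(p > alpha)


def _variances_equal(x: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0.0 or vy == 0.0:
        return False
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    p = 2.0 * min(sps.f.cdf(f, dfx, dfy), sps.f.sf(f, dfx, dfy))
    return bool(min(p, 1.0) > alpha)


def auto_two_sample_test(
    x: Sequence[float],
    y: Sequence[float],
    alpha_assumptions: float = 0.05,
    force: Optional[str] = None,
) -> TestResult:
    """Compare two independent samples with the adaptive t / Mann-Whitney policy.

    Parameters
    ----------
    x, y : array-like
        Samples (missing values dropped); each needs n >= 3.
    alpha_assumptions : float
        Level for the Shapiro-Wilk normality and F variance-equality screens.
    force : {None, "student_t", "mann_whitney_u"}
        Bypass the adaptive policy and run the named branch.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if len(xa) < 3 or len(ya) < 3:
        raise ValueError(f"need n >= 3 per sample, got {len(xa)} and {len(ya)}")
    if force not in (None, "student_t", "mann_whitney_u"):
        raise ValueError(f"unknown force={force!r}")

    if force == "student_t":
        use_t = True
    elif force == "mann_whitney_u":
        use_t = False
    else:
        use_t = (
            _looks_normal(xa, alpha_assumptions)
            and _looks_normal(ya, alpha_assumptions)
            and _variances_equal(xa, ya, alpha_assumptions)
        )

    if use_t:
        res = sps.ttest_ind(xa, ya, equal_var=True)
        df = len(xa) + len(ya) - 2
        return TestResult(float(res.statistic), float(res.pvalue), "student_t", df=df,
                          n=len(xa) + len(ya))
    # exact for small untied samples, tie-corrected normal approximation otherwise
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), "mann_whitney_u",
                      n=len(xa) + len(ya))


def anova_tukey(groups: Sequence[Sequence[float]]) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA omnibus test plus Tukey HSD adjusted pairwise comparisons."""
    arrays = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 3:
        raise ValueError(f"need >= 3 groups, got {len(arrays)}")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has n={len(g)} < 2")
    n_total = sum(len(g) for g in arrays)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_res = sps.f_oneway(*arrays)
    fstat = float(f_res.statistic)
    pval = float(f_res.pvalue)
    if np.isnan(fstat):  # zero between-group variance and zero within
        fstat, pval = 0.0, 1.0
    omnibus = TestResult(fstat, pval, "anova_f",
                         df=(len(arrays) - 1, n_total - len(arrays)), n=n_total)

    tk = sps.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            pairwise.append(
                TestResult(
                    float(tk.statistic[i, j]),
                    float(min(tk.pvalue[i, j], 1.0)),
                    "tukey_hsd",
                    n=len(arrays[i]) + len(arrays[j]),
                    extra={"pair": (i, j)},
                )
            )
    return omnibus, pairwise


def chi_square_test(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction (matching the usual convention for r x c tables
    larger than 2 x 2 and for reported cohort-characteristic comparisons).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError(f"need an r x c table with r, c >= 2, got shape {tab.shape}")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal (empty row or column)")
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
    return TestResult(float(chi2), float(p), "chi_square", df=int(df), n=int(tab.sum()))


def correlate(x: Sequence[float], y: Sequence[float], method: str = "auto",
              alpha_assumptions: float = 0.05) -> TestResult:
    """Pearson or Spearman correlation with two-sided p value.

    ``method="auto"`` uses Pearson only when both variables pass the
    Shapiro-Wilk screen, Spearman otherwise. Pairs with a missing value on
    either side are dropped.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if len(xa) != len(ya):
        raise ValueError(f"length mismatch: {len(xa)} vs {len(ya)}")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 4:
        raise ValueError(f"need n >= 4 complete pairs, got {len(xa)}")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        return TestResult(np.nan, np.nan, "pearson" if method == "pearson" else "spearman",
                          n=len(xa), extra={"constant_input": True})
    if method == "auto":
        method = ("pearson"
                  if _looks_normal(xa, alpha_assumptions) and _looks_normal(ya, alpha_assumptions)
                  else "spearman")
    if method == "pearson":
        r, p = sps.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = sps.spearmanr(xa, ya)
    else:
        raise ValueError(f"unknown method={method!r}")
    return TestResult(float(r), float(min(p, 1.0)), method, n=len(xa))
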