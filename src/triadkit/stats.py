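"""Shared statistical primitives.

Every downstream stage calls these rather than scipy/statsmodels directly, so
the test conventions (two-sided tests, Benjamini-Hochberg FDR, exact
small-sample Mann-Whitney) are fixed in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.formula.api import ols as _smf_ols
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "OLSResult",
    "fisher_exact_2x2",
    "bh_adjust",
    "mann_whitney",
    "ols_fit",
    "anova_two_factor",
    "tukey_contrasts",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    pvalue: float
    method: str
    alternative: str = "two-sided"
    p_adjusted: Optional[float] = None


@dataclass
class OLSResult:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float
    n: int


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The two-sided p-value sums the hypergeometric point probabilities of all
    tables (with the observed margins) at most as probable as the observed one.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table cells must be integers")
    odds, p = scipy.stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return TestResult(statistic=float(odds), pvalue=float(p), method="fisher_exact")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the input order. Order-preserving in ranks
    and never smaller than the raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for the first sample (ties count one half)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all labelings of the pooled sample.

    Handles ties (the enumeration is over value assignments, not ranks).
    Two-sidedness: tables with |U - n1*n2/2| at least as large as observed.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    obs = abs(_u_statistic(x, y) - mu)
    total = 0
    extreme = 0
    idx = np.arange(len(pooled))
    for chosen in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(chosen)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= obs - 1e-12:
            extreme += 1
    return extreme / total


def mann_whitney(x, y, exact_threshold: int = 8) -> TestResult:
    """Two-sided Mann-Whitney test.

    Exact p by full enumeration when the combined sample size is at most
    `exact_threshold`; otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must contain at least one observation")
    u = _u_statistic(x, y)
    if x.size + y.size <= exact_threshold:
        p = _exact_mann_whitney_p(x, y)
        method = "mann_whitney_exact"
    else:
        _, p = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "mann_whitney_normal"
    return TestResult(statistic=u, pvalue=float(min(p, 1.0)), method=method)


def ols_fit(x, y) -> OLSResult:
    """Ordinary least squares of y on x with a two-sided slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.var(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = scipy.stats.linregress(x, y)
    return OLSResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pvalue=float(res.pvalue),
        n=int(x.size),
    )


def anova_two_factor(data: pd.DataFrame, response: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Fixed-effects two-factor ANOVA (type II) on a long-format frame.

    Returns the ANOVA table with F statistics and p-values per factor.
    Raises on empty factor cells.
    """
    counts = data.groupby([factor_a, factor_b], observed=True).size().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        empty = counts.stack(future_stack=True)
        empty = empty[empty.isna() | (empty == 0)].index.tolist()
        raise ValueError(f"empty design cell(s): {empty}")
    model = _smf_ols(f"{response} ~ C({factor_a}) + C({factor_b})", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)


def tukey_contrasts(
    data: pd.DataFrame,
    response: str,
    group_col: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons across the levels of one grouping column."""
    res = pairwise_tukeyhsd(data[response].to_numpy(), data[group_col].to_numpy(), alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    frame["p-adj"] = frame["p-adj"].astype(float)
    frame["meandiff"] = frame["meandiff"].astype(float)
    return frame
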