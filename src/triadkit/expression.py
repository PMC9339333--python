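"""Homoeolog expression divergence and coexpression within triads.

All statistics operate on replicate-mean tpm profiles over tissues.  Triad
expression is normalised per tissue to sum to 1 across the three homoeologs
(so divergence is measured on relative, not absolute, expression), divergence
is the standard deviation of the three fractions, and coexpression is the
pairwise Pearson correlation of homoeolog tissue profiles aggregated through
the Fisher z-transform.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import TestResult, fisher_exact_2x2, mann_whitney

__all__ = [
    "replicate_means",
    "filter_expressed_triads",
    "triad_divergence_sd",
    "triad_fraction_sd",
    "compare_divergence",
    "pairwise_homoeolog_correlation",
    "pairwise_correlations",
    "median_correlation",
    "module_comembership",
]


def replicate_means(expr: pd.DataFrame, sample_tissues: Mapping[str, str]) -> pd.DataFrame:
    """Average replicate columns, returning a genes x tissues matrix."""
    tissues = pd.Series({c: sample_tissues[c] for c in expr.columns})
    return expr.T.groupby(tissues).mean().T


def filter_expressed_triads(
    tissue_means: pd.DataFrame,
    triads: pd.DataFrame,
    threshold: float = 0.5,
    require_all_expressed: bool = False,
) -> pd.DataFrame:
    """Keep triads with evidence of expression.

    A triad is kept when at least one homoeolog exceeds ``threshold`` tpm
    (replicate mean) in at least one tissue.  With ``require_all_expressed``
    every homoeolog must additionally have tpm > 0 in at least one tissue
    (the filter used before correlation analyses).  Triads with a member
    missing from the matrix are dropped with a warning.
    """
    member_cols = ["gene_a", "gene_b", "gene_d"]
    present = triads[member_cols].isin(tissue_means.index).all(axis=1)
    if (~present).any():
        warnings.warn(f"dropping {int((~present).sum())} triads with members absent from the matrix")
    triads = triads[present]
    if len(triads) == 0:
        return triads

    a = tissue_means.loc[triads["gene_a"]].to_numpy()
    b = tissue_means.loc[triads["gene_b"]].to_numpy()
    d = tissue_means.loc[triads["gene_d"]].to_numpy()
    any_over = (a > threshold).any(axis=1) | (b > threshold).any(axis=1) | (d > threshold).any(axis=1)
    keep = any_over
    if require_all_expressed:
        keep = keep & (a > 0).any(axis=1) & (b > 0).any(axis=1) & (d > 0).any(axis=1)
    return triads[keep].reset_index(drop=True)


def triad_divergence_sd(fractions: Sequence[Sequence[float]]) -> np.ndarray:
    """Per-tissue standard deviation of the three homoeolog fractions.

    ``fractions`` is a (3, n_tissues) array of per-tissue normalised
    homoeolog fractions; tissues where the fractions are undefined (NaN,
    from zero triad expression) yield NaN. Sample SD, divisor n-1 = 2.
    """
    arr = np.asarray(fractions, dtype=float)
    if arr.shape[0] != 3:
        raise ValueError("expected fractions for exactly three homoeologs")
    return np.std(arr, axis=0, ddof=1)


def triad_fractions(tissue_means: pd.DataFrame, triads: pd.DataFrame) -> np.ndarray:
    """Per-tissue homoeolog fractions, shape (3, n_triads, n_tissues).

    Each triad's expression is normalised per tissue to sum to 1 across the
    A, B and D homoeologs; tissues with zero triad expression are NaN.
    """
    a = tissue_means.loc[triads["gene_a"]].to_numpy()
    b = tissue_means.loc[triads["gene_b"]].to_numpy()
    d = tissue_means.loc[triads["gene_d"]].to_numpy()
    total = a + b + d
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.stack([a / total, b / total, d / total])
    frac[:, total == 0] = np.nan
    return frac


def triad_fraction_sd(tissue_means: pd.DataFrame, triads: pd.DataFrame) -> pd.DataFrame:
    """Normalised-fraction divergence SD for every triad and tissue.

    The value is the sample SD (ddof=1) of the three per-tissue fractions;
    tissues where the triad total is zero are NaN (fractions undefined).
    """
    frac = triad_fractions(tissue_means, triads)
    sd = np.std(frac, axis=0, ddof=1)
    return pd.DataFrame(sd, index=triads["group_id"].to_numpy(), columns=tissue_means.columns)


def compare_divergence(
    tf_sd: pd.DataFrame, nontf_sd: pd.DataFrame, exact_threshold: int = 8
) -> pd.DataFrame:
    """Per-tissue Mann-Whitney comparison of TF vs non-TF divergence SDs."""
    rows = []
    for tissue in tf_sd.columns:
        x = tf_sd[tissue].dropna().to_numpy()
        y = nontf_sd[tissue].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"tissue {tissue}: fewer than 2 observations in a group; skipped")
            continue
        res = mann_whitney(x, y, exact_threshold=exact_threshold)
        rows.append(
            {
                "tissue": tissue,
                "median_tf": float(np.median(x)),
                "median_nontf": float(np.median(y)),
                "n_tf": len(x),
                "n_nontf": len(y),
                "U": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    return pd.DataFrame(rows, columns=["tissue", "median_tf", "median_nontf", "n_tf", "n_nontf", "U", "pvalue"])


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    du = u - u.mean()
    dv = v - v.mean()
    den = np.sqrt((du**2).sum() * (dv**2).sum())
    if den == 0:
        return float("nan")
    return float((du * dv).sum() / den)


def pairwise_homoeolog_correlation(
    tissue_means: pd.DataFrame, gene_a: str, gene_b: str, gene_d: str
) -> Tuple[float, float, float]:
    """Pearson r between homoeolog tissue profiles: (A-B, B-D, A-D).

    Profiles are replicate-mean tpm across tissues; a homoeolog with zero
    variance yields NaN for its pairs.
    """
    if tissue_means.shape[1] < 3:
        raise ValueError("need at least 3 tissues for a correlation")
    a = tissue_means.loc[gene_a].to_numpy(dtype=float)
    b = tissue_means.loc[gene_b].to_numpy(dtype=float)
    d = tissue_means.loc[gene_d].to_numpy(dtype=float)
    return _pearson(a, b), _pearson(b, d), _pearson(a, d)


def pairwise_correlations(tissue_means: pd.DataFrame, triads: pd.DataFrame) -> pd.DataFrame:
    """Pairwise homoeolog correlations for every triad (vectorised)."""
    a = tissue_means.loc[triads["gene_a"]].to_numpy(dtype=float)
    b = tissue_means.loc[triads["gene_b"]].to_numpy(dtype=float)
    d = tissue_means.loc[triads["gene_d"]].to_numpy(dtype=float)

    def rowcorr(u, v):
        du = u - u.mean(axis=1, keepdims=True)
        dv = v - v.mean(axis=1, keepdims=True)
        den = np.sqrt((du**2).sum(axis=1) * (dv**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (du * dv).sum(axis=1) / den
        r[den == 0] = np.nan
        return r

    return pd.DataFrame(
        {
            "r_ab": rowcorr(a, b),
            "r_bd": rowcorr(b, d),
            "r_ad": rowcorr(a, d),
        },
        index=triads["group_id"].to_numpy(),
    )


def median_correlation(r_values: Sequence[float], clip: float = 1e-12) -> float:
    """Median of Pearson r values through the Fisher z-transform.

    Values are z-transformed (atanh), the median taken, then back-transformed
    with tanh; |r| = 1 is clipped just inside the open interval so atanh is
    finite. NaN entries are ignored.
    """
    r = np.asarray(r_values, dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("no correlation values given")
    if (np.abs(r) > 1).any():
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -1 + clip, 1 - clip))
    return float(np.tanh(np.median(z)))


def module_comembership(
    triads: pd.DataFrame, modules: pd.Series
) -> Tuple[float, int, int]:
    """Fraction of triads whose homoeologs share a coexpression module.

    Only triads with all three members assigned a module other than 0 enter
    the denominator (module 0 collects invariant genes; genes missing from
    the table count as unassigned). Returns (percent, co-member count,
    eligible count); percent is NaN with an empty denominator.
    """
    m_a = triads["gene_a"].map(modules)
    m_b = triads["gene_b"].map(modules)
    m_d = triads["gene_d"].map(modules)
    eligible = m_a.notna() & m_b.notna() & m_d.notna() & (m_a != 0) & (m_b != 0) & (m_d != 0)
    n_eligible = int(eligible.sum())
    same = eligible & (m_a == m_b) & (m_b == m_d)
    n_same = int(same.sum())
    pct = 100.0 * n_same / n_eligible if n_eligible else float("nan")
    return pct, n_same, n_eligible
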