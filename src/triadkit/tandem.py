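"""Tandem duplication detection from gene-order adjacency.

Tandem duplicates are members of the same TF family lying within a small
window of each other in the gene order of one chromosome, measured on the
gene-identifier ordinal scale (identifiers step by 100 between adjacent
genes, i.e. by 1 ordinal unit). Linkage is chained: if A-B and B-C are each
within the window, {A, B, C} is one cluster even when A-C is not, and a
cluster of n genes counts as n - 1 duplication events.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .stats import OLSResult, ols_fit

__all__ = [
    "detect_tandem_events",
    "pct_tandem_per_family",
    "family_median_expression",
    "fit_retention_regression",
]


def detect_tandem_events(genes: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Find tandem duplication events within each TF family.

    Parameters
    ----------
    genes
        Gene table with columns gene_id, tf_family, chromosome and ordinal.
        Rows without a family are ignored (tandem duplication is defined
        within TF families).
    window
        Maximum ordinal gap (in genes) between linked duplicates: 1 allows
        no intervening gene, 2 one, 3 two.

    Returns
    -------
    One row per event (a linked consecutive pair within a cluster) with
    columns family, chromosome, ordinal_1, ordinal_2, gene_1, gene_2 and
    gap (count of intervening gene positions).
    """
    if window not in (1, 2, 3):
        raise ValueError("window must be 1, 2 or 3 genes")
    tf = genes[genes["tf_family"].notna() & (genes["tf_family"] != "")]
    rows = []
    for (family, chrom), sub in tf.groupby(["tf_family", "chromosome"]):
        sub = sub.sort_values("ordinal")
        ords = sub["ordinal"].to_numpy(dtype=float)
        if len(np.unique(ords)) != len(ords):
            raise ValueError(f"duplicate ordinals on chromosome {chrom} in family {family}")
        ids = sub["gene_id"].to_numpy()
        for i in range(len(ords) - 1):
            gap = ords[i + 1] - ords[i]
            if gap <= window + 1e-9:
                rows.append(
                    {
                        "family": family,
                        "chromosome": chrom,
                        "gene_1": ids[i],
                        "gene_2": ids[i + 1],
                        "ordinal_1": ords[i],
                        "ordinal_2": ords[i + 1],
                        "gap": max(0, int(math.ceil(gap - 1e-9)) - 1),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["family", "chromosome", "gene_1", "gene_2", "ordinal_1", "ordinal_2", "gap"],
    )


def pct_tandem_per_family(events: pd.DataFrame, family_gene_counts: Mapping[str, int]) -> pd.Series:
    """Tandem duplication events per 100 genes of each family.

    The event total for a family is divided by its gene count; families in
    ``family_gene_counts`` with no events score 0.
    """
    counts = pd.Series(family_gene_counts, dtype=float)
    if (counts <= 0).any():
        raise ValueError("family gene counts must be positive")
    ev = events.groupby("family").size() if len(events) else pd.Series(dtype=int)
    ev = ev.reindex(counts.index, fill_value=0)
    return 100.0 * ev / counts


def family_median_expression(
    genes: pd.DataFrame, tissue_means: pd.DataFrame
) -> pd.Series:
    """Median expression level per TF family.

    The mean tpm of each gene across tissues is computed first, then the
    median of those per-gene means within each family (midpoint
    interpolation at even counts).
    """
    tf = genes[genes["tf_family"].notna() & (genes["tf_family"] != "")]
    per_gene = tissue_means.mean(axis=1)
    fam = tf.set_index("gene_id")["tf_family"]
    common = fam.index.intersection(per_gene.index)
    return per_gene.loc[common].groupby(fam.loc[common]).median()


def fit_retention_regression(
    x: pd.Series,
    y: pd.Series,
    log_transform_x: bool = False,
) -> OLSResult:
    """Regress per-family triad retention on a per-family predictor.

    ``x`` and ``y`` are aligned on their family index. With
    ``log_transform_x`` the predictor is log-transformed first (natural log);
    families with non-positive x are dropped with a warning.
    """
    joined = pd.concat({"x": x, "y": y}, axis=1).dropna()
    if log_transform_x:
        bad = joined["x"] <= 0
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} families with non-positive predictor before log"
            )
            joined = joined[~bad]
        joined["x"] = np.log(joined["x"])
    if len(joined) < 3:
        raise ValueError("need at least 3 families for the regression")
    return ols_fit(joined["x"].to_numpy(), joined["y"].to_numpy())
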