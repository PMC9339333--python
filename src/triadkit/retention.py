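"""Homoeolog group classification and retention statistics.

A homoeolog *triad* is a 1:1:1 correspondence of genes across the A, B and D
subgenomes of hexaploid wheat; a *diad* is a 1:1 A:B correspondence in the
tetraploid. Retention statistics ask, per transcription-factor family, what
fraction of the family's genes sit in complete groups, and whether that
fraction is enriched relative to non-TF genes (Fisher's exact test, BH-FDR
across families).

Two input dialects are supported for the raw homoeolog tables:

``biomart_one2one``
    pairwise rows (gene_id, homoeolog_id, homoeology_type); only
    ``ortholog_one2one`` rows are kept and groups are the connected
    components of the surviving pairs.
``zavitan``
    one row per group (group_id, gene_a, gene_b, homoeolog_class); rows
    labelled ``singleton`` or ``hit2homolog`` are removed and the remaining
    1:1 rows are diads.
"""

from __future__ import annotations

import math
import re
import warnings
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact_2x2

__all__ = [
    "UNRESOLVED",
    "NON_TF",
    "parse_ordinal",
    "resolve_family",
    "resolve_group_family",
    "classify_groups",
    "retention_percentages",
    "normalized_retention",
]

#: Sentinel family label for groups whose three members all disagree.
UNRESOLVED = "__unresolved__"

#: Label used for genes without a TF family assignment.
NON_TF = "non-TF"

_TRAILING_INT = re.compile(r"(\d+)$")


def parse_ordinal(gene_id: str) -> float:
    """Positional ordinal of a gene from its identifier.

    Gene identifiers end in a number that increases by 100 between adjacent
    genes on a chromosome, so the ordinal is that number divided by 100
    (tandem duplicates inserted between neighbours carry half-step ordinals).
    """
    m = _TRAILING_INT.search(str(gene_id))
    if m is None:
        raise ValueError(f"gene id {gene_id!r} has no trailing numeric ordinal")
    return int(m.group(1)) / 100.0


def resolve_family(isoforms: Sequence[Tuple[str, float, str]]) -> str:
    """Family of a gene from its isoform annotations.

    When isoforms disagree, the family assigned to the longest isoform wins.
    Ties at equal length are broken by the lexicographically smallest isoform
    id, which makes the result independent of input order.
    """
    if len(isoforms) == 0:
        raise ValueError("gene has no isoforms")
    best = min(isoforms, key=lambda iso: (-float(iso[1]), str(iso[0])))
    return best[2]


def resolve_group_family(member_families: Sequence[str]) -> str:
    """Majority-rule family for a homoeolog group.

    Returns the family shared by at least two members; if all members
    disagree the group is flagged :data:`UNRESOLVED`.
    """
    fams = list(member_families)
    if not fams:
        raise ValueError("no member families given")
    counts = pd.Series(fams).value_counts()
    if counts.iloc[0] >= 2 or len(counts) == 1:
        return counts.index[0]
    return UNRESOLVED


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, a):
        self.parent.setdefault(a, a)
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _classify_members(members: Iterable[str], subgenomes: Mapping[str, str]) -> Tuple[str, dict]:
    subs = {}
    for g in members:
        sub = subgenomes.get(g)
        if sub is None:
            return "other", {}
        if sub in subs:
            return "other", {}
        subs[sub] = g
    key = frozenset(subs)
    n = len(subs)
    if n == 1:
        return "singleton", subs
    if n == 2 and key <= {"A", "B", "D"}:
        return "diad", subs
    if key == {"A", "B", "D"}:
        return "triad", subs
    return "other", subs


def classify_groups(
    table: pd.DataFrame,
    dialect: str,
    subgenomes: Mapping[str, str],
    high_confidence: Optional[set] = None,
) -> Tuple[pd.DataFrame, dict]:
    """Build classified homoeolog groups from a raw correspondence table.

    Parameters
    ----------
    table
        Raw homoeolog table in one of the two dialects (see module docstring).
    dialect
        ``"biomart_one2one"`` or ``"zavitan"``.
    subgenomes
        Mapping gene_id -> subgenome letter.
    high_confidence
        If given, rows touching genes outside this set are removed first
        (hexaploid analyses use only high-confidence gene models).

    Returns
    -------
    (groups, removed)
        ``groups`` has columns group_id, gene_a, gene_b, gene_d (missing
        members empty), members (tuple) and cardinality in
        {singleton, diad, triad, other}; ``removed`` logs row counts dropped
        per reason.
    """
    removed: dict = {}
    if dialect == "biomart_one2one":
        df = table.copy()
        n0 = len(df)
        df = df[df["homoeology_type"] == "ortholog_one2one"]
        removed["not_one2one"] = n0 - len(df)
        if high_confidence is not None:
            n1 = len(df)
            ok = df["gene_id"].isin(high_confidence) & df["homoeolog_id"].isin(high_confidence)
            df = df[ok]
            removed["low_confidence"] = n1 - len(df)
        uf = _UnionFind()
        for a, b in zip(df["gene_id"], df["homoeolog_id"]):
            uf.union(a, b)
        comp: dict = {}
        for g in set(df["gene_id"]) | set(df["homoeolog_id"]):
            comp.setdefault(uf.find(g), []).append(g)
        rows = []
        for i, (_, members) in enumerate(sorted(comp.items(), key=lambda kv: str(kv[0]))):
            card, subs = _classify_members(members, subgenomes)
            rows.append(
                {
                    "group_id": f"G{i:06d}",
                    "gene_a": subs.get("A", ""),
                    "gene_b": subs.get("B", ""),
                    "gene_d": subs.get("D", ""),
                    "members": tuple(sorted(members)),
                    "cardinality": card,
                }
            )
        groups = pd.DataFrame(
            rows, columns=["group_id", "gene_a", "gene_b", "gene_d", "members", "cardinality"]
        )
    elif dialect == "zavitan":
        df = table.copy()
        bad = df["homoeolog_class"].isin(["singleton", "hit2homolog"])
        removed["singleton"] = int((df["homoeolog_class"] == "singleton").sum())
        removed["hit2homolog"] = int((df["homoeolog_class"] == "hit2homolog").sum())
        df = df[~bad]
        removed["kept"] = len(df)
        seen: dict = {}
        for _, row in df.iterrows():
            for g in (row["gene_a"], row["gene_b"]):
                if not g or (isinstance(g, float) and math.isnan(g)):
                    continue
                if g in seen and seen[g] != row["group_id"]:
                    raise ValueError(f"gene {g} appears in two groups")
                seen[g] = row["group_id"]
        rows = []
        for _, row in df.iterrows():
            members = [g for g in (row["gene_a"], row["gene_b"]) if isinstance(g, str) and g]
            card, subs = _classify_members(members, subgenomes)
            rows.append(
                {
                    "group_id": row["group_id"],
                    "gene_a": subs.get("A", ""),
                    "gene_b": subs.get("B", ""),
                    "gene_d": "",
                    "members": tuple(sorted(members)),
                    "cardinality": card,
                }
            )
        groups = pd.DataFrame(
            rows, columns=["group_id", "gene_a", "gene_b", "gene_d", "members", "cardinality"]
        )
    else:
        raise ValueError(f"unknown homoeolog table dialect: {dialect!r}")

    dup = pd.Series([g for m in groups["members"] for g in m])
    dup_counts = dup.value_counts()
    if (dup_counts > 1).any():
        raise ValueError(f"gene {dup_counts.idxmax()} appears in two groups")
    return groups, removed


def retention_percentages(
    genes: pd.DataFrame,
    groups: pd.DataFrame,
    complete_class: str = "triad",
    min_complete_groups: int = 0,
) -> pd.DataFrame:
    """Per-family percentage of genes in complete homoeolog groups.

    Parameters
    ----------
    genes
        Gene table with columns gene_id and tf_family (NaN/empty = non-TF).
    groups
        Classified groups from :func:`classify_groups`.
    complete_class
        ``"triad"`` for the hexaploid, ``"diad"`` for the tetraploid.
    min_complete_groups
        Families with at most this many complete groups are dropped from the
        output (the headline figures use families with more than 10).

    Returns one row per TF family plus an aggregate ``TF`` row and the
    ``non-TF`` row, with Fisher's exact enrichment vs non-TF genes and
    BH-adjusted p-values (adjusted across the individual families).
    """
    genes = genes.copy()
    fam = genes["tf_family"].where(genes["tf_family"].notna() & (genes["tf_family"] != ""), NON_TF)
    genes["family"] = fam

    complete = groups[groups["cardinality"] == complete_class]
    complete_genes = set(g for m in complete["members"] for g in m)
    genes["in_complete"] = genes["gene_id"].isin(complete_genes)

    member_fam = genes.set_index("gene_id")["family"]
    fam_group_counts: dict = {}
    for m in complete["members"]:
        fams = [member_fam.get(g, NON_TF) for g in m]
        gfam = resolve_group_family(fams)
        fam_group_counts[gfam] = fam_group_counts.get(gfam, 0) + 1

    nontf = genes[genes["family"] == NON_TF]
    nontf_in = int(nontf["in_complete"].sum())
    nontf_out = int(len(nontf) - nontf_in)

    rows = []
    for family, sub in genes.groupby("family"):
        if family == NON_TF:
            continue
        if len(sub) == 0:
            warnings.warn(f"family {family} has zero genes; omitted")
            continue
        n_in = int(sub["in_complete"].sum())
        n_out = int(len(sub) - n_in)
        res = fisher_exact_2x2([[n_in, n_out], [nontf_in, nontf_out]])
        rows.append(
            {
                "family": family,
                "n_genes": len(sub),
                "n_in_complete": n_in,
                "pct_in_complete": 100.0 * n_in / len(sub),
                "n_complete_groups": fam_group_counts.get(family, 0),
                "odds_ratio": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "family",
            "n_genes",
            "n_in_complete",
            "pct_in_complete",
            "n_complete_groups",
            "odds_ratio",
            "pvalue",
        ],
    )
    if len(summary):
        summary["p_adjusted"] = bh_adjust(summary["pvalue"].to_numpy())
        summary = summary[summary["n_complete_groups"] > min_complete_groups].reset_index(drop=True)
    else:
        summary["p_adjusted"] = pd.Series(dtype=float)

    tf = genes[genes["family"] != NON_TF]
    tf_in = int(tf["in_complete"].sum())
    aggregate_rows = []
    if len(tf):
        res = fisher_exact_2x2([[tf_in, len(tf) - tf_in], [nontf_in, nontf_out]])
        aggregate_rows.append(
            {
                "family": "TF",
                "n_genes": len(tf),
                "n_in_complete": tf_in,
                "pct_in_complete": 100.0 * tf_in / len(tf),
                "n_complete_groups": sum(
                    v for k, v in fam_group_counts.items() if k != NON_TF
                ),
                "odds_ratio": res.statistic,
                "pvalue": res.pvalue,
                "p_adjusted": np.nan,
            }
        )
    if len(nontf):
        aggregate_rows.append(
            {
                "family": NON_TF,
                "n_genes": len(nontf),
                "n_in_complete": nontf_in,
                "pct_in_complete": 100.0 * nontf_in / len(nontf),
                "n_complete_groups": fam_group_counts.get(NON_TF, 0),
                "odds_ratio": np.nan,
                "pvalue": np.nan,
                "p_adjusted": np.nan,
            }
        )
    return pd.concat([summary, pd.DataFrame(aggregate_rows)], ignore_index=True)


def normalized_retention(pct_triads_hexaploid: float, pct_diads_tetraploid: float) -> float:
    """Triad retention adjusted for gene loss that pre-dates hexaploidy.

    ``100 * pct_triads / pct_diads``, both arguments on the percent scale:
    a family with 60% of genes in hexaploid triads but only 80% in tetraploid
    diads formed 75% of the triads it still could.  Returns NaN when the diad
    percentage is zero (undefined).
    """
    if pct_diads_tetraploid <= 0:
        return float("nan")
    return 100.0 * float(pct_triads_hexaploid) / float(pct_diads_tetraploid)
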