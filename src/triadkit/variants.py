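"""SNP filtering, effect classification, nucleotide diversity and mutation load.

The variant table is a pandas DataFrame with one row per SNP and a parallel
genotype matrix (``int8``, sites x individuals, alt-allele dosage 0/1/2 with
-1 for missing calls). Effect categories follow SIFT semantics: a missense
change with SIFT score <= 0.05 is deleterious, > 0.05 tolerated.

Mutation load for an individual is its count of homozygous-alternate calls
in a category divided by the summed canonical transcript length (kb) of the
gene group (TF or non-TF) — group totals, not per-gene lengths.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .stats import anova_two_factor, tukey_contrasts

__all__ = [
    "CONSEQUENCES",
    "CATEGORIES",
    "filter_snps",
    "classify_effect",
    "classify_effects",
    "site_pi",
    "site_pi_all",
    "mutation_load",
    "flag_extreme_individuals",
    "family_snp_proportions",
    "compare_loads",
]

CONSEQUENCES = ("stop_gained", "missense", "synonymous", "splice_region", "other")
CATEGORIES = ("stop_gained", "deleterious_missense", "tolerated_missense", "synonymous")

REGION_FLAGS = ("flag_adaptation", "flag_improvement", "flag_sweep", "flag_introgression")


def _missing_fraction(genotypes: np.ndarray) -> np.ndarray:
    if genotypes.size == 0:
        return np.zeros(genotypes.shape[0])
    return (genotypes < 0).mean(axis=1)


def _maf(genotypes: np.ndarray) -> np.ndarray:
    """Minor allele frequency over non-missing alleles at each site."""
    gt = genotypes.astype(float)
    obs = gt >= 0
    alt = np.where(obs, gt, 0.0).sum(axis=1)
    n_alleles = 2.0 * obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = alt / n_alleles
    f = np.where(n_alleles == 0, np.nan, f)
    return np.minimum(f, 1.0 - f)


def filter_snps(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    expressed_genes: Set[str],
    max_missing: float = 0.25,
    min_maf: float = 0.01,
) -> Tuple[pd.DataFrame, np.ndarray, "OrderedDict[str, int]"]:
    """Apply the SNP filter cascade, logging the count surviving each stage.

    Stages, in order: canonical-CDS consequences only; drop splice-region
    co-annotations; drop missense without a SIFT score; drop sites with
    more than ``max_missing`` missing calls (exactly 25% is retained); keep
    minor allele frequency >= ``min_maf``; keep genes expressed above the
    tpm cutoff; drop sites inside any excluded region (adaptation,
    improvement, sweep or introgression); drop synonymous sites with more
    than one annotation.
    """
    unknown = set(variants["consequence"]) - set(CONSEQUENCES)
    if unknown:
        raise ValueError(f"unknown consequence value(s): {sorted(unknown)}")
    if len(variants) != genotypes.shape[0]:
        raise ValueError("variant table and genotype matrix are misaligned")

    stages: "OrderedDict[str, int]" = OrderedDict()
    mask = np.ones(len(variants), dtype=bool)
    stages["input"] = int(mask.sum())

    v = variants.reset_index(drop=True)
    mask &= v["in_canonical_cds"].to_numpy(dtype=bool)
    mask &= v["consequence"].isin(["stop_gained", "missense", "synonymous"]).to_numpy()
    stages["canonical_cds"] = int(mask.sum())

    mask &= ~v["splice_region"].to_numpy(dtype=bool)
    stages["no_splice_region"] = int(mask.sum())

    missense_no_sift = (v["consequence"] == "missense").to_numpy() & v["sift"].isna().to_numpy()
    mask &= ~missense_no_sift
    stages["missense_has_sift"] = int(mask.sum())

    mask &= _missing_fraction(genotypes) <= max_missing + 1e-12
    stages["missingness"] = int(mask.sum())

    maf = _maf(genotypes)
    mask &= ~np.isnan(maf) & (maf >= min_maf - 1e-12)
    stages["maf"] = int(mask.sum())

    mask &= v["gene_id"].isin(expressed_genes).to_numpy()
    stages["expressed_gene"] = int(mask.sum())

    flagged = np.zeros(len(v), dtype=bool)
    for col in REGION_FLAGS:
        if col in v.columns:
            flagged |= v[col].to_numpy(dtype=bool)
    mask &= ~flagged
    stages["region_exclusion"] = int(mask.sum())

    multi_syn = (v["consequence"] == "synonymous").to_numpy() & (
        v["n_annotations"].to_numpy() > 1
    )
    mask &= ~multi_syn
    stages["single_annotation_synonymous"] = int(mask.sum())

    return v[mask].reset_index(drop=True), genotypes[mask], stages


def classify_effect(consequence: str, sift: Optional[float] = None, sift_cutoff: float = 0.05) -> str:
    """Effect category of a filtered SNP.

    stop_gained takes precedence over any SIFT annotation; missense splits
    on SIFT <= cutoff (deleterious) vs > cutoff (tolerated).
    """
    if consequence == "stop_gained":
        return "stop_gained"
    if consequence == "synonymous":
        return "synonymous"
    if consequence == "missense":
        if sift is None or (isinstance(sift, float) and np.isnan(sift)):
            raise ValueError("missense SNP without SIFT score reached classification")
        return "deleterious_missense" if sift <= sift_cutoff else "tolerated_missense"
    raise ValueError(f"cannot classify consequence {consequence!r}")


def classify_effects(variants: pd.DataFrame, sift_cutoff: float = 0.05) -> pd.Series:
    """Vectorised :func:`classify_effect` over a filtered variant table."""
    return pd.Series(
        [
            classify_effect(c, s, sift_cutoff)
            for c, s in zip(variants["consequence"], variants["sift"])
        ],
        index=variants.index,
        name="category",
    )


def site_pi(genotypes: Sequence[int]) -> float:
    """Per-site nucleotide diversity from diploid alt-dosage genotypes.

    With n = 2 x (non-missing individuals) alleles of which j are alternate,
    pi = 2 j (n - j) / (n (n - 1)) — the proportion of allele pairs that
    differ. Undefined (NaN) with fewer than two called alleles.
    """
    gt = np.asarray(genotypes)
    obs = gt[gt >= 0]
    n = 2 * obs.size
    if n < 2:
        return float("nan")
    j = int(obs.sum())
    return 2.0 * j * (n - j) / (n * (n - 1))


def site_pi_all(genotypes: np.ndarray) -> np.ndarray:
    """Vectorised :func:`site_pi` over a sites x individuals matrix."""
    obs = genotypes >= 0
    n = 2.0 * obs.sum(axis=1)
    j = np.where(obs, genotypes, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def mutation_load(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    categories: pd.Series,
    groups: pd.Series,
    group_transcript_lengths: Mapping[str, float],
    individuals: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-individual homozygous-alternate mutation load per kb.

    Parameters
    ----------
    variants, genotypes
        Filtered SNPs and the aligned genotype matrix.
    categories
        Effect category per SNP (aligned with ``variants``).
    groups
        Gene group per SNP, ``"TF"`` or ``"non-TF"`` (aligned).
    group_transcript_lengths
        Summed canonical transcript length in nucleotides per group
        (the totals over all the group's genes, not only genes with SNPs).
    individuals
        Optional individual identifiers (defaults to ``ind0000``-style).

    Returns a long table with columns individual, group, category,
    hom_alt_count and load_per_kb.
    """
    n_ind = genotypes.shape[1]
    if individuals is None:
        individuals = [f"ind{i:04d}" for i in range(n_ind)]
    rows = []
    hom = genotypes == 2
    cat_arr = np.asarray(categories)
    grp_arr = np.asarray(groups)
    for group in sorted(set(grp_arr)):
        total_nt = float(group_transcript_lengths[group])
        if total_nt <= 0:
            raise ValueError(f"group {group!r} has zero total transcript length")
        kb = total_nt / 1000.0
        for category in CATEGORIES:
            site_mask = (grp_arr == group) & (cat_arr == category)
            counts = hom[site_mask].sum(axis=0)
            for i in range(n_ind):
                rows.append(
                    {
                        "individual": individuals[i],
                        "group": group,
                        "category": category,
                        "hom_alt_count": int(counts[i]),
                        "load_per_kb": counts[i] / kb,
                    }
                )
    return pd.DataFrame(rows)


def flag_extreme_individuals(load_table: pd.DataFrame, tail: float = 0.025) -> Set[str]:
    """Individuals in either 2.5% tail of any group x category load distribution.

    Tail membership is strict: an individual is flagged when its load lies
    strictly below the ``tail`` quantile or strictly above the ``1 - tail``
    quantile (inclusive empirical quantiles, linear interpolation), in any
    of the distributions.
    """
    flagged: Set[str] = set()
    for (_, _), sub in load_table.groupby(["group", "category"]):
        loads = sub["load_per_kb"].to_numpy()
        lo, hi = np.quantile(loads, [tail, 1.0 - tail])
        out = (loads < lo) | (loads > hi)
        flagged.update(sub["individual"].to_numpy()[out])
    return flagged


def family_snp_proportions(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    categories: pd.Series,
    families: pd.Series,
    family_triad_counts: Mapping[str, int],
    extreme_individuals: Set[str],
    individuals: Optional[Sequence[str]] = None,
    min_triads: int = 10,
    min_snps: int = 5,
) -> pd.DataFrame:
    """Per-family proportions of SNP effect categories.

    SNPs whose alternate allele is carried only by individuals with extreme
    mutation loads are dropped. Families must have more than ``min_triads``
    triads and at least ``min_snps`` surviving SNPs; the non-TF group is
    always reported. Rows are sorted by the combined deleterious-missense
    plus stop-gained share, descending.
    """
    n_ind = genotypes.shape[1]
    if individuals is None:
        individuals = [f"ind{i:04d}" for i in range(n_ind)]
    extreme_mask = np.array([ind in extreme_individuals for ind in individuals])

    carriers = genotypes > 0
    has_nonextreme_carrier = (carriers & ~extreme_mask[None, :]).any(axis=1)
    keep = has_nonextreme_carrier

    fam_arr = np.asarray(families)
    cat_arr = np.asarray(categories)
    rows = []
    for family in sorted(set(fam_arr)):
        mask = keep & (fam_arr == family)
        n = int(mask.sum())
        if family != "non-TF":
            if family_triad_counts.get(family, 0) <= min_triads or n < min_snps:
                continue
        row = {"family": family, "n_snps": n}
        for category in CATEGORIES:
            row[f"prop_{category}"] = (
                float((cat_arr[mask] == category).sum()) / n if n else float("nan")
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["prop_harmful"] = out["prop_deleterious_missense"] + out["prop_stop_gained"]
        out = out.sort_values("prop_harmful", ascending=False).reset_index(drop=True)
    return out


def compare_loads(load_table: pd.DataFrame, alpha: float = 0.05) -> Dict[str, object]:
    """Two-factor comparison of mutation load across groups and categories.

    Fits load ~ category + group (fixed effects), reports the ANOVA table,
    Tukey HSD contrasts of TF vs non-TF within each category, and the
    percent difference 100 x (load_nonTF - load_TF) / load_nonTF per
    category.
    """
    groups = sorted(load_table["group"].unique())
    cats = sorted(load_table["category"].unique())
    if len(groups) < 2 or len(cats) < 2:
        raise ValueError("need at least two groups and two categories")
    anova = anova_two_factor(load_table, "load_per_kb", "category", "group")

    df = load_table.copy()
    df["cell"] = df["group"] + "|" + df["category"]
    tukey = tukey_contrasts(df, "load_per_kb", "cell", alpha=alpha)
    wanted = []
    for cat in cats:
        a, b = f"TF|{cat}", f"non-TF|{cat}"
        hit = tukey[
            ((tukey["group1"] == a) & (tukey["group2"] == b))
            | ((tukey["group1"] == b) & (tukey["group2"] == a))
        ]
        if len(hit):
            wanted.append(hit.assign(category=cat))
    contrasts = pd.concat(wanted, ignore_index=True) if wanted else pd.DataFrame()

    means = df.groupby(["group", "category"], observed=True)["load_per_kb"].mean().unstack()
    pct_diff = 100.0 * (means.loc["non-TF"] - means.loc["TF"]) / means.loc["non-TF"]
    return {"anova": anova, "tukey": contrasts, "percent_difference": pct_diff}
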