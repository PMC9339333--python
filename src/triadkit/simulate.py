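"""Synthetic study generator.

Emulates the inputs of a wheat polyploidy retention study: gene annotation
tables for two diploid progenitors (A and D genomes), the tetraploid (AB)
and the hexaploid (ABD); homoeolog correspondence tables in two dialects;
a tpm expression matrix over tissues with replicates; a coexpression-module
assignment table; and an exome-style SNP cohort with SIFT annotations and
genotypes under Hardy-Weinberg.

Every stochastic decision (group cardinality, tandem insertion, SNP effect,
minor allele frequency, ...) is recorded as ground truth so downstream
estimates can be checked against what was actually generated, and a fixed
seed reproduces every table exactly.

The key structural conventions mirror the real annotation: gene identifiers
end in a number that steps by 100 between adjacent genes on a chromosome, and
tandem duplicates are inserted at half-step (+50) identifiers so gene-order
windows see them as adjacent.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .retention import NON_TF

__all__ = [
    "FamilySpec",
    "SimConfig",
    "SyntheticStudy",
    "simulate_genomes",
    "simulate_expression",
    "simulate_cohort",
    "simulate_modules",
    "simulate_study",
    "latent_correlation",
]


@dataclass(frozen=True)
class FamilySpec:
    """Generating parameters for one TF family.

    share is the family's share of TF genes; diad_prob the probability an
    ancestral group survives as an A:B diad in the tetraploid;
    triad_given_diad the conditional probability the D copy is also retained
    in the hexaploid (so the marginal triad probability is their product);
    tandem_rate the per-gene probability of carrying an adjacent duplicate;
    log_mean / log_sd the natural-log location and tissue-profile spread of
    tpm.
    """

    name: str
    share: float
    diad_prob: float
    triad_given_diad: float
    tandem_rate: float = 0.02
    log_mean: float = 1.2
    log_sd: float = 0.9

    @property
    def triad_prob(self) -> float:
        return self.diad_prob * self.triad_given_diad


def _fam(name, share, diad, triad, tandem=0.02, log_mean=1.2, log_sd=0.9):
    return FamilySpec(name, share, diad, triad / diad, tandem, log_mean, log_sd)


# Defaults follow the study conditions: family retention set from the printed
# per-family diad/triad percentages where available (NAC, B3, MADS-M-type),
# other families at levels that make the TF aggregate ~70.5% triads / 82.5%
# diads; low-retention families get low expression and NAC a high tandem rate.
DEFAULT_FAMILIES: Tuple[FamilySpec, ...] = (
    _fam("AP2/ERF", 0.10, 0.85, 0.75),
    _fam("bHLH", 0.09, 0.85, 0.75),
    _fam("MYB", 0.09, 0.85, 0.75),
    _fam("NAC", 0.08, 0.745, 0.510, tandem=0.06, log_mean=0.3),
    _fam("C2H2", 0.07, 0.85, 0.75),
    _fam("WRKY", 0.06, 0.85, 0.75, log_mean=1.6),
    _fam("bZIP", 0.06, 0.85, 0.75),
    _fam("B3", 0.05, 0.639, 0.387, tandem=0.015, log_mean=-0.3),
    _fam("HB-HD-ZIP", 0.05, 0.85, 0.75),
    _fam("GRAS", 0.04, 0.85, 0.75),
    _fam("MADS-M-type", 0.03, 0.613, 0.385, tandem=0.015, log_mean=-0.5),
    _fam("TF-other", 0.28, 0.85, 0.75),
)


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic study.

    Defaults reproduce the study conditions: 811 cohort individuals, 15
    tissues with 2 replicates, a 5.7% TF genome fraction, TF/non-TF diad and
    triad retention at the observed aggregate levels, and a deleterious
    missense rate in TFs at 0.68x the non-TF rate.
    """

    n_groups: int = 35_000
    tf_fraction: float = 0.057
    families: Tuple[FamilySpec, ...] = DEFAULT_FAMILIES

    nontf_diad_prob: float = 0.692
    nontf_triad_given_diad: float = 0.559 / 0.692
    nontf_tandem_rate: float = 0.01
    nontf_log_mean: float = 1.0
    nontf_log_sd: float = 1.0

    n_tissues: int = 15
    n_replicates: int = 2
    homoeolog_correlation: float = 0.93
    replicate_log_sd: float = 0.05

    n_individuals: int = 811
    snp_rates: Dict[str, float] = field(
        default_factory=lambda: {"synonymous": 1.2, "missense": 1.5, "stop_gained": 0.02}
    )
    sift_deleterious_fraction: float = 0.25
    tf_rate_multipliers: Dict[str, float] = field(
        default_factory=lambda: {
            "deleterious_missense": 0.68,
            "tolerated_missense": 1.057,
            "synonymous": 0.824,
            "stop_gained": 1.0,
        }
    )
    maf_beta: Tuple[float, float] = (0.3, 2.0)
    missing_rate: float = 0.05
    splice_coannotation_rate: float = 0.02
    missense_no_sift_rate: float = 0.02
    multi_annotation_rate: float = 0.02
    noncoding_rate: float = 0.02
    region_flag_rates: Dict[str, float] = field(
        default_factory=lambda: {
            "adaptation": 0.02,
            "improvement": 0.02,
            "sweep": 0.02,
            "introgression": 0.02,
        }
    )

    n_modules: int = 20
    module_same_prob_tf: float = 0.355
    module_same_prob_nontf: float = 0.293
    module_zero_rate: float = 0.10

    isoform_conflict_rate: float = 0.004
    low_confidence_rate: float = 0.0
    transcript_log_mean: float = float(np.log(1200.0))
    transcript_log_sd: float = 0.35
    n_chromosomes: int = 7

    seed: int = 0

    def __post_init__(self):
        probs = {
            "tf_fraction": self.tf_fraction,
            "nontf_diad_prob": self.nontf_diad_prob,
            "nontf_triad_given_diad": self.nontf_triad_given_diad,
            "nontf_tandem_rate": self.nontf_tandem_rate,
            "sift_deleterious_fraction": self.sift_deleterious_fraction,
            "missing_rate": self.missing_rate,
            "splice_coannotation_rate": self.splice_coannotation_rate,
            "missense_no_sift_rate": self.missense_no_sift_rate,
            "multi_annotation_rate": self.multi_annotation_rate,
            "noncoding_rate": self.noncoding_rate,
            "module_same_prob_tf": self.module_same_prob_tf,
            "module_same_prob_nontf": self.module_same_prob_nontf,
            "module_zero_rate": self.module_zero_rate,
            "isoform_conflict_rate": self.isoform_conflict_rate,
            "low_confidence_rate": self.low_confidence_rate,
        }
        for fam in self.families:
            probs[f"families[{fam.name}].share"] = fam.share
            probs[f"families[{fam.name}].diad_prob"] = fam.diad_prob
            probs[f"families[{fam.name}].triad_given_diad"] = fam.triad_given_diad
            probs[f"families[{fam.name}].tandem_rate"] = fam.tandem_rate
        for name, value in probs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name, rate in self.region_flag_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"region_flag_rates[{name}] must lie in [0, 1], got {rate}")
        share_sum = sum(f.share for f in self.families)
        if abs(share_sum - 1.0) > 1e-9:
            raise ValueError(f"family shares must sum to 1, got {share_sum}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if not (-1.0 <= self.homoeolog_correlation <= 1.0):
            raise ValueError("homoeolog_correlation must lie in [-1, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = [dataclasses.asdict(f) for f in self.families]
        return d


@dataclass
class SyntheticStudy:
    """All generated tables plus the ground truth behind them."""

    config: SimConfig
    groups: pd.DataFrame
    gene_tables: Dict[str, pd.DataFrame]
    isoforms: pd.DataFrame
    homoeologs_hexaploid: pd.DataFrame
    homoeologs_tetraploid: pd.DataFrame
    tandem_truth: pd.DataFrame
    expression: Optional[pd.DataFrame] = None
    sample_tissues: Optional[Dict[str, str]] = None
    modules: Optional[pd.Series] = None
    module_truth: Optional[pd.DataFrame] = None
    variants: Optional[pd.DataFrame] = None
    genotypes: Optional[np.ndarray] = None
    individuals: Optional[List[str]] = None


def _stage_rngs(seed: int, n: int = 4):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def latent_correlation(target: float, log_sd: float) -> float:
    """Gaussian-copula correlation that yields `target` on the tpm scale.

    Two homoeolog profiles are lognormal with common log-scale SD sigma;
    their Pearson correlation on the natural scale is
    (exp(rho_z sigma^2) - 1) / (exp(sigma^2) - 1), which this inverts for
    rho_z so the generated tpm correlation hits the target in expectation.
    """
    if log_sd == 0 or target == 1.0:
        return float(target)
    s2 = log_sd**2
    inner = 1.0 + target * np.expm1(s2)
    if inner <= 0:
        raise ValueError(
            f"target correlation {target} unreachable for log_sd={log_sd} (lognormal bound)"
        )
    rho_z = float(np.log(inner) / s2)
    if rho_z > 1.0 + 1e-9:
        raise ValueError(f"target correlation {target} unreachable for log_sd={log_sd}")
    return min(rho_z, 1.0)


def _gene_id(prefix: str, chrom: int, sub: str, number: int) -> str:
    return f"{prefix}{chrom}{sub}G{number:07d}"


def simulate_genomes(config: SimConfig) -> SyntheticStudy:
    """Realise group cardinalities and build gene + homoeolog tables."""
    rng = _stage_rngs(config.seed)[0]
    n = config.n_groups

    is_tf = rng.random(n) < config.tf_fraction
    fam_names = [f.name for f in config.families]
    fam_shares = np.array([f.share for f in config.families])
    fam_idx = rng.choice(len(fam_names), size=n, p=fam_shares / fam_shares.sum())
    family = np.where(is_tf, np.array(fam_names, dtype=object)[fam_idx], NON_TF)

    fam_by_name = {f.name: f for f in config.families}
    diad_p = np.array(
        [fam_by_name[f].diad_prob if f != NON_TF else config.nontf_diad_prob for f in family]
    )
    tri_p = np.array(
        [
            fam_by_name[f].triad_given_diad if f != NON_TF else config.nontf_triad_given_diad
            for f in family
        ]
    )
    is_diad = rng.random(n) < diad_p
    is_triad = is_diad & (rng.random(n) < tri_p)
    singleton_sub = rng.choice(["A", "B"], size=n)

    chrom = rng.integers(1, config.n_chromosomes + 1, size=n)
    groups = pd.DataFrame(
        {
            "group_id": [f"GRP{i:06d}" for i in range(n)],
            "family": family,
            "is_tf": is_tf,
            "chromosome": chrom,
            "tetra_class": np.where(is_diad, "diad", "singleton"),
            "hexa_class": np.where(is_triad, "triad", np.where(is_diad, "pair_AB", "singleton")),
            "singleton_sub": singleton_sub,
        }
    )

    tandem_p = np.array(
        [fam_by_name[f].tandem_rate if f != NON_TF else config.nontf_tandem_rate for f in family]
    )

    def build_table(prefix: str, membership: List[np.ndarray], subs: List[str], with_tandem: bool):
        """membership[i] is a boolean mask of groups carrying subgenome subs[i]."""
        rows: List[dict] = []
        tandem_rows: List[dict] = []
        member_ids: Dict[str, List[Optional[str]]] = {s: [None] * n for s in subs}
        for sub, mask in zip(subs, membership):
            for c in range(1, config.n_chromosomes + 1):
                idx = np.flatnonzero(mask & (chrom == c))
                numbers = (np.arange(len(idx)) + 1) * 100
                dup_draw = rng.random(len(idx)) < (tandem_p[idx] if with_tandem else 0.0)
                lengths = np.round(
                    np.exp(
                        rng.normal(config.transcript_log_mean, config.transcript_log_sd, len(idx))
                    )
                ).astype(int)
                low_conf = rng.random(len(idx)) < config.low_confidence_rate
                for k, gi in enumerate(idx):
                    gid = _gene_id(prefix, c, sub, numbers[k])
                    member_ids[sub][gi] = gid
                    rows.append(
                        {
                            "gene_id": gid,
                            "group_id": groups.loc[gi, "group_id"],
                            "subgenome": sub,
                            "chromosome": f"{c}{sub}",
                            "ordinal": numbers[k] / 100.0,
                            "confidence": "low" if low_conf[k] else "high",
                            "tf_family": family[gi] if family[gi] != NON_TF else "",
                            "transcript_length": int(lengths[k]),
                            "is_tandem_dup": False,
                        }
                    )
                    if dup_draw[k]:
                        did = _gene_id(prefix, c, sub, numbers[k] + 50)
                        dlen = int(
                            round(
                                np.exp(
                                    rng.normal(
                                        config.transcript_log_mean, config.transcript_log_sd
                                    )
                                )
                            )
                        )
                        rows.append(
                            {
                                "gene_id": did,
                                "group_id": "",
                                "subgenome": sub,
                                "chromosome": f"{c}{sub}",
                                "ordinal": (numbers[k] + 50) / 100.0,
                                "confidence": "high",
                                "tf_family": family[gi] if family[gi] != NON_TF else "",
                                "transcript_length": dlen,
                                "is_tandem_dup": True,
                            }
                        )
                        tandem_rows.append(
                            {
                                "table": prefix,
                                "family": family[gi],
                                "chromosome": f"{c}{sub}",
                                "parent_gene": gid,
                                "duplicate_gene": did,
                            }
                        )
        table = pd.DataFrame(rows)
        return table, tandem_rows, member_ids

    all_mask = np.ones(n, dtype=bool)
    tet_a = is_diad | (singleton_sub == "A")
    tet_b = is_diad | (singleton_sub == "B")
    hex_a = is_triad | (is_diad & ~is_triad) | (~is_diad & (singleton_sub == "A"))
    hex_b = is_triad | (is_diad & ~is_triad) | (~is_diad & (singleton_sub == "B"))
    hex_d = is_triad.copy()

    dipA, _, _ = build_table("TuG", [all_mask], ["A"], with_tandem=False)
    dipD, _, _ = build_table("AtG", [all_mask], ["D"], with_tandem=False)
    tet, tet_tandem, tet_members = build_table("TdG", [tet_a, tet_b], ["A", "B"], with_tandem=True)
    hexa, hex_tandem, hex_members = build_table(
        "TaG", [hex_a, hex_b, hex_d], ["A", "B", "D"], with_tandem=True
    )
    tandem_truth = pd.DataFrame(
        tet_tandem + hex_tandem,
        columns=["table", "family", "chromosome", "parent_gene", "duplicate_gene"],
    )

    # hexaploid homoeolog correspondences, Biomart-style pairwise one2one rows
    hex_rows = []
    for gi in range(n):
        members = [
            hex_members[s][gi]
            for s, m in (("A", hex_a), ("B", hex_b), ("D", hex_d))
            if m[gi] and hex_members[s][gi] is not None
        ]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                hex_rows.append(
                    {
                        "gene_id": members[i],
                        "homoeolog_id": members[j],
                        "homoeology_type": "ortholog_one2one",
                    }
                )
    # paralog noise rows (filtered out downstream): tandem duplicates paired
    # with their parent's homoeolog as one2many
    parent_group = hexa[hexa["group_id"] != ""].set_index("gene_id")["group_id"]
    hex_dups = tandem_truth[tandem_truth["table"] == "TaG"]
    for _, row in hex_dups.iterrows():
        gid = parent_group.get(row["parent_gene"])
        if gid is None:
            continue
        gi = int(gid[3:])
        mates = [hex_members[s][gi] for s in ("A", "B", "D")]
        mates = [m for m in mates if m is not None and m != row["parent_gene"]]
        if mates:
            hex_rows.append(
                {
                    "gene_id": row["duplicate_gene"],
                    "homoeolog_id": mates[0],
                    "homoeology_type": "ortholog_one2many",
                }
            )
    homoeologs_hex = pd.DataFrame(
        hex_rows, columns=["gene_id", "homoeolog_id", "homoeology_type"]
    )

    # tetraploid homoeolog table, Zavitan-style one row per group
    tet_rows = []
    for gi in range(n):
        a, b = tet_members["A"][gi], tet_members["B"][gi]
        if a is not None and b is not None:
            tet_rows.append(
                {
                    "group_id": f"ZAV{gi:06d}",
                    "gene_a": a,
                    "gene_b": b,
                    "homoeolog_class": "1:1",
                }
            )
        else:
            tet_rows.append(
                {
                    "group_id": f"ZAV{gi:06d}",
                    "gene_a": a or "",
                    "gene_b": b or "",
                    "homoeolog_class": "singleton",
                }
            )
    tet_dups = tandem_truth[tandem_truth["table"] == "TdG"]
    for k, (_, row) in enumerate(tet_dups.iterrows()):
        tet_rows.append(
            {
                "group_id": f"ZAVP{k:05d}",
                "gene_a": row["duplicate_gene"],
                "gene_b": row["parent_gene"],
                "homoeolog_class": "hit2homolog",
            }
        )
    homoeologs_tet = pd.DataFrame(
        tet_rows, columns=["group_id", "gene_a", "gene_b", "homoeolog_class"]
    )

    # isoform table for hexaploid genes; a small fraction get a shorter second
    # isoform assigned to a sister family, exercising the longest-isoform rule
    iso_rows = []
    tf_hex = hexa[hexa["tf_family"] != ""]
    conflict = rng.random(len(tf_hex)) < config.isoform_conflict_rate
    for k, (_, g) in enumerate(tf_hex.iterrows()):
        iso_rows.append(
            {
                "gene_id": g["gene_id"],
                "isoform_id": f"{g['gene_id']}.1",
                "length": g["transcript_length"],
                "family": g["tf_family"],
            }
        )
        if conflict[k]:
            iso_rows.append(
                {
                    "gene_id": g["gene_id"],
                    "isoform_id": f"{g['gene_id']}.2",
                    "length": max(1, int(g["transcript_length"] * 0.6)),
                    "family": f"{g['tf_family']}-related",
                }
            )
    isoforms = pd.DataFrame(iso_rows, columns=["gene_id", "isoform_id", "length", "family"])

    return SyntheticStudy(
        config=config,
        groups=groups,
        gene_tables={
            "diploid_A": dipA,
            "diploid_D": dipD,
            "tetraploid": tet,
            "hexaploid": hexa,
        },
        isoforms=isoforms,
        homoeologs_hexaploid=homoeologs_hex,
        homoeologs_tetraploid=homoeologs_tet,
        tandem_truth=tandem_truth,
    )


def simulate_expression(study: SyntheticStudy, config: Optional[SimConfig] = None) -> pd.DataFrame:
    """Generate the hexaploid tpm matrix, genes x (tissue, replicate).

    Genes in the same homoeolog group share a latent tissue profile whose
    weight is set (via a lognormal copula) so the homoeolog tpm correlation
    equals ``config.homoeolog_correlation`` in expectation; replicates are
    independently noised copies.
    """
    config = config or study.config
    if config.n_tissues < 2:
        raise ValueError("n_tissues must be at least 2 for correlations to be defined")
    rng = _stage_rngs(config.seed)[1]

    genes = study.gene_tables["hexaploid"]
    fam_by_name = {f.name: f for f in config.families}

    fams = genes["tf_family"].to_numpy()
    mu = np.array(
        [fam_by_name[f].log_mean if f else config.nontf_log_mean for f in fams]
    )
    sd = np.array([fam_by_name[f].log_sd if f else config.nontf_log_sd for f in fams])
    rho_z = np.array(
        [
            latent_correlation(
                config.homoeolog_correlation, fam_by_name[f].log_sd if f else config.nontf_log_sd
            )
            for f in fams
        ]
    )

    n_genes = len(genes)
    T = config.n_tissues
    group_ids = genes["group_id"].to_numpy()
    uniq_groups = pd.unique(group_ids[group_ids != ""])
    latent = rng.standard_normal((len(uniq_groups), T))
    gmap = {g: i for i, g in enumerate(uniq_groups)}

    z = np.empty((n_genes, T))
    has_group = group_ids != ""
    z[has_group] = latent[[gmap[g] for g in group_ids[has_group]]]
    z[~has_group] = rng.standard_normal(((~has_group).sum(), T))

    eps = rng.standard_normal((n_genes, T))
    w = np.sqrt(np.clip(rho_z, 0.0, 1.0))[:, None]
    log_tpm = mu[:, None] + sd[:, None] * (w * z + np.sqrt(1.0 - w**2) * eps)
    base = np.exp(log_tpm)

    cols = {}
    tissues = [f"tissue{t + 1:02d}" for t in range(T)]
    sample_tissues: Dict[str, str] = {}
    for t, tissue in enumerate(tissues):
        for r in range(config.n_replicates):
            col = f"{tissue}_rep{r + 1}"
            if config.replicate_log_sd > 0:
                noise = np.exp(rng.normal(0.0, config.replicate_log_sd, n_genes))
            else:
                noise = 1.0
            cols[col] = base[:, t] * noise
            sample_tissues[col] = tissue
    expr = pd.DataFrame(cols, index=genes["gene_id"].to_numpy())
    study.expression = expr
    study.sample_tissues = sample_tissues
    return expr


def simulate_modules(study: SyntheticStudy, config: Optional[SimConfig] = None) -> pd.Series:
    """Assign coexpression-network modules to hexaploid genes.

    Triads are co-assigned to one module with the configured TF or non-TF
    probability, other genes draw independent modules, and every gene is
    independently demoted to module 0 (the unassigned/invariant bucket) at
    ``module_zero_rate``.
    """
    config = config or study.config
    rng = _stage_rngs(config.seed)[3]
    genes = study.gene_tables["hexaploid"]
    modules = pd.Series(
        rng.integers(1, config.n_modules + 1, size=len(genes)),
        index=genes["gene_id"].to_numpy(),
    )

    triads = study.groups[study.groups["hexa_class"] == "triad"]
    gene_by_group: Dict[str, List[str]] = {}
    for gid, grp in zip(genes["gene_id"], genes["group_id"]):
        if grp:
            gene_by_group.setdefault(grp, []).append(gid)
    truth_rows = []
    for _, g in triads.iterrows():
        p_same = config.module_same_prob_tf if g["is_tf"] else config.module_same_prob_nontf
        same = rng.random() < p_same
        members = gene_by_group.get(g["group_id"], [])
        if same and len(members) == 3:
            m = int(rng.integers(1, config.n_modules + 1))
            for gid in members:
                modules.loc[gid] = m
        truth_rows.append({"group_id": g["group_id"], "intended_same_module": bool(same)})
    zero = rng.random(len(modules)) < config.module_zero_rate
    modules[zero] = 0
    study.modules = modules
    study.module_truth = pd.DataFrame(truth_rows, columns=["group_id", "intended_same_module"])
    return modules


_FINE_CATEGORIES = ("synonymous", "deleterious_missense", "tolerated_missense", "stop_gained")


def simulate_cohort(
    study: SyntheticStudy, config: Optional[SimConfig] = None
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Generate the SNP effect table and cohort genotype matrix.

    SNPs land in the canonical coding sequence of hexaploid triad genes at
    per-kb category rates (TF genes scaled by the per-category multipliers).
    Minor allele frequencies follow a scaled Beta spectrum, genotypes are
    Hardy-Weinberg draws at each site's frequency, and calls go missing
    independently. A small fraction of SNPs carry the nuisance annotations
    the downstream filter cascade removes (splice co-annotations, missense
    without SIFT, multi-annotated synonymous, excluded-region flags,
    non-coding placement).
    """
    config = config or study.config
    rng = _stage_rngs(config.seed)[2]
    genes = study.gene_tables["hexaploid"]
    triad_groups = set(study.groups.loc[study.groups["hexa_class"] == "triad", "group_id"])
    tg = genes[genes["group_id"].isin(triad_groups)].reset_index(drop=True)

    zero_len = tg["transcript_length"] <= 0
    if zero_len.any():
        warnings.warn(f"skipping {int(zero_len.sum())} genes with zero transcript length")
        tg = tg[~zero_len].reset_index(drop=True)

    base_rates = {
        "synonymous": config.snp_rates.get("synonymous", 0.0),
        "deleterious_missense": config.snp_rates.get("missense", 0.0)
        * config.sift_deleterious_fraction,
        "tolerated_missense": config.snp_rates.get("missense", 0.0)
        * (1.0 - config.sift_deleterious_fraction),
        "stop_gained": config.snp_rates.get("stop_gained", 0.0),
    }

    is_tf = (tg["tf_family"] != "").to_numpy()
    kb = tg["transcript_length"].to_numpy() / 1000.0

    records: List[dict] = []
    truth_cat: List[str] = []
    for cat in _FINE_CATEGORIES:
        lam = base_rates[cat] * kb
        lam = np.where(is_tf, lam * config.tf_rate_multipliers.get(cat, 1.0), lam)
        counts = rng.poisson(lam)
        for gi in np.flatnonzero(counts):
            g = tg.iloc[gi]
            for _ in range(int(counts[gi])):
                records.append(
                    {
                        "gene_id": g["gene_id"],
                        "chromosome": g["chromosome"],
                        "category": cat,
                        "is_tf": bool(is_tf[gi]),
                        "transcript_length": int(g["transcript_length"]),
                    }
                )
                truth_cat.append(cat)

    n_snps = len(records)
    variants = pd.DataFrame(
        records,
        columns=["gene_id", "chromosome", "category", "is_tf", "transcript_length"],
    )
    if n_snps == 0:
        empty = pd.DataFrame(
            columns=[
                "snp_id",
                "gene_id",
                "chromosome",
                "pos",
                "consequence",
                "sift",
                "in_canonical_cds",
                "splice_region",
                "n_annotations",
                "flag_adaptation",
                "flag_improvement",
                "flag_sweep",
                "flag_introgression",
                "true_category",
                "true_maf",
            ]
        )
        study.variants = empty
        study.genotypes = np.zeros((0, config.n_individuals), dtype=np.int8)
        study.individuals = [f"ind{i:04d}" for i in range(config.n_individuals)]
        return empty, study.genotypes

    cat = variants["category"].to_numpy()
    consequence = np.where(
        np.isin(cat, ["deleterious_missense", "tolerated_missense"]), "missense", cat
    )
    sift = np.full(n_snps, np.nan)
    del_mask = cat == "deleterious_missense"
    tol_mask = cat == "tolerated_missense"
    sift[del_mask] = rng.uniform(0.0, 0.05, del_mask.sum())
    sift[tol_mask] = rng.uniform(0.05 + 1e-9, 1.0, tol_mask.sum())
    no_sift = (rng.random(n_snps) < config.missense_no_sift_rate) & (del_mask | tol_mask)
    sift[no_sift] = np.nan

    a, b = config.maf_beta
    maf = 0.5 * rng.beta(a, b, n_snps)
    maf = np.clip(maf, 1e-3, 0.5)

    geno = (rng.random((n_snps, config.n_individuals)) < maf[:, None]).astype(np.int8)
    geno += (rng.random((n_snps, config.n_individuals)) < maf[:, None]).astype(np.int8)
    missing = rng.random((n_snps, config.n_individuals)) < config.missing_rate
    geno[missing] = -1

    variants = variants.assign(
        snp_id=[f"snp{i:07d}" for i in range(n_snps)],
        pos=rng.integers(1, 3_000_000, size=n_snps),
        consequence=consequence,
        sift=sift,
        in_canonical_cds=~(rng.random(n_snps) < config.noncoding_rate),
        splice_region=rng.random(n_snps) < config.splice_coannotation_rate,
        n_annotations=np.where(
            (cat == "synonymous") & (rng.random(n_snps) < config.multi_annotation_rate), 2, 1
        ),
        true_category=truth_cat,
        true_maf=maf,
    )
    variants.loc[~variants["in_canonical_cds"], "consequence"] = "other"
    for name in ("adaptation", "improvement", "sweep", "introgression"):
        rate = config.region_flag_rates.get(name, 0.0)
        variants[f"flag_{name}"] = rng.random(n_snps) < rate
    variants = variants.drop(columns=["category"])
    order = [
        "snp_id",
        "gene_id",
        "chromosome",
        "pos",
        "consequence",
        "sift",
        "in_canonical_cds",
        "splice_region",
        "n_annotations",
        "flag_adaptation",
        "flag_improvement",
        "flag_sweep",
        "flag_introgression",
        "is_tf",
        "transcript_length",
        "true_category",
        "true_maf",
    ]
    variants = variants[order]
    study.variants = variants
    study.genotypes = geno
    study.individuals = [f"ind{i:04d}" for i in range(config.n_individuals)]
    return variants, geno


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Run every generator stage under one seed."""
    study = simulate_genomes(config)
    simulate_expression(study, config)
    simulate_modules(study, config)
    simulate_cohort(study, config)
    return study


def triad_table(study: SyntheticStudy) -> pd.DataFrame:
    """Ground-truth triads as (group_id, gene_a, gene_b, gene_d, is_tf) rows."""
    genes = study.gene_tables["hexaploid"]
    triad_ids = set(study.groups.loc[study.groups["hexa_class"] == "triad", "group_id"])
    tg = genes[genes["group_id"].isin(triad_ids)]
    piv = tg.pivot(index="group_id", columns="subgenome", values="gene_id")
    out = pd.DataFrame(
        {
            "group_id": piv.index,
            "gene_a": piv["A"].to_numpy(),
            "gene_b": piv["B"].to_numpy(),
            "gene_d": piv["D"].to_numpy(),
        }
    ).reset_index(drop=True)
    is_tf = study.groups.set_index("group_id")["is_tf"]
    out["is_tf"] = out["group_id"].map(is_tf).to_numpy()
    return out


def recover_homoeolog_correlation(study: SyntheticStudy, config: Optional[SimConfig] = None) -> float:
    """Estimate the tpm-scale homoeolog correlation the generator realised.

    Works on the exactly-Gaussian log scale: per homoeolog pair the Pearson
    correlation of replicate-averaged log tpm profiles is computed, corrected
    for small-sample bias (Olkin-Pratt) and for the known replicate-noise
    attenuation, averaged within family, then mapped through the lognormal
    moment formula back to the tpm scale. Returns the pair-count-weighted
    average across families — an (approximately) unbiased estimate of the
    configured ``homoeolog_correlation``.
    """
    config = config or study.config
    if study.expression is None:
        raise ValueError("expression has not been simulated")
    T = config.n_tissues
    tissues = pd.Series(study.sample_tissues)
    log_mean = np.log(study.expression).T.groupby(tissues).mean().T

    fam_by_name = {f.name: f for f in config.families}
    gene_fam = study.gene_tables["hexaploid"].set_index("gene_id")["tf_family"]
    tri = triad_table(study)

    def corrected_r(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        du = u - u.mean(axis=1, keepdims=True)
        dv = v - v.mean(axis=1, keepdims=True)
        r = (du * dv).sum(axis=1) / np.sqrt((du**2).sum(axis=1) * (dv**2).sum(axis=1))
        return r * (1.0 + (1.0 - r**2) / (2.0 * (T - 3)))

    a = log_mean.loc[tri["gene_a"]].to_numpy()
    b = log_mean.loc[tri["gene_b"]].to_numpy()
    d = log_mean.loc[tri["gene_d"]].to_numpy()
    rz = np.concatenate([corrected_r(a, b), corrected_r(b, d), corrected_r(a, d)])
    fams = tri["gene_a"].map(gene_fam).to_numpy()
    fams = np.concatenate([fams, fams, fams])

    total_w = 0.0
    acc = 0.0
    for fam in pd.unique(fams):
        spec_sd = fam_by_name[fam].log_sd if fam else config.nontf_log_sd
        sel = fams == fam
        if spec_sd == 0:
            continue
        s2 = spec_sd**2
        atten = (s2 + config.replicate_log_sd**2 / config.n_replicates) / s2
        rho_z = float(np.mean(rz[sel])) * atten
        rho_z = min(rho_z, 1.0)
        rho_tpm = np.expm1(rho_z * s2) / np.expm1(s2)
        w = sel.sum()
        acc += w * rho_tpm
        total_w += w
    return acc / total_w
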