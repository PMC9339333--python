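"""Readers and writers for the pipeline's on-disk formats.

Tables travel as TSV; the cohort travels as a minimal GT-only VCF (written
as plain text, read back through pysam) plus a VEP-like effect TSV;
exclusion regions as BED; and every run emits a JSON manifest echoing the
configuration, seed and per-output row counts and checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .simulate import SimConfig, SyntheticStudy

__all__ = [
    "write_tsv",
    "read_gene_table",
    "read_homoeolog_table",
    "read_expression",
    "read_modules",
    "read_effects",
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_study",
    "write_manifest",
]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    df["tf_family"] = df["tf_family"].fillna("")
    return df


def read_homoeolog_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_modules(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "module": int})
    return df.set_index("gene_id")["module"]


def read_effects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str, "chromosome": str})


def write_vcf(
    path,
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    individuals: Sequence[str],
) -> None:
    """Write a minimal GT-only VCF (uncompressed text)."""
    chroms = list(dict.fromkeys(variants["chromosome"])) if len(variants) else []
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(individuals) + "\n")
        order = variants.sort_values(["chromosome", "pos"], kind="stable").index
        for i in order:
            row = variants.loc[i]
            calls = "\t".join(gt_map[int(g)] for g in genotypes[variants.index.get_loc(i)])
            fh.write(
                f"{row['chromosome']}\t{int(row['pos'])}\t{row['snp_id']}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> Tuple[pd.DataFrame, np.ndarray, List[str]]:
    """Read a GT-only VCF into (site table, dosage matrix, individuals)."""
    vf = pysam.VariantFile(str(path))
    individuals = list(vf.header.samples)
    sites = []
    rows = []
    for rec in vf:
        sites.append({"snp_id": rec.id, "chromosome": rec.chrom, "pos": rec.pos})
        dosages = []
        for s in individuals:
            alleles = rec.samples[s]["GT"]
            if alleles is None or any(a is None for a in alleles):
                dosages.append(-1)
            else:
                dosages.append(sum(alleles))
        rows.append(dosages)
    gt = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(individuals)), dtype=np.int8)
    return pd.DataFrame(sites, columns=["snp_id", "chromosome", "pos"]), gt, individuals


def write_bed(path, regions: pd.DataFrame) -> None:
    """Write exclusion regions as BED (chrom, start, end, name)."""
    regions[["chromosome", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chromosome", "start", "end", "name"], dtype={"chromosome": str}
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def exclusion_regions_from_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """BED rows (one per flagged SNP) for the four exclusion region classes."""
    rows = []
    for name in ("adaptation", "improvement", "sweep", "introgression"):
        col = f"flag_{name}"
        if col not in variants.columns:
            continue
        for _, v in variants[variants[col]].iterrows():
            rows.append(
                {
                    "chromosome": v["chromosome"],
                    "start": int(v["pos"]) - 1,
                    "end": int(v["pos"]),
                    "name": name,
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])


def write_study(study: SyntheticStudy, outdir) -> Dict[str, str]:
    """Write every generated table; returns path map used by the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    for name, table in study.gene_tables.items():
        p = out / f"genes_{name}.tsv"
        write_tsv(table, p)
        paths[f"genes_{name}"] = str(p)
    write_tsv(study.isoforms, out / "isoforms.tsv")
    paths["isoforms"] = str(out / "isoforms.tsv")
    write_tsv(study.homoeologs_hexaploid, out / "homoeologs_hexaploid.tsv")
    paths["homoeologs_hexaploid"] = str(out / "homoeologs_hexaploid.tsv")
    write_tsv(study.homoeologs_tetraploid, out / "homoeologs_tetraploid.tsv")
    paths["homoeologs_tetraploid"] = str(out / "homoeologs_tetraploid.tsv")
    write_tsv(study.groups, out / "ground_truth_groups.tsv")
    paths["ground_truth_groups"] = str(out / "ground_truth_groups.tsv")
    write_tsv(study.tandem_truth, out / "ground_truth_tandem.tsv")
    paths["ground_truth_tandem"] = str(out / "ground_truth_tandem.tsv")

    if study.expression is not None:
        p = out / "expression_tpm.tsv"
        study.expression.to_csv(p, sep="\t", index_label="gene_id")
        paths["expression"] = str(p)
    if study.modules is not None:
        p = out / "modules.tsv"
        study.modules.rename("module").rename_axis("gene_id").reset_index().to_csv(
            p, sep="\t", index=False
        )
        paths["modules"] = str(p)
        write_tsv(study.module_truth, out / "ground_truth_modules.tsv")
        paths["ground_truth_modules"] = str(out / "ground_truth_modules.tsv")
    if study.variants is not None:
        p = out / "snp_effects.tsv"
        write_tsv(study.variants, p)
        paths["snp_effects"] = str(p)
        v = out / "cohort.vcf"
        write_vcf(v, study.variants, study.genotypes, study.individuals)
        paths["vcf"] = str(v)
        b = out / "exclusion_regions.bed"
        write_bed(b, exclusion_regions_from_variants(study.variants))
        paths["exclusion_regions"] = str(b)
    return paths


def write_manifest(outdir, config: SimConfig, paths: Dict[str, str], extra: Optional[dict] = None) -> str:
    out = Path(outdir)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {
            name: {
                "path": p,
                "sha256": _sha256(Path(p)),
                "n_rows": sum(1 for _ in open(p)) - 1 if p.endswith(".tsv") else None,
            }
            for name, p in paths.items()
        },
    }
    if extra:
        manifest.update(extra)
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=str))
    return str(mp)
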