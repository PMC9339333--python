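import numpy as np
import pandas as pd
import pytest

from triadkit.simulate import SimConfig, simulate_genomes, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A small but fully-featured study configuration."""
    return SimConfig(n_groups=400, n_individuals=60, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def genomes_only():
    cfg = SimConfig(n_groups=600, seed=5)
    return simulate_genomes(cfg)


def make_gene_table(rows):
    """Gene table from (gene_id, family, chromosome, ordinal) tuples."""
    return pd.DataFrame(
        [
            {
                "gene_id": g,
                "tf_family": fam,
                "chromosome": chrom,
                "ordinal": float(o),
                "subgenome": chrom[-1] if chrom and chrom[-1] in "ABD" else "A",
                "confidence": "high",
                "transcript_length": 900,
                "group_id": "",
                "is_tandem_dup": False,
            }
            for g, fam, chrom, o in rows
        ]
    )


def make_variants(specs):
    """Variant table + genotypes from per-SNP dicts (defaults filled in)."""
    defaults = {
        "gene_id": "g1",
        "chromosome": "1A",
        "pos": 100,
        "consequence": "synonymous",
        "sift": np.nan,
        "in_canonical_cds": True,
        "splice_region": False,
        "n_annotations": 1,
        "flag_adaptation": False,
        "flag_improvement": False,
        "flag_sweep": False,
        "flag_introgression": False,
        "is_tf": False,
    }
    rows, genos = [], []
    for i, spec in enumerate(specs):
        spec = dict(spec)
        geno = spec.pop("genotypes")
        row = {**defaults, **spec}
        row.setdefault("snp_id", f"s{i}")
        rows.append(row)
        genos.append(geno)
    columns = ["snp_id", *defaults]
    if not rows:
        return pd.DataFrame(columns=columns), np.zeros((0, 0), dtype=np.int8)
    return pd.DataFrame(rows)[columns], np.array(genos, dtype=np.int8)
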