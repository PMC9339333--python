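"""End-to-end orchestration: simulate -> retention -> tandem -> expression -> variants.

Each stage consumes the outputs of the previous ones, writes its tables
under the run directory, logs row-count deltas to stderr and contributes its
headline numbers to a consolidated JSON report. A fixed seed reproduces the
whole run byte for byte.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import expression as expr_mod
from . import io as io_mod
from . import retention as ret_mod
from . import tandem as tan_mod
from . import variants as var_mod
from .simulate import SimConfig, SyntheticStudy, simulate_study
from .stats import fisher_exact_2x2, mann_whitney

ALL_STAGES = ("simulate", "retention", "tandem", "expression", "variants")


def _log(msg: str) -> None:
    print(f"[triadkit] {msg}", file=sys.stderr)


class MissingStageError(RuntimeError):
    pass


def _tf_percentage(genes: pd.DataFrame) -> float:
    return 100.0 * float((genes["tf_family"] != "").sum()) / len(genes)


def _group_families(groups: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    fam = genes.set_index("gene_id")["tf_family"].replace("", ret_mod.NON_TF)
    out = []
    for members in groups["members"]:
        out.append(ret_mod.resolve_group_family([fam.get(g, ret_mod.NON_TF) for g in members]))
    return pd.Series(out, index=groups.index, name="family")


def run_pipeline(
    config: SimConfig,
    outdir,
    stages: Sequence[str] = ALL_STAGES,
    window: int = 3,
    tpm_threshold: float = 0.5,
    min_maf: float = 0.01,
    max_missing: float = 0.25,
    sift_cutoff: float = 0.05,
    tail: float = 0.025,
    min_triads: int = 10,
    min_snps: int = 5,
) -> Dict[str, object]:
    """Run the requested stages and return the consolidated report dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")

    report: Dict[str, object] = {"seed": config.seed}
    ctx: Dict[str, object] = {}

    if "simulate" in stages:
        _log(f"simulate: {config.n_groups} ancestral groups, seed {config.seed}")
        study = simulate_study(config)
        paths = io_mod.write_study(study, out / "data")
        io_mod.write_manifest(out, config, paths)
        ctx["study"] = study
        for name, table in study.gene_tables.items():
            _log(f"simulate: {name}: {len(table)} genes")
        _log(f"simulate: {len(study.variants)} SNPs, {config.n_individuals} individuals")
    else:
        raise MissingStageError("the simulate stage is required to seed the run directory")
    study: SyntheticStudy = ctx["study"]

    genes_hex = study.gene_tables["hexaploid"]
    genes_tet = study.gene_tables["tetraploid"]

    if "retention" in stages:
        sub_hex = genes_hex.set_index("gene_id")["subgenome"]
        hc = set(genes_hex.loc[genes_hex["confidence"] == "high", "gene_id"])
        groups_hex, removed_hex = ret_mod.classify_groups(
            study.homoeologs_hexaploid, "biomart_one2one", sub_hex, high_confidence=hc
        )
        _log(f"retention: hexaploid groups {len(groups_hex)}, removed rows {removed_hex}")
        sub_tet = genes_tet.set_index("gene_id")["subgenome"]
        groups_tet, removed_tet = ret_mod.classify_groups(
            study.homoeologs_tetraploid, "zavitan", sub_tet
        )
        _log(f"retention: tetraploid groups {len(groups_tet)}, removed rows {removed_tet}")

        summary_hex = ret_mod.retention_percentages(genes_hex, groups_hex, "triad")
        summary_tet = ret_mod.retention_percentages(genes_tet, groups_tet, "diad")
        io_mod.write_tsv(summary_hex, out / "retention_hexaploid.tsv")
        io_mod.write_tsv(summary_tet, out / "retention_tetraploid.tsv")

        hexa = summary_hex.set_index("family")["pct_in_complete"]
        teta = summary_tet.set_index("family")["pct_in_complete"]
        norm_rows = []
        for fam in hexa.index:
            if fam in teta.index:
                norm_rows.append(
                    {
                        "family": fam,
                        "pct_triads_hexaploid": hexa[fam],
                        "pct_diads_tetraploid": teta[fam],
                        "normalized_pct_triads": ret_mod.normalized_retention(
                            hexa[fam], teta[fam]
                        ),
                    }
                )
        normalized = pd.DataFrame(norm_rows)
        io_mod.write_tsv(normalized, out / "retention_normalized.tsv")

        ctx["groups_hex"] = groups_hex
        ctx["summary_hex"] = summary_hex
        report["retention"] = {
            "tf_pct_per_ploidy": {
                name: _tf_percentage(t) for name, t in study.gene_tables.items()
            },
            "pct_tf_in_triads": float(hexa.get("TF", np.nan)),
            "pct_nontf_in_triads": float(hexa.get(ret_mod.NON_TF, np.nan)),
            "pct_tf_in_diads": float(teta.get("TF", np.nan)),
            "pct_nontf_in_diads": float(teta.get(ret_mod.NON_TF, np.nan)),
            "normalized_pct_triads": {
                r["family"]: r["normalized_pct_triads"] for r in norm_rows
            },
        }

    if "expression" in stages or "tandem" in stages or "variants" in stages:
        if "groups_hex" not in ctx:
            raise MissingStageError("stage requires the retention stage output")
        tissue_means = expr_mod.replicate_means(study.expression, study.sample_tissues)
        ctx["tissue_means"] = tissue_means

    if "tandem" in stages:
        events = tan_mod.detect_tandem_events(genes_hex, window=window)
        io_mod.write_tsv(events, out / "tandem_events.tsv")
        tf_genes = genes_hex[genes_hex["tf_family"] != ""]
        fam_counts = tf_genes.groupby("tf_family").size().to_dict()
        pct_tandem = tan_mod.pct_tandem_per_family(events, fam_counts)

        summary_hex = ctx["summary_hex"]
        fam_rows = summary_hex[
            (summary_hex["n_complete_groups"] > min_triads)
            & (~summary_hex["family"].isin(["TF", ret_mod.NON_TF]))
        ].set_index("family")
        pct_triads = fam_rows["pct_in_complete"]
        med_expr = tan_mod.family_median_expression(genes_hex, ctx["tissue_means"])

        report_t: Dict[str, object] = {"n_events": int(len(events)), "window": window}
        try:
            fit_tandem = tan_mod.fit_retention_regression(
                pct_tandem.reindex(pct_triads.index), pct_triads
            )
            report_t["tandem_vs_triads"] = {
                "slope": fit_tandem.slope,
                "r_squared": fit_tandem.r_squared,
                "pvalue": fit_tandem.pvalue,
                "n_families": fit_tandem.n,
            }
        except ValueError as e:
            report_t["tandem_vs_triads"] = {"error": str(e)}
        try:
            fit_expr = tan_mod.fit_retention_regression(
                med_expr.reindex(pct_triads.index), pct_triads, log_transform_x=True
            )
            report_t["expression_vs_triads"] = {
                "slope": fit_expr.slope,
                "r_squared": fit_expr.r_squared,
                "pvalue": fit_expr.pvalue,
                "n_families": fit_expr.n,
            }
        except ValueError as e:
            report_t["expression_vs_triads"] = {"error": str(e)}
        reg = pd.DataFrame(
            {
                "pct_tandem": pct_tandem.reindex(pct_triads.index),
                "median_tpm": med_expr.reindex(pct_triads.index),
                "pct_triads": pct_triads,
            }
        )
        reg.rename_axis("family").reset_index().pipe(io_mod.write_tsv, out / "tandem_regression.tsv")
        _log(f"tandem: {len(events)} events over {len(tf_genes)} TF genes (window {window})")
        report["tandem"] = report_t

    if "expression" in stages:
        groups_hex = ctx["groups_hex"]
        tissue_means = ctx["tissue_means"]
        triads = groups_hex[groups_hex["cardinality"] == "triad"].reset_index(drop=True)
        triads = triads.assign(family=_group_families(triads, genes_hex))
        expressed = expr_mod.filter_expressed_triads(tissue_means, triads, threshold=tpm_threshold)
        _log(f"expression: {len(expressed)} of {len(triads)} triads pass the {tpm_threshold} tpm filter")

        is_tf = expressed["family"] != ret_mod.NON_TF
        sd_tf = expr_mod.triad_fraction_sd(tissue_means, expressed[is_tf])
        sd_nontf = expr_mod.triad_fraction_sd(tissue_means, expressed[~is_tf])
        div_tests = expr_mod.compare_divergence(sd_tf, sd_nontf)
        io_mod.write_tsv(div_tests, out / "expression_divergence_tests.tsv")

        corr_triads = expr_mod.filter_expressed_triads(
            tissue_means, triads, threshold=tpm_threshold, require_all_expressed=True
        )
        is_tf_c = corr_triads["family"] != ret_mod.NON_TF
        rr_tf = expr_mod.pairwise_correlations(tissue_means, corr_triads[is_tf_c])
        rr_nontf = expr_mod.pairwise_correlations(tissue_means, corr_triads[~is_tf_c])
        r_tf = rr_tf.to_numpy().ravel()
        r_nontf = rr_nontf.to_numpy().ravel()
        med_tf = expr_mod.median_correlation(r_tf)
        med_nontf = expr_mod.median_correlation(r_nontf)
        mw = mann_whitney(r_tf[~np.isnan(r_tf)], r_nontf[~np.isnan(r_nontf)])

        pct_tf, same_tf, elig_tf = expr_mod.module_comembership(
            corr_triads[is_tf_c], study.modules
        )
        pct_nontf, same_nontf, elig_nontf = expr_mod.module_comembership(
            corr_triads[~is_tf_c], study.modules
        )
        fisher = fisher_exact_2x2(
            [[same_tf, elig_tf - same_tf], [same_nontf, elig_nontf - same_nontf]]
        )

        report["expression"] = {
            "n_triads_expressed": int(len(expressed)),
            "n_triads_correlation": int(len(corr_triads)),
            "n_tissues_divergent": int((div_tests["pvalue"] < 0.05).sum()),
            "median_r_tf": med_tf,
            "median_r_nontf": med_nontf,
            "coexpression_mw_pvalue": mw.pvalue,
            "module_comembership_pct_tf": pct_tf,
            "module_comembership_pct_nontf": pct_nontf,
            "module_comembership_fisher_pvalue": fisher.pvalue,
        }
        ctx["triads"] = triads
        ctx["expressed_triads"] = expressed

    if "variants" in stages:
        if "tissue_means" not in ctx:
            raise MissingStageError("variants stage requires the expression filter output")
        tissue_means = ctx["tissue_means"]
        variants, genotypes = study.variants, study.genotypes
        expressed_genes = set(
            tissue_means.index[(tissue_means > tpm_threshold).any(axis=1)]
        )
        filtered, gt, stage_counts = var_mod.filter_snps(
            variants, genotypes, expressed_genes, max_missing=max_missing, min_maf=min_maf
        )
        for k, v in stage_counts.items():
            _log(f"variants: {k}: {v}")
        cats = var_mod.classify_effects(filtered, sift_cutoff=sift_cutoff)
        groups_lbl = pd.Series(
            np.where(filtered["is_tf"], "TF", "non-TF"), index=filtered.index
        )
        cat_counts = (
            pd.crosstab(groups_lbl, cats).reindex(
                index=["TF", "non-TF"], columns=list(var_mod.CATEGORIES), fill_value=0
            )
        )
        io_mod.write_tsv(
            filtered.assign(category=cats), out / "variants_filtered.tsv"
        )

        pi = var_mod.site_pi_all(gt)
        io_mod.write_tsv(
            filtered[["snp_id", "gene_id"]].assign(pi=pi, category=cats),
            out / "site_pi.tsv",
        )

        triad_groups = set(study.groups.loc[study.groups["hexa_class"] == "triad", "group_id"])
        tg = genes_hex[genes_hex["group_id"].isin(triad_groups)]
        group_lengths = {
            "TF": float(tg.loc[tg["tf_family"] != "", "transcript_length"].sum()),
            "non-TF": float(tg.loc[tg["tf_family"] == "", "transcript_length"].sum()),
        }
        load = var_mod.mutation_load(
            filtered, gt, cats, groups_lbl, group_lengths, study.individuals
        )
        io_mod.write_tsv(load, out / "mutation_load.tsv")
        extreme = var_mod.flag_extreme_individuals(load, tail=tail)
        _log(f"variants: {len(extreme)} individuals with extreme loads")

        fam_series = (
            genes_hex.set_index("gene_id")["tf_family"].replace("", ret_mod.NON_TF)
        )
        snp_fams = filtered["gene_id"].map(fam_series)
        summary_hex = ctx["summary_hex"]
        triad_counts = summary_hex.set_index("family")["n_complete_groups"].to_dict()
        fam_props = var_mod.family_snp_proportions(
            filtered,
            gt,
            cats,
            snp_fams.rename("family"),
            triad_counts,
            extreme,
            study.individuals,
            min_triads=min_triads,
            min_snps=min_snps,
        )
        io_mod.write_tsv(fam_props, out / "family_snp_proportions.tsv")

        contrasts = var_mod.compare_loads(load)
        contrasts["tukey"].pipe(io_mod.write_tsv, out / "load_contrasts.tsv")

        anova = contrasts["anova"]
        report["variants"] = {
            "filter_stages": dict(stage_counts),
            "category_counts": {
                g: {c: int(cat_counts.loc[g, c]) for c in var_mod.CATEGORIES}
                for g in cat_counts.index
            },
            "category_count_total": int(cat_counts.to_numpy().sum()),
            "mean_pi": float(np.nanmean(pi)) if len(pi) else float("nan"),
            "n_extreme_individuals": len(extreme),
            "anova_F_group": float(anova.loc["C(group)", "F"]),
            "anova_p_group": float(anova.loc["C(group)", "PR(>F)"]),
            "load_percent_difference": {
                k: float(v) for k, v in contrasts["percent_difference"].items()
            },
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    _log(f"report written to {out / 'report.json'}")
    return report
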