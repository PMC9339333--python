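# triadkit

Tools for studying how duplicate genes — transcription factors (TFs) in
particular — are retained through the two hybridisation + whole-genome
duplication steps that produced bread wheat (*Triticum aestivum*, AABBDD).
The gene balance hypothesis predicts that dosage-sensitive regulatory genes
are preferentially kept with a full homoeolog complement after polyploidy;
`triadkit` implements the full analysis chain needed to test that on gene
annotation, homoeology, expression and cohort-variation data, plus a
synthetic-data generator so every stage can be exercised and validated
without any external downloads.

## What it computes

* **Homoeolog group classification** — 1:1:1 *triads* (one A, one B, one D
  copy) in the hexaploid and 1:1 *diads* in the tetraploid, from
  Biomart-style `one2one` pair tables or Zavitan-style group tables
  (`singleton` / `hit2homolog` rows removed). TF family labels are resolved
  by the longest-isoform rule per gene and majority rule per group.
* **Retention statistics** — per-family percentage of genes in complete
  groups, Fisher's exact enrichment vs non-TF genes with Benjamini–Hochberg
  FDR, and the **normalized retention**

  ```
  normalized % in triads = 100 × (% genes in triads, hexaploid)
                                 / (% genes in diads, tetraploid)
  ```

  which corrects the hexaploid triad percentage for losses that already
  happened in the tetraploid (60% triads over 80% diads → 75% of the
  possible triads were formed).
* **Tandem duplication** — events from gene-order adjacency: same-family
  genes within ±k gene positions (k = 1, 2, 3; identifiers step by 100 per
  gene) are chained into clusters, a cluster of n genes counting n − 1
  events; per-family tandem rates and OLS regressions against triad
  retention.
* **Expression divergence and coexpression** — triads filtered at > 0.5 tpm
  (replicate means), per-tissue homoeolog fractions normalised to sum to 1,
  divergence as the SD of the three fractions with per-tissue Mann–Whitney
  TF vs non-TF tests; pairwise homoeolog Pearson correlations over tissues,
  aggregated by Fisher-z medians; WGCNA-style module co-membership
  (module 0 excluded) with Fisher's exact TF vs non-TF contrast.
* **Mutation load** — an eight-stage SNP filter cascade (canonical CDS,
  splice co-annotations, missing SIFT, > 25% missingness, MAF ≥ 0.01,
  expression, selection/introgression region exclusion, multi-annotated
  synonymous sites); SIFT ≤ 0.05 classed deleterious; per-site nucleotide
  diversity π = 2j(n−j)/(n(n−1)); per-individual homozygous-alternate load
  per kb of the group's summed canonical transcripts; 2.5%-tail extreme
  individual flagging; two-factor ANOVA with Tukey HSD contrasts.

## Worked example

```bash
printf 'n_groups: 500\nn_individuals: 80\n' > demo.yaml
triadkit all --seed 23 --config demo.yaml --outdir demo
python - <<'EOF'
import json
r = json.load(open("demo/report.json"))
print("TF in triads:     %.1f%%" % r["retention"]["pct_tf_in_triads"])
print("non-TF in triads: %.1f%%" % r["retention"]["pct_nontf_in_triads"])
print("median r (TF):    %.3f"   % r["expression"]["median_r_tf"])
print("median r (non-TF):%.3f"   % r["expression"]["median_r_nontf"])
print("deleterious load deficit: %.1f%%"
      % r["variants"]["load_percent_difference"]["deleterious_missense"])
EOF
```

With the default study conditions scaled down to 500 ancestral groups and
80 individuals this prints

```
TF in triads:     81.5%
non-TF in triads: 72.2%
median r (TF):    0.939
median r (non-TF):0.943
deleterious load deficit: 50.9%
```

TF genes sit in triads more often than non-TF genes (the generator's
configured retention gap), homoeolog coexpression is high under the default
correlation target of 0.93, and TFs carry fewer homozygous deleterious
missense mutations per kb — noisily at this small cohort size; the
parameter-recovery tests use larger runs. Every output table (retention
summaries, tandem events, divergence tests, per-site π, the load table) is
written under `demo/`, with a `manifest.json` echoing the seed and
configuration; rerunning with the same seed reproduces every file byte for
byte.

## Layout

```
src/triadkit/
  simulate.py    synthetic study generator + ground truth
  retention.py   group classification, family resolution, retention stats
  tandem.py      gene-order tandem duplication detection and regressions
  expression.py  triad expression divergence and coexpression
  variants.py    SNP filtering, effect classes, pi, mutation load
  stats.py       shared tested primitives (Fisher, Mann-Whitney, BH, OLS, ANOVA/Tukey)
  pipeline.py    stage orchestration and consolidated report
  io.py          TSV / VCF / BED / manifest round trips
  cli.py         click CLI (`triadkit simulate|retention|tandem|expression|variants|all`)
```

See `docs/methods.md` for the statistical conventions, generator model and
known limitations.
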