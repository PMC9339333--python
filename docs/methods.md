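# Methods

This note records the models, conventions and numerical choices behind
`triadkit`, in the order the pipeline runs them.

## Background and scope

Bread wheat is a recent allohexaploid: an A×B hybridisation/genome
doubling (~0.4 Mya) produced the wild emmer tetraploid, and a second
hybridisation with the D-genome donor (~10 kya) produced hexaploid wheat.
A *triad* is a homoeolog group with exactly one A, one B and one D copy;
a *diad* is the tetraploid A:B analogue. The analyses ask whether
transcription factors (TFs) — archetypal dosage-sensitive genes under the
gene balance hypothesis — are retained as complete groups more often than
other genes, and whether retention differences between TF families track
expression level, tandem duplication, homoeolog coexpression and
population-level deleterious variation.

The package consumes annotation-level inputs (gene tables, homoeology
tables, a tpm matrix, a module-assignment table, a VEP/SIFT-style effect
table with genotypes). It does not call orthology, run network inference or
predict variant effects itself; those products are treated as inputs, and
the bundled generator produces statistically structured stand-ins for all
of them.

## Synthetic study generator

One ancestral gene group is the unit of simulation. Per group:

* **Cardinality.** The group survives as a tetraploid diad with probability
  `diad_prob` and, conditional on that, as a hexaploid triad with
  probability `triad_given_diad`; the marginal triad probability is the
  product. Non-diad groups keep a single randomly chosen A or B copy; diad
  non-triad groups keep A and B in the hexaploid. Both diploid progenitor
  tables carry every group. Defaults encode the study conditions: marginal
  triad probability 0.705 for TFs (diad 0.825) and 0.559 for non-TFs (diad
  0.692), a 5.7% TF fraction, and per-family values for the three
  low-retention families (NAC 0.510/0.745, B3 0.387/0.639, MADS-M-type
  0.385/0.613). 35,000 groups (the default) yield roughly the study's ~20k
  triads; tests and examples scale `n_groups` down, which changes precision
  only.
* **Gene order.** Within each chromosome × subgenome the gene identifier
  number steps by 100 per gene (ordinal step 1); tandem duplicates are
  inserted at +50 (ordinal +0.5), so any gene-order window sees them as
  adjacent while ordinary neighbours keep the +100 convention. Tandem
  insertion is Bernoulli per gene at the family's `tandem_rate`; the truth
  table records every insertion. The detector will additionally chain
  same-family genes that are coincidentally adjacent — a real feature of
  gene order, not an artefact — so recovery tests compare against the
  truth count plus that measurable background.
* **Expression.** log tpm for gene g in tissue t is
  `mu_f + sd_f (sqrt(rho_z) z_gt + sqrt(1-rho_z) e_gt)` with the latent
  profile `z` shared within a homoeolog group. `rho_z` is chosen by
  inverting the lognormal moment formula
  `corr_tpm = (exp(rho_z s^2)-1)/(exp(s^2)-1)` so the *tpm-scale* Pearson
  correlation between homoeologs equals `homoeolog_correlation` (default
  0.93) in expectation. Replicates are multiplicative lognormal noise
  (log-sd 0.05). Lognormal marginals give the right-skewed tpm
  distributions real data show; family `log_mean` sets expression level
  (low for NAC/B3/MADS-M-type, matching their retention story).
* **Modules.** Each triad is co-assigned one module with probability 0.355
  (TF) / 0.293 (non-TF); other genes draw independent modules from 20; 10%
  of assignments are demoted to module 0, the invariant/unassigned bucket.
* **Cohort.** SNPs land in the canonical CDS of triad genes as Poisson
  draws at per-kb category rates (synonymous 1.2, missense 1.5 split 25%
  deleterious, stop-gained 0.02), with TF genes scaled per category
  (deleterious 0.68, tolerated 1.057, synonymous 0.824) — the configured
  TF deleterious deficit of 32%. Minor allele frequencies follow
  0.5·Beta(0.3, 2) (right-skewed, many rare alleles, so the MAF ≥ 0.01
  filter bites as in real data); genotypes are Hardy–Weinberg draws at the
  site frequency; calls go missing independently at 5%. Small independent
  rates (2%) produce the nuisances the filter cascade exists for: splice
  co-annotations, missense without SIFT, multi-annotated synonymous sites,
  non-coding placement and the four excluded-region flags.

All stages draw from child streams of one seed, so a fixed seed reproduces
every table byte for byte regardless of which stages run.

What the generator does **not** emulate: linkage disequilibrium between
sites, selection acting over generations, biased subgenome fractionation,
read-level noise, isoform-level quantification, and spatial structure in
the excluded regions (flags are per-SNP). Passing tests therefore validate
the analysis logic and its statistical calibration, not the biology of any
particular real data set.

## Retention

Group classification removes non-`one2one` rows (Biomart dialect) or
`singleton`/`hit2homolog` rows (Zavitan dialect), restricts hexaploid
analyses to high-confidence gene models when a confidence set is supplied,
and takes connected components of the surviving pairs. Components are
classed singleton/diad/triad/other; a gene in two groups is an error.
Family labels: longest isoform per gene (ties broken by lexicographically
smallest isoform id, making the result input-order independent); majority
rule per group, with three-way disagreements flagged unresolved and
excluded from per-family summaries while still counting as TF in the
TF vs non-TF totals. The tetraploid table gets no confidence filter (none
is defined for it).

Normalized retention is `100 × pct_triads / pct_diads` computed at full
precision and reported at 1 dp. It is scale-invariant and undefined (NaN)
at zero diad percentage. Published per-family values reproduce at 1 dp
from their own rounded inputs except one family (B3), where 38.7/63.9
recomputes to 60.6 vs a printed 60.5 — the original computation evidently
used unrounded percentages; the statistic is rounding-sensitive at the
first decimal, which is why internal computation never rounds.

Enrichment per family is a two-sided Fisher's exact test of
(in-complete-group, not) vs the non-TF genes, BH-adjusted across families.
Headline figures restrict to families with more than 10 complete groups.

## Tandem duplication

Within one family and one chromosome, genes sorted by ordinal are chained
whenever the consecutive gap is ≤ k (k = 3 by default: up to two
intervening gene positions; k counts genes, not base pairs). Chained
linkage means a cluster of three genes with pairwise gaps 2+2 is one
cluster even though the ends are 4 apart; events per cluster = size − 1,
which reproduces the "cluster of three = two events" accounting. Intervening
genes of other families do not break a link — that is precisely what the
k = 2, 3 windows permit. Event counts are monotone in k and invariant to
row order and uniform ordinal shifts (both property-tested against an
explicit connected-components oracle).

Family-level regressions are ordinary least squares of the per-family triad
percentage on (a) the tandem percentage (100 × events/genes) and (b) the
natural log of the family's median expression, where each gene's mean tpm
across tissues is computed first and the family median second; families
with non-positive medians are dropped before the log with a warning.

## Expression divergence and coexpression

All statistics use replicate-mean tpm per tissue. Triads are kept when any
homoeolog exceeds 0.5 tpm in any tissue; correlation analyses additionally
require every homoeolog to have tpm > 0 somewhere. Per tissue, triad
expression is normalised to sum to 1 over the three homoeologs and
divergence is the **sample** SD (divisor n−1 = 2) of the three fractions —
the convention matters because reported medians sit near 0.09–0.10, and
mainstream statistical environments default to the sample SD. Tissues with
zero triad expression yield no value rather than a (0,0,0) score. TF vs
non-TF divergence is compared per tissue (no cross-tissue averaging) with
a two-sided Mann–Whitney test.

Coexpression: Pearson r per homoeolog pair (A–B, B–D, A–D) over tissues;
zero-variance profiles give missing values. Aggregation passes through the
Fisher z-transform (r clipped to ±(1−10⁻¹²) so atanh stays finite), takes
the median in z-space and back-transforms — monotone, so the median of a
symmetric-in-z set is the centre value and results never leave [−1, 1].
Family-level summaries pool all pairwise r values per triad rather than
per-triad medians (flagged in output). Note that with 15 tissues the
median-r estimator runs slightly high of the generating correlation on
lognormal data; the parameter-recovery machinery therefore uses a separate
estimator (below). Module co-membership counts triads whose three members
share a non-zero module among triads with three non-zero assignments, with
a Fisher's exact TF vs non-TF contrast.

## Variants and mutation load

The filter cascade runs in a fixed order, logging counts after every
stage: canonical-CDS consequences only → drop splice-region co-annotations
→ drop missense without SIFT → drop sites with **strictly more than** 25%
missing calls → keep MAF ≥ 0.01 (computed over non-missing alleles only,
before any extreme-individual exclusion) → keep genes expressed > 0.5 tpm
somewhere → drop sites carrying any of the four region flags (the
exclusions apply jointly) → drop synonymous sites with more than one
annotation. Counts are monotone non-increasing by construction and by
test. Effect classes partition filtered SNPs: stop-gained; missense with
SIFT ≤ 0.05 deleterious, > 0.05 tolerated; synonymous.

Per-site diversity uses the unbiased pairwise estimator
π = 2j(n−j)/(n(n−1)) with n the called allele count and j the alternate
count, equal to the fraction of differing allele pairs (property-tested
against full enumeration). Mutation load per individual and category is
the homozygous-alternate count divided by the group's summed canonical
transcript length in kb — group totals over all TF (or non-TF) triad
genes, not per-gene lengths. Extreme individuals lie strictly outside the
inclusive-quantile (linear interpolation) 2.5%/97.5% bounds of any
group × category distribution; the definition is side-symmetric and
deterministic, and flag counts are sensitive to it, which is why it is
fixed here. SNPs whose every alternate-allele carrier is extreme are
dropped from the family-proportion plot only (families need > 10 triads
and ≥ 5 surviving SNPs). Group contrasts fit load ~ category + group by
OLS with a type-II ANOVA and Tukey HSD on the eight group × category
cells, reporting the four within-category TF vs non-TF contrasts and the
percent difference 100 × (load_nonTF − load_TF)/load_nonTF.

## Statistical conventions

Every test is two-sided; FDR is Benjamini–Hochberg. Mann–Whitney p-values
are exact — by full enumeration over labelings, so ties are handled — when
the combined sample size is ≤ 8 (configurable), otherwise the
tie-corrected normal approximation with continuity correction. Fisher's
exact two-sided p sums hypergeometric point probabilities ≤ the observed
one. Calibration: under simulated nulls the continuous-p tests (OLS slope,
asymptotic Mann–Whitney) reject at 5% within Monte-Carlo error; the exact
discrete tests are *valid* rather than calibrated — their size is at most
the nominal level, as is inherent to exact tests on discrete data — and
the test suite asserts exactly that.

## Parameter recovery

Recovery checks rerun the generator over ≥ 5 seeds at the study conditions
and require the mean recovered value to sit within three Monte-Carlo SDs
(the across-seed SD of the estimates) of the configured value.

* Triad probabilities (0.705/0.559) — classified triad counts over
  ground-truth group totals; binomial, unbiased. 20,000 groups per seed.
* Homoeolog correlation (0.9) — estimated on the log scale, where profiles
  are exactly bivariate normal: per-pair Pearson r of replicate-averaged
  log tpm, Olkin–Pratt small-sample correction
  `r(1 + (1−r²)/(2(T−3)))`, correction for the known replicate-noise
  attenuation `(s² + s_rep²/R)/s²`, family-wise averaging, then the forward
  lognormal map back to the tpm scale. The naive estimators (mean or
  Fisher-z median of tpm-scale r at T = 15) carry O(1/T) biases comparable
  to the Monte-Carlo SD, so an approximately unbiased instrument is the
  correct choice for recovery; the pipeline's reported statistic remains
  the Fisher-z median. ~200 triads per seed.
* Deleterious-load deficit (32%) — the full filter + classification + load
  path; the TF/non-TF rate ratio is preserved through every filter because
  the MAF spectrum and missingness are category-independent. 12,000 groups
  per seed; the estimate is noisy (the Σq² weighting is heavy-tailed) but
  unbiased.

## Known limitations

* The biological realism caveats above: no LD, no selection dynamics, no
  biased fractionation, per-SNP region flags.
* The hexaploid generator never produces A-less or B-less pairs (D is lost
  first), so "other"-class groups arise only from noise rows, not from the
  generator's core model.
* The exact Mann–Whitney enumerator is O(C(n, k)) and intended for the
  small-sample regime it defaults to.
* Percent-difference contrasts divide by the non-TF mean load and are
  unstable when a category is nearly empty (e.g. stop-gained sites in
  small cohorts).
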