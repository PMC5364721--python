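# Methods

## The panel registry

The unit of analysis is a curated registry of 163 angiogenesis-regulatory
genes in four functional groups — 26 transcription regulators (TR), 64
growth factors/receptors (GFR), 27 cytokines/chemokines (CC) and 46
proteases/inhibitors/others (PI) — with seven pro-angiogenic pathway gene
sets of sizes 6 (MAPK), 8 (PI3K-AKT), 10 (NOTCH), 5 (NF-κB), 4 (JAK-STAT),
14 (HIF-VEGF) and 6 (ANG-TIE), a three-way C/C classification (14
pro-angiogenic, 7 anti-angiogenic, 6 bi-functional) and receptor-class
annotations (EC-surface receptor, transcription factor, secreted factor)
for the 15 regulators of the thrombus-leukocyte phenotype.

The registry ships as per-species TSV fixtures (human upper-case, mouse
title-case symbols, resolved case-insensitively with a small alias table
for punctuated and legacy names such as IL-15, VEGFR2, PHD2, HIF1B).
Every gene set that is printed in full in the source literature — the 53
pathway members, the 15 thrombus regulators and their receptor classes,
the housekeeping and reference genes, the named abundant C/Cs and the
regression candidates — is transcribed verbatim and marked
`provenance=curated`. The remaining entries complete the published group
and category *counts* (which are enforced as invariants) with
field-standard angiogenesis genes and are marked `provenance=inferred`;
analyses that aggregate by group, category or pathway depend only on the
counts and on the curated members, not on the identity of inferred rows.
The TR-category field (inflammatory / homeostatic / EC-specific) is
populated only where the source names a TR explicitly (EPAS1 and HIF1A as
EC-specific hypoxia factors, JUN as homeostatic) and left `none`
elsewhere rather than guessed.

## Arbitrary-unit normalisation

For gene *g* and tissue *t* with TPM-like value *x*<sub>gt</sub>:

1. actin ratio r<sub>gt</sub> = x<sub>gt</sub> / x<sub>actin,t</sub>
   (β-actin must be strictly positive in every tissue);
2. AU<sub>gt</sub> = r<sub>gt</sub> / median<sub>t</sub>(r<sub>g·</sub>).

The even-count median is the mean of the two middle order statistics. A
zero median falls back to the median over strictly positive tissues; an
all-zero gene stays all-zero and is flagged unexpressed (it can never be
called high). There are no pseudocounts in this chain. Two invariances
follow and are property-tested: scaling one tissue's library (actin
included) and scaling one gene's row both leave AU unchanged.

## High-expression threshold

For each of the three housekeeping genes the upper limit of its expression
variation is mean + 2·SD of its AU row; the species threshold is the mean
of the three uppers, and a gene–tissue pair is highly expressed iff its AU
is **strictly** greater than the threshold ("larger than"). SD uses the
sample estimator (ddof = 1, config-exposed): tissue panels are small
(18–22), where the unbiased estimator is the conventional choice. The
published species defaults 3.63 (human) and 4.12 (mouse) derive from the
retired EST source and are kept as configuration constants only — nothing
in this package can or does recompute them.

## AP scoring, tiers and composition

AP(t) = 100 × (# panel genes high in t) / 163. Panel genes absent from an
input table count as not-high with the denominator fixed at 163 (keeping
APs comparable across tables; `ap.denominator=observed` is available for
sensitivity checks). Tissues are ranked by descending AP, ties broken by
tissue name so the partition is order-free, and split into contiguous
tiers of sizes ⌈n/3⌉ then a balanced remainder — 6/6/6 at n = 18, 8/7/7 at
n = 22. Composition reports counts and percent-of-high per functional
group; group-level AP uses the group size as denominator, and the
size-weighted mean of group APs recombines exactly to tissue AP.

## Pathway activity and C/C response rules

All decision rules are exact: pathway activity is evaluated as
3 × high_count ≥ pathway_size in integer arithmetic (fractions are carried
as exact rationals, never floats), which makes the minimal activating
count ⌈s/3⌉ for every size s; a tissue has active angiogenic signalling
when strictly more than 2 of the 7 pathways are active. A C/C is abundant
when it is high in strictly more tissues than the median over all 27 C/Cs;
a tissue is a high-responder when strictly more C/Cs are high there than
the median over tissues. Medians include zero-count rows (all rows are
tabulated, so all participate; `cc.median_scope=category` switches the
abundance median to within-category). Both calls are cross-checked against
literal sort-based brute-force reimplementations on random matrices.

## AP regression

Candidate master genes are regressed by OLS with expression (AU) as
response and AP (percent) as predictor; r² is the squared Pearson
correlation and p comes from the t statistic on the slope with n − 2
degrees of freedom (scipy's linregress; statsmodels OLS serves as the
independent oracle in tests). Significant genes (p < 0.05) are tiered by
r²: high at ≥ 0.4, low below 0.3, middle between. Only the high cut (0.4)
and one low-tier placement (r² = 0.2724) are anchored by the source; the
0.3 boundary is this package's default and is config-exposed
(`tiers.low_cut`). Group-level regression recomputes AP within each
functional group; a group with constant AP is omitted from the result
rather than failing the other groups.

## Differential comparison

Values are analysed on log2 scale; linear-scale matrices get log2(x + 1)
(microarray intensities sit above background, so a unit pseudocount is
innocuous). Scale is auto-detected (99th percentile < 30 and no values
below −30 ⇒ already log2) and can be declared to override. The default
per-gene test is Welch's t; the original workflow delegated to GEO2R,
whose moderated t is approximated by the `moderated` option: shrunken
variance s̃² = (d₀·s₀² + d·s²)/(d₀ + d) with d₀ = 4 by default and s₀² the
across-gene mean pooled variance, t referred to d₀ + d degrees of freedom.
As d₀ → 0 this reduces to the pooled (Student) t, which the tests verify
to 1e−9. Classification is up iff p < 0.05 and FC ≥ 2, down iff p < 0.05
and FC ≤ 0.5 (both gates inclusive), else unchanged; p-values are
unadjusted by default, with Benjamini–Hochberg available (`diff.fdr=bh`).
Groups require at least 3 samples each. Rollups report per-pathway up/down
lists, per-C/C-category counts over the fixed denominators 14/7/6, and a
receptor-class profile of the up set. The `ec_dominance` statistic — the
share of significant pathway-member changes lying in HIF-VEGF or ANG-TIE,
"dominant" above 0.5 — is this package's own operationalisation of an
EC-dominated response and is labelled as such in reports; with no
significant pathway-member changes it is reported as 0 with a
defined-flag cleared.

## Synthetic data

`simulate_est_table` draws per-gene-per-tissue EST tag counts from Poisson
distributions at a configurable library size (default 100 000 tags,
β-actin expectation 5 000 TPM), converts counts back to TPM, and boosts
planted (gene, tissue) pairs by a multiplicative factor. Housekeeping rows
carry a symmetric truncated-normal multiplier (mean 1) whose variance is
calibrated so the *total* across-tissue CV of the housekeeping AU —
multiplier plus the Poisson sampling of both the housekeeping and the
shared actin counts — equals `hk_cv`. Two deliberate choices make the
expected threshold exactly 1 + 2·hk_cv: a symmetric multiplier keeps mean
and median aligned (a log-normal multiplier's mean/median ratio
exp(σ²/2) would bias the recovered threshold upward by ~2 % at CV 0.2,
outside the Monte-Carlo band used for validation), and calibrating the
total rather than the multiplier-only CV absorbs the sampling floor. When
`hk_cv` is below that floor the multiplier is zero and the generator
reports the floor itself as the expected threshold (→ 1.0 as the library
grows). Planting a gene in more than half the tissues is rejected, since
its median would absorb the boost. An infeasible boost (≤ expected
threshold) is rejected.

`simulate_group_comparison` draws per-gene baselines N(8, 1.5²) on log2
scale, adds planted effects to cases, and adds N(0, noise_sd²) noise per
sample; defaults (n = 4 per group, noise SD 0.25, planted effect +2 log2)
mirror the small-sample microarray comparisons the pipeline targets.
`paperlike_fixture` bundles a 22-tissue table whose planted structure puts
muscle, heart, eye, lymph node and pancreas at the head of the high tier
with muscle first, and a comparison whose planted up set is exactly the 15
thrombus regulators. All generators take one explicit seed and are
bit-reproducible; no global random state is touched.

What the generators do *not* emulate: real tissue covariance, probe-level
microarray artifacts, batch effects, or the heavy-tailed dispersion of
real EST libraries. Passing recovery tests therefore demonstrates the
correctness and calibration of the *rules and statistics*, not the
biological fidelity of any particular AP ranking.

## Problem sizes and numerical choices

Validation experiments use 200 Monte-Carlo replicates for threshold
recovery (SE ≈ 0.003 at CV 0.2), 1 000 genes (500 planted) for
sensitivity/specificity and 10 000 null genes for type-I calibration —
sizes at which the binomial uncertainty of the measured rates is well
inside the acceptance bands. Exact-rational arithmetic is used wherever a
rule has a boundary (1/3 pathway rule); boundary comparisons are strict
exactly where the defining phrasing is strict ("larger than", "more than
the median", "more than two"), and inclusive where it is inclusive
(≥ 1/3, FC ≥ 2, FC ≤ 0.5). Degenerate inputs have defined behaviour:
zero-variance test rows give p = 1 under equal means, tissues with no high
genes report zero composition with an explicit empty flag, and constant
predictors are errors (single-gene regression) or omissions (group
regression).

## Known limitations

* The published thresholds 3.63/4.12 and the original EST-based AP tables
  cannot be regenerated (source retired); real-data entry points
  (expression TSV, GEO series-matrix reader) are provided but all shipped
  validation runs on synthetic or fixture data.
* Panel rows marked `provenance=inferred` are plausible stand-ins chosen
  to satisfy the published counts, not transcriptions.
* The moderated test is a two-parameter approximation of empirical-Bayes
  variance moderation (fixed prior d₀, mean-variance prior s₀²), not a
  full hyperparameter fit.
* No multiple-testing correction is applied by default, matching the
  emulated workflow; interpret single-comparison calls accordingly.
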