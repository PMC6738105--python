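# drivescan

Multi-cohort discovery of transcription-driver target genes, packaged as a
tested, reusable pipeline. The motivating use case is a chromatin regulator
(such as EZH2 in adrenocortical carcinoma) suspected of acting as a
transcriptional *activator* in partnership with a transcription factor
(such as E2F1): starting from per-cohort expression matrices, the pipeline

1. **screens** every gene for Pearson correlation with the driver in each
   cohort, controls the FDR per cohort (Benjamini–Hochberg), and intersects
   the discoveries across cohorts with a sign-consistency rule;
2. tests whether positively correlated genes **outnumber** negatively
   correlated ones (two-sided Fisher exact test on the 2×2 proportion
   table) — the signature of an activator rather than a repressor;
3. runs **pre-ranked GSEA** (implemented from scratch) over the correlation
   ranking against motif gene-set collections, with gene-label permutation,
   NES, collection-wide FDR and leading-edge extraction, then intersects the
   leading edges of the significant sets into a **core target list**;
4. scores each patient with a **metagene** (mean per-gene z-score over the
   core list) and evaluates prognosis: Kaplan–Meier curves and the log-rank
   test after median dichotomisation, plus univariate/multivariate **Cox**
   proportional-hazards regression (Breslow ties, Wald tests);
5. **nominates targets across species** by filtering a knockout
   differential-expression table (FDR < 0.1, |log2FC| > 1) and intersecting
   the down-regulated orthologs with the human positive list by case-folded
   gene symbol;
6. annotates ChIP-seq **peaks to genes** via ±2 kb windows (around the CDS
   span or the TSS) and reports the bound fraction of any query list;
7. provides the two wet-lab quantification formulas used in validation:
   ΔΔCt relative expression and ChIP-qPCR percent-of-input.

A synthetic-data module generates every input with the statistical
structure the analysis assumes — a latent-factor gene module with tunable
driver correlation ρ, proportional-hazards survival coupled to the module
metagene, gene-set collections with a planted core, a knockout DE table with
planted down-regulation, and peak files with designated bound genes — along
with a ground-truth manifest, so the whole pipeline is testable end to end
without any downloads.

## The statistics in brief

*Screen.* For gene *g* and driver *d* in one cohort, *r* = sample Pearson
coefficient, p two-sided via *t = r√((n−2)/(1−r²))* with *n−2* df,
*q* = BH step-up within the cohort. A gene is a positive (negative) hit at
threshold θ iff *q < θ* in **every** cohort with *r > 0* (*r < 0*)
everywhere. The activator test is Fisher exact on
`[[n_pos, N−n_pos], [n_neg, N−n_neg]]` over the N-gene testable universe.

*Pre-ranked GSEA.* Walking the ranked list, hits increment the running sum
by |r|ʷ/N_R (N_R = Σ over hits of |r|ʷ, default w = 1) and misses decrement
by 1/(N−N_H); ES is the signed maximal deviation. The null comes from
random same-size member draws; NES = ES / mean(|null ES| of the same sign);
q is the GSEA-style ratio of pooled-null to observed NES tail fractions.
The leading edge is the members at or before the peak (ES > 0).

*Survival.* Kaplan–Meier product-limit estimates; log-rank
χ² = (ΣO−E)²/ΣV with hypergeometric variance; Cox partial likelihood via
statsmodels (Breslow tie handling, Efron optional), with monotone-likelihood
detection.

## Worked example

```python
import drivescan as ds

config = ds.SimConfig(n_cohorts=3, n_genes=800, n_samples=100,
                      module_size=60, n_negative=10, seed=3)
bundle = ds.generate_bundle(config)

tables = [ds.correlate_with_driver(c, "EZH2") for c in bundle.cohorts]
inter = ds.intersect_cohorts(tables, fdr_threshold=0.001)
p = ds.sign_proportion_test(len(inter.positive_genes),
                            len(inter.negative_genes), inter.n_universe)

ranked = ds.RankedList.from_correlations(tables, combine="mean")
results = ds.analyze_collection(ranked, bundle.collection, n_perm=1000, seed=5)
core = ds.intersect_leading_edges(results, q_threshold=0.01)

score = ds.metagene_score(bundle.cohorts[0], core, mode="zmean")
table = bundle.survival.with_covariate(
    "metagene", score.scores.reindex(bundle.survival.data.index))
fit = ds.cox_fit(table, ["metagene"])

up, down = ds.filter_de(bundle.de_table)
nom = ds.intersect_targets(inter.positive_genes, down, mouse_de=bundle.de_table)
```

prints (via the obvious `print` statements):

```
60 positive / 10 negative of 799 testable genes
sign-proportion Fisher p = 3.57e-10
5 of 55 gene sets at FDR < 0.01: ['E2F_LIKE_1', ..., 'E2F_LIKE_5']
leading-edge core: 30 genes
Cox: log-HR = 0.65 (HR 1.92), Wald p = 0.00015
24 knockout-down genes -> 24 nominated targets
```

Reading: all 60 planted module genes (and only they) pass the three-cohort
screen at FDR 0.001; the positive excess over the 10 anti-correlated genes
is overwhelming; exactly the five planted motif sets are enriched and their
leading edges intersect to the planted 30-gene core; higher core-metagene
expression carries a hazard ratio of ≈1.9 per unit score, matching the
simulation's log-HR of 0.7; and the human–mouse symbol intersection
nominates exactly the planted knockout-responsive module genes.

## Command line

The same stages are available as subcommands of the `drivescan` console
script — `simulate`, `correlate`, `gsea`, `survive`, `targets`,
`annotate-peaks`, `qpcr`, and `run` (the full pipeline from a YAML config,
writing every intermediate artifact plus a JSON run manifest). See
`drivescan --help`.

## Layout

- `drivescan.formats` — validated readers/writers (expression TSV, GMT,
  survival TSV, DE TSV, BED/GTF); all intervals 0-based half-open internally
- `drivescan.synthetic` — the generators and ground-truth manifest
- `drivescan.correlation` — Pearson screen, BH, intersection, sign test
- `drivescan.gsea` — pre-ranked GSEA and leading-edge intersection
- `drivescan.survival` — metagene, KM, log-rank, Cox
- `drivescan.targets` — DE filtering, symbol intersection, Wilcoxon, ANOVA
- `drivescan.chip` — peak filtering, gene windows, binding matrix
- `drivescan.qpcr` — ΔΔCt and percent-of-input
- `drivescan.pipeline` / `drivescan.cli` — orchestration and CLI

`docs/methods.md` documents the models, parameter choices and limitations.
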