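# Methods

## Scope and data model

The package re-implements a multi-cohort driver-target discovery procedure
as a library plus CLI. Inputs are log2-scale genes × samples expression
matrices (one per cohort), GMT gene-set collections, per-sample survival
tables, a knockout differential-expression table and ChIP peak/gene-model
interval files. Nothing upstream of these (alignment, peak calling,
RMA/RSEM normalisation) is in scope; matrices are assumed already
normalised and log-transformed. All genomic intervals are converted to
0-based half-open coordinates at the I/O boundary (GTF's 1-based closed
convention included) and stay that way internally.

Missing expression values are accepted on input and handled
pairwise-complete in the correlation screen (the per-gene pair count is
reported and genes with fewer than three complete pairs are excluded from
the testing family). Metagene scoring refuses missing values outright: a
silently shrinking gene set would change the score's meaning, so the caller
must impute or drop first.

## Correlation screen

Per cohort, every non-driver gene is correlated with the driver (sample
Pearson r; two-sided p from the t-transform with n−2 df; |r| = 1 maps to
p = 0). The driver is excluded from its own table and from the BH family,
as are genes with undefined correlation (constant on complete pairs).
Benjamini–Hochberg runs within each cohort — the screen treats cohorts as
independent replications, and requiring q < θ in *every* cohort is the
replication criterion. Cross-cohort membership additionally requires a
consistent sign of r in all cohorts; genes passing the FDR gate with mixed
signs are counted in a diagnostic and dropped. Tightening θ can therefore
only shrink the lists (monotonicity, tested).

The activator-vs-repressor comparison is a two-sided Fisher exact test on
`[[n_pos, N−n_pos], [n_neg, N−n_neg]]`; a χ² two-proportion variant is
available (`method="chi2"`). Fisher is the default because on the published
screen counts (314/11 of 15,701) it reproduces the printed p-value to
within rounding, whereas the χ² variant does not.

## Pre-ranked GSEA

The enrichment score follows the weighted Kolmogorov–Smirnov-like running
sum: hits add |metric|^w / N_R, misses subtract 1/(N−N_H), ES is the signed
maximal deviation. Defaults and conventions:

- **w = 1** (the weighted scheme that is the long-standing GSEA default);
  w = 0 reduces exactly to the classical two-sample KS statistic on hit
  positions, which the tests verify against `scipy.stats.ks_2samp`.
- Ranking-metric **ties break lexicographically** by gene identifier, so a
  ranking is reproducible across platforms.
- **Peak ties**: the earliest peak for ES > 0, the latest trough for
  ES < 0; an exact ± magnitude tie resolves to the positive side.
- The null is **gene-label permutation** (random same-size member draws) —
  the only option in pre-ranked mode. Permutations use a vectorised
  candidate-point evaluation (the running sum is piecewise linear between
  hits, so its extrema occur only adjacent to hits); the O(N) running-sum
  path and the fast path agree to 1e-12 in magnitude, and may differ in
  sign only on one-ulp magnitude ties, which is immaterial to the null.
- **p_perm** is the one-sided tail frequency among same-sign null ES with a
  +1 pseudo-count; **NES** divides ES by the mean |null ES| of the same
  sign and is flagged unstable below 10 same-sign nulls. With 1,000
  permutations and a roughly sign-balanced null, the smallest attainable
  p_perm is about 2/1,000 — downstream selection therefore uses the FDR q,
  not p_perm.
- **q** is the standard GSEA FDR: the fraction of pooled null NES at least
  as extreme (same sign) divided by the fraction of observed NES at least
  as extreme, clipped to [0, 1]. BH on p_perm is available behind a flag.
- Per-set permutation streams are spawned from one seed
  (`numpy.random.SeedSequence`), so results are independent of set order
  and reproducible.

“Intersecting the leading edges” of the significant sets defaults to the
strict intersection (present in **all** selected leading edges) — with
heavily overlapping motif sets this is the rule that yields a compact core
rather than the union — and an at-least-k rule is available.

## Metagene and survival

The default metagene is the **z-mean**: per-gene within-cohort z-score,
then the per-sample mean over the listed genes. The plain mean of log2
values (`rawmean`) is provided, but cohorts profiled on different platforms
have incomparable per-gene scales, so the z-mean is the default and the
choice is recorded in the score's provenance. Zero-variance genes are
dropped with a warning in z-mean mode.

Median dichotomisation sends ties (score = median) to "low",
deterministically. Kaplan–Meier and the two-group log-rank test are
computed from their defining formulas (product-limit; χ² = (ΣO−E)²/ΣV with
hypergeometric variance at each distinct event time) and cross-checked
against lifelines in the tests. Cox regression maximises the partial
likelihood via statsmodels' PHReg with **Breslow** tie handling by default
(Efron behind a flag); the test suite checks the fit against a
definition-level Breslow partial-likelihood optimisation. Categorical
covariates are indicator-coded against their first level; the study's
named covariates (prognosis cluster, proliferation-marker group, histology
score, tumour stage) are ordinary columns with no special handling.
Monotone likelihood (perfect separation) is detected from runaway
coefficients (|β| > 20) or non-finite standard errors and raised as a
distinct error rather than reported as a huge hazard ratio.

## Cross-species nomination

The knockout table is filtered with strict inequalities (fdr < 0.1,
|logFC| > 1 by default — boundary values are excluded, matching the
convention that a printed "<" is strict), split by sign, and the
down-regulated genes are intersected with the human positive list by
case-folded symbol equality (upper-casing both sides). No orthology
database is consulted; genes whose mouse and human symbols diverge beyond
casing are missed, a documented limitation. Which human list feeds the
intersection (the full FDR < 0.001 positive list or the leading-edge core)
is configurable; the positive list is the default.

Group comparisons use the Wilcoxon rank-sum test (exact by enumeration when
min(n) ≤ 8 without ties, otherwise normal approximation with tie and
continuity corrections) and classical one-way ANOVA, both via scipy with
explicit degenerate-input handling (identical values in all groups → F = 0,
p = 1).

## Peak-to-gene annotation

Peaks carry their FDR in the BED score column and are filtered at a strict
0.05. Gene windows are the CDS span ± 2 kb by default, with a strand-aware
TSS ± 2 kb alternative — both conventions appear in practice and the anchor
is a flag, not a guess. A gene is bound iff at least one filtered peak
overlaps any of its windows by ≥ 1 bp in half-open coordinates (an abutting
peak does not bind); multiple models per gene contribute the union of their
windows. Overlap queries use an interval tree per chromosome.

## qPCR formulas

ΔΔCt relative expression: RQ = 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref) − (Ct_target,ctrl − Ct_ref,ctrl). ChIP
percent-of-input adjusts the input Ct by log2(1/input_fraction) and returns
100·2^(adjusted − Ct_IP). Both assume 100% amplification efficiency, the
comparative-Ct method's own assumption; efficiency-corrected quantification
is out of scope. Technical replicates are averaged on the Ct scale before
transformation.

## Synthetic data: what it emulates and what it does not

Each cohort draws one latent factor z ~ N(0,1) per sample; the driver is
z + ε and each module gene a·z + ε with ε ~ N(0, σ²), σ = 1 by default. The
loading a is solved from corr(gene, driver) = a/√(a²+σ²) · 1/√(1+σ²) = ρ,
so the requested ρ is the *population* gene–driver correlation; the
driver's own noise caps attainable ρ at 1/√(1+σ²) ≈ 0.71 at σ = 1, and the
config rejects unattainable requests. Anti-correlated genes use −a (so the
sign-proportion table is non-degenerate), background genes are independent
noise of matched variance, and per-gene baselines differ by cohort
(emulating platform offsets). Default conditions — 3 cohorts × 200 samples,
5,000 genes, a 100-gene module at ρ = 0.6 with 20 negative genes — are the
screening setting the pipeline targets.

Survival times are exponential with rate λ·exp(β·score) (λ = 0.02 per
month, β = 0.7 per unit metagene by default); an exponential baseline is the
simplest proportional-hazards-satisfying choice and the log-rank/Cox
contracts are shape-free. Censoring is uniform on (0, m) with m calibrated
by root-finding so the expected censoring fraction matches the requested
rate (0.3 by default).

Gene-set collections plant a known core (half the module, capped at 50)
shared by several signal sets that otherwise differ (per-set module extras
and random background members), plus background-only decoy sets — so strict
leading-edge intersection should return exactly the core. The knockout
table plants logFC ≤ −1.5 at fdr < 0.09 for a random 40% of the module
(mouse symbols are capitalised human symbols; a few mouse-only genes
exercise the name intersection), with null genes drawn so they can never
pass the filter. Peaks are placed wholly inside the ±2 kb CDS windows of
designated bound genes with FDR < 0.05, alongside far-away decoys and
above-threshold peaks in other windows.

Deliberately **not** emulated: microarray probe effects, batch effects,
count-level noise, gene–gene correlation beyond the single module factor,
informative censoring, competing risks, and orthology beyond symbol casing.
Passing tests therefore demonstrate the correctness of the statistical
machinery and the pipeline's ability to recover planted structure under its
own assumptions — not robustness to the messiness of real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full bundle at the default
study scale (3 × 200 × 5,000; 55 gene sets at 1,000 permutations), 2,000
null log-rank simulations at n = 60, and 200 Cox-recovery simulations at
n = 500 — sizes chosen so the planted-structure checks are comfortably
powered while the whole suite completes in well under a minute of compute
per component. Tolerances: exact identities (running-sum conservation,
oracle equivalences) at 1e-9–1e-12; Monte-Carlo quantities at bands implied
by their sampling variance (e.g. log-rank type-I error within [0.035,
0.065] over 2,000 replicates). BH, Fisher, Wilcoxon, ANOVA and Cox fits
delegate to scipy/statsmodels; every one of them is checked against a
definition-level oracle (step-up recursion, hypergeometric enumeration,
rank-sum enumeration, explicit sums of squares, brute-force partial
likelihood) in the tests, keeping the implementation and verification
routes independent.

## Known limitations

- Pre-ranked mode only; phenotype (sample-permutation) GSEA and ssGSEA are
  out of scope.
- No proportional-hazards diagnostics, time-varying covariates or competing
  risks.
- Symbol-equality orthology misses renamed genes.
- The per-cohort BH + all-cohort intersection rule is conservative relative
  to meta-analytic alternatives; a pooled-BH variant
  (`intersect_cohorts(..., bh_scope="pooled")`) re-adjusts all cohorts'
  p-values as one family, but cross-cohort dependence modelling is not
  attempted.
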