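"""Synthetic inputs with the statistical structure the pipeline assumes.

One latent factor per sample drives a correlated gene module: the driver
gene is ``z + noise`` and each module gene ``a*z + noise`` with the loading
``a`` solved from the factor-model identity ``corr(gene, driver) =
a/sqrt(a^2 + sigma^2) * 1/sqrt(1 + sigma^2)`` so the population correlation
with the driver equals the requested rho.  Anti-correlated genes use ``-a``;
background genes are independent noise of matched variance.  Survival times
follow an exponential proportional-hazards model coupled to a metagene
score, with uniform censoring calibrated to the requested censoring rate.
Gene-set, knockout-DE and ChIP-peak generators plant known structure and
record it on a truth object so every downstream stage can be scored against
ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ValidationError
from .formats import (
    DETable,
    ExpressionCohort,
    GeneSet,
    GeneSetCollection,
    GenomicInterval,
    SurvivalTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalParams",
    "SimConfig",
    "SimTruth",
    "gen_cohorts",
    "gen_survival",
    "gen_gmt",
    "gen_mouse_de",
    "gen_gene_models",
    "gen_peaks",
    "generate_bundle",
]


@dataclass
class SurvivalParams:
    baseline_hazard: float = 0.02   # events per month at metagene score 0
    log_hr: float = 0.7             # log hazard ratio per unit metagene
    censoring_rate: float = 0.3

    def validate(self):
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must lie in [0, 1)")


@dataclass
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror the screening setting the pipeline targets: three
    cohorts of 200 samples over 5,000 genes sharing a 100-gene module
    correlated with the driver at rho = 0.6, with 20 anti-correlated genes.
    """

    n_cohorts: int = 3
    n_genes: int = 5000
    n_samples: int = 200
    module_size: int = 100
    n_negative: int = 20
    driver_name: str = "EZH2"
    target_correlation: float = 0.6
    noise_sd: float = 1.0
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    seed: int = 0

    def validate(self):
        if self.module_size + self.n_negative >= self.n_genes:
            raise ValidationError("module_size + n_negative must be < n_genes")
        rho = self.target_correlation
        if not 0 <= rho < 1:
            raise ValidationError("target correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if rho * math.sqrt(1 + self.noise_sd**2) >= 1:
            raise ValidationError(
                f"rho={rho} unattainable at noise_sd={self.noise_sd}: the driver's "
                "reliability caps the achievable gene-driver correlation"
            )
        if self.n_samples < 4 or self.n_cohorts < 1:
            raise ValidationError("need >=1 cohort and >=4 samples")
        self.survival.validate()

    def loading(self) -> float:
        """Module-gene loading ``a`` achieving the target correlation."""
        rho, sd = self.target_correlation, self.noise_sd
        if rho == 0:
            return 0.0
        c = rho * math.sqrt(1 + sd**2)  # required corr(gene, latent)
        return sd * c / math.sqrt(1 - c**2)


@dataclass
class SimTruth:
    """Ground-truth manifest for a synthetic bundle."""

    driver: str
    module_genes: list[str]
    negative_genes: list[str]
    background_genes: list[str]
    latent: dict[str, np.ndarray] = field(default_factory=dict)
    core_genes: list[str] = field(default_factory=list)
    ko_down: list[str] = field(default_factory=list)
    ko_up: list[str] = field(default_factory=list)
    bound_genes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["latent"] = {k: list(map(float, v)) for k, v in self.latent.items()}
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        payload["latent"] = {k: np.array(v) for k, v in payload.get("latent", {}).items()}
        return cls(**payload)


def _gene_universe(config: SimConfig, rng: np.random.Generator):
    others = np.array([f"GENE{i:05d}" for i in range(config.n_genes - 1)], dtype=object)
    rng.shuffle(others)
    module = sorted(others[: config.module_size])
    negative = sorted(others[config.module_size: config.module_size + config.n_negative])
    background = sorted(others[config.module_size + config.n_negative:])
    return module, negative, background


def gen_cohorts(config: SimConfig) -> tuple[list[ExpressionCohort], SimTruth]:
    """Generate the per-cohort expression matrices and the truth manifest.

    All cohorts share one gene universe; each has its own latent factor,
    noise and per-gene baseline (emulating platform differences).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_cohorts + 1)
    assign_rng = np.random.default_rng(streams[0])
    module, negative, background = _gene_universe(config, assign_rng)
    truth = SimTruth(
        driver=config.driver_name,
        module_genes=module,
        negative_genes=negative,
        background_genes=background,
    )
    a = config.loading()
    sd = config.noise_sd
    sd_bg = math.sqrt(a**2 + sd**2)  # match module-gene marginal variance

    genes = [config.driver_name, *module, *negative, *background]
    cohorts = []
    for ci in range(config.n_cohorts):
        rng = np.random.default_rng(streams[ci + 1])
        cohort_id = f"cohort{ci + 1}"
        n = config.n_samples
        z = rng.standard_normal(n)
        rows = np.empty((len(genes), n))
        rows[0] = z + rng.normal(0, sd, n)
        k = 1
        for _ in module:
            rows[k] = a * z + rng.normal(0, sd, n)
            k += 1
        for _ in negative:
            rows[k] = -a * z + rng.normal(0, sd, n)
            k += 1
        rows[k:] = rng.normal(0, sd_bg, (len(background), n))
        baselines = rng.normal(8.0, 1.5, len(genes))
        rows += baselines[:, None]
        samples = [f"{cohort_id}_S{j:04d}" for j in range(n)]
        df = pd.DataFrame(rows, index=genes, columns=samples)
        cohorts.append(ExpressionCohort(cohort_id=cohort_id, values=df))
        truth.latent[cohort_id] = z
    return cohorts, truth


def _censoring_horizon(rates: np.ndarray, target: float) -> float:
    """Upper bound m of Uniform(0, m) censoring giving the requested mean
    censoring probability against exponential event times."""

    def mean_censor_prob(m):
        x = rates * m
        return float(np.mean((1 - np.exp(-x)) / x)) - target

    lo, hi = 1e-9, 1.0
    while mean_censor_prob(hi) > 0:
        hi *= 2
        if hi > 1e12:
            raise ValidationError("cannot calibrate censoring horizon")
    return optimize.brentq(mean_censor_prob, lo, hi)


def gen_survival(metagene_scores: pd.Series, config: SimConfig,
                 rng: np.random.Generator | None = None) -> SurvivalTable:
    """Exponential proportional-hazards event times coupled to a score.

    ``T_i ~ Exponential(lambda * exp(beta * score_i))`` with independent
    Uniform(0, m) censoring, m calibrated so the expected censoring
    fraction matches ``config.survival.censoring_rate``.
    """
    config.survival.validate()
    scores = pd.Series(metagene_scores, dtype=float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ValidationError("metagene scores must be finite")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 777]))
    sp = config.survival
    rates = sp.baseline_hazard * np.exp(sp.log_hr * scores.to_numpy())
    T = rng.exponential(1.0 / rates)
    if sp.censoring_rate == 0:
        time, event = T, np.ones(len(T), dtype=bool)
    else:
        m = _censoring_horizon(rates, sp.censoring_rate)
        C = rng.uniform(0, m, len(T))
        event = T <= C
        time = np.minimum(T, C)
    df = pd.DataFrame({"time": time, "event": event}, index=scores.index)
    return SurvivalTable(df)


def gen_gmt(truth: SimTruth, n_decoy_sets: int = 50,
            overlap_profile: tuple[int, ...] = (10, 10, 10, 10, 10),
            seed: int = 0, core_size: int | None = 50,
            background_per_set: int = 40,
            decoy_size: int = 50) -> tuple[GeneSetCollection, list[str]]:
    """Gene-set collection with planted signal sets sharing a known core.

    Each signal set (one per ``overlap_profile`` entry) contains the full
    planted core, the stated number of set-specific extra module genes, and
    random background members; decoy sets are background-only and mutually
    disjoint while the background lasts.  The planted core is recorded on
    ``truth.core_genes`` and also returned.
    """
    rng = np.random.default_rng(seed)
    module = list(truth.module_genes)
    background = list(truth.background_genes)
    collection = GeneSetCollection()

    core: list[str] = []
    if overlap_profile:
        if core_size is None:
            core_size = max(1, min(50, len(module) // 2))
        if core_size > len(module):
            raise ValidationError("core_size exceeds module size")
        core = sorted(rng.choice(module, size=core_size, replace=False))
        extras_pool = [g for g in module if g not in set(core)]
        rng.shuffle(extras_pool)
        cap = len(extras_pool) // len(overlap_profile)
        if any(n > cap for n in overlap_profile):
            logger.info("overlap_profile capped at %d extras per set", cap)
            overlap_profile = tuple(min(n, cap) for n in overlap_profile)
        offset = 0
        for si, n_extra in enumerate(overlap_profile, start=1):
            extras = extras_pool[offset: offset + n_extra]
            offset += n_extra
            bg = list(rng.choice(background, size=background_per_set, replace=False))
            members = tuple(core) + tuple(extras) + tuple(bg)
            collection.add(GeneSet(
                name=f"E2F_LIKE_{si}",
                description=f"planted motif set {si}: shared core + {n_extra} extras",
                members=members,
            ))

    decoy_pool = background.copy()
    rng.shuffle(decoy_pool)
    for di in range(1, n_decoy_sets + 1):
        if len(decoy_pool) >= decoy_size:
            members = tuple(decoy_pool[:decoy_size])
            decoy_pool = decoy_pool[decoy_size:]
        else:  # background exhausted: sample with overlap
            members = tuple(rng.choice(background, size=decoy_size, replace=False))
        collection.add(GeneSet(
            name=f"DECOY_SET_{di:02d}",
            description="background-only decoy set",
            members=members,
        ))
    truth.core_genes = list(core)
    return collection, list(core)


def _mouse_symbol(human: str) -> str:
    return human.capitalize()


def gen_mouse_de(truth: SimTruth, effect_logfc: float = 1.5, fdr_alpha: float = 0.1,
                 seed: int = 0, down_fraction: float = 0.4,
                 n_up_decoys: int = 10) -> DETable:
    """Knockout DE table in which a subset of module orthologs is planted
    down-regulated (logFC <= -effect, fdr < alpha) against a null background.

    Mouse symbols are the capitalised human symbols.  The planted down and
    up gene lists are recorded on ``truth.ko_down`` / ``truth.ko_up`` using
    the human casing.
    """
    if effect_logfc <= 0 or not 0 < fdr_alpha < 1:
        raise ValidationError("effect_logfc must be > 0 and fdr_alpha in (0, 1)")
    rng = np.random.default_rng(seed)
    module = list(truth.module_genes)
    n_down = max(1, int(round(down_fraction * len(module))))
    down = sorted(rng.choice(module, size=n_down, replace=False))
    up_pool = list(truth.background_genes)
    up = sorted(rng.choice(up_pool, size=n_up_decoys, replace=False)) if n_up_decoys else []

    rows = {}
    human_genes = [truth.driver, *truth.module_genes, *truth.negative_genes,
                   *truth.background_genes]
    down_set, up_set = set(down), set(up)
    for g in human_genes:
        m = _mouse_symbol(g)
        if g in down_set:
            lfc = -(effect_logfc + rng.exponential(0.5))
            fdr = rng.uniform(0, 0.9) * fdr_alpha
        elif g in up_set:
            lfc = effect_logfc + rng.exponential(0.5)
            fdr = rng.uniform(0, 0.9) * fdr_alpha
        else:
            lfc = rng.normal(0, 0.25)
            fdr = rng.uniform(fdr_alpha, 1.0)  # null genes never pass the filter
        rows[m] = (lfc, fdr)
    # mouse-only genes with no human counterpart (exercise name intersection)
    for i in range(20):
        rows[f"Gm{90000 + i}"] = (rng.normal(0, 0.25), rng.uniform(fdr_alpha, 1.0))

    df = pd.DataFrame.from_dict(rows, orient="index", columns=["logFC", "fdr"])
    df.index.name = "gene"
    truth.ko_down = list(down)
    truth.ko_up = list(up)
    return DETable(df)


def gen_gene_models(genes, seed: int = 0, genes_per_chrom: int = 500,
                    spacing: int = 10000, cds_len: int = 2000) -> list[GenomicInterval]:
    """Lay genes out along synthetic chromosomes with non-overlapping
    +/-2 kb windows (spacing > cds_len + 2*pad)."""
    rng = np.random.default_rng(seed)
    models = []
    for i, g in enumerate(genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        start = 5000 + (i % genes_per_chrom) * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GenomicInterval(
            chrom=chrom, start=start, end=start + cds_len,
            strand=strand, name=g,
        ))
    return models


def gen_peaks(bound_genes, gene_models: list[GenomicInterval], seed: int = 0,
              pad: int = 2000, n_decoy_far: int = 20,
              n_high_fdr: int = 10) -> list[GenomicInterval]:
    """ChIP peaks: one significant peak (score/FDR < 0.05) inside the
    +/-pad CDS window of every designated bound gene, plus far-away decoy
    peaks and peaks failing the FDR filter inside windows of unbound genes."""
    rng = np.random.default_rng(seed)
    by_name = {m.name: m for m in gene_models}
    bound = list(bound_genes)
    missing = [g for g in bound if g not in by_name]
    if missing:
        raise ValidationError(f"bound genes without gene models: {missing[:5]}")
    peaks = []
    for g in bound:
        m = by_name[g]
        lo = max(0, m.start - pad)
        hi = m.end + pad
        width = int(rng.integers(150, 400))
        start = int(rng.integers(lo, hi - width))
        peaks.append(GenomicInterval(
            chrom=m.chrom, start=start, end=start + width,
            name=f"peak_{g}", score=float(rng.uniform(0.001, 0.049)),
        ))
    unbound = [m for m in gene_models if m.name not in set(bound)]
    rng.shuffle(unbound)
    for m in unbound[:n_high_fdr]:
        width = int(rng.integers(150, 400))
        start = max(0, m.start - pad // 2)
        peaks.append(GenomicInterval(
            chrom=m.chrom, start=start, end=start + width,
            name=f"weakpeak_{m.name}", score=float(rng.uniform(0.05, 0.5)),
        ))
    for i in range(n_decoy_far):
        start = int(rng.integers(1000, 10_000_000))
        peaks.append(GenomicInterval(
            chrom="chrZ", start=start, end=start + 200,
            name=f"farpeak_{i}", score=float(rng.uniform(0.001, 0.049)),
        ))
    return peaks


@dataclass
class SyntheticBundle:
    """All pipeline inputs for one simulated study, plus ground truth."""

    config: SimConfig
    cohorts: list[ExpressionCohort]
    truth: SimTruth
    collection: GeneSetCollection
    survival: SurvivalTable
    de_table: DETable
    gene_models: list[GenomicInterval]
    peaks: list[GenomicInterval]


def generate_bundle(config: SimConfig | None = None, n_bound: int = 40,
                    **gmt_kwargs) -> SyntheticBundle:
    """Generate every pipeline input from one config/seed.

    Survival is coupled to the z-mean metagene of the true module in the
    first cohort; ChIP peaks are planted in the windows of a random subset
    of the core genes (all of the core if smaller than ``n_bound``).
    """
    from .survival import metagene_score

    config = config or SimConfig()
    config.validate()
    cohorts, truth = gen_cohorts(config)
    root = np.random.SeedSequence([config.seed, 2024])
    s_gmt, s_de, s_models, s_peaks, s_surv, s_bound = (
        np.random.default_rng(c) for c in root.spawn(6)
    )
    gmt_kwargs.setdefault("core_size", None)  # adapt the core to the module size
    collection, core = gen_gmt(truth, seed=int(s_gmt.integers(2**31)), **gmt_kwargs)

    score = metagene_score(cohorts[0], truth.module_genes, mode="zmean",
                           gene_list_id="true_module")
    survival = gen_survival(score.scores, config, rng=s_surv)

    de_table = gen_mouse_de(truth, seed=int(s_de.integers(2**31)))

    all_genes = [truth.driver, *truth.module_genes, *truth.negative_genes,
                 *truth.background_genes]
    gene_models = gen_gene_models(all_genes, seed=int(s_models.integers(2**31)))
    pool = core if core else truth.module_genes
    n_bound = min(n_bound, len(pool))
    bound = sorted(s_bound.choice(pool, size=n_bound, replace=False))
    truth.bound_genes = list(bound)
    peaks = gen_peaks(bound, gene_models, seed=int(s_peaks.integers(2**31)))

    return SyntheticBundle(
        config=config, cohorts=cohorts, truth=truth, collection=collection,
        survival=survival, de_table=de_table, gene_models=gene_models,
        peaks=peaks,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, object]:
    """Write every bundle artifact under ``outdir``; returns the path map."""
    from pathlib import Path

    from .formats import (
        write_bed, write_de_table, write_expression, write_gmt, write_survival,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {"expression": {}}
    for cohort in bundle.cohorts:
        p = outdir / f"expression_{cohort.cohort_id}.tsv"
        write_expression(cohort, p)
        paths["expression"][cohort.cohort_id] = str(p)
    for key, writer, obj, fname in [
        ("gmt", write_gmt, bundle.collection, "gene_sets.gmt"),
        ("survival", write_survival, bundle.survival, "survival.tsv"),
        ("de_table", write_de_table, bundle.de_table, "mouse_de.tsv"),
        ("gene_models", write_bed, bundle.gene_models, "gene_models.bed"),
        ("peaks", write_bed, bundle.peaks, "peaks.bed"),
    ]:
        p = outdir / fname
        writer(obj, p)
        paths[key] = str(p)
    truth_path = outdir / "truth.json"
    truth_path.write_text(bundle.truth.to_json())
    paths["truth"] = str(truth_path)
    return paths
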