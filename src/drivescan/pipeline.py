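"""Full-pipeline orchestration from a single structured config.

Stages run in order — correlate, gsea, survive, targets, annotate-peaks —
each writing its intermediate artifacts under the output directory, and a
machine-readable manifest records parameters, seeds and every summary
statistic.  A stage failure aborts with the stage name; whatever manifest
content exists at that point is retained with a ``.partial`` suffix.
Default thresholds: correlation FDR 0.001, gene-set FDR 0.01, knockout DE
FDR 0.1 with |logFC| > 1, peak FDR 0.05, +/-2 kb windows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import PipelineError, ValidationError
from . import formats
from .correlation import correlate_with_driver, intersect_cohorts, sign_proportion_test
from .gsea import RankedList, analyze_collection, intersect_leading_edges
from .survival import cox_fit, dichotomize_median, km_estimate, logrank_test, metagene_score
from .targets import filter_de, intersect_targets
from .chip import binding_matrix, binding_summary, filter_peaks

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs: input paths and parameters."""

    expression: dict[str, str]          # cohort_id -> TSV path
    gmt: str
    driver: str = "EZH2"
    survival: str | None = None
    de_table: str | None = None
    peaks: dict[str, str] = field(default_factory=dict)  # dataset -> BED path
    gene_models: str | None = None
    outdir: str = "drivescan_out"

    fdr_correlation: float = 0.001
    fdr_geneset: float = 0.01
    fdr_de: float = 0.1
    min_abs_logfc: float = 1.0
    fdr_peaks: float = 0.05
    pad: int = 2000
    anchor: str = "cds"
    gsea_weight: float = 1.0
    n_perm: int = 1000
    metagene_mode: str = "zmean"
    human_list: str = "positive"        # or "core"
    covariates: list[str] = field(default_factory=list)
    sign_test_method: str = "fisher"
    seed: int = 0

    def validate(self):
        for name, value in [
            ("fdr_correlation", self.fdr_correlation),
            ("fdr_geneset", self.fdr_geneset),
            ("fdr_de", self.fdr_de),
            ("fdr_peaks", self.fdr_peaks),
        ]:
            if not 0 < value < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.human_list not in ("positive", "core"):
            raise ValidationError("human_list must be 'positive' or 'core'")
        if int(self.seed) != self.seed:
            raise ValidationError("seed must be an integer")
        paths = [*self.expression.values(), self.gmt, self.survival,
                 self.de_table, self.gene_models, *self.peaks.values()]
        for p in paths:
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON-serialisable: {type(value)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
        "stages": [],
    }

    def fail(stage: str, exc: Exception):
        partial = outdir / "manifest.partial.json"
        _write_json(manifest, partial)
        raise PipelineError(stage, exc) from exc

    # --- load -------------------------------------------------------------
    try:
        config.validate()
        cohorts = [formats.read_expression(p, cid) for cid, p in config.expression.items()]
        collection = formats.read_gmt(config.gmt)
        survival_table = formats.read_survival(config.survival) if config.survival else None
        de_table = formats.read_de_table(config.de_table) if config.de_table else None
        gene_models = (formats.read_gene_models(config.gene_models)
                       if config.gene_models else None)
        peak_sets = {name: formats.read_bed(p) for name, p in config.peaks.items()}
    except Exception as exc:
        fail("load", exc)
    manifest["stages"].append("load")

    # --- correlate ----------------------------------------------------------
    try:
        tables = [correlate_with_driver(c, config.driver) for c in cohorts]
        for t in tables:
            t.table.to_csv(outdir / f"correlation_{t.cohort_id}.tsv", sep="\t",
                           index_label="gene")
        inter = intersect_cohorts(tables, config.fdr_correlation)
        inter.records.to_csv(outdir / "intersection_records.tsv", sep="\t", index=False)
        sign_p = sign_proportion_test(
            len(inter.positive_genes), len(inter.negative_genes), inter.n_universe,
            method=config.sign_test_method,
        )
        manifest["correlation"] = {
            "n_positive": len(inter.positive_genes),
            "n_negative": len(inter.negative_genes),
            "n_universe": inter.n_universe,
            "n_mixed_sign": inter.n_mixed_sign,
            "sign_test_p": sign_p,
            "positive_genes": inter.positive_genes,
            "negative_genes": inter.negative_genes,
        }
    except Exception as exc:
        fail("correlate", exc)
    manifest["stages"].append("correlate")

    # --- gsea ---------------------------------------------------------------
    try:
        ranked = RankedList.from_correlations(tables, combine="mean")
        results = analyze_collection(
            ranked, collection, n_perm=config.n_perm, w=config.gsea_weight,
            seed=config.seed,
        )
        import pandas as pd
        pd.DataFrame([
            {"set": r.set_name, "ES": r.es, "NES": r.nes, "p_perm": r.p_perm,
             "q_fdr": r.q_fdr, "leading_edge_size": len(r.leading_edge)}
            for r in results
        ]).to_csv(outdir / "gsea_results.tsv", sep="\t", index=False)
        core = intersect_leading_edges(results, q_threshold=config.fdr_geneset)
        (outdir / "core_genes.txt").write_text("\n".join(core) + "\n")
        manifest["gsea"] = {
            "n_sets_tested": len(results),
            "n_sets_significant": int(sum(r.q_fdr < config.fdr_geneset for r in results)),
            "core_size": len(core),
            "core_genes": core,
        }
    except Exception as exc:
        fail("gsea", exc)
    manifest["stages"].append("gsea")

    # --- survive ------------------------------------------------------------
    if survival_table is not None:
        try:
            gene_list = core if core else inter.positive_genes
            scored = None
            for cohort in cohorts:
                shared = [s for s in survival_table.sample_ids if s in cohort.values.columns]
                if len(shared) >= 10:
                    score = metagene_score(cohort, gene_list, mode=config.metagene_mode,
                                           gene_list_id="core")
                    scored = (cohort.cohort_id, score)
                    break
            if scored is None:
                raise ValidationError("no cohort shares >=10 samples with the survival table")
            cohort_id, score = scored
            table = survival_table
            aligned = score.scores.reindex(table.data.index).dropna()
            table = formats.SurvivalTable(table.data.loc[aligned.index])
            table = table.with_covariate("metagene", aligned)
            groups = dichotomize_median(aligned)
            hi = groups == "high"
            chi2, logrank_p = logrank_test(
                table.times[hi.to_numpy()], table.events[hi.to_numpy()],
                table.times[~hi.to_numpy()], table.events[~hi.to_numpy()],
            )
            km_hi = km_estimate(table.times[hi.to_numpy()], table.events[hi.to_numpy()])
            km_lo = km_estimate(table.times[~hi.to_numpy()], table.events[~hi.to_numpy()])
            import pandas as pd
            pd.concat([
                pd.DataFrame({"time": km.times, "survival": km.survival,
                              "at_risk": km.at_risk, "group": label})
                for km, label in [(km_hi, "high"), (km_lo, "low")]
            ]).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
            fit = cox_fit(table, ["metagene", *config.covariates])
            pd.DataFrame({
                "coef": fit.coef, "HR": fit.hr, "se": fit.se,
                "wald_z": fit.wald_z, "wald_p": fit.wald_p,
            }).to_csv(outdir / "cox_fit.tsv", sep="\t", index_label="covariate")
            manifest["survival"] = {
                "cohort": cohort_id,
                "n": fit.n,
                "n_events": fit.n_events,
                "logrank_chi2": chi2,
                "logrank_p": logrank_p,
                "cox_metagene_coef": float(fit.coef["metagene"]),
                "cox_metagene_hr": float(fit.hr["metagene"]),
                "cox_metagene_wald_p": float(fit.wald_p["metagene"]),
            }
        except Exception as exc:
            fail("survive", exc)
        manifest["stages"].append("survive")

    # --- targets ------------------------------------------------------------
    if de_table is not None:
        try:
            up, down = filter_de(de_table, fdr_max=config.fdr_de,
                                 min_abs_logfc=config.min_abs_logfc)
            human = inter.positive_genes if config.human_list == "positive" else core
            logger.info("cross-species intersection uses the %s human list "
                        "(%d genes)", config.human_list, len(human))
            nomination = intersect_targets(human, down, human_records=inter.records,
                                           mouse_de=de_table)
            nomination.table.to_csv(outdir / "nominated_targets.tsv", sep="\t")
            manifest["targets"] = {
                "n_mouse_up": len(up),
                "n_mouse_down": len(down),
                "human_list": config.human_list,
                "nominated": nomination.genes,
            }
        except Exception as exc:
            fail("targets", exc)
        manifest["stages"].append("targets")

    # --- annotate-peaks -------------------------------------------------------
    if peak_sets and gene_models is not None:
        try:
            filtered = {name: filter_peaks(p, fdr_max=config.fdr_peaks)
                        for name, p in peak_sets.items()}
            bm = binding_matrix(filtered, gene_models, pad=config.pad,
                                anchor=config.anchor)
            bm.matrix.astype(int).to_csv(outdir / "binding_matrix.tsv", sep="\t")
            summary = binding_summary(bm, core if core else inter.positive_genes)
            summary.to_csv(outdir / "binding_summary.tsv", sep="\t")
            manifest["binding"] = {
                ds: {"n_bound": int(row["n_bound"]), "n_query": int(row["n_query"]),
                     "fraction": float(row["fraction"])}
                for ds, row in summary.iterrows()
            }
        except Exception as exc:
            fail("annotate-peaks", exc)
        manifest["stages"].append("annotate-peaks")

    _write_json(manifest, outdir / "manifest.json")
    return manifest
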