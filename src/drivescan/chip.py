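"""Peak-to-gene binding annotation.

Peaks surviving a strict FDR filter (score column interpreted as peak FDR,
``< 0.05`` by default) are assigned to genes whose +/-2 kb window they
overlap by at least 1 bp in half-open coordinates.  Two window anchors are
supported: the CDS span padded on both sides (default) and a strand-aware
window around the TSS.  Multiple models per gene contribute the union of
their windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .formats import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "BindingMatrix",
    "filter_peaks",
    "gene_window",
    "annotate_binding",
    "binding_matrix",
    "binding_summary",
]


@dataclass
class BindingMatrix:
    """Boolean genes x datasets binding calls with supporting peaks.

    ``matrix`` is a DataFrame (index gene, columns dataset names, bool);
    ``support[(gene, dataset)]`` lists the peaks that made the call.
    """

    matrix: pd.DataFrame
    support: dict[tuple[str, str], list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self):
        for (gene, dataset), peaks in self.support.items():
            if not peaks:
                raise ValidationError("support entries must carry >=1 peak")
        for col in self.matrix.columns:
            for gene in self.matrix.index[self.matrix[col]]:
                if not self.support.get((gene, col)):
                    raise ValidationError(
                        f"gene {gene!r} marked bound in {col!r} without a supporting peak"
                    )

    def bound_genes(self, dataset: str) -> list[str]:
        return sorted(self.matrix.index[self.matrix[dataset]])


def filter_peaks(peaks: list[GenomicInterval], fdr_max: float = 0.05) -> list[GenomicInterval]:
    """Keep peaks with score (FDR) strictly below ``fdr_max``."""
    out = []
    for p in peaks:
        if math.isnan(p.score):
            raise ValidationError(
                f"peak {p.name or p.chrom + ':' + str(p.start)} has no score; the "
                "5th BED column must carry the peak FDR for filtering"
            )
        if p.score < fdr_max:
            out.append(p)
    return out


def gene_window(gene_model: GenomicInterval, pad: int = 2000,
                anchor: str = "cds") -> GenomicInterval:
    """The +/-pad regulatory window of one gene model, clipped at 0.

    ``anchor='cds'`` pads the whole CDS span; ``anchor='tss'`` takes a
    strand-aware window around the transcription start (model start on the
    + strand, model end on the - strand).
    """
    if pad < 0:
        raise ValidationError("pad must be non-negative")
    if anchor == "cds":
        start, end = gene_model.start - pad, gene_model.end + pad
    elif anchor == "tss":
        if gene_model.strand == "+":
            tss = gene_model.start
        elif gene_model.strand == "-":
            tss = gene_model.end
        else:
            raise ValidationError(
                f"gene {gene_model.name!r}: strand required for anchor='tss'"
            )
        start, end = tss - pad, tss + pad
    else:
        raise ValidationError(f"unknown anchor {anchor!r}")
    return GenomicInterval(
        chrom=gene_model.chrom, start=max(0, start), end=end,
        strand=gene_model.strand, name=gene_model.name,
    )


def annotate_binding(peaks: list[GenomicInterval], gene_models: list[GenomicInterval],
                     pad: int = 2000, anchor: str = "cds",
                     dataset: str = "dataset") -> BindingMatrix:
    """Mark each gene bound iff >=1 (pre-filtered) peak overlaps any of its
    windows by >=1 bp (half-open test, same chromosome)."""
    trees: dict[str, IntervalTree] = {}
    gene_names: list[str] = []
    seen = set()
    for m in gene_models:
        if m.name not in seen:
            seen.add(m.name)
            gene_names.append(m.name)
        win = gene_window(m, pad=pad, anchor=anchor)
        if win.end > win.start:
            trees.setdefault(win.chrom, IntervalTree()).addi(win.start, win.end, m.name)

    support: dict[tuple[str, str], list[GenomicInterval]] = {}
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.start, p.end):
            support.setdefault((hit.data, dataset), []).append(p)

    bound = pd.Series(
        [(g, dataset) in support for g in gene_names],
        index=pd.Index(gene_names, name="gene"), dtype=bool,
    )
    return BindingMatrix(matrix=bound.to_frame(name=dataset), support=support)


def binding_matrix(peaks_by_dataset: dict[str, list[GenomicInterval]],
                   gene_models: list[GenomicInterval], pad: int = 2000,
                   anchor: str = "cds") -> BindingMatrix:
    """Annotate several datasets against one set of gene models."""
    if not peaks_by_dataset:
        raise ValidationError("need at least one peak dataset")
    columns = []
    support: dict[tuple[str, str], list[GenomicInterval]] = {}
    for name, peaks in peaks_by_dataset.items():
        bm = annotate_binding(peaks, gene_models, pad=pad, anchor=anchor, dataset=name)
        columns.append(bm.matrix[name])
        support.update(bm.support)
    return BindingMatrix(matrix=pd.concat(columns, axis=1), support=support)


def binding_summary(matrix: BindingMatrix, query_genes) -> pd.DataFrame:
    """Per-dataset bound counts restricted to a query gene list.

    Query genes absent from the gene models are reported in the
    ``n_absent`` column (and logged), not counted in the denominator.
    """
    query = list(dict.fromkeys(query_genes))
    present = [g for g in query if g in matrix.matrix.index]
    absent = [g for g in query if g not in matrix.matrix.index]
    if absent:
        logger.warning("%d query genes absent from gene models: %s%s",
                       len(absent), absent[:5], "..." if len(absent) > 5 else "")
    rows = []
    for ds in matrix.matrix.columns:
        n_bound = int(matrix.matrix.loc[present, ds].sum()) if present else 0
        rows.append({
            "dataset": ds,
            "n_bound": n_bound,
            "n_query": len(present),
            "fraction": n_bound / len(present) if present else math.nan,
            "n_absent": len(absent),
        })
    return pd.DataFrame(rows).set_index("dataset")
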