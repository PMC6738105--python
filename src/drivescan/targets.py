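"""Cross-species target nomination and the group-comparison tests.

The knockout DE table is filtered with strict thresholds (fdr < 0.1 and
|logFC| > 1 by default), split by sign, and the down-regulated orthologs
are intersected with the human driver-correlated gene list by case-folded
symbol equality (human SYMBOL vs mouse Symbol conventions).  Wilcoxon
rank-sum and one-way ANOVA are exposed here because the downstream group
comparisons use them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .formats import DETable

logger = logging.getLogger(__name__)

__all__ = [
    "TargetNomination",
    "filter_de",
    "intersect_targets",
    "wilcoxon_rank_sum",
    "anova_oneway",
]


@dataclass
class TargetNomination:
    """Candidate target genes with per-source evidence.

    ``table`` is indexed by the case-folded (upper) symbol; human evidence
    columns (per-cohort r, q) and mouse columns (logFC, fdr) are attached
    when the corresponding source tables are supplied.
    """

    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def filter_de(de_table: DETable, fdr_max: float = 0.1,
              min_abs_logfc: float = 1.0) -> tuple[list[str], list[str]]:
    """Split significantly deregulated genes by sign.

    Thresholds are strict: ``fdr < fdr_max`` and ``|logFC| > min_abs_logfc``
    (a gene at exactly the boundary is excluded).
    """
    df = de_table.data
    sig = (df["fdr"] < fdr_max) & (df["logFC"].abs() > min_abs_logfc)
    up = sorted(df.index[sig & (df["logFC"] > 0)])
    down = sorted(df.index[sig & (df["logFC"] < 0)])
    return up, down


def intersect_targets(human_positive, mouse_down, human_records: pd.DataFrame | None = None,
                      mouse_de: DETable | None = None) -> TargetNomination:
    """Nominate targets present in both the human positive list and the
    mouse down-regulated list after upper-casing both symbol sets."""
    human = list(human_positive)
    mouse = list(mouse_down)
    if not human or not mouse:
        raise ValidationError("both gene lists must be non-empty")
    h_map = {g.strip().upper(): g for g in human}
    m_map = {g.strip().upper(): g for g in mouse}
    shared = sorted(set(h_map) & set(m_map))
    if not shared:
        logger.warning("human/mouse intersection is empty")

    table = pd.DataFrame(index=pd.Index(shared, name="symbol"))
    table["human_symbol"] = [h_map[s] for s in shared]
    table["mouse_symbol"] = [m_map[s] for s in shared]
    if mouse_de is not None:
        de = mouse_de.data
        table["mouse_logFC"] = [de.loc[m_map[s], "logFC"] if m_map[s] in de.index else np.nan
                                for s in shared]
        table["mouse_fdr"] = [de.loc[m_map[s], "fdr"] if m_map[s] in de.index else np.nan
                              for s in shared]
    if human_records is not None:
        for cohort, sub in human_records.groupby("cohort"):
            sub = sub.set_index(sub["gene"].str.upper())
            table[f"r_{cohort}"] = [sub["r"].get(s, np.nan) for s in shared]
            table[f"q_{cohort}"] = [sub["q"].get(s, np.nan) for s in shared]
    return TargetNomination(table=table)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact p by enumeration when ``min(n_x, n_y) <= 8`` with no ties across
    the pooled sample; otherwise the normal approximation with tie and
    continuity corrections.  Returns ``(U, p)`` with U the Mann–Whitney
    statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F test with (k-1, N-k) degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("groups must be non-empty")
    n_total = sum(len(g) for g in groups)
    if n_total - len(groups) <= 0:
        raise ValidationError("no residual degrees of freedom (N - k <= 0)")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all values identical: no between-group signal
        return 0.0, 1.0
    means = np.array([g.mean() for g in groups])
    if np.ptp(means) == 0 and all(np.ptp(g) == 0 for g in groups):
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
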