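"""Per-gene Pearson screening against a driver gene, FDR control and
cross-cohort intersection.

Every non-driver gene in a cohort is correlated with the driver
(pairwise-complete on missing values), two-sided p-values come from the
t-transform ``t = r sqrt((n-2)/(1-r^2))`` with ``n-2`` degrees of freedom,
and Benjamini–Hochberg adjustment is applied within the cohort over all
genes with a defined correlation.  Genes are then intersected across
cohorts: a gene enters the positive (negative) list iff it passes the FDR
threshold in every cohort with a consistently positive (negative)
coefficient.  The excess of one sign over the other is tested with a
two-sided Fisher exact test on the 2x2 proportion table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)
from .formats import ExpressionCohort

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationTable",
    "IntersectionResult",
    "pearson",
    "bh_adjust",
    "correlate_with_driver",
    "intersect_cohorts",
    "sign_proportion_test",
]


@dataclass
class CorrelationTable:
    """Per-gene correlation with the driver in one cohort.

    ``table`` is indexed by gene with columns ``r``, ``n_pairs``, ``p``,
    ``q``; genes whose correlation is undefined (constant vector or <3
    complete pairs) carry NaN and are excluded from the BH family.
    """

    cohort_id: str
    driver: str
    table: pd.DataFrame

    def defined(self) -> pd.DataFrame:
        return self.table[self.table["r"].notna()]


@dataclass
class IntersectionResult:
    threshold: float
    positive_genes: list[str]
    negative_genes: list[str]
    records: pd.DataFrame  # long: gene, cohort, r, q
    n_universe: int
    n_mixed_sign: int

    def __post_init__(self):
        if set(self.positive_genes) & set(self.negative_genes):
            raise ValidationError("positive and negative gene lists overlap")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value on pairwise-complete
    observations.

    Raises :class:`InsufficientDataError` with fewer than 3 complete pairs
    and :class:`UndefinedCorrelationError` if either vector is constant on
    the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"need >=3 complete pairs, got {n}")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedCorrelationError("constant vector on complete pairs")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _t_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t-transform; |r| == 1 maps to p = 0."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return p


def correlate_with_driver(cohort: ExpressionCohort, driver_gene: str) -> CorrelationTable:
    """Correlation of every non-driver gene with the driver in one cohort.

    BH adjustment is applied within the cohort over all genes with a
    defined coefficient; undefined genes (constant, <3 pairs) are recorded
    with NaN and do not enter the BH family.
    """
    if driver_gene not in cohort.values.index:
        raise ValidationError(
            f"driver gene {driver_gene!r} absent from cohort {cohort.cohort_id}"
        )
    X = cohort.values.drop(index=driver_gene)
    d = cohort.values.loc[driver_gene].to_numpy(dtype=float)
    genes = X.index
    M = X.to_numpy(dtype=float)

    r = np.full(len(genes), np.nan)
    n_pairs = np.zeros(len(genes), dtype=int)

    finite_d = np.isfinite(d)
    finite_M = np.isfinite(M)
    complete = finite_M & finite_d[None, :]
    n_pairs[:] = complete.sum(axis=1)

    all_complete = complete.all(axis=1)
    if all_complete.any() and finite_d.all():
        sub = M[all_complete]
        dc = d - d.mean()
        ssd = float(dc @ dc)
        xc = sub - sub.mean(axis=1, keepdims=True)
        ssx = np.einsum("ij,ij->i", xc, xc)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = (xc @ dc) / np.sqrt(ssx * ssd)
        rr[(ssx == 0) | (ssd == 0)] = np.nan
        r[all_complete] = rr

    # per-gene fallback for rows with missing values
    for i in np.flatnonzero(~(all_complete & finite_d.all())):
        if all_complete[i] and finite_d.all():
            continue
        try:
            r[i], _ = pearson(M[i], d)
        except (InsufficientDataError, UndefinedCorrelationError):
            r[i] = np.nan

    defined = np.isfinite(r) & (n_pairs >= 3)
    r[~defined] = np.nan
    p = np.full(len(genes), np.nan)
    p[defined] = _t_pvalue(r[defined], n_pairs[defined].astype(float))
    q = np.full(len(genes), np.nan)
    if defined.any():
        q[defined] = bh_adjust(p[defined])
    n_undefined = int((~defined).sum())
    if n_undefined:
        logger.warning(
            "cohort %s: %d genes with undefined correlation excluded from BH family",
            cohort.cohort_id, n_undefined,
        )

    table = pd.DataFrame(
        {"r": r, "n_pairs": n_pairs, "p": p, "q": q}, index=genes
    )
    return CorrelationTable(cohort_id=cohort.cohort_id, driver=driver_gene, table=table)


def intersect_cohorts(tables: list[CorrelationTable], fdr_threshold: float,
                      bh_scope: str = "per_cohort") -> IntersectionResult:
    """Genes passing ``q < fdr_threshold`` in every cohort with a consistent
    sign, over the universe of genes testable in all cohorts.

    ``bh_scope='per_cohort'`` (default) uses each table's own within-cohort
    q-values; ``'pooled'`` re-adjusts the p-values of all cohorts as one BH
    family before thresholding.
    """
    if len(tables) < 2:
        raise ValidationError("need at least two cohorts to intersect")
    if not 0 < fdr_threshold < 1:
        raise ValidationError("fdr_threshold must lie in (0, 1)")
    if bh_scope not in ("per_cohort", "pooled"):
        raise ValidationError(f"unknown bh_scope {bh_scope!r}")

    universe = None
    for t in tables:
        defined = set(t.defined().index)
        universe = defined if universe is None else universe & defined
    if not universe:
        raise ValidationError("no gene has a defined correlation in every cohort")
    universe = sorted(universe)

    R = pd.DataFrame({t.cohort_id: t.table.loc[universe, "r"] for t in tables})
    if bh_scope == "pooled":
        P = pd.DataFrame({t.cohort_id: t.table.loc[universe, "p"] for t in tables})
        flat = bh_adjust(P.to_numpy().ravel())
        Q = pd.DataFrame(flat.reshape(P.shape), index=P.index, columns=P.columns)
    else:
        Q = pd.DataFrame({t.cohort_id: t.table.loc[universe, "q"] for t in tables})

    passes = (Q < fdr_threshold).all(axis=1)
    all_pos = (R > 0).all(axis=1)
    all_neg = (R < 0).all(axis=1)
    positive = passes & all_pos
    negative = passes & all_neg
    mixed = passes & ~all_pos & ~all_neg
    if mixed.any():
        logger.warning(
            "%d genes pass FDR %.4g in every cohort with inconsistent signs; excluded",
            int(mixed.sum()), fdr_threshold,
        )

    records = []
    for t in tables:
        sub = t.table.loc[universe, ["r", "q"]].copy()
        sub["cohort"] = t.cohort_id
        sub["gene"] = sub.index
        records.append(sub.reset_index(drop=True))
    records = pd.concat(records, ignore_index=True)[["gene", "cohort", "r", "q"]]

    return IntersectionResult(
        threshold=fdr_threshold,
        positive_genes=sorted(R.index[positive]),
        negative_genes=sorted(R.index[negative]),
        records=records,
        n_universe=len(universe),
        n_mixed_sign=int(mixed.sum()),
    )


def sign_proportion_test(n_pos: int, n_neg: int, n_universe: int, method: str = "fisher") -> float:
    """Two-sided test comparing the proportion of positively vs negatively
    correlated genes out of the testable universe.

    Default is the Fisher exact test on
    ``[[n_pos, N - n_pos], [n_neg, N - n_neg]]``; a chi-square two-proportion
    variant is available with ``method='chi2'``.
    """
    for v in (n_pos, n_neg, n_universe):
        if v < 0:
            raise ValidationError("counts must be non-negative")
    if n_pos > n_universe or n_neg > n_universe:
        raise ValidationError("counts cannot exceed the universe size")
    table = np.array([[n_pos, n_universe - n_pos], [n_neg, n_universe - n_neg]])
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "chi2":
        if n_pos == n_neg:
            return 1.0
        return float(stats.chi2_contingency(table, correction=False).pvalue)
    raise ValidationError(f"unknown method {method!r}")
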