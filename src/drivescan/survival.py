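"""Metagene scoring and survival analysis.

A metagene collapses a gene list to one scalar per sample — by default the
mean of per-gene within-cohort z-scores (``z-mean``), which is robust to
platform-specific per-gene scale; a plain mean of log2 values (``raw-mean``)
is available.  Survival contracts: Kaplan–Meier product-limit estimation,
the two-group log-rank test with median dichotomisation, and Cox
proportional-hazards regression (maximum partial likelihood, Breslow tie
handling by default, Efron behind a flag) with per-covariate Wald tests.
The Cox fit is delegated to statsmodels' PHReg; KM and log-rank are
computed directly from their defining formulas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, SeparationError, ValidationError
from .formats import ExpressionCohort, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "MetageneScore",
    "KMCurve",
    "CoxFit",
    "metagene_score",
    "dichotomize_median",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]


@dataclass
class MetageneScore:
    """Per-sample scalar summary of a gene list."""

    scores: pd.Series
    gene_list_id: str
    cohort_id: str
    mode: str
    n_genes_used: int

    def __post_init__(self):
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("metagene scores must be finite")


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times (prepended with 0), ``survival``
    the estimate after each, ``at_risk`` the risk-set size just before each
    time, and ``censor_times`` the censoring marks.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def __post_init__(self):
        if self.survival[0] != 1.0 or np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("KM survival must start at 1 and be non-increasing")

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (one row per covariate)."""

    coef: pd.Series
    hr: pd.Series
    se: pd.Series
    wald_z: pd.Series
    wald_p: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    ties: str


def metagene_score(cohort: ExpressionCohort, gene_list, mode: str = "zmean",
                   gene_list_id: str = "metagene") -> MetageneScore:
    """Score each sample by the mean over the listed genes.

    ``zmean`` (default) z-scores each gene within the cohort first;
    zero-variance genes are dropped with a warning.  Genes absent from the
    cohort are ignored (warning); if none is present, or a listed gene has
    missing values, the call fails.
    """
    if mode not in ("zmean", "rawmean"):
        raise ValidationError(f"unknown metagene mode {mode!r}")
    gene_list = list(gene_list)
    present = [g for g in gene_list if g in cohort.values.index]
    if not present:
        raise ValidationError(
            f"no listed gene present in cohort {cohort.cohort_id}"
        )
    if len(present) < len(gene_list):
        logger.warning(
            "cohort %s: %d of %d listed genes absent; scoring on the rest",
            cohort.cohort_id, len(gene_list) - len(present), len(gene_list),
        )
    sub = cohort.values.loc[present]
    if sub.isna().to_numpy().any():
        raise ValidationError("missing expression values in listed genes")
    if mode == "zmean":
        sd = sub.std(axis=1, ddof=1)
        flat = sd == 0
        if flat.any():
            logger.warning(
                "cohort %s: dropped %d zero-variance genes from metagene",
                cohort.cohort_id, int(flat.sum()),
            )
            sub = sub.loc[~flat]
            sd = sd.loc[~flat]
            if sub.empty:
                raise ValidationError("all listed genes have zero variance")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        scores = z.mean(axis=0)
    else:
        scores = sub.mean(axis=0)
    return MetageneScore(
        scores=scores, gene_list_id=gene_list_id,
        cohort_id=cohort.cohort_id, mode=mode, n_genes_used=len(sub),
    )


def dichotomize_median(scores: pd.Series) -> pd.Series:
    """Label samples 'high' (score > median) or 'low' (score <= median)."""
    s = pd.Series(scores, dtype=float)
    med = s.median()
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index)
    if (labels == "low").all():
        logger.warning("median dichotomisation produced a single group (all 'low')")
    return labels


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValidationError("survival times must be non-negative and finite")
    event_times = np.unique(t[e])
    surv, n_at_risk, n_ev = [1.0], [len(t)], [0]
    s = 1.0
    out_times = [0.0]
    for ti in event_times:
        at_risk = int((t >= ti).sum())
        d = int(((t == ti) & e).sum())
        s *= 1.0 - d / at_risk
        out_times.append(float(ti))
        surv.append(s)
        n_at_risk.append(at_risk)
        n_ev.append(d)
    return KMCurve(
        times=np.array(out_times),
        survival=np.array(surv),
        at_risk=np.array(n_at_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
        censor_times=np.sort(t[~e]),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed event count in group A is
    compared with its hypergeometric expectation given the pooled risk set;
    the chi-square statistic is ``(sum(O-E))^2 / sum(V)`` on 1 df.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled_t = np.concatenate([ta, tb])
    pooled_e = np.concatenate([ea, eb])
    is_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(pooled_t[pooled_e]):
        at_risk = pooled_t >= ti
        n = int(at_risk.sum())
        n_a = int((at_risk & is_a).sum())
        d = int(((pooled_t == ti) & pooled_e).sum())
        d_a = int(((pooled_t == ti) & pooled_e & is_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def _design_matrix(table: SurvivalTable, covariate_names: list[str]) -> pd.DataFrame:
    """Indicator-code categorical covariates; keep numeric ones as-is."""
    cols = []
    for name in covariate_names:
        if name not in table.data.columns:
            raise ValidationError(f"covariate {name!r} not in survival table")
        col = table.data[name]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cols.append(col.astype(float).rename(name))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            cols.append(dummies.astype(float))
    X = pd.concat(cols, axis=1)
    if X.isna().to_numpy().any():
        raise ValidationError("missing covariate values")
    return X


def cox_fit(table: SurvivalTable, covariate_names: list[str], ties: str = "breslow",
            max_iter: int = 100) -> CoxFit:
    """Cox proportional-hazards regression by maximum partial likelihood.

    Continuous covariates enter as-is; categorical ones are indicator-coded
    against the first level.  Monotone likelihood (perfect separation) is
    detected from runaway coefficients or non-finite standard errors.
    """
    from statsmodels.duration.hazard_regression import PHReg

    if ties not in ("breslow", "efron"):
        raise ValidationError(f"unknown tie handling {ties!r}")
    if not covariate_names:
        raise ValidationError("at least one covariate is required")
    if table.events.sum() == 0:
        raise ValidationError("no events observed")
    X = _design_matrix(table, list(covariate_names))
    for c in X.columns:
        if X[c].nunique() <= 1:
            raise ValidationError(f"covariate {c!r} is constant")

    model = PHReg(table.times, X.to_numpy(), status=table.events.astype(int),
                  ties=ties)
    try:
        res = model.fit(maxiter=max_iter, disp=False)
    except Exception as exc:  # statsmodels raises LinAlgError on flat likelihoods
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc

    params = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not np.isfinite(params).all() or not np.isfinite(se).all():
        raise SeparationError("non-finite Cox estimates (monotone likelihood?)")
    if np.abs(params).max() > 20 or se.max() > 1e3:
        raise SeparationError(
            f"runaway coefficient (|beta|max={np.abs(params).max():.3g}); "
            "likely perfect separation / monotone partial likelihood"
        )

    idx = pd.Index(X.columns)
    z = params / se
    p = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(
        coef=pd.Series(params, index=idx),
        hr=pd.Series(np.exp(params), index=idx),
        se=pd.Series(se, index=idx),
        wald_z=pd.Series(z, index=idx),
        wald_p=pd.Series(p, index=idx),
        log_likelihood=float(model.loglike(params)),
        n=len(table.data),
        n_events=int(table.events.sum()),
        ties=ties,
    )
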