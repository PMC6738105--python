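"""Pre-ranked gene-set enrichment analysis, implemented from scratch.

The enrichment score (ES) is the weighted Kolmogorov–Smirnov-like running
sum: walking down the ranked list, hitting a set member increments the sum
by ``|metric|^w / N_R`` (``N_R`` the sum of ``|metric|^w`` over members) and
a miss decrements by ``1/(N - N_H)``; ES is the signed maximal deviation
from zero.  The null distribution comes from gene-label permutation (random
same-size member draws from the ranked universe), NES divides ES by the
mean absolute null ES of the same sign, the permutation p-value is the
one-sided same-sign tail frequency with a +1 pseudo-count, and the
collection-wide FDR q is the standard ratio of pooled-null to observed NES
tail fractions.  The leading edge is the members at or before the peak
(positive ES) or at or after the trough (negative ES).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .formats import GeneSetCollection
from .correlation import CorrelationTable, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "enrichment_score",
    "permutation_null",
    "fdr_across_sets",
    "analyze_collection",
    "intersect_leading_edges",
]


@dataclass
class RankedList:
    """Genes ordered by descending ranking metric (here: correlation r).

    Metric ties are broken by gene identifier (lexicographic) so rankings
    are reproducible across runs and platforms.
    """

    genes: np.ndarray
    metrics: np.ndarray

    def __post_init__(self):
        genes = np.asarray(self.genes, dtype=object)
        metrics = np.asarray(self.metrics, dtype=float)
        if genes.shape != metrics.shape:
            raise ValidationError("genes and metrics must have equal length")
        if len(set(genes)) != len(genes):
            raise ValidationError("ranked list has duplicate genes")
        if not np.isfinite(metrics).all():
            raise ValidationError("ranking metrics must be finite")
        # sort by descending metric, ties by gene id
        order = sorted(range(len(genes)), key=lambda i: (-metrics[i], str(genes[i])))
        if order != list(range(len(genes))):
            n_ties = len(metrics) - len(np.unique(metrics))
            if n_ties:
                logger.info("ranked list: %d tied metric values broken by gene id", n_ties)
        self.genes = genes[order]
        self.metrics = metrics[order]
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, members) -> np.ndarray:
        """Sorted rank positions (0-based) of the members present in the list."""
        pos = [self._index[m] for m in members if m in self._index]
        return np.array(sorted(pos), dtype=int)

    @classmethod
    def from_pairs(cls, pairs) -> "RankedList":
        genes, metrics = zip(*pairs)
        return cls(np.array(genes, dtype=object), np.array(metrics, dtype=float))

    @classmethod
    def from_correlations(cls, tables: list[CorrelationTable], combine: str = "mean") -> "RankedList":
        """Rank the common testable universe by (mean) correlation with the
        driver across cohorts."""
        frames = [t.defined()["r"].rename(t.cohort_id) for t in tables]
        R = pd.concat(frames, axis=1, join="inner")
        if R.empty:
            raise ValidationError("no gene has a defined correlation in every cohort")
        if combine == "mean":
            metric = R.mean(axis=1)
        elif combine in R.columns:
            metric = R[combine]
        else:
            raise ValidationError(f"unknown combine rule {combine!r}")
        return cls(metric.index.to_numpy(dtype=object), metric.to_numpy(dtype=float))


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    q_fdr: float
    leading_edge: list[str]
    hit_positions: np.ndarray
    n_hits_in_universe: int
    nes_unstable: bool = False


@dataclass
class _ScoredSet:
    """Internal carrier between the per-set permutation stage and the
    collection-wide FDR stage."""

    set_name: str
    es: float
    nes: float
    p_perm: float
    leading_edge: list[str]
    hit_positions: np.ndarray
    null_es: np.ndarray
    nes_unstable: bool


def _hit_weights(metrics: np.ndarray, positions: np.ndarray, w: float) -> np.ndarray:
    if w == 0:
        return np.ones(len(positions))
    return np.abs(metrics[positions]) ** w


def enrichment_score(ranked: RankedList, gene_set, w: float = 1.0):
    """ES, full running sum and leading edge for one gene set.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum[i]`` is
    the sum after processing rank ``i`` (it ends at 0 by construction).
    Peak ties resolve to the earliest peak for ES>0 and the latest trough
    for ES<0; an exact +/- magnitude tie resolves to the positive side.
    """
    members = gene_set.members if hasattr(gene_set, "members") else tuple(gene_set)
    N = len(ranked)
    pos = ranked.positions(members)
    if len(pos) == 0:
        raise ValidationError("no set member present in the ranked list")
    if len(pos) == N:
        raise ValidationError("set covers the entire ranked list")
    hw = _hit_weights(ranked.metrics, pos, w)
    nr = hw.sum()
    if nr == 0:
        raise ValidationError("all hit metrics are zero with w > 0 (degenerate weights)")

    steps = np.full(N, -1.0 / (N - len(pos)))
    steps[pos] = hw / nr
    running = np.cumsum(steps)

    absmax = np.max(np.abs(running))
    if np.any(running == absmax):  # positive wins an exact magnitude tie
        es = float(absmax)
        peak = int(np.flatnonzero(running == absmax)[0])  # earliest peak
        le_pos = pos[pos <= peak]
    else:
        es = float(-absmax)
        trough = int(np.flatnonzero(running == -absmax)[-1])  # latest trough
        le_pos = pos[pos >= trough]
    leading_edge = [ranked.genes[i] for i in le_pos]
    return es, running, leading_edge


def _es_from_positions(abs_w_metrics: np.ndarray, pos: np.ndarray, N: int) -> np.ndarray:
    """Vectorised ES for a (P, S) matrix of sorted hit positions.

    Between hits the running sum decays linearly, so its extrema occur only
    immediately before or after a hit; ES is the signed extremum over those
    2S candidates (and the implicit 0 endpoints).
    """
    P, S = pos.shape
    hw = abs_w_metrics[pos]
    cw = np.cumsum(hw, axis=1)
    nr = cw[:, -1:]
    miss = (pos - np.arange(S)) / (N - S)  # misses seen strictly before hit i
    dev_after = cw / nr - miss
    dev_before = (cw - hw) / nr - miss
    cand = np.concatenate([dev_after, dev_before], axis=1)
    absmax = np.max(np.abs(cand), axis=1)
    has_pos = (cand == absmax[:, None]).any(axis=1)  # positive wins exact ties
    return np.where(has_pos, absmax, -absmax)


def permutation_null(ranked: RankedList, gene_set, n_perm: int = 1000,
                     w: float = 1.0, seed: int | np.random.Generator = 0):
    """Gene-label permutation null for one set.

    Returns a :class:`_ScoredSet` with observed ES, NES (ES over the mean
    absolute same-sign null ES), one-sided p with a +1 pseudo-count, and the
    raw null ES sample.  NES is flagged unstable if fewer than 10 null
    values share the observed sign.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    es, _running, leading = enrichment_score(ranked, gene_set, w=w)
    members = gene_set.members if hasattr(gene_set, "members") else tuple(gene_set)
    pos = ranked.positions(members)
    S, N = len(pos), len(ranked)

    abs_w = np.ones(N) if w == 0 else np.abs(ranked.metrics) ** w
    perm_pos = np.empty((n_perm, S), dtype=int)
    for i in range(n_perm):
        perm_pos[i] = rng.choice(N, size=S, replace=False)
    perm_pos.sort(axis=1)
    null_es = _es_from_positions(abs_w, perm_pos, N)

    same_sign = null_es > 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    unstable = n_same < 10
    if unstable:
        logger.warning(
            "set %s: only %d same-sign null ES values; NES unstable",
            getattr(gene_set, "name", "<anonymous>"), n_same,
        )
    if es >= 0:
        tail = int((null_es[same_sign] >= es).sum())
    else:
        tail = int((null_es[same_sign] <= es).sum())
    p_perm = (tail + 1) / (n_same + 1)
    mean_same = np.abs(null_es[same_sign]).mean() if n_same else np.nan
    nes = es / mean_same if n_same else np.nan

    return _ScoredSet(
        set_name=getattr(gene_set, "name", "<anonymous>"),
        es=float(es), nes=float(nes), p_perm=float(p_perm),
        leading_edge=list(leading), hit_positions=pos,
        null_es=null_es, nes_unstable=unstable,
    )


def _normalize_nulls(null_es: np.ndarray) -> np.ndarray:
    """Rescale a null ES sample to null NES using same-sign means."""
    out = np.full_like(null_es, np.nan)
    pos = null_es > 0
    neg = null_es < 0
    if pos.any():
        out[pos] = null_es[pos] / null_es[pos].mean()
    if neg.any():
        out[neg] = null_es[neg] / np.abs(null_es[neg]).mean()
    out[null_es == 0] = 0.0
    return out


def fdr_across_sets(scored: list[_ScoredSet], method: str = "gsea") -> np.ndarray:
    """Collection-wide FDR q per set.

    ``gsea`` (default): for each observed NES, q is the fraction of pooled
    null NES at least as extreme on the same sign divided by the fraction of
    observed NES at least as extreme, clipped to [0, 1].  ``bh``: BH on the
    permutation p-values.
    """
    if len(scored) < 2:
        logger.warning("fewer than 2 sets: FDR q falls back to the permutation p")
        return np.array([s.p_perm for s in scored])
    if method == "bh":
        return bh_adjust([s.p_perm for s in scored])
    if method != "gsea":
        raise ValidationError(f"unknown FDR method {method!r}")

    obs = np.array([s.nes for s in scored])
    pooled = np.concatenate([_normalize_nulls(s.null_es) for s in scored])
    pooled = pooled[np.isfinite(pooled)]
    q = np.ones(len(scored))
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled < 0]
    obs_finite = obs[np.isfinite(obs)]
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = 1.0
            continue
        if nes >= 0:
            num_den = len(pooled_pos)
            num = (pooled_pos >= nes).sum() / num_den if num_den else 1.0
            den_den = (obs_finite >= 0).sum()
            den = (obs_finite >= nes).sum() / den_den if den_den else 1.0
        else:
            num_den = len(pooled_neg)
            num = (pooled_neg <= nes).sum() / num_den if num_den else 1.0
            den_den = (obs_finite < 0).sum()
            den = (obs_finite <= nes).sum() / den_den if den_den else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q


def analyze_collection(ranked: RankedList, collection: GeneSetCollection,
                       n_perm: int = 1000, w: float = 1.0, seed: int = 0,
                       fdr_method: str = "gsea") -> list[EnrichmentResult]:
    """Score every set in a collection against one ranked list.

    Sets with no member in the ranked universe (or covering it entirely)
    are skipped with a warning.  Per-set permutation streams are spawned
    from the single seed, so results do not depend on set order.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(collection))
    scored = []
    for child, gene_set in zip(children, collection):
        try:
            scored.append(
                permutation_null(ranked, gene_set, n_perm=n_perm, w=w,
                                 seed=np.random.default_rng(child))
            )
        except ValidationError as exc:
            logger.warning("skipping set %s: %s", gene_set.name, exc)
    if not scored:
        return []
    q = fdr_across_sets(scored, method=fdr_method)
    return [
        EnrichmentResult(
            set_name=s.set_name, es=s.es, nes=s.nes, p_perm=s.p_perm,
            q_fdr=float(qi), leading_edge=s.leading_edge,
            hit_positions=s.hit_positions,
            n_hits_in_universe=len(s.hit_positions),
            nes_unstable=s.nes_unstable,
        )
        for s, qi in zip(scored, q)
    ]


def intersect_leading_edges(results: list[EnrichmentResult], q_threshold: float = 0.01,
                            membership_rule: str | int = "all") -> list[str]:
    """Core gene list from the leading edges of sets passing the q threshold.

    ``membership_rule='all'`` (default) keeps genes present in every
    selected leading edge; an integer k keeps genes present in at least k.
    An empty core is returned with a warning, never raised.
    """
    selected = [r for r in results if r.q_fdr < q_threshold]
    if not selected:
        raise ValidationError(f"no gene set passes q < {q_threshold}")
    if membership_rule == "all":
        k = len(selected)
    elif isinstance(membership_rule, (int, np.integer)):
        k = int(membership_rule)
    else:
        raise ValidationError(f"unknown membership rule {membership_rule!r}")
    counts: dict[str, int] = {}
    for r in selected:
        for g in r.leading_edge:
            counts[g] = counts.get(g, 0) + 1
    core = sorted(g for g, c in counts.items() if c >= k)
    if not core:
        logger.warning("leading-edge intersection is empty under rule %r", membership_rule)
    return core
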