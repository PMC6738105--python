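import numpy as np
import pandas as pd
import pytest

from drivescan import (
    RankedList,
    SimConfig,
    analyze_collection,
    correlate_with_driver,
    generate_bundle,
    intersect_cohorts,
)
from drivescan.formats import ExpressionCohort

# Study conditions for the planted-structure bundle: three cohorts of 200
# samples over 5,000 genes, a 100-gene module at rho = 0.6 with 20
# anti-correlated genes, five signal sets sharing a 50-gene core plus 50
# background-only decoy sets.
BUNDLE_SEED = 1234
GSEA_SEED = 7


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(SimConfig(seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def corr_tables(bundle):
    return [correlate_with_driver(c, bundle.truth.driver) for c in bundle.cohorts]


@pytest.fixture(scope="session")
def intersection(corr_tables):
    return intersect_cohorts(corr_tables, fdr_threshold=0.001)


@pytest.fixture(scope="session")
def gsea_results(bundle, corr_tables):
    ranked = RankedList.from_correlations(corr_tables, combine="mean")
    return analyze_collection(ranked, bundle.collection, n_perm=1000, w=1.0,
                              seed=GSEA_SEED)


@pytest.fixture
def tiny_cohort():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 4.0, 6.0, 8.0],
         [5.0, 5.0, 5.0, 5.0],
         [4.0, 3.0, 2.0, 1.0]],
        index=["EZH2", "POS", "FLAT", "NEG"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionCohort(cohort_id="tiny", values=values)


def brute_force_running_sum(genes_in_order, metrics, members, w):
    """Definition-level prefix recomputation of the weighted KS running sum."""
    members = set(members)
    hits = [g in members for g in genes_in_order]
    nr = sum(abs(m) ** w for g, m in zip(genes_in_order, metrics) if g in members)
    n_miss = len(genes_in_order) - sum(hits)
    running, s = [], 0.0
    for g, m, hit in zip(genes_in_order, metrics, hits):
        if hit:
            s += (abs(m) ** w) / nr if w != 0 else 1.0 / sum(hits)
        else:
            s -= 1.0 / n_miss
        running.append(s)
    return np.array(running)


def bh_step_up_oracle(pvals):
    """Textbook BH: q_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
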