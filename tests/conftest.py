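"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, literal
step-up definitions) so they stay independent of the implementation paths
they check.
"""
from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------------
# brute-force Benjamini-Hochberg step-up

def brute_force_bh(pvals, q=0.1):
    """Literal step-up definition: adjusted_i = min_{j: rank>=i} p_(j) M / j,
    capped at 1; reject all p <= p_(k), k the largest rank with
    p_(k) <= k q / M."""
    p = np.asarray(pvals, dtype=float)
    M = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(M)
    running = 1.0
    for i in range(M - 1, -1, -1):
        running = min(running, sorted_p[i] * M / (i + 1))
        adj_sorted[i] = running
    adjusted = np.empty(M)
    adjusted[order] = adj_sorted
    k = 0
    for i in range(M):
        if sorted_p[i] <= (i + 1) * q / M:
            k = i + 1
    threshold = sorted_p[k - 1] if k else 0.0
    reject = p <= threshold if k else np.zeros(M, dtype=bool)
    return adjusted, reject, threshold


# ---------------------------------------------------------------------------
# exhaustive spanning-tree enumeration (Cayley: n^(n-2) labelled trees)

def pruefer_to_edges(seq, n):
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    import heapq
    avail = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(avail)
    for v in seq:
        leaf = heapq.heappop(avail)
        edges.append((min(leaf, v), max(leaf, v)))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(avail, v)
    a = heapq.heappop(avail)
    b = heapq.heappop(avail)
    edges.append((min(a, b), max(a, b)))
    return edges


def enumerate_spanning_trees(n):
    """Yield the edge lists of all n^(n-2) labelled trees on n nodes."""
    if n == 3:
        yield from ([(0, 1), (0, 2)], [(0, 1), (1, 2)], [(0, 2), (1, 2)])
        return
    for seq in product(range(n), repeat=n - 2):
        yield pruefer_to_edges(seq, n)


def max_total_weight_by_enumeration(matrix):
    """Best spanning-tree total weight, by exhaustive enumeration."""
    n = matrix.shape[0]
    best = -np.inf
    for edges in enumerate_spanning_trees(n):
        w = sum(matrix[i, j] for i, j in edges)
        best = max(best, w)
    return best


# ---------------------------------------------------------------------------
# null cohort tables: tree metrics independent of the biomarker

def synthetic_cohort_table(seed, n_subjects=76, n_fhpos=54, effect_size=0.0):
    """Cohort table whose tree metrics come from random unique-weight
    matrices, independent of the biomarker unless an effect is planted."""
    from mstmeg import make_random_matrix, mst_from_matrix
    from mstmeg.stats import metric_column
    from mstmeg.synthcohort import CohortSpec, draw_cohort_table
    from mstmeg.tree import tree_metrics

    spec = CohortSpec.test_profile(n_subjects=n_subjects, n_fhpos=n_fhpos,
                                   effect_size=effect_size, seed=seed)
    table = draw_cohort_table(spec)
    rng = np.random.default_rng(seed + 1)
    for band in ("theta", "alpha", "beta"):
        lf, dd, th = [], [], []
        for _ in range(n_subjects):
            m = tree_metrics(mst_from_matrix(make_random_matrix(10, rng)))
            lf.append(m.LF)
            dd.append(m.D)
            th.append(m.TH)
        table[metric_column(band, "lf")] = lf
        table[metric_column(band, "diameter")] = dd
        table[metric_column(band, "th")] = th
    return table


# ---------------------------------------------------------------------------
# pair-enumeration betweenness oracle

def betweenness_by_pair_enumeration(tree):
    """BC(v) = fraction of unordered pairs {a, b} (a, b != v) whose unique
    tree path passes through v, computed by explicit path enumeration."""
    import networkx as nx
    g = tree.to_networkx()
    n = tree.n_nodes
    counts = np.zeros(n)
    for a, b in combinations(range(n), 2):
        path = nx.shortest_path(g, a, b)
        for v in path[1:-1]:
            counts[v] += 1
    return counts / ((n - 1) * (n - 2) / 2)
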