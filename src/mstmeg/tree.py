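"""Minimum spanning trees of connectivity matrices and their topology.

The spanning tree is built to maximize total connectivity (equivalently,
Kruskal on the reciprocal of positive weights): edges are examined in
descending AEC-c order, with non-positive weights ranked strictly below all
positive ones and ties broken lexicographically by (i, j), so the result is
deterministic even without the unique-weight assumption.

Global metrics for a tree on N nodes with m = N - 1 edges:

* leaf fraction      LF = L / m, L the number of degree-1 nodes;
* normalized diameter D = d / m, d the largest hop distance;
* tree hierarchy     TH = L / (2 m BCmax), BCmax the maximum betweenness
  centrality expressed as the fraction of node pairs (endpoints excluded)
  routed through a node, i.e. normalized by (N-1)(N-2)/2.

A star has LF = 1, d = 2 and TH = 1/2; a path has L = 2 and D = 1.  TH
penalizes both line-like inefficiency and star-like hub overload.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "SpanningTree", "TreeMetrics", "mst_from_matrix", "leaf_fraction",
    "tree_diameter", "tree_betweenness", "tree_hierarchy", "tree_metrics",
    "subject_metrics",
]


@dataclass
class SpanningTree:
    """Loopless connected subgraph on ``n_nodes`` with ``n_nodes - 1`` edges."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.n_nodes
        if n < 3:
            raise ValueError("trees with fewer than 3 nodes are not supported")
        if len(self.edges) != n - 1:
            raise ValueError(
                f"a spanning tree on {n} nodes needs {n - 1} edges, "
                f"got {len(self.edges)}")
        g = self.to_networkx()
        if g.number_of_nodes() != n or not nx.is_connected(g):
            raise ValueError("edges do not form a connected spanning subgraph")
        if not self.node_labels:
            self.node_labels = [f"node_{i:03d}" for i in range(n)]
        if len(self.node_labels) != n:
            raise ValueError("node_labels length does not match n_nodes")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


@dataclass
class TreeMetrics:
    """Global topology metrics of one tree (or an epoch average).

    For a single tree L, d and the degrees are integers; after averaging
    across epochs they are real-valued means.
    """

    n_nodes: int
    m: int
    L: float
    LF: float
    d: float
    D: float
    BCmax: float
    TH: float
    degrees: np.ndarray | None = None


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def mst_from_matrix(matrix: ConnectivityMatrix | np.ndarray) -> SpanningTree:
    """Maximum-connectivity spanning tree of a symmetric matrix (Kruskal).

    Edges carry the original AEC-c weights.  Non-positive weights are never
    preferred over positive ones (descending numeric order guarantees this);
    an all-zero matrix is still spanned via the lexicographic tie-break.
    """
    if isinstance(matrix, ConnectivityMatrix):
        values = matrix.values
        labels = list(matrix.region_labels)
    else:
        values = np.asarray(matrix, dtype=float)
        labels = []
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"matrix must be square, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite entries")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    iu, ju = np.triu_indices(n, 1)
    w = values[iu, ju]
    # stable descending sort on weight; secondary key lexicographic (i, j)
    order = np.lexsort((ju, iu, -w))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j, float(w[k])))
            if len(edges) == n - 1:
                break
    return SpanningTree(n_nodes=n, edges=edges, node_labels=labels)


def leaf_fraction(tree: SpanningTree) -> tuple[int, float]:
    """Leaf count L and leaf fraction LF = L / m."""
    deg = tree.degrees()
    L = int((deg == 1).sum())
    return L, L / tree.n_edges


def tree_diameter(tree: SpanningTree) -> tuple[int, float]:
    """Hop diameter d and normalized diameter D = d / m."""
    g = tree.to_networkx()
    d = nx.diameter(g)
    return int(d), d / tree.n_edges


def tree_betweenness(tree: SpanningTree) -> np.ndarray:
    """Betweenness centrality per node as a fraction of node pairs in [0, 1].

    BC(v) is the share of unordered pairs {a, b} (a, b != v) whose unique
    tree path passes through v, normalized by (N-1)(N-2)/2.
    """
    g = tree.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=True, weight=None)
    return np.array([bc[i] for i in range(tree.n_nodes)])


def tree_hierarchy(tree: SpanningTree) -> float:
    """TH = L / (2 m BCmax); in (0, 1] for any tree with N >= 3."""
    L, _ = leaf_fraction(tree)
    bcmax = float(tree_betweenness(tree).max())
    return L / (2.0 * tree.n_edges * bcmax)


def tree_metrics(tree: SpanningTree) -> TreeMetrics:
    """All global metrics of a single tree."""
    L, lf = leaf_fraction(tree)
    d, dn = tree_diameter(tree)
    bc = tree_betweenness(tree)
    bcmax = float(bc.max())
    th = L / (2.0 * tree.n_edges * bcmax)
    return TreeMetrics(n_nodes=tree.n_nodes, m=tree.n_edges, L=L, LF=lf,
                       d=d, D=dn, BCmax=bcmax, TH=th, degrees=tree.degrees())


def subject_metrics(matrices: list[ConnectivityMatrix | np.ndarray]) -> TreeMetrics:
    """Per-epoch trees, metrics per epoch, arithmetic mean across epochs.

    Yields the subject-level "one single value per topological parameter"
    for one frequency band.
    """
    if not matrices:
        raise ValueError("need at least one epoch matrix")
    per_epoch = []
    n = None
    for m in matrices:
        t = mst_from_matrix(m)
        if n is None:
            n = t.n_nodes
        elif t.n_nodes != n:
            raise ValueError(
                f"mixed matrix sizes: expected {n} nodes, got {t.n_nodes}")
        per_epoch.append(tree_metrics(t))
    assert n is not None
    return TreeMetrics(
        n_nodes=n,
        m=n - 1,
        L=float(np.mean([t.L for t in per_epoch])),
        LF=float(np.mean([t.LF for t in per_epoch])),
        d=float(np.mean([t.d for t in per_epoch])),
        D=float(np.mean([t.D for t in per_epoch])),
        BCmax=float(np.mean([t.BCmax for t in per_epoch])),
        TH=float(np.mean([t.TH for t in per_epoch])),
        degrees=np.mean([t.degrees for t in per_epoch], axis=0),
    )
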