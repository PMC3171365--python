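"""Exact ML structure search over indegree-1 DAGs via minimum spanning tree.

Maximizing the indegree-1 Gaussian BN likelihood over topologies is the
Chow-Liu problem in its Gaussian form: the optimum over the whole class is
an oriented spanning tree of the minimum spanning tree of the complete
graph weighted by w_ij = log(1 - r_ij^2).  Because attaching a parent never
decreases a node's profile likelihood (weights are <= 0), a connected tree
always dominates any forest, and the likelihood depends only on the
undirected edge set, so any orientation of the MST attains the maximum.

Ties in the MST (and hence the optimizing graph) need not be unique;
Kruskal's algorithm with edges sorted lexicographically by (w, i, j) makes
the returned tree deterministic.  ``enumerate_oracle`` provides a brute
force check by exhausting every acyclic parent vector for small p.
"""

from __future__ import annotations

import numpy as np

from .gaussian_bn import (
    NO_PARENT,
    BNTopology,
    ExpressionSample,
    NetworkFit,
    SufficientStats,
    _parent_loglik,
    compute_sufficient_stats,
    edge_weight,
    graph_loglik,
    node_loglik,
)

__all__ = [
    "NotATreeError",
    "SizeError",
    "build_weight_graph",
    "minimum_spanning_tree",
    "orient_tree",
    "fit_ml_network",
    "enumerate_oracle",
]


class NotATreeError(ValueError):
    """The supplied edge set is not a spanning tree."""


class SizeError(ValueError):
    """Problem too large for exhaustive enumeration."""


def build_weight_graph(stats: SufficientStats) -> list[tuple[int, int, float]]:
    """All p*(p-1)/2 weighted edges (i, j, w_ij) of the complete graph, i < j."""
    p = stats.p
    return [
        (i, j, edge_weight(stats, i, j)) for i in range(p) for j in range(i + 1, p)
    ]


def minimum_spanning_tree(
    edges: list[tuple[int, int, float]], p: int
) -> frozenset[tuple[int, int]]:
    """Kruskal's MST with deterministic (w, i, j) lexicographic tie-break.

    Returns the p - 1 undirected edges of a minimum-weight spanning tree of
    the complete graph on p nodes.
    """
    order = sorted((w, i, j) for (i, j, w) in edges)
    uf = list(range(p))

    def find(a: int) -> int:
        while uf[a] != a:
            uf[a] = uf[uf[a]]
            a = uf[a]
        return a

    tree: set[tuple[int, int]] = set()
    for w, i, j in order:
        ri, rj = find(i), find(j)
        if ri != rj:
            uf[ri] = rj
            tree.add((i, j))
            if len(tree) == p - 1:
                break
    if len(tree) != p - 1:
        raise NotATreeError("edge list does not connect all nodes")
    return frozenset(tree)


def orient_tree(tree: frozenset[tuple[int, int]], root: int, p: int | None = None) -> BNTopology:
    """Orient an undirected spanning tree away from ``root``.

    Every non-root node's parent is its neighbor on the unique path toward
    the root.  Raises :class:`NotATreeError` if the edges do not form a
    spanning tree on the implied node set.
    """
    edges = list(tree)
    if p is None:
        p = max(max(i, j) for i, j in edges) + 1 if edges else 1
    if len(edges) != p - 1:
        raise NotATreeError(f"expected {p - 1} edges for {p} nodes, got {len(edges)}")
    adjacency: list[list[int]] = [[] for _ in range(p)]
    for i, j in edges:
        adjacency[i].append(j)
        adjacency[j].append(i)
    parent = np.full(p, NO_PARENT, dtype=int)
    seen = np.zeros(p, dtype=bool)
    seen[root] = True
    stack = [root]
    while stack:
        node = stack.pop()
        for nb in adjacency[node]:
            if not seen[nb]:
                seen[nb] = True
                parent[nb] = node
                stack.append(nb)
    if not seen.all():
        raise NotATreeError("edge set is disconnected or cyclic")
    return BNTopology(parent)


def _fit_from_stats(stats: SufficientStats, root: int = 0) -> tuple[np.ndarray, float]:
    """Parent vector and maximized log-likelihood from summary statistics."""
    tree = minimum_spanning_tree(build_weight_graph(stats), stats.p)
    topo = orient_tree(tree, root, stats.p)
    return topo.parent, _parent_loglik(stats, topo.parent)


def fit_ml_network(data: ExpressionSample) -> NetworkFit:
    """Exact maximum-likelihood indegree-1 network for ``data``.

    Pipeline: sufficient statistics -> complete weighted graph -> Kruskal
    MST -> orientation from node 0.  The returned log-likelihood is the
    maximum of :func:`~bnetdiff.gaussian_bn.graph_loglik` over the entire
    indegree-1 DAG class.
    """
    stats = compute_sufficient_stats(data)
    parent, loglik = _fit_from_stats(stats)
    return NetworkFit(topology=BNTopology(parent), loglik=loglik, stats=stats)


def ml_loglik(values: np.ndarray) -> float:
    """Maximized log-likelihood for a raw (n x p) matrix.

    Fast path used by the permutation engine; numerically identical to
    ``fit_ml_network(ExpressionSample.from_matrix(values)).loglik``.
    """
    sample = ExpressionSample.from_matrix(values)
    stats = compute_sufficient_stats(sample)
    return _fit_from_stats(stats)[1]


def _acyclic(parent: tuple[int, ...]) -> bool:
    p = len(parent)
    state = [0] * p
    for start in range(p):
        node = start
        path = []
        while node != NO_PARENT and state[node] == 0:
            state[node] = 1
            path.append(node)
            node = parent[node]
        if node != NO_PARENT and state[node] == 1:
            return False
        for v in path:
            state[v] = 2
    return True


def enumerate_oracle(data: ExpressionSample, max_p: int = 7) -> NetworkFit:
    """Brute-force ML fit by exhausting every acyclic parent vector.

    Iterates the full space {NO_PARENT, 0..p-1}^p (minus self-parents),
    keeps acyclic vectors and maximizes the graph log-likelihood; ties go
    to the lexicographically smallest parent vector (roots sorting first).
    Only feasible for small p; raises :class:`SizeError` above ``max_p``.
    """
    import itertools

    stats = compute_sufficient_stats(data)
    p = stats.p
    if p > max_p:
        raise SizeError(f"enumeration limited to p <= {max_p}, got {p}")
    # node_term[i][k]: log-likelihood of node i with parent choices ordered
    # [NO_PARENT, 0, 1, ..., p-1] minus i, matching lexicographic order.
    choices = [[NO_PARENT] + [j for j in range(p) if j != i] for i in range(p)]
    node_term = [
        [node_loglik(stats, i, pa) for pa in choices[i]] for i in range(p)
    ]
    best_ll = -np.inf
    best_parent: tuple[int, ...] | None = None
    for combo in itertools.product(*(range(p) for _ in range(p))):
        parent = tuple(choices[i][k] for i, k in enumerate(combo))
        if not _acyclic(parent):
            continue
        ll = sum(node_term[i][k] for i, k in enumerate(combo))
        if ll > best_ll:
            best_ll = ll
            best_parent = parent
    assert best_parent is not None
    topo = BNTopology(np.array(best_parent, dtype=int))
    return NetworkFit(topology=topo, loglik=graph_loglik(stats, topo), stats=stats)
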