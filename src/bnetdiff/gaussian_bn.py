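"""Gaussian Bayesian networks with maximum indegree one.

A Bayesian network restricted to indegree <= 1 is an oriented forest: each
node (gene) has at most one parent, and the joint density factorizes into
univariate Gaussian regressions of each child's expression on its parent's.
For a fixed topology the profile (maximized) log-likelihood has a closed
form in the sample means, maximum-likelihood variances and pairwise
correlations, so the whole fit reduces to summary statistics: the node
contribution is -(n/2) * (log(2*pi*m) + 1) with m the residual ML variance
of the node given its parent, i.e. var_i for a root and var_i * (1 - r^2)
for a child with parent correlation r.

Variances use the ML (divide by n) scaling so that likelihood identities,
such as pooling two identical samples doubling the log-likelihood, hold
exactly.  Residual variances and 1 - r^2 are clamped away from zero so that
degenerate, perfectly collinear inputs (which permutation replicates of
small samples can produce) yield finite likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VARIANCE_FLOOR",
    "WEIGHT_FLOOR",
    "NO_PARENT",
    "ConstantVariableError",
    "CycleError",
    "ExpressionSample",
    "SufficientStats",
    "BNTopology",
    "NetworkFit",
    "compute_sufficient_stats",
    "edge_weight",
    "node_loglik",
    "graph_loglik",
]

#: lower clamp on maximum-likelihood variances (expression^2 units)
VARIANCE_FLOOR = 1e-12
#: lower clamp on 1 - r^2 inside edge weights and residual variances
WEIGHT_FLOOR = 1e-12
#: parent-vector entry marking a root node (no parent)
NO_PARENT = -1


class ConstantVariableError(ValueError):
    """A variable has (near-)zero variance, so correlations are undefined."""

    def __init__(self, variable_ids, group=None):
        self.variable_ids = list(variable_ids)
        self.group = group
        where = f" in group {group}" if group is not None else ""
        super().__init__(
            f"constant variable(s){where}: {', '.join(map(str, self.variable_ids))}"
        )


class CycleError(ValueError):
    """A parent vector does not describe an acyclic graph."""


@dataclass(frozen=True)
class ExpressionSample:
    """An n x p matrix of complete expression replicates.

    Rows are samples (replicates), columns are variables (genes).  Missing
    values are a hard error: the model assumes independent and complete
    replicates.
    """

    values: np.ndarray
    variable_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "variable_ids", tuple(self.variable_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-d (samples x variables) matrix")
        n, p = values.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 variables, got {p}")
        if len(self.variable_ids) != p:
            raise ValueError("variable_ids length does not match matrix width")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix height")
        if len(set(self.variable_ids)) != p:
            raise ValueError("variable_ids must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("missing or non-finite values are not supported")

    @classmethod
    def from_matrix(cls, values, variable_ids=None, sample_ids=None) -> "ExpressionSample":
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        if variable_ids is None:
            variable_ids = tuple(f"g{i + 1}" for i in range(p))
        if sample_ids is None:
            sample_ids = tuple(f"s{i + 1}" for i in range(n))
        return cls(values, tuple(variable_ids), tuple(sample_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset_variables(self, indices) -> "ExpressionSample":
        indices = np.asarray(indices, dtype=int)
        return ExpressionSample(
            self.values[:, indices],
            tuple(self.variable_ids[i] for i in indices),
            self.sample_ids,
        )

    def subset_samples(self, indices) -> "ExpressionSample":
        indices = np.asarray(indices, dtype=int)
        return ExpressionSample(
            self.values[indices, :],
            self.variable_ids,
            tuple(self.sample_ids[i] for i in indices),
        )


@dataclass(frozen=True)
class SufficientStats:
    """Summary statistics sufficient for the indegree-1 Gaussian BN.

    ``var`` uses the maximum-likelihood (divide by n) scaling.  ``corr`` is
    the product-moment correlation matrix with unit diagonal.
    """

    n: int
    mean: np.ndarray
    var: np.ndarray
    corr: np.ndarray

    @property
    def p(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class BNTopology:
    """A parent map over p nodes with indegree <= 1.

    ``parent[i]`` is the parent node of i, or ``NO_PARENT`` (-1) when node i
    is a root.  Validity (range, no self-parent, acyclicity, at least one
    root) is checked at construction.
    """

    parent: np.ndarray

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=int)
        object.__setattr__(self, "parent", parent)
        p = parent.shape[0]
        if parent.ndim != 1 or p < 1:
            raise ValueError("parent must be a 1-d vector")
        if np.any((parent < NO_PARENT) | (parent >= p)):
            raise ValueError("parent entries must lie in {-1, 0..p-1}")
        if np.any(parent == np.arange(p)):
            raise CycleError("a node cannot be its own parent")
        if not np.any(parent == NO_PARENT):
            raise CycleError("at least one node must be a root")
        _assert_acyclic(parent)

    @property
    def p(self) -> int:
        return self.parent.shape[0]

    def undirected_edges(self) -> frozenset:
        """The undirected edge set {(min(i, pa_i), max(i, pa_i))}."""
        edges = set()
        for i, pa in enumerate(self.parent):
            if pa != NO_PARENT:
                edges.add((min(i, int(pa)), max(i, int(pa))))
        return frozenset(edges)


def _assert_acyclic(parent: np.ndarray) -> None:
    """Raise CycleError if following parents from any node loops."""
    p = parent.shape[0]
    state = np.zeros(p, dtype=np.int8)  # 0 unvisited, 1 on path, 2 done
    for start in range(p):
        node = start
        path = []
        while node != NO_PARENT and state[node] == 0:
            state[node] = 1
            path.append(node)
            node = int(parent[node])
        if node != NO_PARENT and state[node] == 1:
            raise CycleError(f"cycle detected through node {node}")
        for v in path:
            state[v] = 2


@dataclass(frozen=True)
class NetworkFit:
    """A fitted topology together with its maximized log-likelihood."""

    topology: BNTopology
    loglik: float
    stats: SufficientStats


def compute_sufficient_stats(
    data: ExpressionSample, variance_floor: float = VARIANCE_FLOOR
) -> SufficientStats:
    """Sample means, ML variances and the correlation matrix of ``data``.

    Raises :class:`ConstantVariableError` (naming the offending variables)
    when any ML variance falls at or below ``variance_floor``, since the
    correlation of a constant variable is undefined.
    """
    x = data.values
    n = x.shape[0]
    mean = x.mean(axis=0)
    centered = x - mean
    var = np.einsum("ij,ij->j", centered, centered) / n
    bad = var <= variance_floor
    if np.any(bad):
        raise ConstantVariableError(
            [data.variable_ids[i] for i in np.flatnonzero(bad)]
        )
    cov = (centered.T @ centered) / n
    denom = np.sqrt(np.outer(var, var))
    corr = np.clip(cov / denom, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SufficientStats(n=n, mean=mean, var=var, corr=corr)


def edge_weight(stats: SufficientStats, i: int, j: int) -> float:
    """MST edge weight w_ij = log(max(1 - r_ij^2, weight_floor)).

    Always <= 0 and finite; symmetric in (i, j).  Minimizing the sum of
    these weights over spanning-tree edges maximizes the tree likelihood.
    """
    if i == j:
        raise ValueError("edge weight requires two distinct nodes")
    r = stats.corr[i, j]
    return float(np.log(max(1.0 - r * r, WEIGHT_FLOOR)))


def _residual_variances(stats: SufficientStats, parent: np.ndarray) -> np.ndarray:
    """Per-node residual ML variance m_i given the parent vector."""
    m = stats.var.astype(float).copy()
    children = np.flatnonzero(parent != NO_PARENT)
    if children.size:
        r = stats.corr[children, parent[children]]
        m[children] = np.maximum(
            stats.var[children] * (1.0 - r * r), VARIANCE_FLOOR * WEIGHT_FLOOR
        )
    return m


def node_loglik(stats: SufficientStats, i: int, parent: int = NO_PARENT) -> float:
    """Profile Gaussian log-likelihood of node i given its parent.

    -(n/2) * (log(2*pi*m) + 1) with m = var_i for a root and
    m = var_i * (1 - r^2) for a child (clamped below).
    """
    if parent == i:
        raise ValueError("a node cannot be its own parent")
    if parent == NO_PARENT:
        m = stats.var[i]
    else:
        r = stats.corr[i, parent]
        m = max(stats.var[i] * (1.0 - r * r), VARIANCE_FLOOR * WEIGHT_FLOOR)
    return -0.5 * stats.n * (np.log(2.0 * np.pi * m) + 1.0)


def _parent_loglik(stats: SufficientStats, parent: np.ndarray) -> float:
    """Vectorized sum of node log-likelihoods for a (trusted) parent vector."""
    m = _residual_variances(stats, parent)
    return float(-0.5 * stats.n * np.sum(np.log(2.0 * np.pi * m) + 1.0))


def graph_loglik(stats: SufficientStats, topology: BNTopology) -> float:
    """Maximized log-likelihood of the whole network.

    The node-wise decomposition makes this
    -(n/2) * [sum_i (log(2*pi*var_i) + 1) + sum_edges log(1 - r^2)],
    which depends on the topology only through its undirected edge set
    (orientation invariance).
    """
    if topology.p != stats.p:
        raise ValueError("topology size does not match statistics")
    _assert_acyclic(topology.parent)
    return _parent_loglik(stats, topology.parent)
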