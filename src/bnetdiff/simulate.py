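"""Synthetic tree-structured Gaussian expression data.

The generator draws a uniform random labelled tree, assigns each node a
marginal mean and standard deviation and each edge a target correlation,
and samples ancestrally: roots from their marginal normal, a child given
its parent's value x from

    Normal(mean_c + rho * (sd_c / sd_p) * (x - mean_p),  sd_c^2 * (1 - rho^2)),

so every node keeps its declared marginal sd and every edge attains its
declared population correlation.  Two-group scenarios model the patterns a
differential-coexpression test must separate: "null" (both phenotype
groups from one model), "decorrelate" (a fraction of edge correlations
zeroed in group B — coexpression present in one class and absent in the
other), and "rewire" (group B on an independently drawn tree with the same
correlation magnitudes).

Default study conditions: p = 10 genes, groups of 25 samples each, edge
correlation 0.9 (a strong coexpression signal), unit marginal sds and zero
means.  All draws are reproducible: the same configuration and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .gaussian_bn import NO_PARENT, BNTopology, ExpressionSample
from .tree_fit import fit_ml_network, orient_tree
from .two_sample_test import TwoSampleData

__all__ = [
    "GenerativeBN",
    "random_tree",
    "sample_bn",
    "two_group_scenario",
    "parameter_recovery_report",
    "null_correlation_sd",
]


@dataclass(frozen=True)
class GenerativeBN:
    """A sampling model: topology plus marginal and edge parameters.

    ``edge_corr[i]`` is the target correlation between node i and its
    parent; entries for root nodes are ignored (kept 0 by convention).
    """

    topology: BNTopology
    means: np.ndarray
    sds: np.ndarray
    edge_corr: np.ndarray

    def __post_init__(self):
        p = self.topology.p
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        rho = np.asarray(self.edge_corr, dtype=float)
        for name, arr in (("means", means), ("sds", sds), ("edge_corr", rho)):
            if arr.shape != (p,):
                raise ValueError(f"{name} must have length p = {p}")
        if np.any(sds <= 0):
            raise ValueError("marginal sds must be positive")
        if np.any(np.abs(rho) >= 1.0):
            raise ValueError("edge correlations must lie in (-1, 1)")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "edge_corr", rho)

    @classmethod
    def with_uniform_corr(
        cls, topology: BNTopology, rho: float = 0.9
    ) -> "GenerativeBN":
        """Zero means, unit sds, correlation ``rho`` on every edge."""
        p = topology.p
        corr = np.where(topology.parent != NO_PARENT, rho, 0.0)
        return cls(topology, np.zeros(p), np.ones(p), corr)


def random_tree(p: int, rng: np.random.Generator) -> BNTopology:
    """Uniform random labelled tree on p nodes, oriented from node 0.

    Sampled by decoding a uniform Prüfer sequence, so each of the p^(p-2)
    labelled trees is equally likely.
    """
    if p < 2:
        raise ValueError("need at least 2 nodes")
    if p == 2:
        edges = frozenset({(0, 1)})
    else:
        seq = [int(v) for v in rng.integers(0, p, size=p - 2)]
        tree = nx.from_prufer_sequence(seq)
        edges = frozenset((min(i, j), max(i, j)) for i, j in tree.edges())
    return orient_tree(edges, root=0, p=p)


def _topological_order(parent: np.ndarray) -> list[int]:
    p = parent.shape[0]
    depth = np.zeros(p, dtype=int)
    for i in range(p):
        d, node = 0, i
        while parent[node] != NO_PARENT:
            node = int(parent[node])
            d += 1
        depth[i] = d
    return sorted(range(p), key=lambda i: (depth[i], i))


def sample_bn(model: GenerativeBN, n: int, rng: np.random.Generator) -> ExpressionSample:
    """Draw n ancestral samples from the generative model."""
    if n < 3:
        raise ValueError("need at least 3 samples")
    parent = model.topology.parent
    p = parent.shape[0]
    values = np.empty((n, p))
    noise = rng.standard_normal((n, p))
    for i in _topological_order(parent):
        pa = int(parent[i])
        if pa == NO_PARENT:
            values[:, i] = model.means[i] + model.sds[i] * noise[:, i]
        else:
            rho = model.edge_corr[i]
            cond_mean = model.means[i] + rho * (model.sds[i] / model.sds[pa]) * (
                values[:, pa] - model.means[pa]
            )
            cond_sd = model.sds[i] * np.sqrt(1.0 - rho * rho)
            values[:, i] = cond_mean + cond_sd * noise[:, i]
    return ExpressionSample.from_matrix(values)


def two_group_scenario(
    kind: str,
    p: int = 10,
    n1: int = 25,
    n2: int = 25,
    strength: float = 1.0,
    rho: float = 0.9,
    rng: np.random.Generator | None = None,
) -> TwoSampleData:
    """A two-phenotype dataset under a named coexpression scenario.

    kind = "null": both groups from one tree model (edge correlation rho).
    kind = "decorrelate": group B keeps the topology but a fraction
    ``strength`` of its edges (randomly chosen) has correlation set to 0.
    kind = "rewire": group B uses an independently drawn random tree with
    the same correlation magnitude.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not (0.0 <= strength <= 1.0):
        raise ValueError("strength must lie in [0, 1]")
    model_a = GenerativeBN.with_uniform_corr(random_tree(p, rng), rho)
    if kind == "null":
        model_b = model_a
    elif kind == "decorrelate":
        children = np.flatnonzero(model_a.topology.parent != NO_PARENT)
        n_zero = int(round(strength * children.size))
        zeroed = rng.choice(children, size=n_zero, replace=False)
        corr = model_a.edge_corr.copy()
        corr[zeroed] = 0.0
        model_b = GenerativeBN(model_a.topology, model_a.means, model_a.sds, corr)
    elif kind == "rewire":
        model_b = GenerativeBN.with_uniform_corr(random_tree(p, rng), rho)
    else:
        raise ValueError(f"unknown scenario kind: {kind!r}")
    group_a = sample_bn(model_a, n1, rng)
    group_b = sample_bn(model_b, n2, rng)
    return TwoSampleData.from_matrices(group_a.values, group_b.values)


def null_correlation_sd(
    n: int,
    replications: int,
    rng: np.random.Generator,
    scale: str = "fisher",
) -> float:
    """Monte-Carlo dispersion of a sample correlation under independence.

    Draws ``replications`` pairs of independent standard-normal samples of
    size n and returns the standard deviation of their sample correlation.
    On the default variance-stabilized Fisher scale (z = atanh r, the scale
    on which correlation confidence intervals are built) the sd is
    approximately 1/sqrt(n - 3); ``scale="raw"`` reports the sd of r
    itself, approximately 1/sqrt(n - 1).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    x = rng.standard_normal((replications, n, 2))
    xc = x - x.mean(axis=1, keepdims=True)
    r = (xc[:, :, 0] * xc[:, :, 1]).sum(axis=1) / np.sqrt(
        (xc[:, :, 0] ** 2).sum(axis=1) * (xc[:, :, 1] ** 2).sum(axis=1)
    )
    if scale == "fisher":
        return float(np.arctanh(r).std())
    if scale == "raw":
        return float(r.std())
    raise ValueError("scale must be 'fisher' or 'raw'")


def parameter_recovery_report(
    p: int,
    rho: float,
    n: int,
    replications: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of replications in which the ML fit recovers the true tree.

    Each replication draws a fresh uniform tree, samples n observations
    with correlation rho on every edge, fits the indegree-1 network and
    compares undirected edge sets exactly.
    """
    hits = 0
    for _ in range(replications):
        topo = random_tree(p, rng)
        model = GenerativeBN.with_uniform_corr(topo, rho)
        fit = fit_ml_network(sample_bn(model, n, rng))
        if fit.topology.undirected_edges() == topo.undirected_edges():
            hits += 1
    return hits / replications
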