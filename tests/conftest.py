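"""Shared fixtures; the heavy simulation batteries are session-scoped."""

from dataclasses import replace

import numpy as np
import pytest

import bnetdiff as bd


def make_battery(seed: int, n_sets: int = 50, n_alt: int = 20, p: int = 10,
                 n1: int = 25, n2: int = 25, rho: float = 0.9):
    """A multi-set two-phenotype dataset: n_alt decorrelated sets, rest null.

    Returns (expr, labels, collection); set names are prefixed ALT_/NULL_
    so tests can tell the ground truth.
    """
    rng = np.random.default_rng(seed)
    kinds = ["decorrelate"] * n_alt + ["null"] * (n_sets - n_alt)
    names: dict[str, tuple[str, ...]] = {}
    cols, gene_names, labels = [], [], None
    for k, kind in enumerate(kinds):
        d = bd.two_group_scenario(kind, p=p, n1=n1, n2=n2, strength=1.0, rho=rho, rng=rng)
        labels = d.labels
        genes = [f"set{k:02d}_g{j}" for j in range(p)]
        prefix = "ALT" if kind == "decorrelate" else "NULL"
        names[f"{prefix}_set{k:02d}"] = tuple(genes)
        gene_names += genes
        cols.append(d.pooled.values)
    expr = bd.ExpressionSample(
        np.hstack(cols), tuple(gene_names), tuple(f"s{i}" for i in range(n1 + n2))
    )
    return expr, labels, bd.GeneSetCollection(names)


@pytest.fixture(scope="session")
def null_pvalues_500():
    """Fixed-test p-values for 500 all-null two-group datasets (B = 199)."""
    rng = np.random.default_rng(42)
    ps = []
    for i in range(500):
        data = bd.two_group_scenario("null", p=10, n1=25, n2=25, rho=0.9, rng=rng)
        ps.append(bd.fixed_permutation_test(data, B=199, seed=1000 + i).p_value)
    return np.array(ps)


@pytest.fixture(scope="session")
def decorrelate_power_pvalues():
    """Per-seed (MLRT, sum-t^2) permutation p-values on decorrelated data.

    50 independent datasets with every edge correlation 0.9 in group A and
    0 in group B, no mean shift; both statistics run in the same balanced
    permutation engine with B = 999.
    """
    p_mlrt, p_sumt2 = [], []
    for i in range(50):
        rng = np.random.default_rng(9000 + i)
        data = bd.two_group_scenario(
            "decorrelate", p=10, n1=25, n2=25, strength=1.0, rho=0.9, rng=rng
        )
        p_mlrt.append(bd.fixed_permutation_test(data, B=999, seed=i).p_value)
        p_sumt2.append(
            bd.fixed_permutation_test(data, B=999, seed=i, statistic="sumt2").p_value
        )
    return np.array(p_mlrt), np.array(p_sumt2)


@pytest.fixture(scope="session")
def battery_fixed_and_stopped():
    """Fixed and stopped gene-set analyses of one 50-set battery.

    Both modes share per-set replicate streams (same master seed) and the
    stopped truncation bound equals the fixed replicate count, so the
    stopped run is embedded in the fixed run replicate-for-replicate.
    """
    expr, labels, collection = make_battery(123)
    config = bd.AnalysisConfig(mode="fixed", B=500, seed=7, fdr_level=0.25)
    fixed = bd.run_geneset_analysis(expr, labels, collection, config)
    stopped = bd.run_geneset_analysis(
        expr, labels, collection, replace(config, mode="stopped")
    )
    return fixed, stopped
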