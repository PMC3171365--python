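"""Two-sample network-equality test with a balanced-permutation null.

The null hypothesis is that two phenotype groups share one Gaussian BN
model.  The generalized maximum-likelihood-ratio statistic (log scale) is

    T = L_A + L_B - L_pooled

where each term is the maximized indegree-1 network log-likelihood of
group A, group B and the pooled sample.  T >= 0 always, large values
rejecting equality.  Asymptotic chi-square calibration is unavailable
(small n, discrete topology space), so significance is estimated by
permuting group labels.

Permutations are *balanced*: each permuted group contains approximately
equal proportions of the two original groups, which reduces spurious
variability when a true difference exists.  The pooled fit is permutation
invariant and is computed once.  The p-value uses the add-one estimator
(1 + #{T_b >= T_obs}) / (1 + B), which is exactly valid under
exchangeability.

Reproducibility: each replicate b draws from its own RNG substream derived
from (seed, b), so results do not depend on evaluation order and fixed and
stopped procedures driven by the same seed see identical replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .gaussian_bn import ConstantVariableError, ExpressionSample, compute_sufficient_stats
from .tree_fit import _fit_from_stats

__all__ = [
    "TwoSampleData",
    "PermutationResult",
    "lrt_statistic",
    "balanced_permutation",
    "plain_permutation",
    "fixed_permutation_test",
]

_MAX_REPLICATE_RETRIES = 100


@dataclass(frozen=True)
class TwoSampleData:
    """A pooled expression sample with binary group labels (A = 1, B = 0)."""

    pooled: ExpressionSample
    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (self.pooled.n,):
            raise ValueError("labels length must match the pooled sample size")
        if not np.all((labels == 0) | (labels == 1)):
            raise ValueError("labels must be binary (group A = 1, group B = 0)")
        if self.n1 < 3 or self.n2 < 3:
            raise ValueError(
                "each group needs at least 3 samples to estimate correlations"
            )

    @classmethod
    def from_matrices(cls, group_a, group_b, variable_ids=None) -> "TwoSampleData":
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        pooled = ExpressionSample.from_matrix(np.vstack([a, b]), variable_ids)
        labels = np.r_[np.ones(a.shape[0], dtype=int), np.zeros(b.shape[0], dtype=int)]
        return cls(pooled, labels)

    @property
    def n1(self) -> int:
        return int(self.labels.sum())

    @property
    def n2(self) -> int:
        return int(self.labels.shape[0] - self.labels.sum())

    def group_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.flatnonzero(self.labels == 1), np.flatnonzero(self.labels == 0)


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic with its permutation exceedance summary."""

    T_obs: float
    B: int
    exceed: int
    p_value: float
    seed: int


def _group_loglik(values: np.ndarray, ids, group: str) -> float:
    try:
        stats = compute_sufficient_stats(ExpressionSample.from_matrix(values, ids))
    except ConstantVariableError as err:
        raise ConstantVariableError(err.variable_ids, group=group) from None
    return _fit_from_stats(stats)[1]


def lrt_statistic(data: TwoSampleData) -> float:
    """T = L_A + L_B - L_pooled, each a maximized network log-likelihood."""
    idx_a, idx_b = data.group_indices()
    x = data.pooled.values
    ids = data.pooled.variable_ids
    ll_a = _group_loglik(x[idx_a], ids, "A")
    ll_b = _group_loglik(x[idx_b], ids, "B")
    ll_pool = _group_loglik(x, ids, "pooled")
    return ll_a + ll_b - ll_pool


def balanced_permutation(n1: int, n2: int, rng: np.random.Generator) -> np.ndarray:
    """One balanced label permutation for group sizes (n1, n2).

    Returns a binary vector of length n1 + n2 whose first n1 positions
    refer to the original group-A members and the rest to group B; ones
    mark membership in the permuted group A.  The permuted group A holds
    k members of the original A — k drawn uniformly from
    {floor(n1/2), ceil(n1/2)} — and n1 - k members of the original B, so
    both permuted groups mix the originals in near-equal proportion.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("balanced permutation needs both group sizes >= 2")
    k = n1 // 2
    if n1 % 2 == 1:
        k += int(rng.integers(0, 2))
    if n1 - k > n2:
        raise ValueError(
            f"balanced permutation infeasible for sizes n1={n1}, n2={n2}"
        )
    labels = np.zeros(n1 + n2, dtype=int)
    labels[rng.choice(n1, size=k, replace=False)] = 1
    labels[n1 + rng.choice(n2, size=n1 - k, replace=False)] = 1
    return labels


def plain_permutation(n1: int, n2: int, rng: np.random.Generator) -> np.ndarray:
    """Unrestricted label shuffle preserving group sizes (sensitivity option)."""
    labels = np.r_[np.ones(n1, dtype=int), np.zeros(n2, dtype=int)]
    return rng.permutation(labels)


def _replicate_rng(seed: int, b: int, retry: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(b), int(retry)]))


StatisticLike = Union[str, Callable[[TwoSampleData], float]]


def _make_replicate_engine(
    data: TwoSampleData, statistic: StatisticLike, permutation: str, cache_pooled: bool
):
    """(T_obs, replicate_fn) where replicate_fn(rng) -> one permuted statistic.

    For the MLRT the pooled fit is permutation invariant, so its
    log-likelihood is computed once and reused across replicates (the
    ``cache_pooled`` flag exists to verify this changes no output).
    """
    idx_a, idx_b = data.group_indices()
    n1, n2 = idx_a.size, idx_b.size
    x = data.pooled.values
    ids = data.pooled.variable_ids
    draw = balanced_permutation if permutation == "balanced" else plain_permutation
    if permutation not in ("balanced", "plain"):
        raise ValueError(f"unknown permutation kind: {permutation!r}")

    def permuted_indices(rng):
        lab = draw(n1, n2, rng)
        new_a = np.r_[idx_a[lab[:n1] == 1], idx_b[lab[n1:] == 1]]
        new_b = np.r_[idx_a[lab[:n1] == 0], idx_b[lab[n1:] == 0]]
        return new_a, new_b

    if statistic == "mlrt":
        ll_pool = _group_loglik(x, ids, "pooled")
        t_obs = (
            _group_loglik(x[idx_a], ids, "A")
            + _group_loglik(x[idx_b], ids, "B")
            - ll_pool
        )

        def replicate(rng):
            new_a, new_b = permuted_indices(rng)
            pool_term = (
                ll_pool if cache_pooled else _group_loglik(x, ids, "pooled")
            )
            return (
                _group_loglik(x[new_a], ids, "A")
                + _group_loglik(x[new_b], ids, "B")
                - pool_term
            )

        return t_obs, replicate

    if statistic == "sumt2":
        from .geneset_pipeline import sum_squared_t_statistic as stat_fn
    elif callable(statistic):
        stat_fn = statistic
    else:
        raise ValueError(f"unknown statistic: {statistic!r}")

    def as_data(new_a, new_b):
        labels = np.zeros(x.shape[0], dtype=int)
        labels[new_a] = 1
        return TwoSampleData(data.pooled, labels)

    t_obs = stat_fn(data)

    def replicate(rng):
        new_a, new_b = permuted_indices(rng)
        return stat_fn(as_data(new_a, new_b))

    return t_obs, replicate


def _draw_replicate(replicate, seed: int, b: int) -> float:
    """One permuted statistic, redrawing degenerate replicates."""
    for retry in range(_MAX_REPLICATE_RETRIES):
        try:
            return replicate(_replicate_rng(seed, b, retry))
        except ConstantVariableError:
            continue
    raise ConstantVariableError(
        ["<unresolved>"], group=f"replicate {b} after {_MAX_REPLICATE_RETRIES} retries"
    )


def fixed_permutation_test(
    data: TwoSampleData,
    B: int,
    seed: int,
    statistic: StatisticLike = "mlrt",
    permutation: str = "balanced",
    cache_pooled: bool = True,
) -> PermutationResult:
    """Fixed-length balanced permutation test with B replicates.

    p-value = (1 + #{T_b >= T_obs}) / (1 + B).
    """
    if B < 1:
        raise ValueError("need at least one permutation replicate")
    t_obs, replicate = _make_replicate_engine(data, statistic, permutation, cache_pooled)
    exceed = 0
    for b in range(B):
        if _draw_replicate(replicate, seed, b) >= t_obs:
            exceed += 1
    return PermutationResult(
        T_obs=float(t_obs),
        B=B,
        exceed=exceed,
        p_value=(1 + exceed) / (1 + B),
        seed=seed,
    )
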