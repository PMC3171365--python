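"""SPRT-stopped permutation testing and step-up/step-down adjustment.

Permutation p-value estimation is the estimation of a binomial exceedance
probability, so Wald's sequential probability ratio test applies: choose
surrogate simple hypotheses p = p0 versus p = p1 bracketing the working
significance level, and stop drawing replicates once the running evidence
favors a large p-value.  For multiple testing only the *upper* SPRT
boundary is kept (small p-values must remain estimable), giving the linear
stopping rule

    stop at the first n with  sum_{i<=n} I_i >= c0 + c1 * n,

with I_i = 1{T_i >= T_obs} and (c0, c1) derived from (p0, p1, alpha, beta).
An early stop certifies a large p-value, which is then conservatively set
to 1; a test that runs to the truncation bound n_max reports the ordinary
add-one estimate.  Driven by a shared replicate stream the stopped p-value
is pathwise >= the fixed one, so any monotone step-up/step-down multiple
testing procedure applied to stopped p-values rejects a subset of what it
would reject on fixed p-values — the stopped procedure is embedded in, and
strictly more conservative than, the fixed procedure, inheriting its error
control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .two_sample_test import (
    StatisticLike,
    TwoSampleData,
    _draw_replicate,
    _make_replicate_engine,
)

__all__ = [
    "StoppingConfig",
    "StoppedResult",
    "MTPResult",
    "sprt_boundaries",
    "sprt_single_test",
    "stopped_permutation_test",
    "bh_rule",
    "holm_rule",
    "bonferroni_rule",
    "adjust_step_up",
    "adjust_step_down",
    "pfer_rate",
]


@dataclass(frozen=True)
class StoppingConfig:
    """Surrogate SPRT hypotheses, error rates and truncation bound.

    Defaults bracket the conventional 0.05 level (p0 = 0.04, p1 = 0.06)
    with SPRT errors alpha = beta = 0.05 and truncation at n_max = 5000
    replicates, the fixed-procedure replication count.
    """

    p0: float = 0.04
    p1: float = 0.06
    alpha_sprt: float = 0.05
    beta_sprt: float = 0.05
    n_max: int = 5000

    def __post_init__(self):
        if not (0.0 < self.p0 < self.p1 < 1.0):
            raise ValueError("require 0 < p0 < p1 < 1")
        if not (0.0 < self.alpha_sprt < 0.5 and 0.0 < self.beta_sprt < 0.5):
            raise ValueError("SPRT error rates must lie in (0, 0.5)")
        if self.n_max < 1:
            raise ValueError("n_max must be at least 1")


@dataclass(frozen=True)
class StoppedResult:
    """Outcome of the one-boundary stopped permutation test."""

    tau: int
    exceed: int
    stopped_early: bool
    p_value: float
    p_empirical: float


@dataclass(frozen=True)
class MTPResult:
    """Raw and adjusted p-values with the rejection set at a given level."""

    raw: np.ndarray
    adjusted: np.ndarray
    method: str
    rejected: np.ndarray


def sprt_boundaries(config: StoppingConfig) -> tuple[float, float]:
    """Linear-count form (c0, c1) of the upper SPRT boundary.

    The Bernoulli log-likelihood ratio crossing
    S_n >= log((1 - beta)/alpha) is algebraically equivalent to the count
    crossing sum(I) >= c0 + c1 * n with

        c1 = log((1-p0)/(1-p1)) / log(p1 (1-p0) / (p0 (1-p1)))
        c0 = log((1-beta)/alpha) / log(p1 (1-p0) / (p0 (1-p1)))

    and p0 < c1 < p1 always.
    """
    p0, p1 = config.p0, config.p1
    denom = math.log(p1 * (1.0 - p0) / (p0 * (1.0 - p1)))
    c1 = math.log((1.0 - p0) / (1.0 - p1)) / denom
    c0 = math.log((1.0 - config.beta_sprt) / config.alpha_sprt) / denom
    return c0, c1


def sprt_single_test(
    indicator_stream: Iterable[int],
    alpha_level: float,
    config: StoppingConfig,
) -> tuple[str, int]:
    """Two-boundary truncated SPRT resolving one test at ``alpha_level``.

    Tests p = p0 (true significance level small: 'significant') against
    p = p1 ('not_significant') on the exceedance indicators.  Crossing the
    upper boundary A* = (1-beta)/alpha concludes not_significant, the lower
    boundary B* = beta/(1-alpha) concludes significant; at truncation the
    decision falls back on the add-one estimate
    (1 + sum I) / (1 + n_max) <= alpha_level.
    Returns (decision, number of indicators consumed).
    """
    log_a = math.log((1.0 - config.beta_sprt) / config.alpha_sprt)
    log_b = math.log(config.beta_sprt / (1.0 - config.alpha_sprt))
    up = math.log(config.p1 / config.p0)
    down = math.log((1.0 - config.p1) / (1.0 - config.p0))
    s = 0.0
    n = 0
    total = 0
    for ind in indicator_stream:
        n += 1
        total += int(ind)
        s += up if ind else down
        if s >= log_a:
            return "not_significant", n
        if s <= log_b:
            return "significant", n
        if n >= config.n_max:
            break
    p_hat = (1 + total) / (1 + n)
    return ("significant" if p_hat <= alpha_level else "not_significant"), n


def stopped_permutation_test(
    data: TwoSampleData,
    config: StoppingConfig,
    seed: int,
    statistic: StatisticLike = "mlrt",
    permutation: str = "balanced",
    early_p: str = "one",
) -> StoppedResult:
    """One-boundary SPRT-stopped balanced permutation test (upper bound only).

    Replicates are drawn from the same (seed, b) substreams as
    :func:`~bnetdiff.two_sample_test.fixed_permutation_test`, so with
    ``config.n_max == B`` the two procedures see identical replicates and
    the stopped p-value is pathwise >= the fixed one.

    ``early_p`` selects the p-value reported after an early stop: "one"
    (default, the conservative assignment that makes the embedding exact)
    or "empirical" ((1 + exceed)/(1 + tau), diagnostic only).
    """
    if early_p not in ("one", "empirical"):
        raise ValueError("early_p must be 'one' or 'empirical'")
    c0, c1 = sprt_boundaries(config)
    t_obs, replicate = _make_replicate_engine(data, statistic, permutation, True)
    exceed = 0
    tau = 0
    stopped_early = False
    for b in range(config.n_max):
        tau = b + 1
        if _draw_replicate(replicate, seed, b) >= t_obs:
            exceed += 1
        if exceed >= c0 + c1 * tau:
            stopped_early = True
            break
    p_empirical = (1 + exceed) / (1 + tau)
    if stopped_early:
        p_value = 1.0 if early_p == "one" else p_empirical
    else:
        p_value = (1 + exceed) / (1 + config.n_max)
    return StoppedResult(
        tau=tau,
        exceed=exceed,
        stopped_early=stopped_early,
        p_value=p_value,
        p_empirical=p_empirical,
    )


# ---------------------------------------------------------------------------
# Step-up / step-down multiple testing procedures.
#
# A procedure is parameterized by its rank multiplier c(i, m): the adjusted
# value of the i-th order statistic is built from p_(i) * c(i, m), monotone
# enforced by a running minimum from the largest rank (step-up) or running
# maximum from the smallest (step-down).


def bh_rule(i: int, m: int) -> float:
    """Benjamini-Hochberg multiplier m / i (step-up, controls FDR)."""
    return m / i


def holm_rule(i: int, m: int) -> float:
    """Holm multiplier m - i + 1 (step-down, controls FWER)."""
    return m - i + 1


def bonferroni_rule(i: int, m: int) -> float:
    """Bonferroni multiplier m (single-step)."""
    return m


def _scaled_order(raw: np.ndarray, rule: Callable[[int, int], float]):
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("raw p-values must be a non-empty 1-d vector")
    if np.any((raw <= 0.0) | (raw > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    m = raw.size
    order = np.argsort(raw, kind="stable")
    mult = np.array([rule(i + 1, m) for i in range(m)], dtype=float)
    return raw, m, order, raw[order] * mult


def adjust_step_up(
    raw: Sequence[float],
    rule: Callable[[int, int], float] = bh_rule,
    alpha: float = 0.05,
    method: str | None = None,
) -> MTPResult:
    """Step-up adjusted p-values: p~_(i) = min_{j >= i} min(1, p_(j) c(j, m)).

    With the default BH rule c(i, m) = m/i this controls the FDR; the
    rejection set {p~ <= alpha} coincides with the classical step-up
    threshold rule.
    """
    raw, m, order, scaled = _scaled_order(raw, rule)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return MTPResult(
        raw=raw,
        adjusted=adjusted,
        method=method or "step-up",
        rejected=adjusted <= alpha,
    )


def adjust_step_down(
    raw: Sequence[float],
    rule: Callable[[int, int], float] = holm_rule,
    alpha: float = 0.05,
    method: str | None = None,
) -> MTPResult:
    """Step-down adjusted p-values: p~_(i) = max_{j <= i} min(1, p_(j) c(j, m))."""
    raw, m, order, scaled = _scaled_order(raw, rule)
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(np.minimum(1.0, scaled)))
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return MTPResult(
        raw=raw,
        adjusted=adjusted,
        method=method or "step-down",
        rejected=adjusted <= alpha,
    )


def pfer_rate(p: float, m: int) -> float:
    """Per-family error rate m * p: expected false positives at threshold p."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be at least 1")
    return m * p
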