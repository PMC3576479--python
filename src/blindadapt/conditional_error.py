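"""Conditional rejection probabilities for partially observed binary designs.

When per-arm sample sizes are known at an interim look, the interim data can
carry real information about the treatment effect: with 0 treated / 3 control
patients enrolled and all three having events, the fixed 3-per-arm design's
one-sided Fisher-equivalent test rejects exactly when none of the next three
(all treated) patients has an event, so its conditional rejection probability
is (1 − p_T)³ — far from alpha in either direction.  This module computes
such conditional probabilities by brute-force enumeration of second-stage
outcome vectors (no closed form assumed), and implements the conditional-error
switching adversary: keep the original (possibly miscalibrated) test when its
conditional error exceeds alpha, otherwise switch to a permutation test —
the strategy that inflates the unconditional error of a test that was not
pre-planned as a permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional, Union

import numpy as np
from scipy.special import ndtr

from . import permutation_engine as engine
from .statistics import SMALLER, TestStatistic, get_statistic

#: Largest number of second-stage outcome vectors enumerated exactly.
ENUM_CAP = 2**20


# ---------------------------------------------------------------------------
# Interim state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterimState:
    """A two-stage binary design frozen at the interim look.

    First stage: ``n_T1``/``n_C1`` patients per arm with ``events_T1``/
    ``events_C1`` observed events.  Second stage: ``n_T2``/``n_C2`` planned
    patients whose outcomes are Bernoulli(``p_T``)/Bernoulli(``p_C``).  The
    final analysis is the one-sided Fisher-equivalent (unstratified)
    permutation test at ``alpha``; ``direction`` = "smaller" means fewer
    events favor treatment.
    """

    n_T1: int
    n_C1: int
    events_T1: int
    events_C1: int
    n_T2: int
    n_C2: int
    p_T: float
    p_C: float
    alpha: float = 0.05
    direction: str = SMALLER

    def __post_init__(self):
        for name in ("n_T1", "n_C1", "events_T1", "events_C1", "n_T2", "n_C2"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer")
        if self.events_T1 > self.n_T1 or self.events_C1 > self.n_C1:
            raise ValueError("more events than patients in a first-stage arm")
        for name in ("p_T", "p_C"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ConditionalErrorResult:
    probability: float
    method: str  # "exact" | "monte_carlo"
    mc_standard_error: float = 0.0

    def __float__(self) -> float:
        return self.probability


@lru_cache(maxsize=4096)
def _final_test_rejects(
    n_t: int, n_c: int, e_t: int, e_c: int, alpha: float, direction: str
) -> bool:
    """Does the unstratified permutation test (diff in proportions) reject
    on a trial with these final counts?  Cached: the statistic depends on
    the data only through the 2×2 counts."""
    y = np.array([1.0] * e_t + [0.0] * (n_t - e_t) + [1.0] * e_c + [0.0] * (n_c - e_c))
    z = np.array([True] * n_t + [False] * n_c)
    stat = get_statistic("diff_props", direction)
    res = engine.permutation_pvalue(y, z, stat, mode="exact")
    return bool(res.p_value <= alpha)


def conditional_rejection_probability(
    state: InterimState,
    cap: int = ENUM_CAP,
    B: int = 100_000,
    seed: Optional[int] = None,
) -> ConditionalErrorResult:
    """Probability that the final test rejects, given the first stage.

    Exact mode enumerates all 2^(n_T2 + n_C2) second-stage outcome vectors,
    weights each by its Bernoulli probability under (p_T, p_C), and sums the
    rejection indicators.  Beyond ``cap`` vectors it falls back to seeded
    Monte Carlo with a reported standard error.
    """
    n2 = state.n_T2 + state.n_C2
    n_t = state.n_T1 + state.n_T2
    n_c = state.n_C1 + state.n_C2

    def rejects(e_t2: np.ndarray, e_c2: np.ndarray) -> np.ndarray:
        out = np.empty(len(e_t2), dtype=bool)
        for i, (a, b) in enumerate(zip(e_t2, e_c2)):
            out[i] = _final_test_rejects(
                n_t,
                n_c,
                state.events_T1 + int(a),
                state.events_C1 + int(b),
                state.alpha,
                state.direction,
            )
        return out

    if 2**n2 <= cap:
        # every second-stage outcome vector, as rows of bits
        if n2 == 0:
            bits = np.zeros((1, 0), dtype=bool)
        else:
            idx = np.arange(2**n2, dtype=np.int64)
            bits = (idx[:, None] >> np.arange(n2)[None, :]) & 1
            bits = bits.astype(bool)
        t_bits = bits[:, : state.n_T2]
        c_bits = bits[:, state.n_T2 :]
        e_t2 = t_bits.sum(axis=1)
        e_c2 = c_bits.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_p = (
                e_t2 * np.log(np.maximum(state.p_T, 1e-300))
                + (state.n_T2 - e_t2) * np.log(np.maximum(1 - state.p_T, 1e-300))
                + e_c2 * np.log(np.maximum(state.p_C, 1e-300))
                + (state.n_C2 - e_c2) * np.log(np.maximum(1 - state.p_C, 1e-300))
            )
        prob = np.exp(log_p)
        # degenerate probabilities: zero out impossible vectors exactly
        if state.p_T == 0.0:
            prob[e_t2 > 0] = 0.0
        if state.p_T == 1.0:
            prob[e_t2 < state.n_T2] = 0.0
        if state.p_C == 0.0:
            prob[e_c2 > 0] = 0.0
        if state.p_C == 1.0:
            prob[e_c2 < state.n_C2] = 0.0
        rej = rejects(e_t2, e_c2)
        return ConditionalErrorResult(float(prob[rej].sum()), "exact")

    rng = np.random.default_rng(seed)
    e_t2 = rng.binomial(state.n_T2, state.p_T, size=B)
    e_c2 = rng.binomial(state.n_C2, state.p_C, size=B)
    rej = rejects(e_t2, e_c2)
    p_hat = float(rej.mean())
    se = float(np.sqrt(p_hat * (1 - p_hat) / B))
    return ConditionalErrorResult(p_hat, "monte_carlo", se)


# ---------------------------------------------------------------------------
# Conditional error of a fixed design given the lumped data
# ---------------------------------------------------------------------------

TestLike = Union[TestStatistic, Callable[[np.ndarray, np.ndarray], float]]


def normal_approx_prop_test(direction: str = SMALLER) -> Callable:
    """One-sided two-proportion z-test (pooled variance, no continuity
    correction) returning a p-value.  Deliberately the kind of
    nominal-level approximate test whose conditional error can exceed alpha
    on small samples — the contrast case for the permutation test."""

    def pvalue(y: np.ndarray, z: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=bool)
        ok = ~np.isnan(y)
        y_t, y_c = y[ok & z], y[ok & ~z]
        if y_t.size == 0 or y_c.size == 0:
            return 1.0
        p_pool = float(np.concatenate([y_t, y_c]).mean())
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / y_t.size + 1 / y_c.size))
        if se == 0:
            return 1.0
        zscore = (y_t.mean() - y_c.mean()) / se
        return float(ndtr(zscore)) if direction == SMALLER else float(ndtr(-zscore))

    return pvalue


def conditional_error_of_fixed_design(
    lumped_y: np.ndarray,
    scheme: engine.RandomizationScheme,
    test: TestLike,
    alpha: float,
    stratum=None,
) -> float:
    """Probability, over uniformly distributed consistent assignment
    vectors given the lumped outcomes, that ``test`` rejects at ``alpha``.

    For a permutation test (pass its `TestStatistic`) this is exactly the
    attainable size, hence ≤ alpha.  For an approximate test (pass a
    callable ``(y, z) -> p``) it can exceed alpha — the opening for the
    switching adversary.
    """
    if isinstance(test, TestStatistic):
        return engine.attainable_size(lumped_y, test, scheme, alpha, stratum=stratum)
    y = np.asarray(lumped_y, dtype=float)
    masks = engine.enumerate_assignments(scheme, stratum)
    rejects = sum(1 for m in masks if test(y, m) <= alpha)
    return rejects / len(masks)


@dataclass(frozen=True)
class SwitchDecision:
    """Outcome of the conditional-error switching adversary on one lumped
    data set: which branch was taken and the conditional rejection
    probability on each branch."""

    branch: str  # "no_change" | "switch"
    conditional_error_original: float
    conditional_error_permutation: float

    @property
    def conditional_error_taken(self) -> float:
        return (
            self.conditional_error_original
            if self.branch == "no_change"
            else self.conditional_error_permutation
        )


def switching_adversary(
    lumped_y: np.ndarray,
    scheme: engine.RandomizationScheme,
    original_test: TestLike,
    permutation_statistic: TestStatistic,
    alpha: float,
) -> SwitchDecision:
    """Keep the original test when its conditional error given the lumped
    data exceeds alpha; otherwise switch to the permutation test.

    The switch branch is controlled at alpha (engine validity); the
    no-change branch keeps whatever conditional error the original test
    had, which exceeds alpha by construction of the branch condition —
    hence the strategy inflates the unconditional error whenever the
    original test was not itself the permutation test.
    """
    ce_orig = conditional_error_of_fixed_design(lumped_y, scheme, original_test, alpha)
    ce_perm = engine.attainable_size(lumped_y, permutation_statistic, scheme, alpha)
    branch = "no_change" if ce_orig > alpha else "switch"
    return SwitchDecision(
        branch=branch,
        conditional_error_original=ce_orig,
        conditional_error_permutation=ce_perm,
    )
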