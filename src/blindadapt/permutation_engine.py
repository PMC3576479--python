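"""Exact and Monte-Carlo permutation tests, plain and stratified.

A permutation (randomization) test conditions on the observed outcomes y and
treats every treatment-assignment vector z consistent with the randomization
scheme — the per-arm counts, per stratum when those were known at adaptation
time — as equally likely.  The p-value refers the observed statistic t(y, z)
to its distribution over all consistent z.  Because this distribution is
computed conditionally on y, the test's conditional size given y (its
"attainable size") never exceeds the nominal level, which is precisely the
guarantee that survives any pre-unblinding adaptation.

Exact mode has two routes:

* explicit enumeration of consistent assignment vectors, for any statistic,
  capped at `EXACT_CAP` vectors;
* a subset-sum convolution for *linear* statistics (those exposing weights,
  see `blindadapt.statistics.TestStatistic.weights`) on complete data: the
  null distribution of ``sum(w[z])`` is built per stratum by dynamic
  programming over distinct outcome values and convolved across strata.  For
  binary outcomes this reproduces the (product-)hypergeometric distribution
  exactly and has no practical size limit.

Monte-Carlo mode samples consistent vectors uniformly (seeded Fisher–Yates
shuffles within strata, or an equivalent vectorized uniform k-subset draw)
and uses the add-one estimator p = (1 + #extreme) / (1 + B), which can never
report p = 0 and keeps the test valid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .statistics import (
    LARGER,
    SMALLER,
    DegenerateStatistic,
    TestStatistic,
)

#: Largest number of assignment vectors enumerated explicitly.
EXACT_CAP = 10**6

#: Relative tolerance for "tied with the observed statistic".
TIE_RTOL = 1e-12

#: Value-class count up to which the subset-sum DP is attempted.
_DP_MAX_CLASSES = 16

#: Below this many consistent assignments, linear statistics use direct
#: enumeration (a matrix product) instead of the subset-sum DP.
_MATMUL_CAP = 100_000


class EnumerationCapError(ValueError):
    """Exact enumeration would exceed EXACT_CAP; use Monte-Carlo mode."""


class InconsistentAssignmentError(ValueError):
    """The observed z does not match the randomization scheme."""


# ---------------------------------------------------------------------------
# Randomization scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomizationScheme:
    """Per-stratum (n_T, n_C) arm counts; one stratum = fully blinded."""

    strata: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.strata:
            raise ValueError("scheme needs at least one stratum")
        for n_t, n_c in self.strata:
            if n_t < 0 or n_c < 0:
                raise ValueError("arm counts must be nonnegative")

    @property
    def n(self) -> int:
        return sum(n_t + n_c for n_t, n_c in self.strata)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @classmethod
    def from_assignments(
        cls, z: np.ndarray, stratum: Optional[np.ndarray] = None
    ) -> "RandomizationScheme":
        z = _as_mask(z)
        if stratum is None:
            return cls(strata=((int(z.sum()), int((~z).sum())),))
        stratum = np.asarray(stratum, dtype=int)
        out = []
        for s in np.unique(stratum):
            in_s = stratum == s
            n_t = int((z & in_s).sum())
            out.append((n_t, int(in_s.sum()) - n_t))
        return cls(strata=tuple(out))


def n_consistent(scheme: RandomizationScheme) -> int:
    """Number of assignment vectors consistent with the scheme:
    the product over strata of binomial coefficients C(n_s, n_T_s)."""
    return math.prod(math.comb(n_t + n_c, n_t) for n_t, n_c in scheme.strata)


def _as_mask(z) -> np.ndarray:
    z = np.asarray(z)
    if z.dtype == bool:
        return z
    mask = np.zeros(len(z), dtype=bool)
    for i, lab in enumerate(z):
        if lab == "T":
            mask[i] = True
        elif lab != "C":
            raise ValueError(f"unknown arm label {lab!r} at position {i}")
    return mask


def _stratum_groups(n: int, stratum: Optional[np.ndarray]) -> list[np.ndarray]:
    if stratum is None:
        return [np.arange(n)]
    stratum = np.asarray(stratum, dtype=int)
    return [np.where(stratum == s)[0] for s in np.unique(stratum)]


@lru_cache(maxsize=32)
def _combo_masks(n: int, k: int) -> np.ndarray:
    """All C(n, k) boolean masks of k chosen positions out of n."""
    m = math.comb(n, k)
    out = np.zeros((m, n), dtype=bool)
    for row, combo in enumerate(itertools.combinations(range(n), k)):
        out[row, list(combo)] = True
    return out


def enumerate_assignments(
    scheme: RandomizationScheme,
    stratum: Optional[np.ndarray] = None,
    cap: int = EXACT_CAP,
) -> np.ndarray:
    """All consistent assignment masks, shape (N, n), True = treated.

    ``stratum`` maps subject positions to strata; by default strata occupy
    contiguous blocks in scheme order.  Raises `EnumerationCapError` when the
    count exceeds ``cap`` (callers should fall back to Monte Carlo).
    """
    total = n_consistent(scheme)
    if total > cap:
        raise EnumerationCapError(
            f"{total} consistent assignments exceed the cap of {cap}; "
            "use Monte-Carlo mode"
        )
    n = scheme.n
    if stratum is None:
        bounds = np.cumsum([0] + [n_t + n_c for n_t, n_c in scheme.strata])
        groups = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(scheme.strata))]
    else:
        groups = _stratum_groups(n, stratum)
        if len(groups) != len(scheme.strata):
            raise ValueError("stratum labels do not match the scheme")
    masks = np.zeros((1, n), dtype=bool)
    for g, (n_t, n_c) in zip(groups, scheme.strata):
        if len(g) != n_t + n_c:
            raise ValueError("stratum size does not match the scheme")
        local = _combo_masks(len(g), n_t)
        m = local.shape[0]
        prev = masks.shape[0]
        masks = np.repeat(masks, m, axis=0)
        masks[:, g] = np.tile(local, (prev, 1))
    return masks


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test.

    ``attainable_p`` (exact mode only) is the sorted grid of p-values the
    test can produce on these outcomes — its conditional rejection
    probability at level alpha is the largest attainable p not above alpha.
    ``degenerate`` flags a statistic that carried no information (p forced
    to 1).
    """

    p_value: float
    n_permutations: int
    method: str  # "exact" | "monte_carlo"
    observed_statistic: float
    attainable_p: Optional[tuple[float, ...]] = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Exact null distributions for linear statistics
# ---------------------------------------------------------------------------


def _subset_sum_dist(w: np.ndarray, k: int, cap: int = EXACT_CAP) -> dict[float, int]:
    """Distribution of sum(w over a uniform k-subset): value -> #subsets.

    Uses a DP over distinct-value classes (multivariate hypergeometric
    structure) when there are few distinct values, else explicit enumeration
    under the cap.  Counts are exact integers.
    """
    w = np.round(np.asarray(w, dtype=float), 12)
    values, counts = np.unique(w, return_counts=True)
    if k == 0 or k == len(w):
        return {float(w.sum()) if k else 0.0: 1}
    if len(values) <= _DP_MAX_CLASSES:
        # state: (number chosen so far) -> {sum: count}
        states: dict[int, dict[float, int]] = {0: {0.0: 1}}
        for v, c in zip(values, counts):
            nxt: dict[int, dict[float, int]] = {}
            for chosen, sums in states.items():
                for j in range(0, min(int(c), k - chosen) + 1):
                    ways = math.comb(int(c), j)
                    bucket = nxt.setdefault(chosen + j, {})
                    add = round(v * j, 12)
                    for s, cnt in sums.items():
                        key = round(s + add, 12)
                        bucket[key] = bucket.get(key, 0) + cnt * ways
            states = nxt
        return states[k]
    if math.comb(len(w), k) > cap:
        raise EnumerationCapError(
            "too many distinct values and too many subsets for exact mode; "
            "use Monte-Carlo mode"
        )
    dist: dict[float, int] = {}
    for combo in itertools.combinations(range(len(w)), k):
        s = round(float(w[list(combo)].sum()), 12)
        dist[s] = dist.get(s, 0) + 1
    return dist


def _convolve(d1: dict[float, int], d2: dict[float, int]) -> dict[float, int]:
    out: dict[float, int] = {}
    for a, ca in d1.items():
        for b, cb in d2.items():
            key = round(a + b, 12)
            out[key] = out.get(key, 0) + ca * cb
    return out


def _linear_null_distribution(
    w: np.ndarray,
    scheme: RandomizationScheme,
    groups: Sequence[np.ndarray],
) -> dict[float, int]:
    dist = {0.0: 1}
    for g, (n_t, _) in zip(groups, scheme.strata):
        dist = _convolve(dist, _subset_sum_dist(w[g], n_t))
    return dist


def _dist_pvalue_grid(
    dist: dict[float, int], direction: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Support sorted most-favorable-first, cumulative counts, and total."""
    support = np.array(sorted(dist, reverse=(direction == LARGER)))
    counts = np.array([dist[float(s)] for s in support], dtype=object)
    cum = np.cumsum(counts)
    return support, cum, int(cum[-1])


def _tol(t_obs: float) -> float:
    return TIE_RTOL * max(1.0, abs(t_obs))


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------


def _exact_pvalue(y, zmask, stratum, statistic, scheme) -> PermutationResult:
    groups = _stratum_groups(len(y), stratum)
    try:
        t_obs = statistic.evaluate(y, zmask)
    except DegenerateStatistic:
        return PermutationResult(
            p_value=1.0,
            n_permutations=n_consistent(scheme),
            method="exact",
            observed_statistic=float("nan"),
            attainable_p=(1.0,),
            degenerate=True,
        )
    y = np.asarray(y, dtype=float)
    complete = not np.isnan(y).any()
    linear = complete and statistic.weights is not None
    if linear and n_consistent(scheme) > _MATMUL_CAP:
        # round once so the observed sum and the DP's keys agree to tolerance
        w = np.round(np.asarray(statistic.weights(y), dtype=float), 12)
        s_obs = float(w[zmask].sum())
        dist = _linear_null_distribution(w, scheme, groups)
        support, cum, total = _dist_pvalue_grid(dist, statistic.direction)
        tol = _tol(s_obs)
        if statistic.direction == SMALLER:
            extreme = int(cum[np.searchsorted(support, s_obs + tol, side="right") - 1])
        else:
            # support is descending; favorable = support >= s_obs - tol
            idx = np.searchsorted(-support, -(s_obs - tol), side="right") - 1
            extreme = int(cum[idx]) if idx >= 0 else 0
        attainable = tuple(float(c) / total for c in cum)
        return PermutationResult(
            p_value=extreme / total,
            n_permutations=total,
            method="exact",
            observed_statistic=t_obs,
            attainable_p=attainable,
        )
    masks = enumerate_assignments(scheme, stratum)
    if linear:
        w = np.asarray(statistic.weights(y), dtype=float)
        s_all = masks.astype(float) @ w
        s_obs = float(w[zmask].sum())
        # t is increasing in the treated weight sum, so tails transfer
        t_all, t_obs_cmp = s_all, s_obs
    else:
        t_all = np.array([statistic.evaluate(y, m) for m in masks])
        t_obs_cmp = t_obs
    tol = _tol(t_obs_cmp)
    if statistic.direction == SMALLER:
        extreme = int((t_all <= t_obs_cmp + tol).sum())
    else:
        extreme = int((t_all >= t_obs_cmp - tol).sum())
    total = len(masks)
    order = np.sort(t_all) if statistic.direction == SMALLER else -np.sort(-t_all)
    uniq_counts = np.unique(np.round(order, 12), return_counts=True)[1]
    attainable = tuple((np.cumsum(uniq_counts) / total).tolist())
    return PermutationResult(
        p_value=extreme / total,
        n_permutations=total,
        method="exact",
        observed_statistic=t_obs,
        attainable_p=attainable,
    )


def _mc_pvalue(y, zmask, stratum, statistic, scheme, B, seed) -> PermutationResult:
    rng = np.random.default_rng(seed)
    try:
        t_obs = statistic.evaluate(y, zmask)
    except DegenerateStatistic:
        return PermutationResult(
            p_value=1.0,
            n_permutations=B,
            method="monte_carlo",
            observed_statistic=float("nan"),
            degenerate=True,
        )
    y = np.asarray(y, dtype=float)
    groups = _stratum_groups(len(y), stratum)
    complete = not np.isnan(y).any()
    tol = _tol(t_obs)
    if complete and statistic.weights is not None:
        w = np.asarray(statistic.weights(y), dtype=float)
        s_obs = float(w[zmask].sum())
        extreme = 0
        chunk = 1 << 14
        done = 0
        while done < B:
            m = min(chunk, B - done)
            s = np.zeros(m)
            for g, (n_t, _) in zip(groups, scheme.strata):
                if n_t == 0:
                    continue
                if n_t == len(g):
                    s += w[g].sum()
                    continue
                r = rng.random((m, len(g)))
                idx = np.argpartition(r, n_t - 1, axis=1)[:, :n_t]
                s += w[g][idx].sum(axis=1)
            if statistic.direction == SMALLER:
                extreme += int((s <= s_obs + tol).sum())
            else:
                extreme += int((s >= s_obs - tol).sum())
            done += m
    else:
        extreme = 0
        for _ in range(B):
            mask = np.zeros(len(y), dtype=bool)
            for g, (n_t, _) in zip(groups, scheme.strata):
                mask[g[rng.permutation(len(g))[:n_t]]] = True
            t = statistic.evaluate(y, mask)
            if statistic.direction == SMALLER:
                extreme += t <= t_obs + tol
            else:
                extreme += t >= t_obs - tol
    return PermutationResult(
        p_value=(1 + extreme) / (1 + B),
        n_permutations=B,
        method="monte_carlo",
        observed_statistic=t_obs,
    )


def _check_consistent(zmask, stratum, scheme) -> None:
    observed = RandomizationScheme.from_assignments(zmask, stratum)
    if observed.strata != scheme.strata:
        raise InconsistentAssignmentError(
            f"observed per-stratum counts {observed.strata} do not match "
            f"the scheme {scheme.strata}"
        )


def permutation_pvalue(
    y,
    z_observed,
    statistic: TestStatistic,
    scheme: Optional[RandomizationScheme] = None,
    mode: str = "exact",
    B: int = 9999,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Plain (single-stratum) permutation p-value.

    Exact mode: p = #{consistent z : t(y, z) at least as favorable to
    treatment as observed} / N, ties at the observed value counting as
    extreme.  Monte-Carlo mode: add-one estimator over B uniform draws.
    """
    zmask = _as_mask(z_observed)
    if scheme is None:
        scheme = RandomizationScheme.from_assignments(zmask)
    else:
        if scheme.n_strata != 1:
            raise ValueError("permutation_pvalue is unstratified; use "
                             "stratified_permutation_pvalue for >1 stratum")
        _check_consistent(zmask, None, scheme)
    if mode == "exact":
        return _exact_pvalue(y, zmask, None, statistic, scheme)
    if mode == "monte_carlo":
        return _mc_pvalue(y, zmask, None, statistic, scheme, B, seed)
    raise ValueError(f"unknown mode {mode!r}")


def stratified_permutation_pvalue(
    y,
    z_observed,
    statistic: TestStatistic,
    stratum,
    scheme: Optional[RandomizationScheme] = None,
    mode: str = "exact",
    B: int = 9999,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Permutation p-value restricted to assignments preserving per-stratum
    arm counts — the fix when per-arm sizes were known at adaptation time.

    With a single stratum this reduces bitwise to `permutation_pvalue`.
    """
    zmask = _as_mask(z_observed)
    stratum = np.asarray(stratum, dtype=int)
    if scheme is None:
        scheme = RandomizationScheme.from_assignments(zmask, stratum)
    else:
        _check_consistent(zmask, stratum, scheme)
    if mode == "exact":
        return _exact_pvalue(y, zmask, stratum, statistic, scheme)
    if mode == "monte_carlo":
        return _mc_pvalue(y, zmask, stratum, statistic, scheme, B, seed)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Fisher's exact test (one-sided) — the binary special case
# ---------------------------------------------------------------------------

FEWER_T_EVENTS = "fewer"
MORE_T_EVENTS = "more"


def fisher_exact_one_sided(table, direction: str = FEWER_T_EVENTS) -> float:
    """One-sided Fisher exact p for a 2×2 table, margins fixed.

    ``table`` is ``[[events_T, nonevents_T], [events_C, nonevents_C]]``.
    ``direction`` states which tail is favorable to treatment: ``"fewer"``
    (fewer events among treated) or ``"more"``.  Empty margins give p = 1.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    n_t = a + b
    m = a + c  # total events
    if n == 0 or n_t == 0 or n_t == n or m == 0 or m == n:
        return 1.0
    rv = hypergeom(n, m, n_t)  # events among treated, margins fixed
    if direction == FEWER_T_EVENTS:
        return float(rv.cdf(a))
    if direction == MORE_T_EVENTS:
        return float(rv.sf(a - 1))
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Conditional size diagnostics
# ---------------------------------------------------------------------------


def attainable_size(
    y,
    statistic: TestStatistic,
    scheme: RandomizationScheme,
    alpha: float,
    stratum=None,
) -> float:
    """Fraction of consistent assignments whose permutation p-value is
    ≤ alpha — the test's conditional type I error rate given the lumped
    outcomes y.  Always ≤ alpha, by construction of the permutation test.
    """
    y = np.asarray(y, dtype=float)
    groups = _stratum_groups(len(y), stratum)
    eps = 1e-12
    complete = not np.isnan(y).any()
    linear = complete and statistic.weights is not None
    if linear and n_consistent(scheme) > _MATMUL_CAP:
        w = np.asarray(statistic.weights(y), dtype=float)
        dist = _linear_null_distribution(w, scheme, groups)
        _, cum, total = _dist_pvalue_grid(dist, statistic.direction)
        probs = np.array([float(c) / total for c in cum])
        ok = probs <= alpha + eps
        return float(probs[ok].max()) if ok.any() else 0.0
    masks = enumerate_assignments(scheme, stratum)
    if linear:
        # t is increasing in the treated weight sum; tails transfer directly
        w = np.asarray(statistic.weights(y), dtype=float)
        t_all = masks.astype(float) @ w
    else:
        t_all = np.array([statistic.evaluate(y, m) for m in masks])
    total = len(masks)
    t_r = np.round(t_all, 12)
    uniq, counts = np.unique(t_r, return_counts=True)
    if statistic.direction == LARGER:
        uniq, counts = uniq[::-1], counts[::-1]
    probs = np.cumsum(counts) / total
    ok = probs <= alpha + eps
    return float(probs[ok].max()) if ok.any() else 0.0
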