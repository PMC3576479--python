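"""Monte-Carlo laboratory: rejection rates of fixed and adaptive analyses.

Each scenario couples a synthetic-trial recipe with an adaptation rule, an
original analysis plan, and a null structure (strong null: treatment touches
nothing; weak null: treatment shifts some endpoints but not the tested one).
Replications use independent RNG streams derived from (seed, replicate), so
results are reproducible and order-independent.

Besides the generic scenario runner there are two purpose-built studies:

* `simulate_samplesize_adversary` — the partially blinded two-stage binary
  design in which per-arm counts are known at the interim.  The adversary
  keeps the original design whenever its conditional rejection probability is
  positive and otherwise extends the second stage (within a cap) to maximize
  that probability.  The plain permutation test's type I error is inflated by
  this strategy; the stratified test — which conditions on the per-arm counts
  at adaptation time — stays at or below alpha.
* `drug_level_selection_study` — three "blinded" endpoints, one of which is
  the drug level in blood.  The adversarial rule reconstructs arm labels
  from positive drug levels and picks the clinical endpoint with the more
  favorable statistic; with two exchangeable clinical endpoints the
  resulting test rejects exactly when the smaller of the two per-endpoint
  p-values clears alpha, which the study also measures directly as an
  independent oracle.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from . import permutation_engine as engine
from .adaptation import (
    AdaptationRule,
    AdaptationWarning,
    AnalysisPlan,
    run_adaptive_analysis,
)
from .conditional_error import InterimState, conditional_rejection_probability
from .statistics import SMALLER, get_statistic
from .trial_data import GeneratorConfig, generate_trial

DEFAULT_REPS = 10_000


# ---------------------------------------------------------------------------
# Scenario plumbing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """One simulation condition.

    ``null_endpoints`` lists the endpoints the treatment does NOT affect;
    None means the strong null (nothing is affected), in which case every
    rejection is a type I error.  Under a weak null only rejections whose
    chosen endpoint is in ``null_endpoints`` count as type I errors.
    """

    name: str
    config: GeneratorConfig
    rule: AdaptationRule
    plan: AnalysisPlan
    reps: int = DEFAULT_REPS
    seed: int = 0
    mode: str = "exact"
    B: int = 9999
    null_endpoints: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Rejection rate with its Monte-Carlo standard error.

    ``rejection_rate`` counts every rejection; ``type_i_error_rate`` counts
    only rejections of a truly null endpoint (they coincide under the strong
    null).  ``branch_frequencies`` maps the adaptation taken (endpoint,
    statistic, threshold) to its relative frequency; frequencies sum to 1.
    """

    rejection_rate: float
    mc_standard_error: float
    reps: int
    seed: int
    branch_frequencies: dict[str, float] = field(default_factory=dict)
    type_i_error_rate: Optional[float] = None
    n_failed: int = 0


def _mc_se(rate: float, reps: int) -> float:
    return math.sqrt(rate * (1.0 - rate) / reps)


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng([seed, rep])


def simulate_rejection_rate(scenario: Scenario) -> SimulationResult:
    """Run the scenario: generate trial -> blinded adaptation -> permutation
    test, ``reps`` times, and tally rejections and adaptation branches."""
    rejections = 0
    type_i = 0
    failed = 0
    branches: dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AdaptationWarning)
        warnings.simplefilter("ignore", UserWarning)
        for rep in range(scenario.reps):
            rng = _rep_rng(scenario.seed, rep)
            try:
                trial = generate_trial(scenario.config, rng=rng)
                record = run_adaptive_analysis(
                    trial,
                    scenario.rule,
                    scenario.plan,
                    mode=scenario.mode,
                    B=scenario.B,
                    seed=int(rng.integers(2**31)),
                )
            except Exception:
                failed += 1
                continue
            plan = record.chosen_plan
            key = f"{plan.endpoint}|{plan.statistic}|{plan.threshold}"
            branches[key] = branches.get(key, 0) + 1
            if record.reject:
                rejections += 1
                if (
                    scenario.null_endpoints is None
                    or plan.endpoint in scenario.null_endpoints
                ):
                    type_i += 1
    done = scenario.reps - failed
    rate = rejections / done if done else float("nan")
    return SimulationResult(
        rejection_rate=rate,
        mc_standard_error=_mc_se(rate, done) if done else float("nan"),
        reps=done,
        seed=scenario.seed,
        branch_frequencies={k: v / done for k, v in sorted(branches.items())},
        type_i_error_rate=type_i / done if done else float("nan"),
        n_failed=failed,
    )


def scenario_report(results: Mapping[str, SimulationResult]) -> pd.DataFrame:
    """Flat table of scenario results, CSV-ready.

    Columns: scenario, rate, se, reps, seed, branch_frequencies (JSON).
    """
    rows = [
        {
            "scenario": name,
            "rate": res.rejection_rate,
            "se": res.mc_standard_error,
            "reps": res.reps,
            "seed": res.seed,
            "branch_frequencies": json.dumps(res.branch_frequencies),
        }
        for name, res in results.items()
    ]
    return pd.DataFrame(
        rows, columns=["scenario", "rate", "se", "reps", "seed", "branch_frequencies"]
    )


# ---------------------------------------------------------------------------
# The per-arm-counts-known sample-size adversary (two-stage binary design)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=65536)
def _plain_rejects(
    n_t: int, n_c: int, e_t: int, e_c: int, alpha: float
) -> bool:
    y = np.array([1.0] * e_t + [0.0] * (n_t - e_t) + [1.0] * e_c + [0.0] * (n_c - e_c))
    z = np.array([True] * n_t + [False] * n_c)
    stat = get_statistic("diff_props", SMALLER)
    return bool(engine.permutation_pvalue(y, z, stat, mode="exact").p_value <= alpha)


@lru_cache(maxsize=65536)
def _stratified_rejects(
    n_t1: int,
    n_c1: int,
    e_t1: int,
    e_c1: int,
    n_t2: int,
    n_c2: int,
    e_t2: int,
    e_c2: int,
    alpha: float,
) -> bool:
    y = np.array(
        [1.0] * e_t1
        + [0.0] * (n_t1 - e_t1)
        + [1.0] * e_c1
        + [0.0] * (n_c1 - e_c1)
        + [1.0] * e_t2
        + [0.0] * (n_t2 - e_t2)
        + [1.0] * e_c2
        + [0.0] * (n_c2 - e_c2)
    )
    z = np.array(
        [True] * n_t1 + [False] * n_c1 + [True] * n_t2 + [False] * n_c2
    )
    stratum = np.array([1] * (n_t1 + n_c1) + [2] * (n_t2 + n_c2))
    stat = get_statistic("diff_props", SMALLER)
    res = engine.stratified_permutation_pvalue(y, z, stat, stratum, mode="exact")
    return bool(res.p_value <= alpha)


def _planning_ce(
    n_t1: int, n_c1: int, e_t1: int, e_c1: int, n_t2: int, n_c2: int,
    p_event: float, alpha: float,
) -> float:
    """Conditional rejection probability of the plain Fisher-equivalent
    test, summing over second-stage *event counts* with exact binomial
    weights — an exact regrouping of the outcome-vector enumeration, used by
    the adversary to plan its extension.  Vectorized via the hypergeometric
    tail; its agreement with `conditional_rejection_probability` (which runs
    the engine on enumerated outcome vectors) is a tested invariant."""
    a = np.arange(n_t2 + 1)
    b = np.arange(n_c2 + 1)
    pa = binom.pmf(a, n_t2, p_event)
    pb = binom.pmf(b, n_c2, p_event)
    shape = (n_t2 + 1, n_c2 + 1)
    e_t = np.broadcast_to(e_t1 + a[:, None], shape)
    e_c = np.broadcast_to(e_c1 + b[None, :], shape)
    n_t, n_c = n_t1 + n_t2, n_c1 + n_c2
    n = n_t + n_c
    m = e_t + e_c
    pval = np.ones(shape)
    ok = (m > 0) & (m < n) & (n_t > 0) & (n_c > 0)
    if ok.any():
        pval[ok] = hypergeom.cdf(e_t[ok], n, m[ok], n_t)
    rej = pval <= alpha + 1e-12
    return float((pa[:, None] * pb[None, :])[rej].sum())


@dataclass(frozen=True)
class AdversaryDecision:
    """The design the sample-size adversary commits to at the interim."""

    n_T2: int
    n_C2: int
    extended: bool
    conditional_error_planned: float
    conditional_error_chosen: float


def samplesize_adversary_decision(
    n_t1: int,
    n_c1: int,
    e_t1: int,
    e_c1: int,
    planned_t2: int,
    planned_c2: int,
    p_event: float = 0.5,
    alpha: float = 0.05,
    max_extension: int = 150,
    search_width: int = 8,
) -> AdversaryDecision:
    """The adversary's interim decision, given per-arm counts and events.

    Keep the planned second stage when the original design's conditional
    rejection probability is positive; otherwise extend the second stage —
    at most ``max_extension`` extra patients, any split across arms — to
    the design maximizing that probability.  The conditional error of a
    small-sample Fisher test is heavily quantized, so meaningful extensions
    are large and the maximizing design almost always spends (nearly) the
    whole budget: the search therefore considers every arm split but only
    extension totals within ``search_width`` of the cap, plus the planned
    design.  Ties break toward the smallest extension, then the fewer
    treated patients (deterministic).
    """
    state = InterimState(
        n_T1=n_t1, n_C1=n_c1, events_T1=e_t1, events_C1=e_c1,
        n_T2=planned_t2, n_C2=planned_c2, p_T=p_event, p_C=p_event, alpha=alpha,
    )
    ce0 = conditional_rejection_probability(state).probability
    if ce0 > 0.0:
        return AdversaryDecision(planned_t2, planned_c2, False, ce0, ce0)
    best = (planned_t2, planned_c2)
    best_ce = ce0
    candidates = []
    lo = max(1, max_extension - search_width + 1)
    for extra in range(lo, max_extension + 1):
        for extra_t in range(extra + 1):
            candidates.append((extra, extra_t, extra - extra_t))
    for _, extra_t, extra_c in sorted(candidates):
        n_t2, n_c2 = planned_t2 + extra_t, planned_c2 + extra_c
        ce = _planning_ce(n_t1, n_c1, e_t1, e_c1, n_t2, n_c2, p_event, alpha)
        if ce > best_ce + 1e-15:
            best, best_ce = (n_t2, n_c2), ce
    return AdversaryDecision(best[0], best[1], best != (planned_t2, planned_c2),
                             ce0, best_ce)


@dataclass(frozen=True)
class TwoStageStudyResult:
    """Plain vs stratified analysis of the same simulated two-stage trials."""

    plain: SimulationResult
    stratified: SimulationResult
    extension_frequency: float


def simulate_samplesize_adversary(
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    *,
    n_per_arm: int = 3,
    interim_after: int = 3,
    p_event: float = 0.5,
    alpha: float = 0.05,
    adaptive: bool = True,
    max_extension: int = 150,
) -> TwoStageStudyResult:
    """Type I error of the plain and stratified permutation tests in the
    two-stage binary design with per-arm counts known at the interim.

    Each replicate randomizes ``2 * n_per_arm`` patients (complete
    randomization, random enrollment order), observes the first
    ``interim_after`` outcomes (Bernoulli(``p_event``) in both arms — the
    strong null), lets the adversary fix the second stage when ``adaptive``,
    draws the remaining outcomes, and applies both final analyses to the
    same data.  One-sided, fewer events favoring treatment.
    """
    n_total = 2 * n_per_arm
    if not 0 < interim_after < n_total:
        raise ValueError("interim must fall strictly inside the trial")
    decisions: dict[tuple[int, int, int], AdversaryDecision] = {}
    plain_rej = strat_rej = extended = 0
    for rep in range(reps):
        rng = _rep_rng(seed, rep)
        order = np.array(["T"] * n_per_arm + ["C"] * n_per_arm, dtype=object)
        order = order[rng.permutation(n_total)]
        stage1 = order[:interim_after]
        n_t1 = int((stage1 == "T").sum())
        n_c1 = interim_after - n_t1
        ev1 = rng.random(interim_after) < p_event
        e_t1 = int(ev1[stage1 == "T"].sum())
        e_c1 = int(ev1[stage1 == "C"].sum())
        planned_t2, planned_c2 = n_per_arm - n_t1, n_per_arm - n_c1
        if adaptive:
            key = (n_t1, e_t1, e_c1)
            if key not in decisions:
                decisions[key] = samplesize_adversary_decision(
                    n_t1, n_c1, e_t1, e_c1, planned_t2, planned_c2,
                    p_event=p_event, alpha=alpha, max_extension=max_extension,
                )
            dec = decisions[key]
            n_t2, n_c2 = dec.n_T2, dec.n_C2
            extended += dec.extended
        else:
            n_t2, n_c2 = planned_t2, planned_c2
        e_t2 = int(rng.binomial(n_t2, p_event)) if n_t2 else 0
        e_c2 = int(rng.binomial(n_c2, p_event)) if n_c2 else 0
        plain_rej += _plain_rejects(
            n_t1 + n_t2, n_c1 + n_c2, e_t1 + e_t2, e_c1 + e_c2, alpha
        )
        strat_rej += _stratified_rejects(
            n_t1, n_c1, e_t1, e_c1, n_t2, n_c2, e_t2, e_c2, alpha
        )
    plain_rate = plain_rej / reps
    strat_rate = strat_rej / reps
    return TwoStageStudyResult(
        plain=SimulationResult(
            rejection_rate=plain_rate,
            mc_standard_error=_mc_se(plain_rate, reps),
            reps=reps,
            seed=seed,
            type_i_error_rate=plain_rate,
        ),
        stratified=SimulationResult(
            rejection_rate=strat_rate,
            mc_standard_error=_mc_se(strat_rate, reps),
            reps=reps,
            seed=seed,
            type_i_error_rate=strat_rate,
        ),
        extension_frequency=extended / reps,
    )


# ---------------------------------------------------------------------------
# Drug-level (three-endpoint) selection study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionStudyResult:
    """Rates from the drug-level endpoint-selection study.

    ``fixed`` tests the pre-specified endpoint; ``adaptive`` lets the
    adversarial rule choose; ``oracle`` rejects when the smaller of the two
    per-endpoint p-values is ≤ alpha (computed from direct engine calls,
    independently of the adaptation machinery).
    """

    fixed: SimulationResult
    adaptive: SimulationResult
    oracle: SimulationResult


def drug_level_selection_study(
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    *,
    n_per_arm: int = 5,
    alpha: float = 0.05,
    statistic: str = "wilcoxon",
    rule_factory=None,
) -> SelectionStudyResult:
    """Global strong null with two exchangeable continuous clinical
    endpoints plus a drug-level endpoint that perfectly separates the arms.

    Per replicate: one trial; the fixed analysis tests endpoint "a"; the
    adversarial rule (default: the drug-level row adversary) picks its
    endpoint and that choice is analyzed; the oracle evaluates both
    per-endpoint p-values directly and rejects when min(p_a, p_b) ≤ alpha.
    """
    from .adaptation import drug_level_adversary_rule

    if rule_factory is None:
        rule_factory = drug_level_adversary_rule
    from .trial_data import EndpointSpec

    config = GeneratorConfig(
        strata=((n_per_arm, n_per_arm),),
        endpoints={
            "a": EndpointSpec(kind="continuous"),
            "b": EndpointSpec(kind="continuous"),
            "drug": EndpointSpec(kind="drug_level"),
        },
    )
    plan = AnalysisPlan(endpoint="a", statistic=statistic, direction=SMALLER, alpha=alpha)
    rule = rule_factory("drug", ["a", "b"])
    stat = get_statistic(statistic, SMALLER)
    fixed_rej = adapt_rej = oracle_rej = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AdaptationWarning)
        for rep in range(reps):
            rng = _rep_rng(seed, rep)
            trial = generate_trial(config, rng=rng)
            z = trial.arm_mask
            p_a = engine.permutation_pvalue(trial.outcomes["a"], z, stat).p_value
            p_b = engine.permutation_pvalue(trial.outcomes["b"], z, stat).p_value
            fixed_rej += p_a <= alpha
            oracle_rej += min(p_a, p_b) <= alpha
            record = run_adaptive_analysis(trial, rule, plan, mode="exact")
            adapt_rej += record.reject
    def _res(k: int) -> SimulationResult:
        r = k / reps
        return SimulationResult(
            rejection_rate=r,
            mc_standard_error=_mc_se(r, reps),
            reps=reps,
            seed=seed,
            type_i_error_rate=r,
        )
    return SelectionStudyResult(
        fixed=_res(fixed_rej), adaptive=_res(adapt_rej), oracle=_res(oracle_rej)
    )
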