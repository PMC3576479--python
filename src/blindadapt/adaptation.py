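"""Blinded views, adaptation rules, and the adaptive analysis runner.

Before unblinding, investigators may examine only the *lumped* data X: the
pooled outcomes from both arms with treatment labels hidden.  Any adaptation
decided from X — switching endpoint, statistic, or a derived-endpoint
threshold — leaves the permutation test's conditional type I error rate at or
below alpha, because X is independent of the assignment vector under the
strong null.  The price is the conclusion: a significant result only shows
the treatment affects *at least one* of the variables the rule examined, so
every rule declares exactly which view components it reads and the decision
record carries that declaration.

The catalog contains legitimate rules (variance-based endpoint selection,
outlier-triggered switch to a rank test, relaxing an infeasible binary
threshold) and deliberately adversarial ones (reconstructing arm labels from
a drug-level endpoint, or from its lumped correlations) that exist to
demonstrate, in the simulation lab, how a blinded-in-name-only adaptation
degrades the rejectable hypothesis.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import permutation_engine as engine
from .statistics import EvaluationError, SMALLER, get_statistic
from .trial_data import TrialData


class BlindingError(RuntimeError):
    """An operation would reveal treatment labels."""


class AdaptationWarning(UserWarning):
    """Emitted when an adversarial rule is exercised."""


# ---------------------------------------------------------------------------
# The blinded view: houses X
# ---------------------------------------------------------------------------


class BlindedView:
    """Lumped, label-free access to trial outcomes.

    Rows are re-ordered by a keyed permutation whose key is a digest of the
    (sorted) outcome values themselves — deterministic, label-free, and
    independent of enrollment order, so neither arm labels nor enrollment
    position can leak through this type.  Two trials differing only by an
    arm relabeling produce indistinguishable views.

    Exposed: the shuffled outcome matrix, per-endpoint missingness counts
    (totals, never per arm), total n, and per-stratum totals (never per-arm
    counts; when those are known the engine must stratify instead).
    """

    def __init__(self, trial: TrialData):
        names = trial.endpoint_names
        rows = np.column_stack([trial.outcomes[name] for name in names])
        # digest of value content only: sort rows lexicographically first
        canon = rows[np.lexsort(rows.T[::-1])]
        digest = hashlib.sha256(np.ascontiguousarray(canon).tobytes()).digest()
        key = int.from_bytes(digest[:4], "big")
        perm = np.random.default_rng(key).permutation(trial.n)
        self._names = names
        self._rows = rows[perm]
        self._stratum = trial.stratum[perm]
        self.n = trial.n
        self.missing_counts = {
            name: int(np.isnan(trial.outcomes[name]).sum()) for name in names
        }
        self.stratum_totals = tuple(
            int((trial.stratum == s).sum()) for s in range(1, trial.n_strata + 1)
        )

    @property
    def endpoint_names(self) -> tuple[str, ...]:
        return self._names

    def lumped(self, endpoint: str) -> np.ndarray:
        """The pooled outcome values of one endpoint (order shuffled)."""
        return self._rows[:, self._names.index(endpoint)].copy()

    def lumped_matrix(self) -> np.ndarray:
        return self._rows.copy()

    def lumped_variance(self, endpoint: str) -> float:
        """Available-case sample variance (ddof=1) of the pooled values."""
        y = self.lumped(endpoint)
        y = y[~np.isnan(y)]
        if y.size < 2:
            return float("nan")
        return float(np.var(y, ddof=1))

    def lumped_correlation(self, endpoint_a: str, endpoint_b: str) -> float:
        """Pearson correlation of two endpoints over jointly complete rows.

        A summary measure — yet still enough to leak effect ordering when one
        endpoint is assignment-revealing.  NaN when either column is
        constant.
        """
        a, b = self.lumped(endpoint_a), self.lumped(endpoint_b)
        ok = ~np.isnan(a) & ~np.isnan(b)
        a, b = a[ok], b[ok]
        if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])


def blinded_view(trial: TrialData) -> BlindedView:
    """The lumped data X an adaptation rule is allowed to see."""
    return BlindedView(trial)


# ---------------------------------------------------------------------------
# Analysis plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisPlan:
    """What will be tested once the blind is broken.

    ``threshold`` derives a binary endpoint ``1[y >= threshold]`` from a
    continuous column (e.g. "blood-pressure increase of at least 10 mmHg").
    ``alpha`` is fixed at the design value: adaptation may change endpoint,
    statistic, or threshold — never the significance level.
    """

    endpoint: str
    statistic: str = "diff_means"
    direction: str = SMALLER
    alpha: float = 0.05
    threshold: Optional[float] = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def adapted(self, **changes) -> "AnalysisPlan":
        """A new plan differing only in endpoint/statistic/threshold."""
        if "alpha" in changes and changes["alpha"] != self.alpha:
            raise ValueError("adaptation may not change alpha")
        changes.pop("alpha", None)
        return replace(self, **changes)

    def resolve_outcome(self, outcomes: dict[str, np.ndarray]) -> np.ndarray:
        y = np.asarray(outcomes[self.endpoint], dtype=float)
        if self.threshold is None:
            return y
        out = np.where(np.isnan(y), np.nan, (y >= self.threshold).astype(float))
        return out


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdaptationRule:
    """A deterministic mapping (BlindedView, original plan) -> plan.

    ``declared_inputs`` lists the view components the rule reads; the
    decision record repeats them so the rejected hypothesis — "no effect on
    any variable the rule examined" — is auditable.  ``adversarial`` marks
    rules that exist only to demonstrate failure modes.
    """

    name: str
    decide: Callable[[BlindedView, AnalysisPlan], AnalysisPlan]
    declared_inputs: tuple[str, ...]
    adversarial: bool = False

    def __call__(self, view: BlindedView, plan: AnalysisPlan) -> AnalysisPlan:
        if self.adversarial:
            warnings.warn(
                f"rule {self.name!r} is adversarial: it exists to demonstrate "
                "type I error inflation, not for use in a real trial",
                AdaptationWarning,
                stacklevel=2,
            )
        return self.decide(view, plan)


def identity_rule() -> AdaptationRule:
    """No adaptation: reduces the adaptive analysis to the fixed design."""
    return AdaptationRule(
        name="identity",
        decide=lambda view, plan: plan,
        declared_inputs=(),
    )


def min_variance_rule(candidates: Sequence[str]) -> AdaptationRule:
    """Select the candidate endpoint with the smallest lumped variance.

    Ties break by candidate order; fully missing candidates are excluded
    with a warning.  Variances use available cases only.
    """
    candidates = tuple(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate endpoints")

    def decide(view: BlindedView, plan: AnalysisPlan) -> AnalysisPlan:
        best_name, best_var = None, np.inf
        for name in candidates:
            v = view.lumped_variance(name)
            if np.isnan(v):
                warnings.warn(
                    f"candidate {name!r} has <2 observed values; excluded",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            if v < best_var:  # strict: earlier candidate wins ties
                best_name, best_var = name, v
        if best_name is None:
            return plan
        return plan.adapted(endpoint=best_name)

    return AdaptationRule(
        name="min_variance",
        decide=decide,
        declared_inputs=tuple(f"lumped_variance:{c}" for c in candidates),
    )


def outlier_switch_rule(k: float = 5.0) -> AdaptationRule:
    """Switch a planned difference-in-means test to the rank-sum test when
    the lumped values contain an outlier.

    Outlier criterion: any value farther than ``k`` median absolute
    deviations (scaled by 1.4826 to be consistent for Gaussian data) from
    the lumped median; falls back to an IQR criterion (k/5 * 1.5 fences)
    when the MAD is zero on non-constant data.
    """

    def decide(view: BlindedView, plan: AnalysisPlan) -> AnalysisPlan:
        if plan.statistic != "diff_means":
            return plan
        y = view.lumped(plan.endpoint)
        y = y[~np.isnan(y)]
        if y.size == 0 or np.ptp(y) == 0:
            return plan
        med = np.median(y)
        mad = np.median(np.abs(y - med)) * 1.4826
        if mad > 0:
            has_outlier = bool((np.abs(y - med) > k * mad).any())
        else:
            q1, q3 = np.percentile(y, [25, 75])
            iqr = q3 - q1
            if iqr == 0:
                # mass concentrated on one value; any other value is an outlier
                has_outlier = True
            else:
                fence = (k / 5.0) * 1.5 * iqr
                has_outlier = bool(((y < q1 - fence) | (y > q3 + fence)).any())
        if has_outlier:
            return plan.adapted(statistic="wilcoxon")
        return plan

    return AdaptationRule(
        name="outlier_switch",
        decide=decide,
        declared_inputs=("lumped:planned-endpoint",),
    )


def min_attainable_fisher_p(
    total_events: int, n_T: int, n_C: int, direction: str = engine.FEWER_T_EVENTS
) -> float:
    """Smallest one-sided Fisher p attainable when the lumped event total is
    fixed: put every event in the unfavorable arm."""
    m = int(total_events)
    if direction == engine.FEWER_T_EVENTS:
        e_t = max(0, m - n_C)  # as few treated events as the margins allow
    else:
        e_t = min(m, n_T)
    table = [[e_t, n_T - e_t], [m - e_t, n_C - (m - e_t)]]
    return engine.fisher_exact_one_sided(table, direction)


def threshold_feasibility_rule(
    fallback_threshold: float,
    scheme: engine.RandomizationScheme | None = None,
) -> AdaptationRule:
    """Relax the cut of a derived binary endpoint when significance is
    literally impossible at the planned one.

    From the lumped event total m the rule computes the minimum attainable
    one-sided Fisher p (all m events in one arm).  If even that exceeds
    alpha, the endpoint is re-derived at ``fallback_threshold``; if the
    fallback is also infeasible the plan stays unchanged, with a warning.
    ``scheme`` supplies the design's per-arm sizes (design knowledge, not
    data); by default a balanced split of n is assumed.
    """

    def decide(view: BlindedView, plan: AnalysisPlan) -> AnalysisPlan:
        if plan.threshold is None:
            return plan
        if scheme is not None:
            n_t = sum(s[0] for s in scheme.strata)
            n_c = sum(s[1] for s in scheme.strata)
        else:
            n_t, n_c = view.n // 2, view.n - view.n // 2
        fisher_dir = (
            engine.FEWER_T_EVENTS if plan.direction == SMALLER else engine.MORE_T_EVENTS
        )

        def min_p(threshold: float) -> float:
            y = view.lumped(plan.endpoint)
            m = int(np.nansum(y >= threshold))
            return min_attainable_fisher_p(m, n_t, n_c, fisher_dir)

        tol = 1e-12
        if min_p(plan.threshold) <= plan.alpha + tol:
            return plan
        if min_p(fallback_threshold) <= plan.alpha + tol:
            return plan.adapted(threshold=fallback_threshold)
        warnings.warn(
            "fallback threshold also cannot reach significance; plan unchanged",
            UserWarning,
            stacklevel=2,
        )
        return plan

    return AdaptationRule(
        name="threshold_feasibility",
        decide=decide,
        declared_inputs=("lumped:planned-endpoint", "event-total-at-thresholds"),
    )


def _reconstruct_arms(drug: np.ndarray) -> Optional[np.ndarray]:
    """Treated mask from drug level > 0; None when levels fail to separate."""
    ok = ~np.isnan(drug)
    pos = drug > 0
    if not pos[ok].any() or pos[ok].all():
        return None
    return pos


def drug_level_adversary_rule(
    drug_endpoint: str, candidates: Sequence[str]
) -> AdaptationRule:
    """Adversarial: unblind via a drug-level endpoint, then pick the clinical
    endpoint with the more treatment-favorable statistic.

    Blinding hides labels, not values — a subject with a positive drug level
    is treated.  The rule is formally a function of the lumped data, so the
    permutation test still controls its conditional error; what breaks is
    the *conclusion*, which collapses to "the treatment affects at least one
    of the variables examined" (trivially true of the drug level).  Shipped
    to power the simulation lab's inflation demonstration.
    """
    candidates = tuple(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two clinical endpoints")

    def decide(view: BlindedView, plan: AnalysisPlan) -> AnalysisPlan:
        stat = get_statistic(plan.statistic, plan.direction)
        z = _reconstruct_arms(view.lumped(drug_endpoint))
        if z is None:
            return plan.adapted(endpoint=candidates[0])
        best_name, best_t = candidates[0], None
        for name in candidates:
            y = plan.adapted(endpoint=name).resolve_outcome(
                {name: view.lumped(name)}
            )
            try:
                t = stat.evaluate(y, z)
            except EvaluationError:
                continue  # candidate unusable under the reconstructed labels
            better = best_t is None or (
                t < best_t if stat.direction == SMALLER else t > best_t
            )
            if better:
                best_name, best_t = name, t
        return plan.adapted(endpoint=best_name)

    return AdaptationRule(
        name="drug_level_adversary",
        decide=decide,
        declared_inputs=(f"lumped:{drug_endpoint}",)
        + tuple(f"lumped:{c}" for c in candidates),
        adversarial=True,
    )


def correlation_leak_rule(
    drug_endpoint: str, candidates: Sequence[str]
) -> AdaptationRule:
    """Adversarial: read ONLY the lumped correlations between the drug level
    and each clinical endpoint — summary measures, no subject rows — and
    select the endpoint with the larger absolute correlation.

    Demonstrates that summary measures are no safeguard: when the drug level
    separates the arms, the endpoint more correlated with it is the one with
    the stronger apparent treatment effect.
    """
    candidates = tuple(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two clinical endpoints")

    def decide(view: BlindedView, plan: AnalysisPlan) -> AnalysisPlan:
        best_name, best_r = candidates[0], -np.inf
        for name in candidates:
            r = view.lumped_correlation(drug_endpoint, name)
            if np.isnan(r):
                continue
            if abs(r) > best_r:  # strict: earlier candidate wins ties
                best_name, best_r = name, abs(r)
        return plan.adapted(endpoint=best_name)

    return AdaptationRule(
        name="correlation_leak",
        decide=decide,
        declared_inputs=tuple(
            f"lumped_correlation:{drug_endpoint},{c}" for c in candidates
        ),
        adversarial=True,
    )


_RULE_FACTORIES: dict[str, Callable[..., AdaptationRule]] = {
    "identity": identity_rule,
    "min_variance": min_variance_rule,
    "outlier_switch": outlier_switch_rule,
    "threshold_feasibility": threshold_feasibility_rule,
    "drug_level_adversary": drug_level_adversary_rule,
    "correlation_leak": correlation_leak_rule,
}


def make_rule(name: str, **params) -> AdaptationRule:
    """Build a shipped rule by config name."""
    try:
        factory = _RULE_FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown rule {name!r}; choose from {sorted(_RULE_FACTORIES)}"
        ) from None
    return factory(**params)


def rule_names() -> tuple[str, ...]:
    return tuple(sorted(_RULE_FACTORIES))


# ---------------------------------------------------------------------------
# End-to-end adaptive analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecisionRecord:
    """Everything needed to audit one adaptive analysis."""

    original_plan: AnalysisPlan
    chosen_plan: AnalysisPlan
    rule_name: str
    declared_inputs: tuple[str, ...]
    result: engine.PermutationResult
    reject: bool
    conclusion: str
    adversarial: bool = False


def run_adaptive_analysis(
    trial: TrialData,
    rule: AdaptationRule,
    original_plan: AnalysisPlan,
    mode: str = "exact",
    B: int = 9999,
    seed: Optional[int] = None,
) -> DecisionRecord:
    """Blinded adaptation followed by the (stratified, when the trial has
    more than one stratum) permutation test of the chosen plan.

    The rule sees only ``blinded_view(trial)``; the engine then tests the
    chosen endpoint/statistic at the design alpha.  The decision record
    states the rejectable hypothesis in its honest form: no effect on any
    variable the rule examined plus the tested endpoint.
    """
    view = blinded_view(trial)
    plan = rule(view, original_plan)
    if plan.alpha != original_plan.alpha:
        raise BlindingError("adaptation changed alpha")
    y = plan.resolve_outcome(trial.outcomes)
    statistic = get_statistic(plan.statistic, plan.direction)
    if trial.n_strata > 1:
        result = engine.stratified_permutation_pvalue(
            y, trial.arm_mask, statistic, trial.stratum, mode=mode, B=B, seed=seed
        )
    else:
        result = engine.permutation_pvalue(
            y, trial.arm_mask, statistic, mode=mode, B=B, seed=seed
        )
    examined = set(rule.declared_inputs) | {f"endpoint:{plan.endpoint}"}
    conclusion = (
        "rejection would imply an effect on at least one of: "
        + ", ".join(sorted(examined))
    )
    return DecisionRecord(
        original_plan=original_plan,
        chosen_plan=plan,
        rule_name=rule.name,
        declared_inputs=rule.declared_inputs,
        result=result,
        reject=bool(result.p_value <= plan.alpha),
        conclusion=conclusion,
        adversarial=rule.adversarial,
    )
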