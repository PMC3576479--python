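import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blindadapt import (
    AdaptationWarning,
    AnalysisPlan,
    RandomizationScheme,
    blinded_view,
    correlation_leak_rule,
    drug_level_adversary_rule,
    fisher_exact_one_sided,
    identity_rule,
    get_statistic,
    make_rule,
    min_attainable_fisher_p,
    min_variance_rule,
    outlier_switch_rule,
    permutation_pvalue,
    run_adaptive_analysis,
    threshold_feasibility_rule,
)
from conftest import make_trial


def drug_trial(effect_a=0.0, effect_b=0.0):
    """6-subject fixture with a drug level that separates arms exactly and
    two continuous endpoints with prescribed treatment effects."""
    base = [0.3, -0.1, 0.5, 0.2, -0.4, 0.1]
    return make_trial(
        {
            "a": [v + (effect_a if i < 3 else 0.0) for i, v in enumerate(base)],
            "b": [v + (effect_b if i < 3 else 0.0) for i, v in enumerate(base)],
            "drug": [1.2, 0.7, 2.0, 0.0, 0.0, 0.0],
        },
        arms="TTTCCC",
    )


# ---------------------------------------------------------------------------
# Blinded view
# ---------------------------------------------------------------------------


class TestBlindedView:
    def test_relabeling_yields_identical_view(self):
        trial = drug_trial(effect_a=-1.0)
        v1, v2 = blinded_view(trial), blinded_view(trial.relabeled())
        np.testing.assert_array_equal(v1.lumped_matrix(), v2.lumped_matrix())
        assert v1.missing_counts == v2.missing_counts
        assert v1.stratum_totals == v2.stratum_totals

    def test_row_count_and_missing_counts(self):
        trial = make_trial({"y": [1, np.nan, 3, np.nan, 5, 6]}, arms="TTTCCC")
        view = blinded_view(trial)
        assert view.n == 6
        assert len(view.lumped("y")) == 6
        assert view.missing_counts == {"y": 2}

    def test_values_remain_visible_even_when_revealing(self):
        """Blinding hides labels, not values: a drug-level endpoint still
        shows three positive and three zero measurements."""
        view = blinded_view(drug_trial())
        drug = view.lumped("drug")
        assert int((drug > 0).sum()) == 3
        assert int((drug == 0).sum()) == 3

    def test_per_stratum_totals_but_never_per_arm(self):
        trial = make_trial({"y": range(6)}, arms="TCTCTC", strata=[1, 1, 1, 2, 2, 2])
        view = blinded_view(trial)
        assert view.stratum_totals == (3, 3)
        assert not hasattr(view, "arm")


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


class TestMinVariance:
    def test_selects_smaller_lumped_variance(self):
        trial = make_trial(
            {"a": [0, 4, 0, 4, 0, 4], "b": [1, 2, 1, 2, 1, 2]}, arms="TTTCCC"
        )
        plan = AnalysisPlan(endpoint="a")
        chosen = min_variance_rule(["a", "b"])(blinded_view(trial), plan)
        assert chosen.endpoint == "b"

    def test_tie_breaks_by_candidate_order(self):
        trial = make_trial({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]}, arms="TTCC")
        plan = AnalysisPlan(endpoint="b")
        chosen = min_variance_rule(["a", "b"])(blinded_view(trial), plan)
        assert chosen.endpoint == "a"

    def test_variance_on_available_cases_only(self):
        # "a" has a missing cell; its available-case variance is still the
        # smaller one and must be the basis of the decision
        a = [1, 3, 1, 3, 1, np.nan, 3, 1, 3, 1]
        b = [0, 4.3, 0, 4.3, 0, 4.3, 0, 4.3, 0, 4.3]
        trial = make_trial({"a": a, "b": b}, arms="TTTTTCCCCC")
        view = blinded_view(trial)
        assert view.lumped_variance("a") < view.lumped_variance("b")
        plan = AnalysisPlan(endpoint="b")
        assert min_variance_rule(["a", "b"])(view, plan).endpoint == "a"


class TestOutlierSwitch:
    def test_gross_outlier_triggers_wilcoxon(self):
        trial = make_trial({"y": [0.1, -0.2, 0.05, 40.0]}, arms="TTCC")
        plan = AnalysisPlan(endpoint="y", statistic="diff_means")
        chosen = outlier_switch_rule(k=5.0)(blinded_view(trial), plan)
        assert chosen.statistic == "wilcoxon"

    def test_clean_gaussian_sample_left_unchanged(self):
        rng = np.random.default_rng(21)
        y = rng.standard_normal(100)
        trial = make_trial({"y": y}, arms="T" * 50 + "C" * 50)
        plan = AnalysisPlan(endpoint="y", statistic="diff_means")
        chosen = outlier_switch_rule(k=5.0)(blinded_view(trial), plan)
        assert chosen.statistic == "diff_means"

    def test_constant_data_unchanged(self):
        trial = make_trial({"y": [2, 2, 2, 2]}, arms="TTCC")
        plan = AnalysisPlan(endpoint="y", statistic="diff_means")
        assert outlier_switch_rule()(blinded_view(trial), plan) == plan

    def test_zero_mad_falls_back_to_iqr(self):
        # median-concentrated mass: MAD = 0 but the lone 9 is an outlier
        trial = make_trial({"y": [0, 0, 0, 0, 0, 9]}, arms="TTTCCC")
        plan = AnalysisPlan(endpoint="y", statistic="diff_means")
        chosen = outlier_switch_rule()(blinded_view(trial), plan)
        assert chosen.statistic == "wilcoxon"


class TestThresholdFeasibility:
    scheme = RandomizationScheme(((3, 3),))

    def plan(self):
        return AnalysisPlan(
            endpoint="bp", statistic="diff_props", threshold=10.0, alpha=0.05
        )

    def test_zero_events_switch_to_fallback(self):
        # no increase reaches 10 mmHg, three reach 5 mmHg
        trial = make_trial({"bp": [6, 7, 5, 2, 1, 0]}, arms="TTTCCC")
        rule = threshold_feasibility_rule(5.0, scheme=self.scheme)
        chosen = rule(blinded_view(trial), self.plan())
        assert chosen.threshold == 5.0

    def test_three_events_feasible_unchanged(self):
        trial = make_trial({"bp": [12, 11, 10, 2, 1, 0]}, arms="TTTCCC")
        rule = threshold_feasibility_rule(5.0, scheme=self.scheme)
        assert rule(blinded_view(trial), self.plan()).threshold == 10.0

    def test_one_event_infeasible_switch(self):
        # minimum attainable p with one event is 0.5 > alpha
        trial = make_trial({"bp": [11, 7, 5, 2, 1, 0]}, arms="TTTCCC")
        rule = threshold_feasibility_rule(5.0, scheme=self.scheme)
        assert rule(blinded_view(trial), self.plan()).threshold == 5.0

    def test_min_attainable_p_values(self):
        assert min_attainable_fisher_p(0, 3, 3) == 1.0
        assert min_attainable_fisher_p(3, 3, 3) == pytest.approx(0.05)
        assert min_attainable_fisher_p(1, 3, 3) == pytest.approx(0.5)


class TestDrugLevelAdversary:
    def test_selects_stronger_effect(self):
        trial = drug_trial(effect_a=-2.0, effect_b=-5.0)
        plan = AnalysisPlan(endpoint="a", statistic="diff_means", direction="smaller")
        with pytest.warns(AdaptationWarning):
            chosen = drug_level_adversary_rule("drug", ["a", "b"])(
                blinded_view(trial), plan
            )
        assert chosen.endpoint == "b"

    def test_identical_endpoints_tie_break_first(self):
        trial = drug_trial()
        plan = AnalysisPlan(endpoint="b", statistic="diff_means")
        with pytest.warns(AdaptationWarning):
            chosen = drug_level_adversary_rule("drug", ["a", "b"])(
                blinded_view(trial), plan
            )
        assert chosen.endpoint == "a"

    def test_non_separating_drug_level_falls_back(self):
        trial = make_trial(
            {"a": [1, 2, 3, 4], "b": [4, 3, 2, 1], "drug": [1, 1, 1, 1]},
            arms="TTCC",
        )
        plan = AnalysisPlan(endpoint="b", statistic="diff_means")
        with pytest.warns(AdaptationWarning):
            chosen = drug_level_adversary_rule("drug", ["a", "b"])(
                blinded_view(trial), plan
            )
        assert chosen.endpoint == "a"


class TestCorrelationLeak:
    def test_selects_larger_absolute_correlation(self):
        # b is (negatively) collinear with drug; a is weakly related
        trial = make_trial(
            {
                "a": [0.3, -0.1, 0.5, 0.2, -0.4, 0.6],
                "b": [-1.2, -0.7, -2.0, 0.1, 0.05, -0.02],
                "drug": [1.2, 0.7, 2.0, 0.0, 0.0, 0.0],
            },
            arms="TTTCCC",
        )
        view = blinded_view(trial)
        assert abs(view.lumped_correlation("drug", "b")) > abs(
            view.lumped_correlation("drug", "a")
        )
        plan = AnalysisPlan(endpoint="a")
        with pytest.warns(AdaptationWarning):
            chosen = correlation_leak_rule("drug", ["a", "b"])(view, plan)
        assert chosen.endpoint == "b"

    def test_zero_variance_endpoint_falls_back_to_first(self):
        trial = make_trial(
            {"a": [5, 5, 5, 5], "b": [5, 5, 5, 5], "drug": [1, 2, 0, 0]},
            arms="TTCC",
        )
        plan = AnalysisPlan(endpoint="b")
        with pytest.warns(AdaptationWarning):
            chosen = correlation_leak_rule("drug", ["a", "b"])(
                blinded_view(trial), plan
            )
        assert chosen.endpoint == "a"


def test_make_rule_registry_round_trip():
    rule = make_rule("min_variance", candidates=["a", "b"])
    assert rule.name == "min_variance"
    with pytest.raises(KeyError):
        make_rule("no_such_rule")


def test_alpha_is_immutable_under_adaptation():
    plan = AnalysisPlan(endpoint="a", alpha=0.05)
    with pytest.raises(ValueError, match="alpha"):
        plan.adapted(alpha=0.01)


# ---------------------------------------------------------------------------
# End-to-end runner
# ---------------------------------------------------------------------------


def test_identity_rule_reduces_to_fixed_design(worked_binary_trial):
    trial = worked_binary_trial
    plan = AnalysisPlan(endpoint="event", statistic="diff_props", direction="smaller")
    record = run_adaptive_analysis(trial, identity_rule(), plan)
    direct = permutation_pvalue(
        trial.outcomes["event"], trial.arm_mask, get_statistic("diff_props", "smaller")
    )
    assert record.result.p_value == direct.p_value
    assert record.chosen_plan == plan
    assert record.reject


def test_threshold_scenario_end_to_end():
    """No event clears the strict cut, so the analysis runs at the relaxed
    one and the p-value equals the Fisher-equivalent permutation test on the
    re-derived binary endpoint."""
    trial = make_trial({"bp": [6.0, 7.0, 5.0, 2.0, 1.0, 0.0]}, arms="CCCTTT")
    plan = AnalysisPlan(
        endpoint="bp", statistic="diff_props", direction="smaller", threshold=10.0
    )
    rule = threshold_feasibility_rule(5.0, scheme=RandomizationScheme(((3, 3),)))
    record = run_adaptive_analysis(trial, rule, plan)
    assert record.chosen_plan.threshold == 5.0
    derived = (trial.outcomes["bp"] >= 5.0).astype(float)
    e_t = int(derived[trial.arm_mask].sum())
    e_c = int(derived[~trial.arm_mask].sum())
    expected = fisher_exact_one_sided([[e_t, 3 - e_t], [e_c, 3 - e_c]], "fewer")
    assert record.result.p_value == pytest.approx(expected)
    assert "endpoint:bp" in record.conclusion


def test_stratified_engine_used_when_strata_present():
    trial = make_trial(
        {"event": [1, 1, 1, 0, 0, 0]},
        arms="CCCTTT",
        strata=[1, 1, 1, 2, 2, 2],
        binary=("event",),
    )
    plan = AnalysisPlan(endpoint="event", statistic="diff_props", direction="smaller")
    record = run_adaptive_analysis(trial, identity_rule(), plan)
    assert record.result.n_permutations == 1  # degenerate stratified set
    assert not record.reject


def test_decision_record_carries_declared_inputs():
    trial = drug_trial()
    plan = AnalysisPlan(endpoint="a", statistic="diff_means")
    rule = min_variance_rule(["a", "b"])
    record = run_adaptive_analysis(trial, rule, plan)
    assert record.declared_inputs == ("lumped_variance:a", "lumped_variance:b")
    assert "at least one" in record.conclusion
    assert not record.adversarial


# ---------------------------------------------------------------------------
# Blinding contract property
# ---------------------------------------------------------------------------


def _shipped_rules():
    return [
        identity_rule(),
        min_variance_rule(["a", "b"]),
        outlier_switch_rule(),
        threshold_feasibility_rule(0.0),
        drug_level_adversary_rule("drug", ["a", "b"]),
        correlation_leak_rule("drug", ["a", "b"]),
    ]


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_every_rule_is_invariant_under_arm_relabeling(seed):
    """decide(view(trial)) == decide(view(relabeled trial)) for all rules."""
    rng = np.random.default_rng(seed)
    n = 8
    trial = make_trial(
        {
            "a": rng.standard_normal(n),
            "b": rng.standard_normal(n) * 2,
            "drug": np.where(rng.random(n) < 0.5, rng.lognormal(size=n), 0.0),
        },
        arms="TTTTCCCC",
    )
    plan = AnalysisPlan(endpoint="a", statistic="diff_means", threshold=0.5)
    v1, v2 = blinded_view(trial), blinded_view(trial.relabeled())
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rule in _shipped_rules():
            assert rule(v1, plan) == rule(v2, plan), rule.name
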