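"""Expected utilities, pattern probabilities and the decision rule."""

from itertools import combinations

import numpy as np
import pytest

import addarm
from addarm import (
    DecisionOutcome,
    JointPredictive,
    NormalPrior,
    Stage1Observation,
    decide,
    decision_map_priors,
    decision_map_stage1,
    disjunctive_utility,
    exact_count_distribution,
    expected_count_utility,
    joint_predictive,
    marginal_rejection_probs,
    pattern_probability,
)
from scipy.stats import binom, norm


def _independent_jp(probs):
    """Hand-built joint predictive with independent margins.

    Unit variances, zero means, thresholds chosen so the marginal rejection
    probability of hypothesis k is probs[k].
    """
    m = len(probs)
    thr = norm.isf(np.asarray(probs))
    return JointPredictive(
        arm_order=tuple(range(1, m + 1)),
        mean=np.zeros(m),
        cov=np.eye(m),
        thresholds=thr,
    )


class TestMarginals:
    def test_case_study_add(self, jp_add):
        np.testing.assert_allclose(
            marginal_rejection_probs(jp_add), [0.500, 0.311], atol=2e-3
        )

    def test_threshold_at_mean_gives_half(self):
        jp = _independent_jp([0.5])
        assert marginal_rejection_probs(jp)[0] == pytest.approx(0.5)

    def test_extreme_threshold_kills_the_probability(self, jp_add):
        jp = JointPredictive(
            jp_add.arm_order, jp_add.mean, jp_add.cov, [1e6, 1e6]
        )
        assert expected_count_utility(jp) == pytest.approx(0.0, abs=1e-12)


class TestCountUtility:
    def test_equals_sum_of_marginals(self, jp_add):
        assert expected_count_utility(jp_add) == pytest.approx(
            marginal_rejection_probs(jp_add).sum()
        )

    def test_equals_expectation_of_exact_count_distribution(self, jp_add):
        dist = exact_count_distribution(jp_add)
        expectation = float(np.arange(len(dist)) @ dist)
        assert expected_count_utility(jp_add) == pytest.approx(expectation, abs=1e-4)


class TestDisjunctiveUtility:
    def test_dimension_one_reduces_to_the_marginal(self, jp_noadd):
        assert disjunctive_utility(jp_noadd) == pytest.approx(
            marginal_rejection_probs(jp_noadd)[0], abs=1e-9
        )

    def test_independent_margins_closed_form(self):
        probs = [0.3, 0.5, 0.12]
        jp = _independent_jp(probs)
        expected = 1 - np.prod([1 - p for p in probs])
        assert disjunctive_utility(jp) == pytest.approx(expected, abs=1e-5)

    def test_bounded_by_count_and_one(self, jp_add, jp_noadd):
        for jp in (jp_add, jp_noadd):
            d = disjunctive_utility(jp)
            c = expected_count_utility(jp)
            assert 0.0 <= d <= min(1.0, c) + 1e-9
            assert c <= jp.dim


class TestPatternProbabilities:
    def test_all_subsets_sum_to_one(self, jp_add):
        total = sum(
            pattern_probability(jp_add, s)
            for v in range(jp_add.dim + 1)
            for s in combinations(range(jp_add.dim), v)
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_empty_set_in_dimension_one_is_the_complement(self, jp_noadd):
        p = marginal_rejection_probs(jp_noadd)[0]
        assert pattern_probability(jp_noadd, ()) == pytest.approx(1 - p, abs=1e-9)

    def test_out_of_range_index_rejected(self, jp_add):
        with pytest.raises(ValueError):
            pattern_probability(jp_add, {5})


class TestExactCountDistribution:
    def test_dimension_one(self, jp_noadd):
        p = marginal_rejection_probs(jp_noadd)[0]
        np.testing.assert_allclose(
            exact_count_distribution(jp_noadd), [1 - p, p], atol=1e-9
        )

    def test_sums_to_one_and_matches_marginals(self, jp_add):
        dist = exact_count_distribution(jp_add)
        assert dist.sum() == pytest.approx(1.0, abs=1e-4)
        assert dist.shape == (3,)

    def test_exchangeable_independent_arms_are_binomial(self):
        p = 0.37
        jp = _independent_jp([p, p, p])
        np.testing.assert_allclose(
            exact_count_distribution(jp), binom.pmf(np.arange(4), 3, p), atol=1e-5
        )

    def test_large_dimension_unsupported(self):
        jp = _independent_jp([0.5] * 13)
        with pytest.raises(ValueError):
            exact_count_distribution(jp)


class TestDecide:
    def test_case_study_directions_under_argmax(self, case):
        count = decide(
            case.design, case.priors, case.obs, case.plan_add, case.plan_noadd,
            "count", epsilon=0.0,
        )
        disj = decide(
            case.design, case.priors, case.obs, case.plan_add, case.plan_noadd,
            "disjunctive", epsilon=0.0,
        )
        assert count.optimal == "add"
        assert disj.optimal == "no_add"

    def test_near_ties_fall_in_the_indifference_band(self, case):
        out = decide(
            case.design, case.priors, case.obs, case.plan_add, case.plan_noadd,
            "disjunctive", epsilon=0.01,
        )
        assert abs(out.eu_add - out.eu_noadd) < 0.01
        assert out.optimal == "indifferent"

    def test_exact_tie_is_indifferent_even_at_zero_epsilon(self):
        out = DecisionOutcome.from_utilities(0.5, 0.5, 0.0)
        assert out.optimal == "indifferent"

    def test_band_is_open_at_epsilon(self):
        assert DecisionOutcome.from_utilities(0.52, 0.5, 0.02).optimal == "add"
        assert DecisionOutcome.from_utilities(0.519, 0.5, 0.02).optimal == "indifferent"

    def test_swapped_plans_rejected(self, case):
        with pytest.raises(ValueError):
            decide(
                case.design, case.priors, case.obs, case.plan_noadd, case.plan_add,
                "count",
            )

    def test_unknown_kind_rejected(self, case):
        with pytest.raises(ValueError):
            decide(
                case.design, case.priors, case.obs, case.plan_add, case.plan_noadd,
                "conjunctive",
            )


def _rejection_prob(case, xbar1, xbar0, m0=0.0):
    priors = {**case.priors, 1: NormalPrior(m0, case.priors[1].variance)}
    obs = Stage1Observation(xbar1={0: xbar0, 1: xbar1})
    jp = joint_predictive(case.design, case.plan_noadd, priors, obs)
    return marginal_rejection_probs(jp)[0]


class TestMonotonicity:
    """Rejection probability moves the right way along 5-point ladders."""

    def test_increasing_in_treatment_stage_one_mean(self, case):
        probs = [_rejection_prob(case, x, 5.0) for x in (2, 4, 6, 8, 10)]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_decreasing_in_control_stage_one_mean(self, case):
        probs = [_rejection_prob(case, 8.0, x) for x in (1, 3, 5, 7, 9)]
        assert all(b < a for a, b in zip(probs, probs[1:]))

    def test_increasing_in_prior_mean(self, case):
        probs = [_rejection_prob(case, 8.0, 5.0, m0=m) for m in (-10, -5, 0, 5, 10)]
        assert all(b > a for a, b in zip(probs, probs[1:]))


class TestDecisionMaps:
    def test_prior_map_shape_and_labels(self, case):
        table = decision_map_priors(
            case.design, case.obs, case.priors, grid_arm=1,
            means=[-5.0, 0.0, 5.0], variances=[1.0, 5.0, 10.0],
            plan_add=case.plan_add, plan_noadd=case.plan_noadd, kind="count",
        )
        assert len(table) == 9
        assert set(table.label) <= {"add", "no_add", "indifferent"}

    def test_case_study_prior_point_prefers_adding(self, case):
        table = decision_map_priors(
            case.design, case.obs, case.priors, grid_arm=1,
            means=[0.0], variances=[10.0],
            plan_add=case.plan_add, plan_noadd=case.plan_noadd, kind="count",
        )
        assert table.label.iloc[0] == "add"

    def test_hopeless_initial_arm_prior_prefers_adding(self, case):
        table = decision_map_priors(
            case.design, case.obs, case.priors, grid_arm=1,
            means=[-20.0], variances=[10.0],
            plan_add=case.plan_add, plan_noadd=case.plan_noadd, kind="count",
        )
        assert table.label.iloc[0] == "add"
        assert table.eu_noadd.iloc[0] < 0.1

    def test_empty_grid_rejected(self, case):
        with pytest.raises(ValueError):
            decision_map_priors(
                case.design, case.obs, case.priors, grid_arm=1,
                means=[], variances=[1.0],
                plan_add=case.plan_add, plan_noadd=case.plan_noadd, kind="count",
            )

    def test_stage1_map_is_deterministic(self):
        fx = addarm.illustration_one_initial_arm()
        kwargs = dict(
            grid_arms=(0, 1), x_values=[-0.2, 0.2], y_values=[-0.2, 0.2],
            plan_add=fx.plan_add, plan_noadd=fx.plan_noadd, kind="disjunctive",
        )
        t1 = decision_map_stage1(fx.design, fx.priors, **kwargs)
        t2 = decision_map_stage1(fx.design, fx.priors, **kwargs)
        assert t1.equals(t2)

    def test_failing_initial_arm_favours_adding_under_both_utilities(self):
        fx = addarm.illustration_one_initial_arm()
        for kind in ("count", "disjunctive"):
            t = decision_map_stage1(
                fx.design, fx.priors, (0, 1), [0.4], [-0.4],
                plan_add=fx.plan_add, plan_noadd=fx.plan_noadd, kind=kind,
            )
            assert t.label.iloc[0] == "add"

    def test_two_strong_initial_arms_do_not_add_under_disjunctive(self):
        fx = addarm.illustration_two_initial_arms()
        t = decision_map_stage1(
            fx.design, fx.priors, (1, 2), [0.4], [0.4],
            plan_add=fx.plan_add, plan_noadd=fx.plan_noadd,
            fixed_means={0: 0.0}, kind="disjunctive",
        )
        assert t.label.iloc[0] in ("no_add", "indifferent")

    def test_stage1_map_requires_fixed_means_for_remaining_arms(self):
        fx = addarm.illustration_two_initial_arms()
        with pytest.raises(ValueError):
            decision_map_stage1(
                fx.design, fx.priors, (1, 2), [0.0], [0.0],
                plan_add=fx.plan_add, plan_noadd=fx.plan_noadd, kind="count",
            )
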