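"""Evaluation metrics against brute-force / textbook recomputation."""

import numpy as np
import pytest

from mealforge.meal_store import SLOTS, Meal
from mealforge.metrics import (
    creation_rate,
    energy_agreement,
    plan_accuracy,
    rejection_metrics,
    topn_promotion_accuracy,
    variety_stats,
)
from mealforge.plan_engine import build_plan
from mealforge.profile_model import UserProfile

from conftest import make_plan_meals, toy_ruleset


def _profile(**kwargs):
    base = dict(sex="M", age=40.0, height=1.75, weight=80.0, pal=1.4)
    base.update(kwargs)
    return UserProfile(**base)


class TestRejectionMetrics:
    def test_formula_arithmetic(self):
        # TP=9, FP=0, FN=1 -> precision 1.0, recall 0.9, F 0.947
        truth = {f"m{i}": i < 10 for i in range(20)}
        rejected = {f"m{i}": i < 9 for i in range(20)}
        m = rejection_metrics(rejected, truth)
        assert (m.tp, m.fp, m.fn) == (9, 0, 1)
        assert m.precision == pytest.approx(1.0)
        assert m.recall == pytest.approx(0.9)
        assert m.f_measure == pytest.approx(0.947, abs=5e-4)

    def test_perfect_agreement(self):
        truth = {f"m{i}": i % 3 == 0 for i in range(12)}
        m = rejection_metrics(dict(truth), truth)
        assert (m.precision, m.recall, m.f_measure) == (1.0, 1.0, 1.0)

    def test_empty_denominators_default_to_one_with_warning(self):
        truth = {"a": False, "b": False}
        with pytest.warns(UserWarning):
            m = rejection_metrics({}, truth)
        assert m.precision == 1.0 and m.recall == 1.0

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 20))
            truth = {f"m{i}": bool(rng.integers(2)) for i in range(n)}
            rejected = {f"m{i}": bool(rng.integers(2)) for i in range(n)}
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = rejection_metrics(rejected, truth)
            tp = sum(rejected[k] and truth[k] for k in truth)
            fp = sum(rejected[k] and not truth[k] for k in truth)
            fn = sum(not rejected[k] and truth[k] for k in truth)
            if tp + fp:
                assert m.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert m.recall == pytest.approx(tp / (tp + fn))


class TestTopN:
    def _meals(self):
        return [
            Meal(id=f"m{i}", title="x", slot="lunch", energy=100.0,
                 nutrients={"iron": float(i)})
            for i in range(10)
        ]

    def test_promoted_subset_of_top3_scores_one_everywhere(self):
        meals = self._meals()
        promoted = {"m9", "m8"}           # the two highest iron totals
        for n in (3, 5, 10, 20):
            assert topn_promotion_accuracy(promoted, meals, "iron", n) == 1.0

    def test_partial_overlap_counts(self):
        meals = self._meals()
        promoted = {"m9", "m0"}           # one in top-3, one dead last
        assert topn_promotion_accuracy(promoted, meals, "iron", 3) == 0.5

    def test_empty_promotion_is_na(self):
        assert topn_promotion_accuracy(set(), self._meals(), "iron", 5) is None

    def test_ties_broken_by_meal_id(self):
        meals = [
            Meal(id=i, title="x", slot="lunch", energy=1.0,
                 nutrients={"iron": 5.0})
            for i in ("a", "b", "c")
        ]
        assert topn_promotion_accuracy({"a"}, meals, "iron", 1) == 1.0
        assert topn_promotion_accuracy({"c"}, meals, "iron", 1) == 0.0


class TestPlanAccuracy:
    def test_all_in_range_is_100(self):
        plan = build_plan(0, make_plan_meals())
        out = plan_accuracy([plan], [toy_ruleset()], [_profile()])
        assert out.overall_pct == 100.0

    def test_counting_one_of_four_out(self):
        # fat out of range: 1 of the 4 scored checks misses -> 75%
        plan = build_plan(0, make_plan_meals(fat=150.0))
        out = plan_accuracy([plan], [toy_ruleset()], [_profile()])
        assert out.overall_pct == pytest.approx(75.0)
        assert out.n_macro + out.n_other == 4

    def test_group_without_applicable_rules_is_na(self):
        from mealforge.profile_model import Importance, NutrientRule, RuleSet
        from mealforge.nutrients import UnitKind
        rs = RuleSet(
            group="X", sex="A", energy_target=2000.0,
            rules=[NutrientRule("fibre", 25, 35, UnitKind.PER_DAY,
                                Importance.NON_ESSENTIAL)],
        )
        plan = build_plan(0, make_plan_meals())
        out = plan_accuracy([plan], [rs], [_profile()])
        assert out.overall_pct is None and out.other_pct is None

    def test_invariant_to_rule_ordering(self):
        plan = build_plan(0, make_plan_meals(fat=150.0))
        rs = toy_ruleset()
        forward = plan_accuracy([plan], [rs], [_profile()])
        rs_rev = toy_ruleset()
        rs_rev.rules = list(reversed(rs_rev.rules))
        backward = plan_accuracy([plan], [rs_rev], [_profile()])
        assert forward.overall_pct == backward.overall_pct


class TestEnergyAgreement:
    def test_exact_match_degenerate_case(self):
        targets = [1800.0, 2000.0, 2400.0, 2600.0]
        out = energy_agreement(list(targets), targets)
        assert out.mean_pct_diff == 0.0 and out.sd_pct_diff == 0.0
        assert out.pearson_r == pytest.approx(1.0)
        assert out.bland_altman_within_pct == 100.0

    def test_constant_distribution_r_is_na(self):
        with pytest.warns(UserWarning, match="constant"):
            out = energy_agreement([2000.0, 2000.0], [2000.0, 2000.0])
        assert out.pearson_r is None

    def test_ten_pair_fixture_matches_textbook_formulas(self):
        """Independent recomputation with explicit formulas."""
        rng = np.random.default_rng(3)
        targets = rng.uniform(1500.0, 3000.0, size=10)
        plans = targets * (1.0 + rng.normal(0.0, 0.05, size=10))
        out = energy_agreement(plans, targets)
        d = (plans - targets) / targets * 100.0
        assert out.mean_pct_diff == pytest.approx(d.mean())
        assert out.sd_pct_diff == pytest.approx(d.std(ddof=1))
        # Pearson via the covariance definition
        r = (
            np.sum((plans - plans.mean()) * (targets - targets.mean()))
            / np.sqrt(np.sum((plans - plans.mean()) ** 2)
                      * np.sum((targets - targets.mean()) ** 2))
        )
        assert out.pearson_r == pytest.approx(float(r), rel=1e-12)
        lo, hi = d.mean() - 1.96 * d.std(ddof=1), d.mean() + 1.96 * d.std(ddof=1)
        assert out.bland_altman_within_pct == pytest.approx(
            100.0 * np.mean((d >= lo) & (d <= hi))
        )

    def test_symmetric_under_pair_permutation(self):
        rng = np.random.default_rng(4)
        targets = rng.uniform(1500.0, 3000.0, size=12)
        plans = targets + rng.normal(0.0, 80.0, size=12)
        a = energy_agreement(plans, targets)
        perm = rng.permutation(12)
        b = energy_agreement(plans[perm], targets[perm])
        assert a.mean_pct_diff == pytest.approx(b.mean_pct_diff)
        assert a.pearson_r == pytest.approx(b.pearson_r)
        assert a.bland_altman_within_pct == pytest.approx(
            b.bland_altman_within_pct
        )


class TestVarietyAndCreation:
    def _week(self, ids_per_slot):
        week = []
        for day in range(7):
            meals = {}
            for slot in SLOTS:
                mid = ids_per_slot[slot][day]
                meals[slot] = Meal(id=mid, title="x", slot=slot, energy=300.0)
            week.append(build_plan(day, meals))
        return week

    def test_unique_counts(self):
        ids = {s: [f"{s}{d}" for d in range(7)] for s in SLOTS}
        ids["breakfast"] = ["same"] * 7      # a single repeated breakfast
        stats = variety_stats([self._week(ids)])
        assert stats["breakfast"]["counts"] == [1]
        assert stats["dinner"]["counts"] == [7]

    def test_creation_rate_counting(self):
        profiles = [
            _profile(),
            _profile(intolerances={"lactose"}),
            _profile(intolerances={"lactose"}),
            _profile(dietary_choice="vegan", intolerances={"lactose"}),
        ]
        successes = [True, True, False, False]
        rates = creation_rate(successes, profiles)
        assert rates.overall_pct == pytest.approx(50.0)
        assert rates.by_condition_at_least_pct["lactose"] == pytest.approx(
            100.0 / 3
        )
        assert rates.by_condition_count_pct[0] == 100.0
        assert rates.by_condition_count_pct[2] == 0.0

    def test_76_of_100_is_76_percent(self):
        profiles = [_profile() for _ in range(100)]
        successes = [i < 76 for i in range(100)]
        assert creation_rate(successes, profiles).overall_pct == 76.0
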