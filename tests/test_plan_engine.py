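"""Fitness scoring fidelity and plan-search behaviour."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mealforge.meal_store import SLOTS, Meal
from mealforge.plan_engine import (
    ScoringConfig,
    apply_variety_filters,
    build_plan,
    generate_daily_plan,
    generate_weekly_plan,
    nutrient_factor,
    pools_by_slot,
    score_plan,
    _search_day,
)
from mealforge.profile_model import Importance, NutrientRule, UserProfile
from mealforge.nutrients import UnitKind
from mealforge.synthetic_data import MealDBSpec, generate_meal_db

from conftest import make_plan_meals, toy_ruleset


def _profile(**kwargs):
    base = dict(sex="M", age=40.0, height=1.75, weight=80.0, pal=1.4)
    base.update(kwargs)
    return UserProfile(**base)


class TestNutrientFactor:
    def test_in_range_awards(self):
        cfg = ScoringConfig()
        essential = NutrientRule("cho", 35, 55, UnitKind.PERCENT_ENERGY,
                                 Importance.ESSENTIAL)
        desirable = NutrientRule("fibre", 25, 35, UnitKind.PER_DAY,
                                 Importance.DESIRABLE)
        assert nutrient_factor(45.0, essential, cfg) == 0.01
        assert nutrient_factor(30.0, desirable, cfg) == 0.1

    def test_two_essentials_in_range_product(self):
        cfg = ScoringConfig()
        rule = NutrientRule("cho", 35, 55, UnitKind.PERCENT_ENERGY,
                            Importance.ESSENTIAL)
        product = nutrient_factor(40.0, rule, cfg) * nutrient_factor(50.0, rule, cfg)
        assert product == pytest.approx(1e-4, abs=1e-15)

    def test_out_of_range_penalty(self):
        cfg = ScoringConfig()
        rule = NutrientRule("fibre", 25, 35, UnitKind.PER_DAY,
                            Importance.DESIRABLE)
        assert nutrient_factor(60.0, rule, cfg) == 10.0

    def test_bonus_range_earns_extra_award(self):
        cfg = ScoringConfig()
        rule = NutrientRule("cho", 35, 55, UnitKind.PERCENT_ENERGY,
                            Importance.DESIRABLE, bonus=True)
        assert nutrient_factor(45.0, rule, cfg) == 0.01

    def test_non_essential_is_excluded(self):
        cfg = ScoringConfig()
        rule = NutrientRule("iron", 10, 45, UnitKind.PER_DAY,
                            Importance.NON_ESSENTIAL)
        assert nutrient_factor(999.0, rule, cfg) is None

    def test_literal_mode_zeroes_instead(self):
        cfg = ScoringConfig(literal_weights=True)
        rule = NutrientRule("iron", 10, 45, UnitKind.PER_DAY,
                            Importance.NON_ESSENTIAL)
        assert nutrient_factor(999.0, rule, cfg) == 0.0

    def test_constant_ordering_enforced(self):
        with pytest.raises(ValueError, match="penalty"):
            ScoringConfig(penalty_value=0.5)


class TestScorePlan:
    """Hand-computed fixture: 1900 kcal plan against a 2000 kcal target.

    cho 250 g -> 52.63 %EI in [35,55], essential  -> 0.01
    protein 80 g -> 1.0 g/kg in [0.8,1.2], desirable -> 0.1
    fat 60 g -> 28.42 %EI in [25,35], essential -> 0.01
    fibre 30 g in [25,35], desirable -> 0.1
    iron non-essential -> excluded
    s_cal = 100; S_macro = 0.01*0.1*0.01 = 1e-5; S_micro = 0.1
    no repeated foods -> x 0.1
    fitness = 100 * 1e-5 * 0.1 * 0.1 = 1e-5
    """

    def test_hand_computed_fitness(self, fixed_ruleset):
        plan = build_plan(0, make_plan_meals())
        score = score_plan(plan, fixed_ruleset, _profile())
        assert score.s_calories == pytest.approx(100.0, abs=1e-12)
        assert score.s_macro == pytest.approx(1e-5, abs=1e-12)
        assert score.s_micro == pytest.approx(0.1, abs=1e-12)
        assert score.repeat_count == 0
        assert score.fitness == pytest.approx(1e-5, abs=1e-12)
        assert not score.violates_essential

    def test_degrading_one_essential_multiplies_by_1000(self, fixed_ruleset):
        base = score_plan(build_plan(0, make_plan_meals()), fixed_ruleset,
                          _profile())
        # fat 90 g -> 42.6 %EI, outside [25, 35]: essential award -> penalty
        worse = score_plan(
            build_plan(0, make_plan_meals(fat=90.0)), fixed_ruleset, _profile()
        )
        assert worse.s_macro / base.s_macro == pytest.approx(1000.0)
        assert worse.fitness / base.fitness == pytest.approx(1000.0)
        assert worse.essential_out == ["fat"]

    def test_energy_exactly_at_target_annihilates_fitness(self):
        # 2400 kcal splits exactly across the six slots
        fixed_ruleset = toy_ruleset(energy_target=2400.0)
        plan = build_plan(0, make_plan_meals(energy_total=2400.0))
        score = score_plan(plan, fixed_ruleset, _profile())
        assert score.s_calories == 0.0
        assert score.fitness == 0.0

    def test_repeated_food_weighting(self, fixed_ruleset):
        meals = make_plan_meals(with_foods=True)
        # same ingredient in two slots: r = 1 -> weight (1+1) instead of 0.1
        meals["lunch"].ingredients = [("food_breakfast", 100.0)]
        plan = build_plan(0, meals)
        score = score_plan(plan, fixed_ruleset, _profile())
        assert score.repeat_count == 1
        no_repeat = score_plan(
            build_plan(0, make_plan_meals(with_foods=True)), fixed_ruleset,
            _profile(),
        )
        assert score.fitness / no_repeat.fitness == pytest.approx(2.0 / 0.1)

    def test_literal_mode_zeroes_whole_fitness(self, fixed_ruleset):
        plan = build_plan(0, make_plan_meals())
        cfg = ScoringConfig(literal_weights=True)
        assert score_plan(plan, fixed_ruleset, _profile(), cfg).fitness == 0.0


def _random_pools(rng, sizes):
    """Small per-slot pools with varied composition for oracle checks."""
    pools = {}
    counter = 0
    for slot, n in zip(SLOTS, sizes):
        pool = []
        for _ in range(n):
            energy = float(rng.uniform(100.0, 900.0))
            pool.append(Meal(
                id=f"r{counter:03d}", title="r", slot=slot, energy=energy,
                ingredients=[(f"ing{rng.integers(0, 12)}", 50.0)],
                nutrients={
                    "cho": energy * float(rng.uniform(0.30, 0.60)) / 4.0,
                    "protein": energy * float(rng.uniform(0.08, 0.25)) / 4.0,
                    "fat": energy * float(rng.uniform(0.20, 0.40)) / 9.0,
                    "fibre": float(rng.uniform(0.0, 12.0)),
                },
            ))
            counter += 1
        pools[slot] = pool
    return pools


def _brute_force_best(pools, ruleset, profile, cfg):
    best = None
    for combo in itertools.product(*[pools[s] for s in SLOTS]):
        plan = build_plan(0, dict(zip(SLOTS, combo)))
        score = score_plan(plan, ruleset, profile, cfg)
        key = (score.fitness, score.s_calories, plan.meal_ids)
        if best is None or key < best[0]:
            best = (key, plan, score)
    return best


class TestDailySearch:
    def test_matches_exhaustive_oracle_on_small_pools(self):
        """Sampled search with budget >= pool size equals brute force."""
        rng = np.random.default_rng(42)
        cfg = ScoringConfig(candidate_budget=1000)
        profile = _profile()
        ruleset = toy_ruleset(energy_target=2200.0)
        for trial in range(10):
            sizes = rng.integers(1, 4, size=6)
            pools = _random_pools(rng, sizes)
            result = generate_daily_plan(pools, ruleset, profile, cfg, rng=trial)
            (key, _, best_score) = _brute_force_best(pools, ruleset, profile, cfg)
            assert result.plan.score.fitness == pytest.approx(
                best_score.fitness, rel=1e-12
            )
            assert result.plan.meal_ids == key[2]

    def test_empty_slot_pool_is_typed_failure(self):
        rng = np.random.default_rng(0)
        pools = _random_pools(rng, [2, 2, 2, 2, 2, 2])
        pools["supper"] = []
        result = generate_daily_plan(pools, toy_ruleset(), _profile())
        assert not result.ok and result.status == "empty_slot"

    def test_single_candidate_per_slot_returns_that_plan(self):
        rng = np.random.default_rng(1)
        pools = _random_pools(rng, [1] * 6)
        result = generate_daily_plan(pools, toy_ruleset(2000.0), _profile())
        expected = tuple(pools[s][0].id for s in SLOTS)
        assert result.plan.meal_ids == expected

    def test_essential_violation_is_typed_failure(self):
        # every meal far too fatty: fat %EI essential cannot be met
        meals = make_plan_meals(fat=200.0)
        pools = {s: [meals[s]] for s in SLOTS}
        result = generate_daily_plan(pools, toy_ruleset(1900.0), _profile())
        assert result.status == "essential_violation"
        assert "fat" in result.diagnostics["essential_out"]

    def test_deterministic_under_seed(self):
        db = generate_meal_db(MealDBSpec(n_meals=120), seed=5)
        pools = pools_by_slot(db.meals)
        profile = _profile()
        ruleset = toy_ruleset(2100.0)
        a = generate_daily_plan(pools, ruleset, profile, rng=123)
        b = generate_daily_plan(pools, ruleset, profile, rng=123)
        assert a.plan.meal_ids == b.plan.meal_ids
        assert a.plan.score.fitness == b.plan.score.fitness


@pytest.fixture(scope="module")
def db_pools():
    db = generate_meal_db(MealDBSpec(n_meals=150), seed=11)
    return pools_by_slot(db.meals)


class TestWeeklyPlan:
    def test_weekly_determinism(self, db_pools):
        profile = _profile()
        ruleset = toy_ruleset(2100.0)
        a = generate_weekly_plan(db_pools, ruleset, profile, seed=9)
        b = generate_weekly_plan(db_pools, ruleset, profile, seed=9)
        assert [p.meal_ids for p in a.plans] == [p.meal_ids for p in b.plans]

    def test_meal_usage_cap_and_distinct_day_tuples(self, db_pools):
        profile = _profile()
        ruleset = toy_ruleset(2100.0)
        result = generate_weekly_plan(db_pools, ruleset, profile, seed=3)
        assert result.status in ("ok", "partial")
        tuples = [p.meal_ids for p in result.plans]
        assert len(set(tuples)) == len(tuples)
        from collections import Counter
        usage = Counter(mid for t in tuples for mid in t)
        assert max(usage.values()) <= 3

    def test_dominant_breakfast_capped_at_three_days(self):
        """One clearly-best breakfast must not fill more than 3 of 7 days."""
        rng = np.random.default_rng(21)
        pools = _random_pools(rng, [4, 3, 3, 3, 3, 3])
        # make one breakfast dominate: perfectly aligned with the target
        star = pools["breakfast"][0]
        star.energy = 500.0
        star.nutrients = {"cho": 62.5, "protein": 18.0, "fat": 16.0, "fibre": 7.0}
        ruleset = toy_ruleset(2100.0)
        result = generate_weekly_plan(pools, ruleset, _profile(), seed=2)
        breakfasts = [p.meals["breakfast"].id for p in result.plans]
        assert sum(b == star.id for b in breakfasts) <= 3

    def test_variety_filters_idempotent(self, db_pools):
        profile = _profile()
        ruleset = toy_ruleset(2100.0)
        cfg = ScoringConfig()
        import numpy as _np
        children = _np.random.SeedSequence(4).spawn(7)
        day_cands = []
        for d in range(7):
            cands = _search_day(
                db_pools, ruleset, profile, cfg,
                _np.random.default_rng(children[d]),
            )
            cands.order = cands.order[:cfg.keep_alternatives]
            day_cands.append(cands)
        first, _ = apply_variety_filters(day_cands, cfg)
        second, _ = apply_variety_filters(day_cands, cfg)
        assert first == second

    def test_average_slot_variety_with_rich_pools(self):
        """With many near-tied options, slots average >= 3 unique meals."""
        db = generate_meal_db(MealDBSpec(n_meals=300), seed=13)
        pools = pools_by_slot(db.meals)
        profile = _profile()
        ruleset = toy_ruleset(2100.0)
        varieties = []
        for seed in range(20):
            result = generate_weekly_plan(pools, ruleset, profile, seed=seed)
            for slot in SLOTS:
                varieties.append(
                    len({p.meals[slot].id for p in result.plans})
                )
        assert float(np.mean(varieties)) >= 3.0


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    energy=st.floats(min_value=1200.0, max_value=3200.0),
    fat=st.floats(min_value=20.0, max_value=160.0),
)
def test_vectorized_and_scalar_scoring_agree(energy, fat):
    """The array-based search scores exactly like the reference scorer."""
    meals = make_plan_meals(energy_total=energy, fat=fat, with_foods=True)
    pools = {s: [meals[s]] for s in SLOTS}
    profile = _profile()
    ruleset = toy_ruleset(2000.0)
    cfg = ScoringConfig()
    cands = _search_day(pools, ruleset, profile, cfg, np.random.default_rng(0))
    plan = build_plan(0, meals)
    reference = score_plan(plan, ruleset, profile, cfg)
    assert cands.fitness[0] == pytest.approx(reference.fitness, rel=1e-12)
    assert cands.s_cal[0] == pytest.approx(reference.s_calories, rel=1e-12)
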