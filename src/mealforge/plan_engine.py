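"""Quantitative layer: fitness scoring and daily/weekly plan generation.

A daily nutritional plan (NP) fills the six meal slots from per-slot
candidate pools.  Its fitness is a cost (lower is better):

    fitness = S_calories * S_macro * S_micro * variety_weight

where ``S_calories`` is the absolute difference between the plan's energy
and the user's target energy intake, and each ``S_*`` is a product of
per-nutrient factors: ``penalty`` (10) when the value falls outside its
target range, ``award`` (0.1) when inside, ``essential award`` (0.01)
when inside and the rule is essential or carries the group's bonus flag.
Non-essential rules are excluded from the product (weight zero is read as
"drop the factor"; a literal mode that zeroes the product instead is
available for fidelity experiments).  The variety weight multiplies by
the award value when no food repeats within the day and by ``1 + r`` when
``r`` foods repeat.

Daily plans are found by seeded randomized search over slot combinations
(exhaustive when the combination space fits the candidate budget);
weekly plans are seven daily plans post-filtered so that no meal appears
in more than three days and no two days share the identical slot-ordered
meal tuple, iterating from the fittest day downwards.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np

from .meal_store import SLOTS, Meal
from .nutrients import ATWATER_KCAL_PER_G, MACRO_NUTRIENTS, UnitKind
from .profile_model import Importance, NutrientRule, RuleSet, UserProfile


@dataclass
class ScoringConfig:
    penalty_value: float = 10.0
    award_value: float = 0.1
    essential_award_value: float = 0.01
    candidate_budget: int = 2000
    day_time_limit_s: float = 165.0    # per-day search budget
    week_time_limit_s: float = 195.0   # whole-request budget
    literal_weights: bool = False      # w=0 zeroes the product (fidelity mode)
    max_meal_uses_per_week: int = 3
    keep_alternatives: int = 400       # ranked fallbacks kept per day
    refine_sweeps: int = 2             # local slot-swap passes after sampling

    def __post_init__(self) -> None:
        if not (
            self.penalty_value > 1.0 > self.award_value
            > self.essential_award_value > 0.0
        ):
            raise ValueError(
                "scoring constants must satisfy penalty > 1 > award > "
                "essential award > 0"
            )
        if self.candidate_budget < 1:
            raise ValueError("candidate budget must be positive")


@dataclass
class PlanScore:
    s_calories: float
    s_macro: float
    s_micro: float
    fitness: float
    repeat_count: int
    essential_out: list[str] = field(default_factory=list)

    @property
    def violates_essential(self) -> bool:
        return bool(self.essential_out)


@dataclass
class NutritionalPlan:
    day: int
    meals: dict[str, Meal]          # slot -> meal
    totals: dict[str, float]
    energy: float
    score: PlanScore | None = None

    def __post_init__(self) -> None:
        for slot, meal in self.meals.items():
            if meal.slot != slot:
                raise ValueError(
                    f"slot {slot!r} filled with a {meal.slot!r} meal ({meal.id})"
                )

    @property
    def meal_ids(self) -> tuple[str, ...]:
        return tuple(self.meals[s].id for s in SLOTS)

    def to_dict(self) -> dict:
        return {
            "day": self.day,
            "meals": {s: self.meals[s].id for s in SLOTS},
            "energy": self.energy,
            "totals": dict(sorted(self.totals.items())),
            "score": None
            if self.score is None
            else {
                "s_calories": self.score.s_calories,
                "s_macro": self.score.s_macro,
                "s_micro": self.score.s_micro,
                "fitness": self.score.fitness,
                "repeat_count": self.score.repeat_count,
                "essential_out": list(self.score.essential_out),
            },
        }


def plan_totals(meals: dict[str, Meal]) -> tuple[dict[str, float], float]:
    totals: dict[str, float] = {}
    energy = 0.0
    for meal in meals.values():
        energy += meal.energy
        for nut, amount in meal.nutrients.items():
            totals[nut] = totals.get(nut, 0.0) + amount
    return totals, energy


def build_plan(day: int, meals: dict[str, Meal]) -> NutritionalPlan:
    totals, energy = plan_totals(meals)
    return NutritionalPlan(day=day, meals=meals, totals=totals, energy=energy)


# ---------------------------------------------------------------------------
# Scoring (scalar reference path)
# ---------------------------------------------------------------------------

def rule_value(
    total: float,
    rule: NutrientRule,
    *,
    plan_energy: float,
    body_weight: float,
) -> float:
    """A plan's daily total converted into the rule's unit."""
    if rule.unit_kind is UnitKind.PERCENT_ENERGY:
        return total * ATWATER_KCAL_PER_G[rule.nutrient] / max(plan_energy, 1e-9) * 100.0
    if rule.unit_kind is UnitKind.G_PER_KG_BW:
        return total / body_weight
    if rule.unit_kind is UnitKind.PORTIONS_PER_DAY:
        return total / 80.0
    return total


def nutrient_factor(
    value: float, rule: NutrientRule, cfg: ScoringConfig
) -> float | None:
    """The p_i factor for one rule, or ``None`` when the rule is unscored.

    Non-essential rules carry weight zero and are excluded from the
    product; in literal mode they return 0.0, annihilating it.
    """
    if not rule.scored:
        return 0.0 if cfg.literal_weights else None
    if not rule.lower <= value <= rule.upper:
        return cfg.penalty_value
    if rule.importance is Importance.ESSENTIAL or rule.bonus:
        return cfg.essential_award_value
    return cfg.award_value


def repeated_food_count(meals: dict[str, Meal]) -> int:
    """Number of repeated ingredient appearances within one plan."""
    all_ids = [fid for meal in meals.values() for fid in meal.food_ids]
    return len(all_ids) - len(set(all_ids))


def score_plan(
    plan: NutritionalPlan,
    ruleset: RuleSet,
    profile: UserProfile,
    cfg: ScoringConfig | None = None,
) -> PlanScore:
    """Score one plan against the user's resolved nutrient-range table."""
    cfg = cfg or ScoringConfig()
    s_cal = abs(plan.energy - ruleset.energy_target)
    s_macro = 1.0
    s_micro = 1.0
    essential_out: list[str] = []
    for rule in ruleset.rules:
        value = rule_value(
            plan.totals.get(rule.nutrient, 0.0),
            rule,
            plan_energy=plan.energy,
            body_weight=profile.weight,
        )
        factor = nutrient_factor(value, rule, cfg)
        if factor is None:
            continue
        if rule.nutrient in MACRO_NUTRIENTS:
            s_macro *= factor
        else:
            s_micro *= factor
        if (
            rule.importance is Importance.ESSENTIAL
            and not rule.lower <= value <= rule.upper
        ):
            essential_out.append(rule.nutrient)
    r = repeated_food_count(plan.meals)
    variety_weight = cfg.award_value if r == 0 else float(1 + r)
    fitness = s_cal * s_macro * s_micro * variety_weight
    return PlanScore(
        s_calories=s_cal,
        s_macro=s_macro,
        s_micro=s_micro,
        fitness=fitness,
        repeat_count=r,
        essential_out=essential_out,
    )


# ---------------------------------------------------------------------------
# Daily plan search
# ---------------------------------------------------------------------------

@dataclass
class DailyPlanResult:
    status: str                       # ok | empty_slot | essential_violation | time_limit
    plan: NutritionalPlan | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


class _DayCandidates:
    """Ranked scored slot-combinations for one day (replacement source)."""

    def __init__(self, pools, order, combos, fitness, s_cal, repeats,
                 essential_ok, s_macro, s_micro, energy):
        self.pools = pools
        self.order = order            # candidate indices, best first
        self.combos = combos
        self.fitness = fitness
        self.s_cal = s_cal
        self.repeats = repeats
        self.essential_ok = essential_ok
        self.s_macro = s_macro
        self.s_micro = s_micro
        self.energy = energy

    def __len__(self) -> int:
        return len(self.order)

    def meal_ids(self, rank: int) -> tuple[str, ...]:
        idx = self.combos[self.order[rank]]
        return tuple(self.pools[s][idx[j]].id for j, s in enumerate(SLOTS))

    def plan(self, rank: int, day: int) -> NutritionalPlan:
        ci = self.order[rank]
        idx = self.combos[ci]
        meals = {s: self.pools[s][idx[j]] for j, s in enumerate(SLOTS)}
        plan = build_plan(day, meals)
        plan.score = PlanScore(
            s_calories=float(self.s_cal[ci]),
            s_macro=float(self.s_macro[ci]),
            s_micro=float(self.s_micro[ci]),
            fitness=float(self.fitness[ci]),
            repeat_count=int(self.repeats[ci]),
            essential_out=[] if self.essential_ok[ci] else ["unresolved"],
        )
        return plan


def _search_day(
    pools: dict[str, list[Meal]],
    ruleset: RuleSet,
    profile: UserProfile,
    cfg: ScoringConfig,
    rng: np.random.Generator,
) -> _DayCandidates | str:
    """Score up to ``candidate_budget`` slot combinations, ranked best-first.

    When the combination space exceeds the budget, the sampled optimum is
    additionally improved by ``refine_sweeps`` deterministic passes of
    single-slot substitution (coordinate descent), which recovers targets
    in the tails of the day-energy distribution that uniform sampling
    covers poorly.  Refinement only ever adds better-scoring candidates,
    so with exhaustive enumeration it is a no-op.  Returns the ranked
    candidates, or an error status string.
    """
    for slot in SLOTS:
        if not pools.get(slot):
            return "empty_slot"
    sizes = [len(pools[s]) for s in SLOTS]
    n_combos = int(np.prod([float(n) for n in sizes]))
    exhaustive = n_combos <= cfg.candidate_budget
    if exhaustive:
        combos = np.array(
            list(itertools.product(*[range(n) for n in sizes])), dtype=np.intp
        )
    else:
        combos = np.stack(
            [rng.integers(0, n, size=cfg.candidate_budget) for n in sizes],
            axis=1,
        ).astype(np.intp)
        combos = np.unique(combos, axis=0)

    scored_rules = [r for r in ruleset.rules if r.scored]
    # per-slot arrays: energies and native nutrient totals per rule
    slot_energy = {s: np.array([m.energy for m in pools[s]]) for s in SLOTS}
    slot_values = {
        s: np.array(
            [[m.nutrients.get(r.nutrient, 0.0) for r in scored_rules]
             for m in pools[s]]
        ).reshape(len(pools[s]), len(scored_rules))
        for s in SLOTS
    }
    slot_foods = {s: [m.food_ids for m in pools[s]] for s in SLOTS}
    slot_ids = {s: [m.id for m in pools[s]] for s in SLOTS}
    literal_zero = cfg.literal_weights and any(
        not r.scored for r in ruleset.rules
    )

    def score_combos(cmb: np.ndarray) -> dict:
        energy = np.zeros(len(cmb))
        totals = np.zeros((len(cmb), len(scored_rules)))
        for j, s in enumerate(SLOTS):
            energy += slot_energy[s][cmb[:, j]]
            totals += slot_values[s][cmb[:, j]]
        s_macro = np.ones(len(cmb))
        s_micro = np.ones(len(cmb))
        essential_ok = np.ones(len(cmb), dtype=bool)
        for k, rule in enumerate(scored_rules):
            if rule.unit_kind is UnitKind.PERCENT_ENERGY:
                value = (
                    totals[:, k] * ATWATER_KCAL_PER_G[rule.nutrient]
                    / np.maximum(energy, 1e-9) * 100.0
                )
            elif rule.unit_kind is UnitKind.G_PER_KG_BW:
                value = totals[:, k] / profile.weight
            elif rule.unit_kind is UnitKind.PORTIONS_PER_DAY:
                value = totals[:, k] / 80.0
            else:
                value = totals[:, k]
            out = (value < rule.lower) | (value > rule.upper)
            in_award = (
                cfg.essential_award_value
                if rule.importance is Importance.ESSENTIAL or rule.bonus
                else cfg.award_value
            )
            factor = np.where(out, cfg.penalty_value, in_award)
            if rule.nutrient in MACRO_NUTRIENTS:
                s_macro *= factor
            else:
                s_micro *= factor
            if rule.importance is Importance.ESSENTIAL:
                essential_ok &= ~out
        repeats = np.empty(len(cmb), dtype=np.intp)
        for i, idx in enumerate(cmb):
            all_ids = []
            for j, s in enumerate(SLOTS):
                all_ids.extend(slot_foods[s][idx[j]])
            repeats[i] = len(all_ids) - len(set(all_ids))
        s_cal = np.abs(energy - ruleset.energy_target)
        variety = np.where(repeats == 0, cfg.award_value, 1.0 + repeats)
        fitness = s_cal * s_macro * s_micro * variety
        if literal_zero:
            fitness = np.zeros_like(fitness)
        return {
            "energy": energy, "s_macro": s_macro, "s_micro": s_micro,
            "essential_ok": essential_ok, "repeats": repeats,
            "s_cal": s_cal, "fitness": fitness,
        }

    arrays = score_combos(combos)

    def sort_key(i: int):
        idx = combos[i]
        return (
            arrays["fitness"][i],
            arrays["s_cal"][i],
            tuple(slot_ids[s][idx[j]] for j, s in enumerate(SLOTS)),
        )

    order = sorted(range(len(combos)), key=sort_key)

    if not exhaustive and cfg.refine_sweeps > 0:
        # multistart: the fittest sample, and the sample closest to the
        # energy target (descent from there only needs to repair ranges)
        starts = [order[0], int(np.argmin(arrays["s_cal"]))]
        improved_rows = []
        for start in dict.fromkeys(starts):
            current = combos[start].copy()
            best_key = (arrays["fitness"][start], arrays["s_cal"][start])
            for _ in range(cfg.refine_sweeps):
                changed = False
                for j, s in enumerate(SLOTS):
                    trial = np.tile(current, (sizes[j], 1))
                    trial[:, j] = np.arange(sizes[j])
                    sc = score_combos(trial)
                    ranked = sorted(
                        range(sizes[j]),
                        key=lambda i: (
                            sc["fitness"][i], sc["s_cal"][i], slot_ids[s][i]
                        ),
                    )
                    top = ranked[0]
                    if (sc["fitness"][top], sc["s_cal"][top]) < best_key:
                        current = trial[top].copy()
                        best_key = (sc["fitness"][top], sc["s_cal"][top])
                        improved_rows.append(current.copy())
                        changed = True
                if not changed:
                    break
        if improved_rows:
            extra = np.array(improved_rows, dtype=np.intp)
            extra_arrays = score_combos(extra)
            combos = np.vstack([combos, extra])
            for key in arrays:
                arrays[key] = np.concatenate([arrays[key], extra_arrays[key]])
            order = sorted(range(len(combos)), key=sort_key)

    return _DayCandidates(
        pools, order, combos,
        arrays["fitness"], arrays["s_cal"], arrays["repeats"],
        arrays["essential_ok"], arrays["s_macro"], arrays["s_micro"],
        arrays["energy"],
    )


def generate_daily_plan(
    pools: dict[str, list[Meal]],
    ruleset: RuleSet,
    profile: UserProfile,
    cfg: ScoringConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> DailyPlanResult:
    """Best-of-budget daily plan; typed failure instead of an exception.

    Fails when a slot pool is empty, when the minimum-fitness plan still
    violates an essential rule, or when the time budget expires first.
    """
    cfg = cfg or ScoringConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t0 = time.monotonic()
    cands = _search_day(pools, ruleset, profile, cfg, rng)
    if isinstance(cands, str):
        return DailyPlanResult(status=cands)
    if time.monotonic() - t0 > cfg.day_time_limit_s:
        return DailyPlanResult(
            status="time_limit", diagnostics={"elapsed_s": time.monotonic() - t0}
        )
    plan = cands.plan(0, day=0)
    plan.score = score_plan(plan, ruleset, profile, cfg)  # exact scalar rescore
    if plan.score.violates_essential:
        return DailyPlanResult(
            status="essential_violation",
            plan=plan,
            diagnostics={"essential_out": plan.score.essential_out},
        )
    return DailyPlanResult(
        status="ok", plan=plan,
        diagnostics={"candidates_scored": len(cands)},
    )


# ---------------------------------------------------------------------------
# Weekly plan with variety filters
# ---------------------------------------------------------------------------

@dataclass
class WeeklyPlanResult:
    status: str                        # ok | partial | <daily failure status>
    plans: list[NutritionalPlan] = field(default_factory=list)
    prefilter_meal_ids: list[tuple[str, ...]] = field(default_factory=list)
    prefilter_fitness: list[float] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def apply_variety_filters(
    day_candidates: list[_DayCandidates],
    cfg: ScoringConfig,
) -> tuple[list[int], list[str]]:
    """Pick one candidate rank per day honouring the two week-level filters.

    Iterates days from the fittest pre-filter choice downwards; each day
    takes its best-ranked candidate whose slot tuple has not been used by
    an already-fixed day and whose meals stay within the per-week usage
    cap.  Deterministic given the ranked lists, hence idempotent.
    Returns chosen ranks per day plus relaxation notes.
    """
    n_days = len(day_candidates)
    day_order = sorted(
        range(n_days),
        key=lambda d: (day_candidates[d].fitness[day_candidates[d].order[0]], d),
    )
    chosen = [0] * n_days
    notes: list[str] = []
    used_counts: dict[str, int] = {}
    seen_tuples: set[tuple[str, ...]] = set()
    for d in day_order:
        cands = day_candidates[d]
        pick = None
        count_ok_pick = None   # satisfies both filters but not essentials
        tuple_ok_pick = None   # satisfies only the distinct-tuple filter
        for rank in range(len(cands)):
            ids = cands.meal_ids(rank)
            if ids in seen_tuples:
                continue
            if tuple_ok_pick is None:
                tuple_ok_pick = rank
            if all(
                used_counts.get(mid, 0) + 1 <= cfg.max_meal_uses_per_week
                for mid in set(ids)
            ):
                if cands.essential_ok[cands.order[rank]]:
                    pick = rank
                    break
                if count_ok_pick is None:
                    count_ok_pick = rank
        if pick is None:
            # fall back: essential-violating alternative, then usage-cap
            # relaxation, then the day's own best
            if count_ok_pick is not None:
                pick = count_ok_pick
            else:
                pick = tuple_ok_pick if tuple_ok_pick is not None else 0
                notes.append(
                    f"day {d}: variety constraints relaxed "
                    f"(rank {pick} accepted)"
                )
        chosen[d] = pick
        ids = cands.meal_ids(pick)
        seen_tuples.add(ids)
        for mid in ids:
            used_counts[mid] = used_counts.get(mid, 0) + 1
    return chosen, notes


def generate_weekly_plan(
    pools: dict[str, list[Meal]],
    ruleset: RuleSet,
    profile: UserProfile,
    cfg: ScoringConfig | None = None,
    seed: int | None = None,
    n_days: int = 7,
) -> WeeklyPlanResult:
    """Seven daily plans, post-filtered for weekly variety.

    Filter semantics: no meal in more than ``max_meal_uses_per_week``
    (default 3) of the week's plans, and no two days sharing an identical
    slot-ordered meal tuple, replacing offenders in less-fit days with
    their next-best alternatives.  An infeasible week yields a partial
    result with diagnostics rather than an exception.
    """
    cfg = cfg or ScoringConfig()
    t0 = time.monotonic()
    children = np.random.SeedSequence(seed).spawn(n_days)
    day_candidates: list[_DayCandidates] = []
    for d in range(n_days):
        if time.monotonic() - t0 > cfg.week_time_limit_s:
            return WeeklyPlanResult(
                status="time_limit",
                diagnostics={"days_completed": d,
                             "elapsed_s": time.monotonic() - t0},
            )
        rng = np.random.default_rng(children[d])
        cands = _search_day(pools, ruleset, profile, cfg, rng)
        if isinstance(cands, str):
            return WeeklyPlanResult(status=cands, diagnostics={"day": d})
        # keep the ranked head as the replacement source
        cands.order = cands.order[: max(cfg.keep_alternatives, 1)]
        day_candidates.append(cands)

    prefilter_ids = [c.meal_ids(0) for c in day_candidates]
    prefilter_fitness = [
        float(c.fitness[c.order[0]]) for c in day_candidates
    ]
    chosen, notes = apply_variety_filters(day_candidates, cfg)
    plans = [
        day_candidates[d].plan(chosen[d], day=d) for d in range(n_days)
    ]
    for plan in plans:  # exact scalar rescore of the filtered selection
        plan.score = score_plan(plan, ruleset, profile, cfg)
    essential_bad = [
        d for d in range(n_days) if plans[d].score.violates_essential
    ]
    status = "ok"
    diagnostics: dict = {"relaxations": notes, "chosen_ranks": chosen}
    if essential_bad:
        status = "essential_violation"
        diagnostics["essential_violation_days"] = essential_bad
    elif notes:
        status = "partial"
    return WeeklyPlanResult(
        status=status,
        plans=plans,
        prefilter_meal_ids=prefilter_ids,
        prefilter_fitness=prefilter_fitness,
        diagnostics=diagnostics,
    )


def pools_by_slot(meals: list[Meal]) -> dict[str, list[Meal]]:
    """Partition a meal list into the six slot pools (order preserved)."""
    pools: dict[str, list[Meal]] = {s: [] for s in SLOTS}
    for meal in meals:
        pools[meal.slot].append(meal)
    return pools
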