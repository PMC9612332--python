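"""Synthetic study data: virtual user populations and labelled meal databases.

The generators define the conditions every downstream experiment runs
under.  ``generate_users`` draws profiles with at most one condition per
non-medical group according to configurable probability tables (presets
mirror the published virtual-population recipes); ``generate_meal_db``
composes slot-typed meals from a synthetic ingredient pool plus the
shipped knowledge base, with exact ground-truth labels of which
restriction triggers each meal violates, optional injected annotation
noise, and nutrient totals that are always the sum of the ingredient
contributions.

Meals are engineered for range plausibility, not culinary realism: each
meal's macronutrient energy shares, fibre density and fruit/vegetable
mass are drawn from bands wide enough that a combinatorial optimizer can
assemble daily plans meeting the expert ranges for any energy target the
demographic recipe can produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knowledge_base import KnowledgeBase, default_kb, kb_from_dict, kb_to_dict
from .meal_store import SLOTS, Meal
from .profile_model import UserProfile

# ---------------------------------------------------------------------------
# Virtual users
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    """Recipe for a virtual user population.

    Probability tables map tokens to draw probabilities; per group at most
    one token is drawn and the remaining mass means "none".  The
    challenging-profile mode instead forces at least one medical condition
    (a cardiovascular/diabetes split) plus obesity with the given
    probability.
    """

    n: int = 100
    age_range: tuple[float, float] = (20.0, 65.0)
    pal_range: tuple[float, float] = (1.2, 1.7)
    male_fraction: float = 0.5
    height_range: dict = field(
        default_factory=lambda: {"M": (1.60, 2.00), "F": (1.50, 1.90)}
    )
    weight_range: dict = field(
        default_factory=lambda: {"M": (60.0, 180.0), "F": (40.0, 150.0)}
    )
    diet_probs: dict = field(default_factory=dict)
    intolerance_probs: dict = field(default_factory=dict)
    deficiency_probs: dict = field(default_factory=dict)
    allergy_probs: dict = field(default_factory=dict)
    medical_probs: dict = field(default_factory=dict)
    challenging: bool = False
    heart_disease_prob: float = 0.53   # vs type-2 diabetes, challenging mode
    obesity_prob: float = 0.65         # added independently, challenging mode

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("population size must be positive")
        for name, probs in (
            ("diet", self.diet_probs),
            ("intolerance", self.intolerance_probs),
            ("deficiency", self.deficiency_probs),
            ("allergy", self.allergy_probs),
            ("medical", self.medical_probs),
        ):
            total = sum(probs.values())
            if total > 1.0 + 1e-9:
                raise ValueError(f"{name} probabilities sum to {total} > 1")


def accuracy_population_spec(n: int = 100) -> PopulationSpec:
    """General adult population for the plan-accuracy experiment.

    Demographics follow the virtual-population recipe (ages 20–65, even
    sex split, per-sex uniform height/weight ranges); medical conditions
    are assigned so users spread over the supported groups with emphasis
    on cardiovascular disease, type-2 diabetes and obesity.  No food
    restrictions, so every meal pool stays maximal.
    """
    return PopulationSpec(
        n=n,
        medical_probs={
            "heart_disease": 0.20,
            "type_2_diabetes": 0.22,
            "anemia": 0.07,
            "low_fruit_veg_intake": 0.04,
        },
    )


def capacity_population_spec(n: int = 300) -> PopulationSpec:
    """Challenging-profile population for the capacity experiment."""
    return PopulationSpec(
        n=n,
        diet_probs={
            "pescatarian": 0.12,
            "red_meat_avoider": 0.12,
            "vegan": 0.16,
            "vegetarian": 0.12,
        },
        intolerance_probs={
            "fodmaps": 0.23,
            "gluten": 0.19,
            "lactose": 0.06,
            "salicylates": 0.07,
        },
        deficiency_probs={"iron": 0.21},
        allergy_probs={
            "banana": 0.08,
            "egg": 0.09,
            "peanut": 0.08,
            "tree_nut": 0.13,
            "crustacean": 0.10,
        },
        challenging=True,
    )


def _draw_token(rng: np.random.Generator, probs: dict) -> str | None:
    if not probs:
        return None
    tokens = sorted(probs)
    p = np.array([probs[t] for t in tokens])
    u = rng.random()
    acc = 0.0
    for token, pi in zip(tokens, p):
        acc += pi
        if u < acc:
            return token
    return None


def generate_users(
    spec: PopulationSpec, seed: int | None = None
) -> list[UserProfile]:
    """Draw a reproducible virtual population from the spec."""
    rng = np.random.default_rng(seed)
    users = []
    for i in range(spec.n):
        sex = "M" if rng.random() < spec.male_fraction else "F"
        age = rng.uniform(*spec.age_range)
        height = rng.uniform(*spec.height_range[sex])
        weight = rng.uniform(*spec.weight_range[sex])
        pal = rng.uniform(*spec.pal_range)
        diet = _draw_token(rng, spec.diet_probs)
        intolerance = _draw_token(rng, spec.intolerance_probs)
        deficiency = _draw_token(rng, spec.deficiency_probs)
        allergy = _draw_token(rng, spec.allergy_probs)
        medical: set[str] = set()
        if spec.challenging:
            medical.add(
                "heart_disease"
                if rng.random() < spec.heart_disease_prob
                else "type_2_diabetes"
            )
            if rng.random() < spec.obesity_prob:
                medical.add("obesity")
        else:
            token = _draw_token(rng, spec.medical_probs)
            if token:
                medical.add(token)
        users.append(
            UserProfile(
                sex=sex,
                age=age,
                height=height,
                weight=weight,
                pal=pal,
                dietary_choice=diet,
                intolerances={intolerance} if intolerance else set(),
                deficiencies={deficiency} if deficiency else set(),
                allergies={allergy} if allergy else set(),
                medical_conditions=medical,
                user_id=f"u{i:04d}",
            )
        )
    return users


# ---------------------------------------------------------------------------
# Synthetic meal database
# ---------------------------------------------------------------------------

#: default slot mix, proportional to the unique-option counts of the
#: reference database (breakfast-heavy, supper-light)
DEFAULT_SLOT_MIX = {
    "breakfast": 269,
    "morning_snack": 246,
    "lunch": 236,
    "afternoon_snack": 231,
    "dinner": 220,
    "supper": 48,
}

#: per-slot energy draw ranges; day totals span ~850–4450 kcal so that every
#: energy target the demographic recipe can produce is bracketed
DEFAULT_SLOT_ENERGY = {
    "breakfast": (180.0, 950.0),
    "morning_snack": (50.0, 400.0),
    "lunch": (280.0, 1200.0),
    "afternoon_snack": (50.0, 400.0),
    "dinner": (240.0, 1100.0),
    "supper": (50.0, 400.0),
}

#: slot-wise draw ranges for fruit / vegetable grams per meal
_FRUIT_RANGE = {
    "breakfast": (0.0, 140.0),
    "morning_snack": (0.0, 170.0),
    "lunch": (0.0, 80.0),
    "afternoon_snack": (0.0, 170.0),
    "dinner": (0.0, 80.0),
    "supper": (0.0, 170.0),
}
_VEG_RANGE = {
    "breakfast": (0.0, 60.0),
    "morning_snack": (0.0, 40.0),
    "lunch": (0.0, 260.0),
    "afternoon_snack": (0.0, 40.0),
    "dinner": (0.0, 260.0),
    "supper": (0.0, 40.0),
}


@dataclass
class MealDBSpec:
    n_meals: int = 2266
    slot_mix: dict = field(default_factory=lambda: dict(DEFAULT_SLOT_MIX))
    slot_energy_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_SLOT_ENERGY)
    )
    protein_frac_range: tuple[float, float] = (0.09, 0.22)
    fat_frac_range: tuple[float, float] = (0.25, 0.30)
    sfa_frac_range: tuple[float, float] = (0.055, 0.095)
    other_frac_range: tuple[float, float] = (0.02, 0.06)
    cho_frac_cap: float = 0.54
    fibre_density_range: tuple[float, float] = (5.0, 22.0)  # g per 1000 kcal
    n_variants_per_archetype: int = 8
    violation_fractions: dict = field(default_factory=dict)  # trigger -> frac
    annotation_noise: float = 0.0
    richness_percentile: float = 80.0
    richness_nutrients: tuple[str, ...] = ("iron", "protein", "fibre")

    def __post_init__(self) -> None:
        if self.n_meals <= 0:
            raise ValueError("n_meals must be positive")
        for trig, frac in self.violation_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"violation fraction for {trig!r} not in [0,1]")
        if not 0.0 <= self.annotation_noise <= 1.0:
            raise ValueError("annotation noise must lie in [0,1]")


def rejection_db_spec(n_meals: int = 500, noise: float = 0.0) -> MealDBSpec:
    """A database with labelled violations for the rejection experiment."""
    return MealDBSpec(
        n_meals=n_meals,
        annotation_noise=noise,
        violation_fractions={
            "allergy_banana": 0.06,
            "allergy_avocado": 0.05,
            "allergy_tree_nut": 0.06,
            "allergy_peanut": 0.05,
            "allergy_egg": 0.06,
            "allergy_crustacean": 0.05,
            "kosher": 0.06,
            "vegan": 0.08,
            "lactose": 0.06,
            "gluten": 0.06,
            "fructose": 0.06,
            "salicylates": 0.05,
            "fodmaps": 0.06,
            "type_2_diabetes": 0.06,
        },
    )


def capped_energy_db_spec(n_meals: int = 2266) -> MealDBSpec:
    """Preset with capped slot energies.

    Reproduces the infeasibility of very high (> 3000 kcal) daily targets:
    the maximum achievable day sits near 2600 kcal, so athlete-sized
    targets cannot be met.
    """
    capped = {
        slot: (lo, hi * 0.6) for slot, (lo, hi) in DEFAULT_SLOT_ENERGY.items()
    }
    return MealDBSpec(n_meals=n_meals, slot_energy_ranges=capped)


@dataclass
class MealDB:
    """A generated database: meals, exact truth labels, and the KBs used."""

    meals: list[Meal]
    labels: dict                # meal id -> sorted list of violated triggers
    kb: KnowledgeBase           # what the reasoner sees (possibly noisy)
    clean_kb: KnowledgeBase     # noise-free annotations (ground truth)


# archetype per-100g compositions; fibre/iron jitter is added per variant
_ARCHETYPES = {
    "staple": {"cho": 70.0, "protein": 8.0, "fat": 2.0, "sfa": 0.4,
               "fibre": 4.0, "iron": 2.0},
    "protein": {"protein": 25.0, "fat": 8.0, "sfa": 2.5, "iron": 2.2},
    "oil_low": {"fat": 100.0, "sfa": 10.0},
    "oil_high": {"fat": 100.0, "sfa": 60.0},
    "fruitmix": {"cho": 12.0, "fibre": 2.0, "fruit": 100.0, "iron": 0.4},
    "vegmix": {"cho": 5.0, "protein": 2.0, "fibre": 3.0, "veg": 100.0,
               "iron": 1.5},
    "fibreboost": {"cho": 25.0, "protein": 10.0, "fat": 4.0, "sfa": 0.8,
                   "fibre": 45.0, "iron": 9.0},
}


def _build_food_pool(rng: np.random.Generator, spec: MealDBSpec) -> dict:
    """Synthetic ingredient variants, as KB food dictionaries."""
    foods: dict[str, dict] = {}
    for arche, comp in _ARCHETYPES.items():
        for v in range(spec.n_variants_per_archetype):
            nutrients = dict(comp)
            if "fibre" in nutrients:
                nutrients["fibre"] *= float(rng.uniform(0.7, 1.3))
            if "iron" in nutrients:
                nutrients["iron"] *= float(rng.uniform(0.6, 1.4))
            foods[f"syn_{arche}_{v:02d}"] = {
                "name": f"Synthetic {arche} #{v}",
                "categories": ["synthetic"],
                "nutrients": {k: round(val, 4) for k, val in nutrients.items()},
                "rich_in": [],
            }
    return foods


def _solve_meal_grams(
    rng: np.random.Generator,
    spec: MealDBSpec,
    slot: str,
    pool_ids: dict,
    variants: dict,
) -> tuple[list[tuple[str, float]], float]:
    """Pick ingredient variants and solve grams for one meal's targets."""
    lo, hi = spec.slot_energy_ranges[slot]
    energy = float(rng.uniform(lo, hi))
    p_f = rng.uniform(*spec.protein_frac_range)
    f_f = rng.uniform(*spec.fat_frac_range)
    o_f = rng.uniform(*spec.other_frac_range)
    c_f = min(spec.cho_frac_cap, 1.0 - p_f - f_f - o_f)
    s_f = rng.uniform(*spec.sfa_frac_range)
    fibre_target = rng.uniform(*spec.fibre_density_range) * energy / 1000.0
    fruit_g = float(rng.uniform(*_FRUIT_RANGE[slot]))
    veg_g = float(rng.uniform(*_VEG_RANGE[slot]))

    chosen = {
        arche: pool_ids[arche][rng.integers(len(pool_ids[arche]))]
        for arche in _ARCHETYPES
    }
    comp = {arche: variants[fid]["nutrients"] for arche, fid in chosen.items()}

    # nutrient targets in grams
    targets = np.array([
        c_f * energy / 4.0,       # cho
        p_f * energy / 4.0,       # protein
        f_f * energy / 9.0,       # fat
        s_f * energy / 9.0,       # sfa
        fibre_target,             # fibre
    ])
    # fixed contributions from the drawn fruit / vegetable mass
    fixed = np.zeros(5)
    for arche, grams in (("fruitmix", fruit_g), ("vegmix", veg_g)):
        c = comp[arche]
        fixed += grams / 100.0 * np.array([
            c.get("cho", 0.0), c.get("protein", 0.0), c.get("fat", 0.0),
            c.get("sfa", 0.0), c.get("fibre", 0.0),
        ])
    solved_arches = ["staple", "protein", "oil_low", "oil_high", "fibreboost"]
    a = np.array([
        [comp[x].get(n, 0.0) / 100.0 for x in solved_arches]
        for n in ("cho", "protein", "fat", "sfa", "fibre")
    ])
    grams, *_ = np.linalg.lstsq(a, targets - fixed, rcond=None)
    grams = np.clip(grams, 0.0, None)

    ingredients = [
        (chosen[x], round(float(g), 2))
        for x, g in zip(solved_arches, grams)
        if g > 0.5
    ]
    if fruit_g > 0.5:
        ingredients.append((chosen["fruitmix"], round(fruit_g, 2)))
    if veg_g > 0.5:
        ingredients.append((chosen["vegmix"], round(veg_g, 2)))
    return ingredients, energy


def _offending_foods(trigger: str, kb: KnowledgeBase) -> list[str]:
    """Default-KB foods violating the trigger's restriction rule(s)."""
    rules = [r for r in kb.restriction_rules if r.trigger == trigger]
    if not rules:
        raise ValueError(f"no restriction rule for trigger {trigger!r}")
    offenders = []
    for fid, food in kb.foods.items():
        if fid.startswith("syn_"):
            continue
        for rule in rules:
            hit = any(
                any(
                    cat in kb.hierarchy.ancestors(ann)
                    for ann, deg in food.categories.items()
                    if deg >= rule.degree_threshold
                )
                for cat in rule.forbidden_categories
            ) or any(
                food.nutrients.get(nut, 0.0) > 0.0
                for nut in rule.forbidden_nutrients
            )
            if hit:
                offenders.append(fid)
                break
    if not offenders:
        raise ValueError(
            f"violation fraction for {trigger!r} unreachable: "
            "no offending food in the knowledge-base pool"
        )
    return sorted(offenders)


def brute_force_violations(meal: Meal, kb: KnowledgeBase) -> set[str]:
    """Triggers violated by a meal, by exhaustive path enumeration.

    Independent of the reasoner: reachability is recomputed here by
    walking child->parent edges, so this can serve as a ground-truth
    oracle for the rejection layer.
    """
    parents: dict[str, set[str]] = {}
    for child, parent in kb.hierarchy.edges():
        parents.setdefault(child, set()).add(parent)

    def reach(cat: str, target: str, seen: frozenset = frozenset()) -> bool:
        if cat == target:
            return True
        return any(
            reach(p, target, seen | {cat})
            for p in parents.get(cat, ())
            if p not in seen
        )

    violated: set[str] = set()
    for rule in kb.restriction_rules:
        for fid, _ in meal.ingredients:
            food = kb.food(fid)
            cat_hit = any(
                deg >= rule.degree_threshold and reach(ann, cat)
                for ann, deg in food.categories.items()
                for cat in rule.forbidden_categories
            )
            nut_hit = any(
                food.nutrients.get(nut, 0.0) > 0.0
                for nut in rule.forbidden_nutrients
            )
            if cat_hit or nut_hit:
                violated.add(rule.trigger)
                break
    return violated


_NOISE_CATEGORIES = (
    "ham", "banana", "tree_nut", "milk", "wheat", "crustacean", "egg",
)


def generate_meal_db(
    spec: MealDBSpec,
    seed: int | None = None,
    kb: KnowledgeBase | None = None,
) -> MealDB:
    """Generate a labelled synthetic meal database.

    Returns the meals, a map of exact truth labels (which restriction
    triggers each meal violates, computed on noise-free annotations by
    path enumeration), the knowledge base the reasoner should consume
    (with annotation noise applied, if any) and the clean one.
    """
    rng = np.random.default_rng(seed)
    base = kb_to_dict(kb or default_kb())

    # extend the KB with the synthetic ingredient pool
    variants = _build_food_pool(rng, spec)
    base["categories"]["synthetic"] = ["food"]
    base["foods"].update(variants)
    pool_ids = {
        arche: sorted(
            fid for fid in variants if fid.startswith(f"syn_{arche}_")
        )
        for arche in _ARCHETYPES
    }
    clean = kb_from_dict(base)

    # richness tags for the configured nutrients are reassigned from
    # scratch so tagged foods sit at/above the concentration percentile
    for nutrient in spec.richness_nutrients:
        amounts = {
            fid: f.nutrients.get(nutrient, 0.0)
            for fid, f in clean.foods.items()
        }
        positive = [v for v in amounts.values() if v > 0]
        if not positive:
            continue
        cut = float(np.percentile(positive, spec.richness_percentile))
        for fid, v in amounts.items():
            clean.foods[fid].rich_in.discard(nutrient)
            if v >= cut and v > 0:
                clean.foods[fid].rich_in.add(nutrient)
    for fid, food in clean.foods.items():
        base["foods"][fid]["rich_in"] = sorted(food.rich_in)

    # slot counts proportional to the mix
    mix_total = sum(spec.slot_mix.values())
    counts = {
        s: int(spec.n_meals * spec.slot_mix.get(s, 0) / mix_total)
        for s in SLOTS
    }
    leftover = spec.n_meals - sum(counts.values())
    for s in SLOTS:
        if leftover <= 0:
            break
        counts[s] += 1
        leftover -= 1

    meals: list[Meal] = []
    for slot in SLOTS:
        for _ in range(counts[slot]):
            ingredients, energy = _solve_meal_grams(
                rng, spec, slot, pool_ids, variants
            )
            mid = f"m{len(meals):05d}"
            meals.append(
                Meal(
                    id=mid,
                    title=f"Synthetic {slot.replace('_', ' ')} {mid}",
                    slot=slot,
                    energy=round(energy, 2),
                    ingredients=ingredients,
                )
            )

    # inject restriction violations (offending default-KB ingredients)
    for trigger in sorted(spec.violation_fractions):
        frac = spec.violation_fractions[trigger]
        n_violate = int(round(frac * len(meals)))
        if n_violate == 0:
            continue
        offenders = _offending_foods(trigger, clean)
        picks = rng.choice(len(meals), size=n_violate, replace=False)
        for mi in picks:
            meal = meals[mi]
            fid = offenders[rng.integers(len(offenders))]
            if fid not in meal.food_ids:
                grams = float(rng.uniform(20.0, 80.0))
                meal.ingredients.append((fid, round(grams, 2)))

    # finalize totals (conservation by construction) and meal energy
    from .meal_store import nutrient_totals_from_ingredients

    for meal in meals:
        meal.nutrients = {
            k: round(v, 6)
            for k, v in nutrient_totals_from_ingredients(meal, clean).items()
        }
        extra = sum(
            grams / 100.0 * (
                4.0 * clean.food(fid).nutrients.get("cho", 0.0)
                + 4.0 * clean.food(fid).nutrients.get("protein", 0.0)
                + 9.0 * clean.food(fid).nutrients.get("fat", 0.0)
            )
            for fid, grams in meal.ingredients
            if not fid.startswith("syn_")
        )
        meal.energy = round(meal.energy + extra, 2)

    # exact truth labels on the clean annotations
    labels = {
        meal.id: sorted(brute_force_violations(meal, clean)) for meal in meals
    }

    # annotation noise: spurious extra category annotations (food level)
    noisy = clean
    if spec.annotation_noise > 0:
        noisy_dict = kb_from_dict(base)  # fresh copy
        for fid in sorted(noisy_dict.foods):
            if rng.random() < spec.annotation_noise:
                cat = _NOISE_CATEGORIES[rng.integers(len(_NOISE_CATEGORIES))]
                noisy_dict.foods[fid].categories.setdefault(cat, 1.0)
        noisy = noisy_dict

    return MealDB(meals=meals, labels=labels, kb=noisy, clean_kb=clean)
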