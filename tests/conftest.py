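import pytest

from mealforge.knowledge_base import default_kb
from mealforge.meal_store import SLOTS, Meal
from mealforge.nutrients import UnitKind
from mealforge.profile_model import (
    Importance,
    NutrientRule,
    RuleSet,
    RuleTables,
    UserProfile,
)


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture(scope="session")
def tables():
    return RuleTables.default()


@pytest.fixture
def healthy_male():
    return UserProfile(sex="M", age=40.0, height=1.75, weight=80.0, pal=1.4)


def make_plan_meals(
    energy_total: float = 1900.0,
    cho: float = 250.0,
    protein: float = 80.0,
    fat: float = 60.0,
    fibre: float = 30.0,
    iron: float = 15.0,
    with_foods: bool = False,
) -> dict[str, Meal]:
    """Six-slot toy plan with the given daily totals, split evenly."""
    meals = {}
    n = len(SLOTS)
    for i, slot in enumerate(SLOTS):
        ingredients = [(f"food_{slot}", 100.0)] if with_foods else []
        meals[slot] = Meal(
            id=f"toy_{i}",
            title=f"Toy {slot}",
            slot=slot,
            energy=energy_total / n,
            ingredients=ingredients,
            nutrients={
                "cho": cho / n,
                "protein": protein / n,
                "fat": fat / n,
                "fibre": fibre / n,
                "iron": iron / n,
            },
        )
    return meals


@pytest.fixture
def toy_plan_meals():
    return make_plan_meals()


def toy_ruleset(energy_target: float = 2000.0) -> RuleSet:
    """Fixed rule table for hand-computed scoring checks."""
    return RuleSet(
        group="TEST",
        sex="A",
        energy_target=energy_target,
        rules=[
            NutrientRule("cho", 35, 55, UnitKind.PERCENT_ENERGY,
                         Importance.ESSENTIAL),
            NutrientRule("protein", 0.8, 1.2, UnitKind.G_PER_KG_BW,
                         Importance.DESIRABLE),
            NutrientRule("fat", 25, 35, UnitKind.PERCENT_ENERGY,
                         Importance.ESSENTIAL),
            NutrientRule("fibre", 25, 35, UnitKind.PER_DAY,
                         Importance.DESIRABLE),
            NutrientRule("iron", 10, 45, UnitKind.PER_DAY,
                         Importance.NON_ESSENTIAL),
        ],
    )


@pytest.fixture
def fixed_ruleset():
    return toy_ruleset()
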