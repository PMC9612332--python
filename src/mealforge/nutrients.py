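"""Nutrient registry, units and rule-unit conversions.

Meal and food compositions are stored in each nutrient's *native* unit
(grams for macronutrients, fibre and the fruit/vegetable mass tallies,
milligrams for iron, gram-equivalent marker amounts for intolerance
markers such as lactose or gluten).  Rule tables express bounds in one of
four unit kinds; :func:`to_rule_units` maps a plan total into the unit of
the rule it is checked against.
"""

from __future__ import annotations

from enum import Enum

#: kcal per gram used to convert macronutrient mass into energy share.
ATWATER_KCAL_PER_G = {"cho": 4.0, "protein": 4.0, "fat": 9.0, "sfa": 9.0}

#: grams of fruit or vegetables per portion.
PORTION_GRAMS = 80.0

#: Macronutrient ids scored in the macronutrient product; every other
#: rule nutrient belongs to the "other dietary components" product.
MACRO_NUTRIENTS = frozenset({"cho", "protein", "fat", "sfa"})

#: Native units for the nutrients used by the shipped tables/KB.
NATIVE_UNITS = {
    "cho": "g",
    "protein": "g",
    "fat": "g",
    "sfa": "g",
    "fibre": "g",
    "fruit": "g",
    "veg": "g",
    "iron": "mg",
    # intolerance / condition markers (amount > 0 triggers a restriction)
    "lactose": "g",
    "gluten": "g",
    "fructose": "g",
    "salicylates": "g",
    "sulfites": "g",
    "amines": "g",
    "caffeine": "g",
    "fodmaps": "g",
    "added_sugar": "g",
}


class UnitKind(str, Enum):
    """Unit in which a nutrient-range rule is expressed."""

    PERCENT_ENERGY = "percent_energy"   # % of the plan's energy intake
    G_PER_KG_BW = "g_per_kg_bw"         # grams per kg body weight per day
    PER_DAY = "per_day"                 # native amount per day
    PORTIONS_PER_DAY = "portions_per_day"  # 80 g portions per day


def to_rule_units(
    amount: float,
    nutrient: str,
    unit_kind: "UnitKind | str",
    *,
    plan_energy_kcal: float,
    body_weight_kg: float,
) -> float:
    """Convert a daily plan total ``amount`` (native units) into rule units.

    ``percent_energy`` uses the plan's own energy intake as the denominator,
    so a plan is judged on the composition it actually delivers.
    """
    kind = UnitKind(unit_kind)
    if kind is UnitKind.PERCENT_ENERGY:
        if nutrient not in ATWATER_KCAL_PER_G:
            raise ValueError(
                f"no energy-conversion factor for nutrient {nutrient!r}"
            )
        if plan_energy_kcal <= 0:
            raise ValueError("plan energy must be positive for %EI rules")
        return amount * ATWATER_KCAL_PER_G[nutrient] / plan_energy_kcal * 100.0
    if kind is UnitKind.G_PER_KG_BW:
        if body_weight_kg <= 0:
            raise ValueError("body weight must be positive for g/kg rules")
        return amount / body_weight_kg
    if kind is UnitKind.PORTIONS_PER_DAY:
        return amount / PORTION_GRAMS
    return amount


def grams_for_percent_energy(
    percent: float, nutrient: str, plan_energy_kcal: float
) -> float:
    """Inverse of the %EI conversion (bounds in %EI -> absolute grams)."""
    return percent / 100.0 * plan_energy_kcal / ATWATER_KCAL_PER_G[nutrient]
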