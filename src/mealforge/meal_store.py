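"""Meal data model, CSV/JSONL readers and writers, plan-name grammar.

The canonical interchange formats are JSON-lines (one meal object per
line) and a documented CSV dialect (UTF-8, comma separated, header row,
with the ``ingredients`` and ``nutrients`` columns carrying compact JSON).
Meals may carry nutrient totals without ingredient composition; when
composition is present the totals must equal the sum of the ingredient
contributions (checked by :func:`check_conservation`).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SLOTS = (
    "breakfast",
    "morning_snack",
    "lunch",
    "afternoon_snack",
    "dinner",
    "supper",
)

GENDER_CODES = ("M", "F", "A")

DIET_CODES = (
    "NA", "Vegetarian", "VegetarianL", "VegetarianO", "Vegan",
    "Pescatarian", "RMA", "Halal", "Kosher",
)


class MealSchemaError(ValueError):
    """Malformed meal record or file."""


@dataclass
class Meal:
    id: str
    title: str
    slot: str
    energy: float                                   # kcal
    ingredients: list[tuple[str, float]] = field(default_factory=list)
    nutrients: dict[str, float] = field(default_factory=dict)
    method: str | None = None

    def __post_init__(self) -> None:
        if self.slot not in SLOTS:
            raise MealSchemaError(
                f"meal {self.id!r}: unknown slot {self.slot!r}"
            )
        if self.energy < 0:
            raise MealSchemaError(f"meal {self.id!r}: negative energy")
        for food_id, grams in self.ingredients:
            if grams < 0:
                raise MealSchemaError(
                    f"meal {self.id!r}: negative quantity for {food_id!r}"
                )

    @property
    def food_ids(self) -> list[str]:
        return [fid for fid, _ in self.ingredients]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "title": self.title,
            "slot": self.slot,
            "energy": self.energy,
            "ingredients": [[fid, grams] for fid, grams in self.ingredients],
            "nutrients": dict(sorted(self.nutrients.items())),
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "Meal":
        missing = {"id", "title", "slot", "energy"} - set(raw)
        if missing:
            raise MealSchemaError(f"meal record missing fields: {sorted(missing)}")
        return cls(
            id=str(raw["id"]),
            title=str(raw["title"]),
            slot=raw["slot"],
            energy=float(raw["energy"]),
            ingredients=[
                (str(fid), float(g)) for fid, g in raw.get("ingredients") or []
            ],
            nutrients={
                k: float(v) for k, v in (raw.get("nutrients") or {}).items()
            },
            method=raw.get("method"),
        )


def nutrient_totals_from_ingredients(meal: Meal, kb) -> dict[str, float]:
    """Sum ingredient contributions (grams/100 x per-100g composition)."""
    totals: dict[str, float] = {}
    for food_id, grams in meal.ingredients:
        food = kb.food(food_id)
        for nut, per100 in food.nutrients.items():
            totals[nut] = totals.get(nut, 0.0) + grams / 100.0 * per100
    return totals


def check_conservation(meal: Meal, kb, rel_tol: float = 1e-6) -> bool:
    """True iff stored nutrient totals match the ingredient sums.

    Meals without ingredient composition vacuously conserve.
    """
    if not meal.ingredients:
        return True
    expected = nutrient_totals_from_ingredients(meal, kb)
    keys = set(expected) | {
        k for k, v in meal.nutrients.items() if v != 0.0
    }
    for key in keys:
        a = meal.nutrients.get(key, 0.0)
        b = expected.get(key, 0.0)
        if abs(a - b) > rel_tol * max(1.0, abs(a), abs(b)):
            return False
    return True


# ---------------------------------------------------------------------------
# Plan-name convention: partner-group-calories-index-gender-diet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanName:
    """Six-field plan name, e.g. ``UoS-C1a-1500-001-F-Vegetarian``."""

    partner: str
    group_code: str
    calories: int
    index: str           # zero-padded, preserved verbatim for round trips
    gender: str
    diet: str

    def __str__(self) -> str:
        return format_plan_name(self)


class PlanNameError(ValueError):
    """Plan name does not match the six-field grammar."""


# both the ASCII hyphen and the en-dash are accepted as field separators
_SEPARATORS = re.compile(r"[-–]")


def parse_plan_name(s: str) -> PlanName:
    fields = _SEPARATORS.split(s)
    if len(fields) != 6:
        raise PlanNameError(
            f"expected 6 hyphen-delimited fields, got {len(fields)}: {s!r}"
        )
    partner, group_code, calories, index, gender, diet = fields
    if not calories.isdigit():
        raise PlanNameError(f"field 3 (calories) is not numeric: {calories!r}")
    if not index.isdigit():
        raise PlanNameError(f"field 4 (index) is not numeric: {index!r}")
    if gender not in GENDER_CODES:
        raise PlanNameError(f"field 5 (gender) unknown: {gender!r}")
    if diet not in DIET_CODES:
        raise PlanNameError(f"field 6 (diet) unknown: {diet!r}")
    return PlanName(partner, group_code, int(calories), index, gender, diet)


def format_plan_name(p: PlanName) -> str:
    return f"{p.partner}-{p.group_code}-{p.calories}-{p.index}-{p.gender}-{p.diet}"


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "title", "slot", "energy", "ingredients", "nutrients", "method"]


def write_meals(meals: list[Meal], path: str | Path, format: str = "jsonl") -> None:
    path = Path(path)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for meal in meals:
                fh.write(json.dumps(meal.to_dict()) + "\n")
    elif format == "csv":
        rows = []
        for meal in meals:
            d = meal.to_dict()
            d["ingredients"] = json.dumps(d["ingredients"])
            d["nutrients"] = json.dumps(d["nutrients"])
            rows.append(d)
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_meals(path: str | Path, format: str | None = None) -> list[Meal]:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        meals = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    meals.append(Meal.from_dict(json.loads(line)))
        return meals
    if format == "csv":
        df = pd.read_csv(path, dtype={"id": str, "title": str})
        missing = {"id", "title", "slot", "energy"} - set(df.columns)
        if missing:
            raise MealSchemaError(f"missing required column(s): {sorted(missing)}")
        meals = []
        for rec in df.to_dict("records"):
            rec["ingredients"] = json.loads(rec.get("ingredients") or "[]")
            rec["nutrients"] = json.loads(rec.get("nutrients") or "{}")
            method = rec.get("method")
            rec["method"] = None if pd.isna(method) else method
            meals.append(Meal.from_dict(rec))
        return meals
    raise ValueError(f"unknown format {format!r}")
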