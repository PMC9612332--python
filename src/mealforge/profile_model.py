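"""User profiles, user-group classification and nutrient-range resolution.

A profile carries physical characteristics (sex, age, height, weight,
physical activity level) plus token sets for dietary choice, intolerances,
deficiencies, allergies, medical conditions and explicit goals.  From it
the package derives BMI, basal metabolic rate, a daily energy target and
the per-user table of nutrient target ranges (the resolved
:class:`RuleSet`) used by the quantitative plan generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

from .nutrients import UnitKind, grams_for_percent_energy

# ---------------------------------------------------------------------------
# Vocabularies (the condition groups a profile may draw tokens from)
# ---------------------------------------------------------------------------

DIET_TOKENS = frozenset({
    "pescatarian", "red_meat_avoider", "vegan", "vegetarian",
    "lactovegetarian", "lacto_ovo_vegetarian", "ovo_vegetarian",
    "halal", "kosher",
})

INTOLERANCE_TOKENS = frozenset({
    "amines", "caffeine", "fodmaps", "fructose", "gluten", "lactose",
    "salicylates", "sulfites",
})

DEFICIENCY_TOKENS = frozenset({
    "calcium", "electrolytes", "folic_acid", "iron", "magnesium",
    "potassium", "sodium", "vitamin_a", "vitamin_b12", "vitamin_c",
    "vitamin_d", "fluid",
})

ALLERGY_TOKENS = frozenset({
    "anise", "avocado", "banana", "celery", "chamomile", "egg", "fish",
    "garlic", "kiwi", "linseed", "lupin", "milk", "mustard",
    "passion_fruit", "peach", "peanut", "pollen", "sesame", "soy",
    "strawberry", "sulfite", "sulfur_dioxide", "tree_nut", "wheat",
    "gluten", "crustacean", "mollusc",
})

MEDICAL_TOKENS = frozenset({
    "angina", "dyslipidemia", "hypertension", "peripheral_artery_disease",
    "myocardial_infarction", "heart_disease", "anemia", "celiac_disease",
    "hypertrophy", "inflammatory_bowel_disease", "kidney_disease",
    "musculoskeletal_problem", "obesity", "previous_stroke",
    "type_2_diabetes", "low_fruit_veg_intake",
})

#: medical tokens counted as cardiovascular disease for group classification
CVD_TOKENS = frozenset({
    "angina", "dyslipidemia", "hypertension", "peripheral_artery_disease",
    "myocardial_infarction", "heart_disease", "previous_stroke",
})


class ProfileError(ValueError):
    """Invalid profile field or unknown vocabulary token."""


class UnsupportedAgeError(ProfileError):
    """Profiles younger than 15 years are out of scope."""


@dataclass
class UserProfile:
    sex: str                      # "M" or "F"
    age: float                    # years
    height: float                 # metres
    weight: float                 # kg body weight
    pal: float = 1.4              # physical activity level
    dietary_choice: str | None = None
    intolerances: set[str] = field(default_factory=set)
    deficiencies: set[str] = field(default_factory=set)
    allergies: set[str] = field(default_factory=set)
    medical_conditions: set[str] = field(default_factory=set)
    explicit_goals: set[str] = field(default_factory=set)
    user_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ProfileError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.age > 0:
            raise ProfileError("age must be positive")
        if not 0.5 < self.height < 2.5:
            raise ProfileError("height (m) must lie in (0.5, 2.5)")
        if not self.weight > 0:
            raise ProfileError("weight must be positive")
        if not self.pal >= 1.0:
            raise ProfileError("PAL must be >= 1.0")
        for name, tokens, vocab in (
            ("intolerance", self.intolerances, INTOLERANCE_TOKENS),
            ("deficiency", self.deficiencies, DEFICIENCY_TOKENS),
            ("allergy", self.allergies, ALLERGY_TOKENS),
            ("medical condition", self.medical_conditions, MEDICAL_TOKENS),
        ):
            unknown = set(tokens) - vocab
            if unknown:
                raise ProfileError(f"unknown {name} token(s): {sorted(unknown)}")
        if self.dietary_choice is not None and self.dietary_choice not in DIET_TOKENS:
            raise ProfileError(f"unknown dietary choice {self.dietary_choice!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def bmi(self) -> float:
        return compute_bmi(self.weight, self.height)

    def active_tokens(self) -> set[str]:
        """Rule-trigger tokens for the knowledge base (prefixed per group)."""
        tokens: set[str] = set()
        if self.dietary_choice:
            tokens.add(self.dietary_choice)
        tokens |= set(self.intolerances)
        tokens |= {f"allergy_{a}" for a in self.allergies}
        tokens |= {f"deficiency_{d}" for d in self.deficiencies}
        tokens |= set(self.medical_conditions)
        return tokens

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "sex": self.sex,
            "age": self.age,
            "height": self.height,
            "weight": self.weight,
            "pal": self.pal,
            "dietary_choice": self.dietary_choice,
            "intolerances": sorted(self.intolerances),
            "deficiencies": sorted(self.deficiencies),
            "allergies": sorted(self.allergies),
            "medical_conditions": sorted(self.medical_conditions),
            "explicit_goals": sorted(self.explicit_goals),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "UserProfile":
        return cls(
            sex=raw["sex"],
            age=float(raw["age"]),
            height=float(raw["height"]),
            weight=float(raw["weight"]),
            pal=float(raw.get("pal", 1.4)),
            dietary_choice=raw.get("dietary_choice"),
            intolerances=set(raw.get("intolerances") or ()),
            deficiencies=set(raw.get("deficiencies") or ()),
            allergies=set(raw.get("allergies") or ()),
            medical_conditions=set(raw.get("medical_conditions") or ()),
            explicit_goals=set(raw.get("explicit_goals") or ()),
            user_id=raw.get("user_id"),
        )


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_m <= 0:
        raise ProfileError("weight and height must be positive")
    return weight_kg / height_m**2


def compute_bmr(profile: UserProfile) -> float:
    """Basal metabolic rate (kcal/day) by the Mifflin–St Jeor equation.

    BMR = 10 W + 6.25 H(cm) - 5 A + s, with s = +5 for males and -161
    for females.
    """
    s = 5.0 if profile.sex == "M" else -161.0
    return (
        10.0 * profile.weight + 6.25 * profile.height * 100.0
        - 5.0 * profile.age + s
    )


# ---------------------------------------------------------------------------
# Group classification
# ---------------------------------------------------------------------------

def classify_group(profile: UserProfile) -> str:
    """Assign one of the ten user groups (A1–A3, B1–B2, C1–C5).

    Age bands bound the A-groups; medical-condition groups (C2 CVD, C3
    type-2 diabetes, C4 iron deficiency, C5 low fruit & vegetables) take
    precedence over the obesity group C1, which takes precedence over the
    B-groups (overweight, athletes).  Profiles under 15 are unsupported.
    """
    if profile.age < 15:
        raise UnsupportedAgeError("profiles younger than 15 y are unsupported")
    if profile.age < 18:
        return "A1"
    if profile.age > 65:
        return "A3"
    conditions = profile.medical_conditions
    if conditions & CVD_TOKENS:
        return "C2"
    if "type_2_diabetes" in conditions:
        return "C3"
    if "anemia" in conditions or "iron" in profile.deficiencies:
        return "C4"
    if "low_fruit_veg_intake" in conditions:
        return "C5"
    if "obesity" in conditions or profile.bmi >= 30.0:
        return "C1"
    if profile.pal >= 1.745:
        return "B2"
    if profile.bmi >= 25.0:
        return "B1"
    return "A2"


# ---------------------------------------------------------------------------
# Nutrient-range rules (the per-user "KT" table)
# ---------------------------------------------------------------------------

class Importance(str, Enum):
    ESSENTIAL = "essential"        # the plan must abide
    DESIRABLE = "desirable"        # the plan should abide
    NON_ESSENTIAL = "non_essential"  # the plan may disregard


@dataclass
class NutrientRule:
    nutrient: str
    lower: float
    upper: float
    unit_kind: UnitKind
    importance: Importance
    bonus: bool = False   # extra-award ("highlighted") range for the group

    def __post_init__(self) -> None:
        self.unit_kind = UnitKind(self.unit_kind)
        self.importance = Importance(self.importance)
        if self.lower > self.upper:
            raise ProfileError(
                f"rule for {self.nutrient!r}: lower bound exceeds upper"
            )

    @property
    def scored(self) -> bool:
        """Whether the rule enters the fitness product (weight w=1)."""
        return self.importance is not Importance.NON_ESSENTIAL

    def absolute_bounds(
        self, *, energy_target_kcal: float, body_weight_kg: float
    ) -> tuple[float, float]:
        """Bounds converted to the nutrient's native daily amount."""
        if self.unit_kind is UnitKind.PERCENT_ENERGY:
            return (
                grams_for_percent_energy(self.lower, self.nutrient, energy_target_kcal),
                grams_for_percent_energy(self.upper, self.nutrient, energy_target_kcal),
            )
        if self.unit_kind is UnitKind.G_PER_KG_BW:
            return self.lower * body_weight_kg, self.upper * body_weight_kg
        if self.unit_kind is UnitKind.PORTIONS_PER_DAY:
            return self.lower * 80.0, self.upper * 80.0
        return self.lower, self.upper


@dataclass
class RuleSet:
    """Resolved nutrient-range table for one user (group x sex)."""

    group: str
    sex: str                      # "M", "F" or "A" (all)
    energy_target: float          # kcal/day
    rules: list[NutrientRule]
    authoritative: bool = True

    def __post_init__(self) -> None:
        if self.energy_target <= 0:
            raise ProfileError("energy target must be positive")
        seen: set[str] = set()
        for rule in self.rules:
            if rule.nutrient in seen:
                raise ProfileError(f"duplicate rule for {rule.nutrient!r}")
            seen.add(rule.nutrient)

    def rule_for(self, nutrient: str) -> NutrientRule | None:
        for rule in self.rules:
            if rule.nutrient == nutrient:
                return rule
        return None


# ---------------------------------------------------------------------------
# Rule-table configuration
# ---------------------------------------------------------------------------

class RuleTableError(ValueError):
    """Missing or malformed rule-table configuration."""


@dataclass
class RuleTables:
    """Per-group, per-sex nutrient rules plus energy adjustment factors."""

    groups: dict          # group -> {"sexes": {sex: [NutrientRule,...]}, ...}

    @classmethod
    def from_dict(cls, raw: dict) -> "RuleTables":
        groups = {}
        for gid, gspec in (raw.get("groups") or {}).items():
            sexes = {}
            for sex, rules in (gspec.get("sexes") or {}).items():
                sexes[sex] = [
                    NutrientRule(
                        nutrient=r["nutrient"],
                        lower=float(r["lower"]),
                        upper=float(r["upper"]),
                        unit_kind=r["unit"],
                        importance=r.get("importance", "desirable"),
                        bonus=bool(r.get("bonus", False)),
                    )
                    for r in rules
                ]
            groups[gid] = {
                "sexes": sexes,
                "energy_adjustment": float(gspec.get("energy_adjustment", 1.0)),
                "authoritative": bool(gspec.get("authoritative", False)),
            }
        return cls(groups=groups)

    @classmethod
    def load(cls, path: str | Path) -> "RuleTables":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "RuleTables":
        return cls.load(Path(__file__).parent / "data" / "rule_tables.yaml")

    def energy_adjustment(self, group: str) -> float:
        try:
            return self.groups[group]["energy_adjustment"]
        except KeyError:
            raise RuleTableError(f"no rule table for group {group!r}") from None


def energy_target(
    profile: UserProfile, tables: RuleTables, group: str | None = None
) -> float:
    """Daily energy target: BMR x PAL x group adjustment factor.

    Weight-management groups carry a deficit factor (default 0.85 for the
    obesity and excess-weight groups) in the table configuration.
    """
    group = group or classify_group(profile)
    return compute_bmr(profile) * profile.pal * tables.energy_adjustment(group)


def resolve_ruleset(
    profile: UserProfile, tables: RuleTables, group: str | None = None
) -> RuleSet:
    """The per-user KT: group/sex-matched rules plus the energy target."""
    group = group or classify_group(profile)
    if group not in tables.groups:
        raise RuleTableError(f"no rule table for group {group!r}")
    sexes = tables.groups[group]["sexes"]
    sex = profile.sex if profile.sex in sexes else "A"
    if sex not in sexes:
        raise RuleTableError(
            f"no rule table for group {group!r} and sex {profile.sex!r}"
        )
    return RuleSet(
        group=group,
        sex=sex,
        energy_target=energy_target(profile, tables, group),
        rules=list(sexes[sex]),
        authoritative=tables.groups[group]["authoritative"],
    )
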