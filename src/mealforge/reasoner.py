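"""Qualitative layer: reject incompatible meals, flag meals to promote.

A meal is rejected for a profile when any ingredient is subsumed by a
restricted category, or carries a restricted nutrient marker at a
positive amount.  Rejection is fail-safe: an unknown ingredient id is a
hard error rather than a silent acceptance, because the layer's contract
is safety.  Promotion is purely qualitative: a meal is flagged when it
contains at least one food tagged rich in a nutrient the profile should
increase — the absolute concentration is not considered here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .knowledge_base import (
    KnowledgeBase,
    is_subsumed,
    promoted_nutrients,
)
from .meal_store import Meal
from .profile_model import UserProfile


@dataclass
class RejectionReason:
    trigger: str          # the profile token whose rule fired
    food_id: str          # offending ingredient
    target: str           # restricted category or nutrient id
    kind: str             # "category" or "nutrient"


@dataclass
class RejectionDecision:
    meal_id: str
    rejected: bool
    reasons: list[RejectionReason] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.rejected == bool(self.reasons)

    def to_dict(self) -> dict:
        return {
            "meal_id": self.meal_id,
            "rejected": self.rejected,
            "reasons": [
                {
                    "trigger": r.trigger,
                    "food_id": r.food_id,
                    "target": r.target,
                    "kind": r.kind,
                }
                for r in self.reasons
            ],
        }


def _active_rules(profile: UserProfile, kb: KnowledgeBase):
    tokens = profile.active_tokens()
    return [rule for rule in kb.restriction_rules if rule.trigger in tokens]


def reject_meal(
    meal: Meal, profile: UserProfile, kb: KnowledgeBase
) -> RejectionDecision:
    """Decide rejection for one meal, listing every firing rule."""
    reasons: list[RejectionReason] = []
    rules = _active_rules(profile, kb)
    for food_id, grams in meal.ingredients:
        food = kb.food(food_id)   # unknown id -> hard error (fail closed)
        for rule in rules:
            for category in sorted(rule.forbidden_categories):
                if is_subsumed(
                    food, category, kb.hierarchy,
                    degree_threshold=rule.degree_threshold,
                ):
                    reasons.append(
                        RejectionReason(rule.trigger, food_id, category, "category")
                    )
            for nutrient in sorted(rule.forbidden_nutrients):
                if food.nutrients.get(nutrient, 0.0) > 0.0:
                    reasons.append(
                        RejectionReason(rule.trigger, food_id, nutrient, "nutrient")
                    )
    return RejectionDecision(meal.id, bool(reasons), reasons)


def filter_meals(
    meals: list[Meal], profile: UserProfile, kb: KnowledgeBase
) -> tuple[list[Meal], list[RejectionDecision]]:
    """First-level filtering: accepted meals (original order) + decisions."""
    decisions = [reject_meal(meal, profile, kb) for meal in meals]
    accepted = [
        meal for meal, dec in zip(meals, decisions) if not dec.rejected
    ]
    return accepted, decisions


def promote_meals(
    meals: list[Meal], profile: UserProfile, kb: KnowledgeBase
) -> set[str]:
    """Meal ids containing >= 1 food tagged rich in a promoted nutrient."""
    wanted = promoted_nutrients(profile, kb)
    if not wanted:
        return set()
    promoted: set[str] = set()
    for meal in meals:
        for food_id, _ in meal.ingredients:
            if kb.food(food_id).rich_in & wanted:
                promoted.add(meal.id)
                break
    return promoted
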