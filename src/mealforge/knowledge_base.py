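"""Food knowledge base: foods, category hierarchy, restriction/promotion rules.

This is the world model of the qualitative layer.  Categories form an
is-a DAG (a food may carry several direct annotations, e.g. turkey ham is
both turkey and ham); restrictions forbid whole category subtrees or
nutrient markers; promotions name nutrients a profile should get more of.
Subsumption is crisp by default, with an optional graded-membership degree
per annotation and a per-rule threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import yaml

logger = logging.getLogger(__name__)


class KnowledgeBaseError(ValueError):
    """Malformed knowledge base (cycles, dangling ids, bad schema)."""


@dataclass
class Food:
    """A simple food usable as a meal ingredient.

    ``nutrients`` holds amounts per 100 g in each nutrient's native unit.
    ``categories`` maps direct category annotations to a membership degree
    in (0, 1]; crisp annotations use degree 1.  ``rich_in`` are qualitative
    richness tags used by meal promotion.
    """

    id: str
    name: str
    categories: dict[str, float] = field(default_factory=dict)
    nutrients: dict[str, float] = field(default_factory=dict)
    rich_in: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for nut, amount in self.nutrients.items():
            if amount < 0:
                raise KnowledgeBaseError(
                    f"food {self.id!r}: negative amount for {nut!r}"
                )
        for cat, degree in self.categories.items():
            if not 0 < degree <= 1:
                raise KnowledgeBaseError(
                    f"food {self.id!r}: degree for {cat!r} outside (0, 1]"
                )


class CategoryHierarchy:
    """Is-a DAG over category ids; edges point child -> parent."""

    def __init__(self, edges: Mapping[str, Iterable[str]] | None = None,
                 nodes: Iterable[str] = ()):  # noqa: D107
        self._g = nx.DiGraph()
        self._g.add_nodes_from(nodes)
        for child, parents in (edges or {}).items():
            for parent in parents:
                self._g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise KnowledgeBaseError(f"category hierarchy has a cycle: {cycle}")
        # reflexive-transitive closure, cached once; hierarchies are small
        self._ancestors = {
            n: {n} | nx.descendants(self._g, n) for n in self._g.nodes
        }

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges)

    def __contains__(self, category: str) -> bool:
        return category in self._g

    def ancestors(self, category: str) -> set[str]:
        """All categories subsuming ``category``, including itself."""
        if category not in self._g:
            raise KnowledgeBaseError(f"unknown category {category!r}")
        return set(self._ancestors[category])


@dataclass
class RestrictionRule:
    """Forbids category subtrees and/or nutrient markers for a trigger token.

    ``degree_threshold`` is the graded-membership cut: an annotation counts
    only if its degree is at or above the threshold (crisp default 1e-9,
    i.e. any positive membership triggers).
    """

    trigger: str
    forbidden_categories: set[str] = field(default_factory=set)
    forbidden_nutrients: set[str] = field(default_factory=set)
    degree_threshold: float = 1e-9

    def __post_init__(self) -> None:
        if not self.forbidden_categories and not self.forbidden_nutrients:
            raise KnowledgeBaseError(
                f"rule for {self.trigger!r} forbids nothing"
            )
        if not 0 < self.degree_threshold <= 1:
            raise KnowledgeBaseError(
                f"rule for {self.trigger!r}: threshold outside (0, 1]"
            )


@dataclass
class PromotionRule:
    """Marks a nutrient to increase for a trigger (condition or goal) token."""

    trigger: str
    nutrient: str


class KnowledgeBase:
    """Foods + hierarchy + declarative restriction/promotion rules."""

    def __init__(
        self,
        hierarchy: CategoryHierarchy,
        foods: Iterable[Food] = (),
        restriction_rules: Iterable[RestrictionRule] = (),
        promotion_rules: Iterable[PromotionRule] = (),
        nutrient_ids: Iterable[str] = (),
    ) -> None:
        self.hierarchy = hierarchy
        self.foods: dict[str, Food] = {}
        for food in foods:
            if food.id in self.foods:
                raise KnowledgeBaseError(f"duplicate food id {food.id!r}")
            for cat in food.categories:
                if cat not in hierarchy:
                    raise KnowledgeBaseError(
                        f"food {food.id!r} annotated with unknown category {cat!r}"
                    )
            self.foods[food.id] = food
        self.restriction_rules = list(restriction_rules)
        self.promotion_rules = list(promotion_rules)
        self.nutrient_ids = set(nutrient_ids)
        for food in self.foods.values():
            self.nutrient_ids |= set(food.nutrients)
        for rule in self.restriction_rules:
            for cat in rule.forbidden_categories:
                if cat not in hierarchy:
                    raise KnowledgeBaseError(
                        f"rule {rule.trigger!r} forbids unknown category {cat!r}"
                    )
        for rule in self.promotion_rules:
            if rule.nutrient not in self.nutrient_ids:
                raise KnowledgeBaseError(
                    f"promotion rule {rule.trigger!r} names unknown "
                    f"nutrient {rule.nutrient!r}"
                )

    # -- queries -----------------------------------------------------------

    def food(self, food_id: str) -> Food:
        try:
            return self.foods[food_id]
        except KeyError:
            raise KnowledgeBaseError(f"unknown food id {food_id!r}") from None


def is_subsumed(
    food: Food,
    category: str,
    hierarchy: CategoryHierarchy,
    *,
    degree_threshold: float = 1e-9,
) -> bool:
    """True iff a direct annotation of ``food`` reaches ``category``.

    Reachability is the reflexive-transitive closure of the is-a DAG, so a
    food annotated ``ham`` is subsumed by ``pork`` when ham is-a pork.
    """
    if category not in hierarchy:
        raise KnowledgeBaseError(f"unknown category {category!r}")
    for cat, degree in food.categories.items():
        if degree >= degree_threshold and category in hierarchy.ancestors(cat):
            return True
    return False


def restricted_categories(profile, kb: KnowledgeBase) -> set[str]:
    """Union of forbidden category/nutrient ids over the profile's triggers.

    Tokens with no matching rule contribute nothing (logged at DEBUG).
    """
    out: set[str] = set()
    triggers = set(profile.active_tokens())
    by_trigger = {}
    for rule in kb.restriction_rules:
        by_trigger.setdefault(rule.trigger, []).append(rule)
    for token in sorted(triggers):
        rules = by_trigger.get(token)
        if not rules:
            logger.debug("profile token %r has no restriction rule", token)
            continue
        for rule in rules:
            out |= rule.forbidden_categories
            out |= rule.forbidden_nutrients
    return out


def promoted_nutrients(profile, kb: KnowledgeBase) -> set[str]:
    """Nutrient ids the profile should increase, per the promotion rules."""
    triggers = set(profile.active_tokens()) | set(profile.explicit_goals)
    return {
        rule.nutrient for rule in kb.promotion_rules if rule.trigger in triggers
    }


# -- file round trip ------------------------------------------------------


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load a YAML/JSON knowledge base file (see the shipped default)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return kb_from_dict(raw)


def kb_from_dict(raw: dict) -> KnowledgeBase:
    if not isinstance(raw, dict):
        raise KnowledgeBaseError("KB file must be a mapping")
    cats = raw.get("categories", {}) or {}
    edges = {
        child: ([parents] if isinstance(parents, str) else list(parents or []))
        for child, parents in cats.items()
    }
    nodes = set(edges)
    for parents in edges.values():
        nodes |= set(parents)
    hierarchy = CategoryHierarchy(edges, nodes)
    foods = []
    for fid, spec in (raw.get("foods", {}) or {}).items():
        cats_field = spec.get("categories", {})
        if isinstance(cats_field, list):
            cats_field = {c: 1.0 for c in cats_field}
        foods.append(
            Food(
                id=fid,
                name=spec.get("name", fid),
                categories={c: float(d) for c, d in cats_field.items()},
                nutrients={
                    k: float(v) for k, v in (spec.get("nutrients") or {}).items()
                },
                rich_in=set(spec.get("rich_in") or ()),
            )
        )
    restrictions = []
    for spec in raw.get("restriction_rules", []) or []:
        restrictions.append(
            RestrictionRule(
                trigger=spec["trigger"],
                forbidden_categories=set(spec.get("categories") or ()),
                forbidden_nutrients=set(spec.get("nutrients") or ()),
                degree_threshold=float(spec.get("degree_threshold", 1e-9)),
            )
        )
    promotions = [
        PromotionRule(trigger=spec["trigger"], nutrient=spec["nutrient"])
        for spec in raw.get("promotion_rules", []) or []
    ]
    return KnowledgeBase(
        hierarchy,
        foods,
        restrictions,
        promotions,
        nutrient_ids=set(raw.get("nutrients") or ()),
    )


def kb_to_dict(kb: KnowledgeBase) -> dict:
    cats: dict[str, list[str]] = {n: [] for n in sorted(kb.hierarchy.nodes)}
    for child, parent in kb.hierarchy.edges():
        cats[child].append(parent)
    return {
        "categories": {c: sorted(ps) for c, ps in cats.items()},
        "nutrients": sorted(kb.nutrient_ids),
        "foods": {
            f.id: {
                "name": f.name,
                "categories": dict(sorted(f.categories.items())),
                "nutrients": dict(sorted(f.nutrients.items())),
                "rich_in": sorted(f.rich_in),
            }
            for f in sorted(kb.foods.values(), key=lambda f: f.id)
        },
        "restriction_rules": [
            {
                "trigger": r.trigger,
                "categories": sorted(r.forbidden_categories),
                "nutrients": sorted(r.forbidden_nutrients),
                "degree_threshold": r.degree_threshold,
            }
            for r in kb.restriction_rules
        ],
        "promotion_rules": [
            {"trigger": r.trigger, "nutrient": r.nutrient}
            for r in kb.promotion_rules
        ],
    }


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(kb_to_dict(kb), fh, sort_keys=False)


def default_kb() -> KnowledgeBase:
    """The shipped default knowledge base.

    A compact reconstruction in the spirit of a full nutrition ontology:
    it covers every profile-vocabulary token with either a restriction/
    promotion rule or an explicit empty contribution, but is not an
    authoritative expert model.
    """
    path = Path(__file__).parent / "data" / "default_kb.yaml"
    return load_kb(path)
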