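"""Reproducible end-to-end experiment runs at configurable scale.

Three experiment kinds mirror the evaluation protocol of the system:

``rejection``
    A labelled synthetic meal database is filtered for a panel of
    restriction-bearing profiles; rejection precision/recall/F are pooled
    over the panel against the exact truth labels.

``capacity``
    A challenging virtual population (each profile has at least one
    medical condition, plus probabilistic diets, intolerances,
    deficiencies and allergies) asks for a daily plan; creation rates
    are reported overall, per condition, and per condition count.

``accuracy``
    A general-population cohort receives a weekly plan each; within-range
    nutrient accuracy, energy agreement (mean % difference, Pearson r,
    paired t-test, Bland–Altman within-limits fraction) and per-slot meal
    variety are computed over all generated daily plans.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .metrics import (
    creation_rate,
    energy_agreement,
    plan_accuracy,
    pool_rejection_metrics,
    rejection_metrics,
    variety_stats,
)
from .plan_engine import ScoringConfig, generate_weekly_plan, pools_by_slot
from .profile_model import RuleTables, UserProfile, classify_group, resolve_ruleset
from .reasoner import filter_meals
from .synthetic_data import (
    MealDB,
    MealDBSpec,
    PopulationSpec,
    accuracy_population_spec,
    capacity_population_spec,
    generate_meal_db,
    generate_users,
    rejection_db_spec,
)

#: restriction-bearing profile panel for the rejection experiment:
#: simple and direct food restrictions, nutrient restrictions, diets,
#: a condition, and a combination — ten profiles in total.
REJECTION_PANEL: tuple[tuple[str, dict], ...] = (
    ("banana+avocado allergy", {"allergies": {"banana", "avocado"}}),
    ("tree nut allergy", {"allergies": {"tree_nut"}}),
    ("egg+peanut allergy", {"allergies": {"egg", "peanut"}}),
    ("crustacean allergy", {"allergies": {"crustacean"}}),
    ("lactose intolerance", {"intolerances": {"lactose"}}),
    ("gluten intolerance", {"intolerances": {"gluten"}}),
    ("fructose intolerance", {"intolerances": {"fructose"}}),
    ("type 2 diabetes", {"medical_conditions": {"type_2_diabetes"}}),
    ("vegan", {"dietary_choice": "vegan"}),
    ("kosher", {"dietary_choice": "kosher"}),
)


def _panel_profile(overrides: dict) -> UserProfile:
    base = dict(sex="M", age=40.0, height=1.75, weight=75.0, pal=1.4)
    base.update(overrides)
    return UserProfile(**base)


def _truth_for_profile(
    profile: UserProfile, db: MealDB
) -> dict[str, bool]:
    """Ground truth: does each meal violate any of the profile's triggers?"""
    triggers = profile.active_tokens()
    return {
        mid: bool(set(labels) & triggers) for mid, labels in db.labels.items()
    }


def run_rejection_experiment(
    n_meals: int = 500,
    noise: float = 0.0,
    seed: int | None = 0,
) -> dict:
    """Filter a labelled DB for the profile panel; pooled rejection metrics."""
    db = generate_meal_db(rejection_db_spec(n_meals, noise), seed=seed)
    per_profile = {}
    pooled_inputs = []
    for name, overrides in REJECTION_PANEL:
        profile = _panel_profile(overrides)
        _, decisions = filter_meals(db.meals, profile, db.kb)
        truth = _truth_for_profile(profile, db)
        m = rejection_metrics(decisions, truth)
        pooled_inputs.append(m)
        per_profile[name] = {
            "precision": m.precision,
            "recall": m.recall,
            "f_measure": m.f_measure,
            "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
        }
    pooled = pool_rejection_metrics(pooled_inputs)
    return {
        "experiment": "rejection",
        "n_meals": n_meals,
        "noise": noise,
        "seed": seed,
        "per_profile": per_profile,
        "pooled": {
            "precision": pooled.precision,
            "recall": pooled.recall,
            "f_measure": pooled.f_measure,
        },
    }


@dataclass
class AccuracyRun:
    """Raw artifacts of the accuracy experiment, for metric computation."""

    profiles: list[UserProfile] = field(default_factory=list)
    rulesets: list = field(default_factory=list)
    weekly: list = field(default_factory=list)      # WeeklyPlanResult per user
    plan_list: list = field(default_factory=list)   # flattened daily plans
    plan_rulesets: list = field(default_factory=list)
    plan_profiles: list = field(default_factory=list)
    plan_energies: list = field(default_factory=list)
    plan_targets: list = field(default_factory=list)


def run_accuracy_collection(
    n_users: int = 100,
    n_days: int = 7,
    seed: int | None = 0,
    db_spec: MealDBSpec | None = None,
    population: PopulationSpec | None = None,
    tables: RuleTables | None = None,
    cfg: ScoringConfig | None = None,
) -> AccuracyRun:
    """Generate population + DB, produce weekly plans, collect raw pairs."""
    ss = np.random.SeedSequence(seed)
    db_seed, user_seed, plan_seed0 = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    ]
    db = generate_meal_db(db_spec or MealDBSpec(n_meals=480), seed=db_seed)
    users = generate_users(
        population or accuracy_population_spec(n_users), seed=user_seed
    )
    tables = tables or RuleTables.default()
    cfg = cfg or ScoringConfig()
    run = AccuracyRun()
    for i, profile in enumerate(users):
        accepted, _ = filter_meals(db.meals, profile, db.kb)
        ruleset = resolve_ruleset(profile, tables)
        result = generate_weekly_plan(
            pools_by_slot(accepted), ruleset, profile, cfg,
            seed=plan_seed0 + i, n_days=n_days,
        )
        run.profiles.append(profile)
        run.rulesets.append(ruleset)
        run.weekly.append(result)
        if result.status in ("ok", "partial"):
            for plan in result.plans:
                run.plan_list.append(plan)
                run.plan_rulesets.append(ruleset)
                run.plan_profiles.append(profile)
                run.plan_energies.append(plan.energy)
                run.plan_targets.append(ruleset.energy_target)
    return run


def run_accuracy_experiment(
    n_users: int = 100,
    n_days: int = 7,
    seed: int | None = 0,
    **kwargs,
) -> dict:
    """Accuracy/energy/variety report over a scaled synthetic cohort."""
    run = run_accuracy_collection(n_users, n_days, seed, **kwargs)
    acc = plan_accuracy(run.plan_list, run.plan_rulesets, run.plan_profiles)
    agreement = energy_agreement(run.plan_energies, run.plan_targets)
    weeks = [
        r.plans for r in run.weekly if r.status in ("ok", "partial")
    ]
    varieties = variety_stats(weeks)
    created = sum(r.status in ("ok", "partial") for r in run.weekly)
    groups = sorted({classify_group(p) for p in run.profiles})
    return {
        "experiment": "accuracy",
        "n_users": n_users,
        "n_days": n_days,
        "seed": seed,
        "groups_present": groups,
        "weekly_creation_rate_pct": 100.0 * created / len(run.weekly),
        "n_daily_plans": len(run.plan_list),
        "accuracy": {
            "macro_pct": acc.macro_pct,
            "other_pct": acc.other_pct,
            "overall_pct": acc.overall_pct,
            "n_macro_checks": acc.n_macro,
            "n_other_checks": acc.n_other,
        },
        "energy": {
            "mean_pct_diff": agreement.mean_pct_diff,
            "sd_pct_diff": agreement.sd_pct_diff,
            "mean_abs_pct_diff": agreement.mean_abs_pct_diff,
            "pearson_r": agreement.pearson_r,
            "t_p_value": agreement.t_p_value,
            "bland_altman_within_pct": agreement.bland_altman_within_pct,
            "n_pairs": agreement.n,
        },
        "variety": varieties,
    }


def run_capacity_experiment(
    n_users: int = 300,
    n_meals: int = 800,
    seed: int | None = 0,
    tables: RuleTables | None = None,
    cfg: ScoringConfig | None = None,
) -> dict:
    """Creation-rate curves for a challenging virtual population."""
    ss = np.random.SeedSequence(seed)
    db_seed, user_seed, plan_seed0 = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    ]
    db = generate_meal_db(rejection_db_spec(n_meals), seed=db_seed)
    users = generate_users(capacity_population_spec(n_users), seed=user_seed)
    tables = tables or RuleTables.default()
    cfg = cfg or ScoringConfig()
    successes = []
    for i, profile in enumerate(users):
        accepted, _ = filter_meals(db.meals, profile, db.kb)
        ruleset = resolve_ruleset(profile, tables)
        result = generate_weekly_plan(
            pools_by_slot(accepted), ruleset, profile, cfg,
            seed=plan_seed0 + i, n_days=1,
        )
        successes.append(result.status in ("ok", "partial"))
    rates = creation_rate(successes, users)
    return {
        "experiment": "capacity",
        "n_users": n_users,
        "n_meals": n_meals,
        "seed": seed,
        "overall_pct": rates.overall_pct,
        "by_condition_at_least_pct": rates.by_condition_at_least_pct,
        "by_condition_count_pct": {
            str(k): v for k, v in rates.by_condition_count_pct.items()
        },
    }


def run_experiment(name: str, seed: int | None = 0, **kwargs) -> dict:
    """Dispatch one of the named experiments; the report embeds the seed
    and a hash of the effective configuration."""
    runners = {
        "rejection": run_rejection_experiment,
        "capacity": run_capacity_experiment,
        "accuracy": run_accuracy_experiment,
    }
    if name not in runners:
        raise ValueError(f"unknown experiment {name!r}")
    report = runners[name](seed=seed, **kwargs)
    config_repr = json.dumps(
        {"name": name, "seed": seed, **{k: str(v) for k, v in kwargs.items()}},
        sort_keys=True,
    )
    report["config_hash"] = hashlib.sha256(config_repr.encode()).hexdigest()[:12]
    return report
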