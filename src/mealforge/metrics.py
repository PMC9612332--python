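"""Evaluation harness: rejection quality, promotion ranking, plan accuracy,
energy agreement (including Bland–Altman limits) and variety statistics.

Rates are returned in [0, 1] for classification metrics and in percent
for the plan-level accuracy and energy-difference statistics, matching
how such results are conventionally tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .meal_store import SLOTS, Meal
from .plan_engine import NutritionalPlan, rule_value
from .profile_model import Importance, RuleSet, UserProfile


# ---------------------------------------------------------------------------
# Rejection precision / recall
# ---------------------------------------------------------------------------

@dataclass
class RejectionMetrics:
    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    fn: int
    tn: int


def rejection_metrics(
    rejected: dict[str, bool] | list,
    truth: dict[str, bool],
) -> RejectionMetrics:
    """Precision/recall/F over rejections against ground-truth violations.

    ``rejected`` maps meal id to the reasoner's decision (or is a list of
    decision objects); ``truth`` maps meal id to whether the meal truly
    violates the profile's restrictions.  A true positive is a rejected
    meal that truly violates.  Empty denominators (nothing rejected /
    nothing to reject) count as perfect, with a warning.
    """
    if not isinstance(rejected, dict):
        rejected = {d.meal_id: d.rejected for d in rejected}
    tp = fp = fn = tn = 0
    for mid, is_violation in truth.items():
        was_rejected = bool(rejected.get(mid, False))
        if was_rejected and is_violation:
            tp += 1
        elif was_rejected:
            fp += 1
        elif is_violation:
            fn += 1
        else:
            tn += 1
    if tp + fp == 0:
        warnings.warn("no rejections made; precision defaults to 1.0")
        precision = 1.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no violations to find; recall defaults to 1.0")
        recall = 1.0
    else:
        recall = tp / (tp + fn)
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return RejectionMetrics(precision, recall, f, tp, fp, fn, tn)


def pool_rejection_metrics(per_profile: list[RejectionMetrics]) -> RejectionMetrics:
    """Pool confusion counts over profiles (micro-average)."""
    tp = sum(m.tp for m in per_profile)
    fp = sum(m.fp for m in per_profile)
    fn = sum(m.fn for m in per_profile)
    tn = sum(m.tn for m in per_profile)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return RejectionMetrics(precision, recall, f, tp, fp, fn, tn)


# ---------------------------------------------------------------------------
# Top-n promotion accuracy
# ---------------------------------------------------------------------------

def topn_promotion_accuracy(
    promoted: set[str],
    meals: list[Meal],
    nutrient: str,
    n: int,
) -> float | None:
    """Fraction of promoted meals among the top-n by absolute nutrient total.

    Meals are ranked by their total amount of ``nutrient`` (ties broken by
    meal id).  Returns ``None`` (reported as NA) when nothing was promoted.
    """
    if not promoted:
        return None
    ranked = sorted(
        meals,
        key=lambda m: (-m.nutrients.get(nutrient, 0.0), m.id),
    )
    top = {m.id for m in ranked[:n]}
    return len(promoted & top) / len(promoted)


# ---------------------------------------------------------------------------
# Plan within-range accuracy
# ---------------------------------------------------------------------------

@dataclass
class PlanAccuracy:
    macro_pct: float | None       # % of macro rule checks within range
    other_pct: float | None       # % of other-dietary-component checks
    overall_pct: float | None
    n_macro: int
    n_other: int


def plan_accuracy(
    plans: list[NutritionalPlan],
    rulesets: list[RuleSet],
    profiles: list[UserProfile],
) -> PlanAccuracy:
    """Within-range accuracy pooled over (plan, rule) checks.

    Each essential or desirable rule of a plan's resolved table is one
    check; the value is the plan's daily total converted to the rule's
    unit.  Macronutrients and other dietary components are reported
    separately; a pool with no applicable rules yields ``None`` (NA).
    """
    from .nutrients import MACRO_NUTRIENTS

    macro_hit = macro_n = other_hit = other_n = 0
    for plan, ruleset, profile in zip(plans, rulesets, profiles):
        for rule in ruleset.rules:
            if rule.importance is Importance.NON_ESSENTIAL:
                continue
            value = rule_value(
                plan.totals.get(rule.nutrient, 0.0),
                rule,
                plan_energy=plan.energy,
                body_weight=profile.weight,
            )
            hit = rule.lower <= value <= rule.upper
            if rule.nutrient in MACRO_NUTRIENTS:
                macro_n += 1
                macro_hit += hit
            else:
                other_n += 1
                other_hit += hit
    macro_pct = 100.0 * macro_hit / macro_n if macro_n else None
    other_pct = 100.0 * other_hit / other_n if other_n else None
    total_n = macro_n + other_n
    overall = (
        100.0 * (macro_hit + other_hit) / total_n if total_n else None
    )
    return PlanAccuracy(macro_pct, other_pct, overall, macro_n, other_n)


# ---------------------------------------------------------------------------
# Energy agreement
# ---------------------------------------------------------------------------

@dataclass
class EnergyAgreement:
    mean_pct_diff: float          # signed mean % difference
    sd_pct_diff: float
    mean_abs_pct_diff: float
    pearson_r: float | None       # None when a distribution is constant
    t_p_value: float | None
    bland_altman_within_pct: float
    n: int


def energy_agreement(
    plan_energies: "np.ndarray | list[float]",
    targets: "np.ndarray | list[float]",
) -> EnergyAgreement:
    """Agreement between recommended and target daily energy intakes.

    Per-pair signed percentage difference (plan − target) / target × 100;
    Pearson correlation and a paired t-test over the raw energies; and the
    Bland–Altman fraction of differences within mean ± 1.96 sd.
    """
    plan_energies = np.asarray(plan_energies, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if plan_energies.shape != targets.shape or plan_energies.ndim != 1:
        raise ValueError("plan energies and targets must be matching 1-d arrays")
    if len(plan_energies) == 0:
        raise ValueError("no pairs to compare")
    diffs = (plan_energies - targets) / targets * 100.0
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    pearson_r = None
    t_p = None
    if len(diffs) > 1:
        if np.std(plan_energies) > 0 and np.std(targets) > 0:
            pearson_r = float(stats.pearsonr(plan_energies, targets).statistic)
        else:
            warnings.warn("constant energy distribution; Pearson r undefined")
        t_p = float(stats.ttest_rel(plan_energies, targets).pvalue)
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((diffs >= lo) & (diffs <= hi)) * 100.0)
    return EnergyAgreement(
        mean_pct_diff=mean,
        sd_pct_diff=sd,
        mean_abs_pct_diff=float(np.mean(np.abs(diffs))),
        pearson_r=pearson_r,
        t_p_value=t_p,
        bland_altman_within_pct=within,
        n=len(diffs),
    )


# ---------------------------------------------------------------------------
# Variety and creation-rate statistics
# ---------------------------------------------------------------------------

def variety_stats(weekly_plans: list[list[NutritionalPlan]]) -> dict:
    """Per-slot distribution of unique meals per week (values in 1..7)."""
    per_slot: dict[str, list[int]] = {s: [] for s in SLOTS}
    for week in weekly_plans:
        for slot in SLOTS:
            per_slot[slot].append(
                len({plan.meals[slot].id for plan in week})
            )
    return {
        slot: {
            "counts": sorted(values),
            "mean": float(np.mean(values)) if values else None,
            "median": float(np.median(values)) if values else None,
        }
        for slot, values in per_slot.items()
    }


@dataclass
class CreationRates:
    overall_pct: float
    by_condition_at_least_pct: dict = field(default_factory=dict)
    by_condition_exact_pct: dict = field(default_factory=dict)
    by_condition_count_pct: dict = field(default_factory=dict)


def creation_rate(
    successes: list[bool], profiles: list[UserProfile]
) -> CreationRates:
    """Plan-creation success curves per condition and per condition count."""
    if len(successes) != len(profiles):
        raise ValueError("successes and profiles must align")
    n = len(successes)
    overall = 100.0 * sum(successes) / n if n else 0.0

    def tokens(p: UserProfile) -> tuple[str, ...]:
        return tuple(sorted(p.active_tokens()))

    at_least: dict[str, list[bool]] = {}
    exact: dict[tuple, list[bool]] = {}
    by_count: dict[int, list[bool]] = {}
    for ok, profile in zip(successes, profiles):
        toks = tokens(profile)
        for tok in toks:
            at_least.setdefault(tok, []).append(ok)
        exact.setdefault(toks, []).append(ok)
        by_count.setdefault(len(toks), []).append(ok)
    return CreationRates(
        overall_pct=overall,
        by_condition_at_least_pct={
            tok: 100.0 * sum(v) / len(v) for tok, v in sorted(at_least.items())
        },
        by_condition_exact_pct={
            ", ".join(k) or "(none)": 100.0 * sum(v) / len(v)
            for k, v in sorted(exact.items())
        },
        by_condition_count_pct={
            k: 100.0 * sum(v) / len(v) for k, v in sorted(by_count.items())
        },
    )


# ---------------------------------------------------------------------------
# Plotting hooks
# ---------------------------------------------------------------------------

def plot_bland_altman(plan_energies, targets, path) -> None:
    """Bland–Altman plot of energy differences, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plan_energies = np.asarray(plan_energies, dtype=float)
    targets = np.asarray(targets, dtype=float)
    diffs = (plan_energies - targets) / targets * 100.0
    means = (plan_energies + targets) / 2.0
    mean = diffs.mean()
    sd = diffs.std(ddof=1) if len(diffs) > 1 else 0.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=8, alpha=0.6)
    ax.axhline(mean, color="k", lw=1)
    for limit in (mean - 1.96 * sd, mean + 1.96 * sd):
        ax.axhline(limit, color="r", lw=1, ls="--")
    ax.set_xlabel("mean of plan and target energy (kcal)")
    ax.set_ylabel("difference (% of target)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_variety_histogram(weekly_plans, path) -> None:
    """Histogram of unique meals per week, one panel per slot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    varieties = variety_stats(weekly_plans)
    fig, axes = plt.subplots(2, 3, figsize=(10, 6), sharey=True)
    for ax, slot in zip(axes.flat, SLOTS):
        ax.hist(
            varieties[slot]["counts"],
            bins=np.arange(0.5, 8.5, 1.0),
            edgecolor="k",
        )
        ax.set_title(slot.replace("_", " "))
        ax.set_xlabel("unique meals / week")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
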