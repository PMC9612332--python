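# mealforge

A knowledge-based recommender for personalised daily and weekly meal
plans, built for nutrition-informatics research on safe, rule-governed
diet recommendation. It targets ten user groups — healthy adolescents,
adults and seniors, athletes, and adults with excess weight, obesity,
cardiovascular disease, type-2 diabetes, iron deficiency, or a diet low
in fruit and vegetables — and separates the problem into two layers that
can be evaluated independently:

1. **A qualitative rule layer** (the safety layer). Foods live in an
   is-a category DAG (ham → pork → red meat → meat); declarative rules
   map profile tokens (allergies, intolerances, diets, medical
   conditions) to forbidden category subtrees or nutrient markers. A
   meal is *rejected* when any ingredient is subsumed by a forbidden
   category or carries a forbidden nutrient marker at a positive amount,
   and *promoted* when it contains a food tagged rich in a nutrient the
   user should increase.

2. **A quantitative plan generator.** A daily nutritional plan (NP)
   fills six slots (breakfast, morning snack, lunch, afternoon snack,
   dinner, supper) from the accepted meals. Candidate slot combinations
   are scored by the multiplicative cost

   ```
   NP_fitness = S_calories × S_macro × S_micro,     S_* = Π_i w_i p_i
   ```

   where `S_calories = |plan energy − target energy|`, the weight
   `w_i` is 1 for essential/desirable nutrient rules and 0 (factor
   dropped) otherwise, and the factor `p_i` is **10** (penalty) when the
   nutrient falls outside its target range, **0.1** (award) when inside,
   and **0.01** (essential award) when inside an essential or
   group-highlighted range. Ranges come from per-group rule tables in
   %EI (Atwater 4/4/9), g/kg body weight, g/day or 80-g portions; the
   energy target is Mifflin–St Jeor BMR × PAL × a group adjustment.
   Weekly plans are post-filtered for variety: repeated foods within a
   day are discouraged through a fitness weight, no meal may appear in
   more than three of the week's plans, and no two days may share an
   identical slot-ordered meal tuple.

Because the expert-validated meal database behind the original study is
not redistributable, the package ships a synthetic-data module that
generates labelled meal databases (with exact ground truth for which
restriction each meal violates) and virtual user populations, so the
full evaluation harness — rejection precision/recall, top-n promotion
accuracy, within-range plan accuracy, energy agreement with Bland–Altman
limits, variety and capacity curves — runs offline and reproducibly.

## Worked example

```python
from mealforge import (
    MealDBSpec, RuleTables, ScoringConfig, UserProfile, classify_group,
    filter_meals, generate_meal_db, generate_weekly_plan, pools_by_slot,
    resolve_ruleset,
)

user = UserProfile(sex="F", age=52, height=1.66, weight=88.0, pal=1.35,
                   medical_conditions={"type_2_diabetes"},
                   intolerances={"lactose"})
db = generate_meal_db(MealDBSpec(n_meals=300), seed=7)
accepted, decisions = filter_meals(db.meals, user, db.kb)
ruleset = resolve_ruleset(user, RuleTables.default())
week = generate_weekly_plan(pools_by_slot(accepted), ruleset, user,
                            ScoringConfig(), seed=11)
```

Output:

```
group: C3
energy target: 2020 kcal/day
accepted meals: 300/300
weekly plan: ok
  day 0:  2020.1 kcal  fitness 2.58e-09  CHO 54.4 %EI  fibre 31.1 g
  day 1:  2019.2 kcal  fitness 7.74e-09  CHO 54.6 %EI  fibre 31.9 g
  day 2:  2020.5 kcal  fitness 2.7e-09   CHO 51.4 %EI  fibre 33.4 g
unique meals/slot: {'breakfast': 7, 'morning_snack': 7, 'lunch': 7,
                    'afternoon_snack': 5, 'dinner': 6, 'supper': 5}
```

The user lands in group C3 (adults with type-2 diabetes), whose table
demands CHO 45 ± 10 %EI (the group's highlighted, extra-award range),
protein 0.8–1.4 g/kg, fat 30 ± 10 %EI, SFA 5–10 %EI, fibre 30–45 g/day
and 2–5 / 3–5 fruit/vegetable portions. Every generated day sits within
about 1 kcal of the 2020 kcal target, keeps CHO and fibre inside the C3
bands (hence the tiny multiplicative fitness values — lower is better),
and the week offers 5–7 distinct meals per slot. This meal database
contains no lactose-bearing meals, so the lactose intolerance removes
nothing here; on databases with labelled violations the same call
rejects every offending meal (see the rejection experiment below).

## Command line

```bash
mealforge synth users --n 100 --seed 1 --out users.json
mealforge synth meals --n 500 --seed 1 --out meals.jsonl --kb-out kb.yaml
mealforge filter --profile profile.json --meals meals.jsonl --kb kb.yaml --out decisions.jsonl
mealforge plan --profile profile.json --meals meals.jsonl --kb kb.yaml --seed 3 --out plan.json
mealforge experiment accuracy --seed 1 --out report.json
```

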