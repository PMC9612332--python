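# Methods

## The two-layer recommendation model

**Qualitative layer.** The knowledge base holds a category hierarchy
(an is-a DAG over food categories; a food may carry several direct
annotations, e.g. turkey ham is annotated both *turkey* and *ham*),
foods with per-100 g composition, restriction rules (profile token →
forbidden category subtrees and/or nutrient markers) and promotion
rules (token → nutrient to increase). Rejection is defined by
subsumption: a meal is rejected for a profile when some ingredient's
annotation reaches a forbidden category in the reflexive-transitive
closure of the DAG, or when an ingredient carries a forbidden nutrient
marker at amount > 0. Intolerances (lactose, gluten, fructose,
salicylates, sulfites, amines, caffeine, FODMAPs) are modelled as
nutrient markers rather than categories, so a lactose-free dairy product
is correctly accepted for a lactose-intolerant user. Annotations carry a
membership degree in (0, 1] with a per-rule threshold; the shipped
knowledge base is crisp (degree 1), since the outcomes being evaluated
are binary accept/reject. Promotion is deliberately qualitative: a meal
is flagged if it contains at least one food *tagged* rich in a promoted
nutrient; absolute concentrations are the quantitative layer's business.
Unknown ingredient ids raise instead of silently passing — the layer's
contract is safety, and the caller decides how to degrade.

**Profiles and rule resolution.** A profile carries sex, age, height,
weight, physical activity level (PAL) and token sets drawn from fixed
vocabularies (9 diets, 8 intolerances, 12 deficiencies, 27 allergies,
16 medical conditions). Group classification is deterministic: under-15
unsupported, 15–18 adolescents (A1), over 65 seniors (A3); otherwise
medical-condition groups take precedence (CVD C2, then type-2 diabetes
C3, then iron deficiency C4, then low fruit & vegetables C5), then
obesity C1 (BMI ≥ 30 or the token), then athletes B2 (PAL ≥ 1.745),
then excess weight B1 (BMI ≥ 25), else healthy adults A2. The priority
of disease groups over the obesity group reflects that profiles pairing
obesity with a disease are evaluated under the disease's rules.

Energy target = BMR × PAL × group adjustment. BMR uses Mifflin–St Jeor
(10 W + 6.25 H[cm] − 5 A + 5 for males, −161 for females) — the study
this package operationalises does not pin a formula, and Mifflin–St Jeor
is the contemporary standard; it is configurable. The adjustment factor
defaults to 0.85 for the weight-management groups (C1, B1) and 1.0
elsewhere, expressing a mild prescribed deficit; it lives in the rule
table file.

Rule tables are per group and sex, one record per nutrient with bounds,
unit kind, importance class (essential / desirable / non-essential) and
a bonus flag for the group's highlighted range (CHO for C3, iron for C4,
fruit & vegetables for C5). Only the C1 and C3 tables transcribe
published expert ranges; the other eight groups are explicitly flagged
non-authoritative placeholders assembled from the same EFSA-style bands
(the table file says so). Two placeholder choices deserve note: the
other-dietary-component rows of C1 and C2 are non-essential, consistent
with those groups reporting no applicable checks in that category; and
the C4 iron band is 10–45 mg/day — at least a reference-intake floor,
capped by the tolerable upper intake level (45 mg/day). An earlier
draft capped iron at 20 mg/day; that was wrong both nutritionally and
structurally (dietary iron scales with food mass, so any high-energy
plan would violate it) and was corrected.

**Quantitative layer.** For a candidate day (one meal per slot):

* `S_calories` = |Σ meal energy − target| (kcal);
* `S_macro` and `S_micro` are products of per-rule factors: 10 when the
  plan's value falls outside the rule's range, 0.1 inside, 0.01 inside
  an essential or bonus range. CHO, protein, fat and SFA form the macro
  product; fibre, fruit, vegetables, iron and any other components form
  the micro product. Values are converted to rule units per plan: %EI
  uses the plan's own energy as denominator (Atwater 4/4/9 kcal/g),
  g/kg divides by body weight, portions divide by 80 g.
* Non-essential rules carry weight 0. Read literally, a zero weight
  would zero the whole product and thus every plan's fitness; the
  package interprets weight 0 as *excluding* the factor. A literal mode
  (`ScoringConfig.literal_weights`) exists for fidelity experiments.
* Variety weighting: with `r` repeated ingredient appearances within the
  day, fitness is multiplied by the award value (0.1) if `r = 0` and by
  `(1 + r)` otherwise. The exact weighting of repeats is an open point
  in the source material; this choice is configurable.

Fitness is a cost; note the degenerate case that a plan exactly at the
energy target has fitness 0 regardless of nutrient factors — with
continuous synthetic energies this is a measure-zero event, and ties are
broken by smaller `S_calories`, then the lexicographic slot-ordered
meal-id tuple, so results are reproducible to the bit.

**Search.** Daily plans: if the slot-pool product has at most
`candidate_budget` (default 2000) combinations, all are scored
(vectorised over numpy arrays); otherwise the seeded RNG samples that
many. After sampling, the best candidate is improved by deterministic
coordinate descent — `refine_sweeps` (default 2) passes in which each
slot in turn is re-optimised against the full pool with the other five
held fixed — started from both the fittest sample and the sample closest
to the energy target. Rationale: the sum of six independent slot draws
concentrates; plain uniform sampling at a scaled-down budget almost
never proposes combinations in the tails of the day-energy distribution,
whereas the original system searched for minutes per plan. Refinement
only ever adds candidates that score strictly better, so when the space
is enumerated exhaustively it is a no-op and the search equals brute
force exactly (asserted in the tests). Generation fails, as a typed
result, when a slot pool is empty, when the best plan still violates an
essential rule, or when the time budget (defaults 165 s/day, 195 s/week,
matching near-real-time service limits) expires.

**Weekly variety filters.** Seven daily searches run on independent
seed-sequence substreams; the ranked candidate lists are kept as
replacement sources. Days are then fixed from the fittest pre-filter
choice downwards; each day takes its best-ranked candidate whose full
slot-ordered meal tuple is new and whose meals stay within three uses
per week, preferring essential-feasible candidates; tiered fallbacks
(drop the essential preference, then the usage cap) are recorded as
relaxation diagnostics rather than raised. The pass is deterministic in
its inputs, hence idempotent. "Sequence of meals" is read as the
full six-slot tuple of one day; a contiguous-subsequence reading across
days is noted as an alternative but not implemented. Filtered selections
are re-scored exactly, and the pre-filter fitness per day is reported
alongside.

## Synthetic data: what it emulates, and what it does not

`generate_users` draws profiles with at most one token per non-medical
condition group from configurable probability tables. Two presets:

* **capacity** — the challenging-profile recipe: diets (pescatarian
  12 %, red-meat avoider 12 %, vegan 16 %, vegetarian 12 %),
  intolerances (FODMAPs 23 %, gluten 19 %, lactose 6 %, salicylates
  7 %), iron deficiency 21 %, allergies (banana 8 %, egg 9 %, peanut
  8 %, tree nut 13 %, crustacean 10 %), and at least one medical
  condition (heart disease 53 % vs type-2 diabetes 47 %) plus obesity
  with probability 65 %.
* **accuracy** — a general adult cohort: ages 20–65, even sex split,
  male height/weight uniform on 1.60–2.00 m / 60–180 kg, female on
  1.50–1.90 m / 40–150 kg, all uniform (the source protocol says
  "normal or uniform" without resolving which per variable; uniform is
  the default, configurable per variable). PAL is not specified anywhere
  upstream; the preset draws U(1.2, 1.7), a sedentary-to-active general
  population, leaving athletes to the capacity preset. Medical
  conditions are assigned so the cohort spreads across groups with
  emphasis on CVD, T2D and obesity.

`generate_meal_db` composes each meal from a pool of synthetic
archetype ingredients (staple, protein source, two oil blends differing
in saturated-fat share, fruit mix, vegetable mix, fibre booster; eight
jittered variants each) by solving a small linear system so the meal
approximately realises drawn targets: slot-specific energy, protein
share U(0.09, 0.22) of energy, fat share U(0.25, 0.30), SFA share
U(0.055, 0.095), CHO as the complement capped at 0.54, fibre density
U(5, 22) g/1000 kcal, and slot-appropriate fruit/vegetable masses.
Negative solutions are clipped and totals are always recomputed from the
final ingredient list, so nutrient conservation (totals = Σ grams/100 ×
per-100 g composition) holds exactly by construction. Slot energy
ranges default to breakfast 180–950, lunch 280–1200, dinner 240–1100
and snacks/supper 50–400 kcal, so day totals span roughly 850–4450 kcal
— wide enough to bracket every energy target the accuracy demographics
can produce (up to ≈ 4100 kcal); a capped preset (slot maxima × 0.6)
deliberately reproduces the infeasibility of > 3000 kcal targets.

Restriction violations are injected by appending an offending ingredient
(found automatically by checking the knowledge base's foods against the
trigger's rule) to a requested fraction of meals; ground-truth labels
are then computed by an independent brute-force path-enumeration checker
over the *clean* annotations, so labels are exact even for cross-trigger
effects (a banana injected for the banana-allergy fraction also carries
fructose and FODMAP markers). Annotation noise adds spurious extra
category annotations at the food level — emulating over-broad food
descriptions (a turkey ham additionally labelled plain ham) — which by
design produces spurious rejections against the clean truth. Richness
tags are reassigned so tagged foods sit at or above the configured
concentration percentile (default 80th).

What the generator does **not** emulate: culinary coherence, real
food-composition covariance (micronutrients beyond iron are carried by
the shipped hand-written foods only), portion-size conventions, cuisine
or cultural structure, and correlated multi-condition comorbidity beyond
the recipes above. Passing evaluations therefore demonstrate that the
pipeline is sound and that the optimizer meets expert ranges *when the
meal supply makes that feasible*; they say nothing about accuracy on a
real expert-curated meal database.

## Evaluation harness

Rejection precision/recall/F are computed over rejections (TP = rejected
and truly violating) and pooled across profiles by summing confusion
counts (micro-average), not by averaging per-profile rates; empty
denominators report 1.0 with a warning. Note one asymmetry: the
upstream narrative attributes annotation-noise errors to recall on the
accepted side, whereas under this definition they surface as rejection
false positives; with zero noise the two views coincide at 1.0/1.0.
Top-n promotion accuracy ranks meals by absolute nutrient total (ties
by meal id) and reports |promoted ∩ top-n| / |promoted| at n ∈ {20, 10,
5, 3}, NA when nothing is promoted. Plan accuracy counts each
(daily plan, essential-or-desirable rule) pair as one check,
per-nutrient-per-day, pooled across users by counting pairs rather than
averaging group means; macronutrients and other dietary components are
reported separately and a pool with no applicable rules reports NA.
Energy agreement uses signed per-pair percentage differences
(plan − target)/target × 100 (the mean absolute difference is reported
alongside), Pearson r and a paired t-test via scipy, and the
Bland–Altman within-limits share (fraction of differences inside
mean ± 1.96 sd, sample sd with ddof = 1). Variety is the number of
unique meals per slot across a week (1–7); creation rate is
successes/attempts overall, per condition ("at least"), per exact
condition set and per condition count.

## Numerical choices and degenerate inputs

* Scoring constants 10 / 0.1 / 0.01 are exact binary-float products of
  small literals; the hand-computed fixtures assert to 1e-12.
* Plan ranking keys are (fitness, S_calories, meal-id tuple) — total
  order, no RNG tie-breaking needed after candidate de-duplication.
* %EI conversion guards against zero plan energy (max(E, 1e-9));
  %EI → grams → %EI round-trips to 1e-9 relative.
* Sampled candidate matrices are de-duplicated (np.unique by row), so
  the effective budget can be slightly below the nominal one.
* All randomness flows from numpy SeedSequence spawns — integer state,
  no time-based seeding; identical seeds give bit-identical plans,
  populations and reports across platforms.
* Scaled problem sizes: the shipped experiments use a 480-meal database
  and 100 users × 7 days for the accuracy run, 500 meals × 10 profiles
  for the rejection run, and 240-meal pools over 50 seeds for the
  variety checks. These are the package's default study sizes; all are
  parameters.

## Known limitations

* The shipped knowledge base is a compact reconstruction, not an expert
  ontology: ~50 foods, one rule per trigger, no compound-food recipe
  decomposition, no fuzzy inference beyond graded membership thresholds.
* Eight of ten rule-table groups are non-authoritative placeholders.
* The optimizer is a sampled search with local refinement, not a global
  optimizer; its optimality guarantee holds only when the combination
  space fits the candidate budget.
* Promotion ranking quality (top-n) depends entirely on how richness
  tags relate to meal-level totals; with tag-dense synthetic pools the
  metric is easy, so it is exercised on constructed fixtures instead.
* Real-user preference learning (ratings), recipe/instruction
  generation, and food-composition database integration are out of
  scope.
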