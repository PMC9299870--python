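# dietpair

Can routinely collected **household consumption and expenditure survey
(HCES)** data stand in for individual **24-hour dietary recall (24HR)** data
when building linear-programming (LP) diet models for 12–23-month-old
children?  `dietpair` implements the full comparison pipeline needed to
answer that question:

1. **AME redistribution** — household food quantities are apportioned to the
   index child by adult-male-equivalents (AMEs).  A member's AME is their
   energy requirement divided by that of an adult male aged 18–29.9 y;
   under-two members are scaled down by the recommended breastmilk energy
   share (67% at 6–8 mo, 55% at 9–11 mo, 39% at 12–23 mo, exclusively
   breastfed below 6 mo).  The child's gram/day intake of food *f* is

   `g(f) = Q(f) · A_c / (Σ_m A_m) / d`

   with `Q(f)` the household quantity over the `d`-day recall and `A` the
   breastmilk-adjusted AMEs.
2. **LP parameter generation** — food lists (foods consumed by ≥ 5% of
   eligible households or children, non-nutritive items excluded, breastmilk
   always included), nearest-rank median portions over consumers,
   consumer-fraction serving limits per food, 10th/90th-percentile weekly
   serving bounds per food subgroup and group, and 50th-percentile group
   goals.
3. **Diet optimization** — module 1 checks parameter feasibility; module 2
   finds the nutritionally best isocaloric diet (maximin share of the 13
   modeled nutrients' RNIs, capped at 100%, within the average food
   pattern); module 3 maximizes/minimizes each nutrient, optionally forcing
   food-based recommendations (FBRs) by raising subgroup serving floors.
4. **FBR selection** — up to eight candidate subgroups (the best nutrient
   sources in the module-2 diet), all 2^k − k − 1 combinations of two or
   more (247 at the cap), scored by how many nutrients the forced minimized
   diets keep at ≥ 65% of the RNI; the highest score with the fewest
   recommendations wins.
5. **Agreement statistics** — overall agreement (matched items / items in
   either arm, or a fixed universe) and eligible agreement (matched items /
   items in both arms), portion-size ratios, and cross-region summaries.

Because real paired surveys are not publicly deposited, the package includes
a first-class **synthetic-data generator**: paired surveys drawn from one
"true" food environment with controllable divergence (questionnaire
coverage, survey windows, recall length, propensity noise, sample sizes).
HCES quantities are generated bottom-up from member-level pseudo-intakes, so
redistribution has an exact truth to recover.  It also bundles, as worked
examples, the regional classification tables from a published four-country
HCES/24HR comparison, which the agreement statistics reproduce exactly.

Intended users: nutrition modelers and survey methodologists evaluating
household data reuse for child diet modeling, and anyone needing a tested,
scriptable Optifood-style LP pipeline.

## Worked example

```python
import dietpair as dp

env = dp.generate_environment(seed=11)                 # shared food truth
knobs = dp.DivergenceKnobs(n_households=300, n_children=300, seed=11)
hces = dp.generate_hces(env, knobs)                    # household arm

params = dp.generate_parameters(hces, env.taxonomy)    # LP inputs
model = dp.DietModel(params, env.fct, mode="within_pattern")
print(model.fit().summary())
```

```
Nutritionally best diet (within_pattern, source=hces)
status: optimal    worst nutrient share t* = 0.626
daily energy: 903 kcal (target 894)

food                         servings/wk    g/day
food_000                            5.36      1.8
...
breastmilk                          7.00    528.3

nutrient            daily    % RNI
fat                 39.71    132.4
calcium            312.79     62.6
...
iron                 7.26     62.6
zinc                 5.25     62.6
```

The worst nutrient reaches 62.6% of its RNI (`t* = 0.626`): calcium, iron,
and zinc cannot reach 100% even in the best diet, so they are the region's
problem nutrients.  Breastmilk is fixed at 7 weekly servings of 528 g/day
(39% of the 894 kcal/day requirement at 0.66 kcal/g).  Continuing,

```python
free = dp.DietModel(params, env.fct, mode="free_pattern")
report = dp.run_fbr_pipeline(model, free)
print(report.assessment.problem_nutrients)  # ['calcium', 'iron', 'zinc']
print(report.final.subgroups, report.final.score)  # ('fish', 'eggs') 10
print(report.residual)                      # ['calcium', 'iron', 'zinc']
```

selects the smallest FBR set holding 10 of 13 nutrients at ≥ 65% RNI; the
three problem nutrients remain inadequate, as their classification implies.

The full paired comparison (both arms, agreement statistics, regional
summary) is one call or one command:

```bash
dietpair run --seed 7 --out runs/demo          # writes comparison_report.json
```

## Layout

```
src/dietpair/
  core.py       domain types, references, CSV/YAML I/O, validation
  ame.py        lactation inference, AMEs, redistribution, breastmilk portion
  params.py     survey -> LP model parameters
  lp.py         DietModel/DietResults over scipy's HiGHS solver (modules 1-3)
  fbr.py        problem nutrients, good sources, FBR enumeration/selection
  agreement.py  agreement statistics + bundled regional tables
  synth.py      food environments and paired synthetic surveys
  workflow.py   end-to-end runs and comparison reports
  cli.py        `dietpair` command-line interface
docs/methods.md   model, assumptions, parameters, limitations
```
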