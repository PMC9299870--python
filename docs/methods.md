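# Methods

This note documents the models and procedures implemented in `dietpair`,
the assumptions behind them, the tunable parameters and their defaults, what
the synthetic-data generator does and does not emulate, and the numerical
choices that matter for reproducing results.

## Scope and populations

The pipeline targets 12–23-month-old breastfed children.  Two survey types
feed it: household consumption and expenditure surveys (HCES), which record
household-level food quantities over a 7- or 14-day recall from a closed
questionnaire, and individual quantitative 24-hour recalls (24HR), which
record one-day child-level intakes.  Thirteen nutrients are modeled (fat,
protein, calcium, iron, zinc, niacin, riboflavin, thiamin, vitamins A, B6,
B12, C, and folate); energy is handled as an isocaloric constraint, not a
goal.  Iron and zinc references assume low bioavailability, appropriate for
diets low in animal-source foods.

## AME redistribution

Each household member's adult-male-equivalent (AME) is their estimated
energy requirement (EER, by age band, sex, and pregnancy/lactation status)
divided by the EER of an adult male aged 18–29.9 years.  Age bands are
half-open `[lo, hi)` intervals in months throughout, which keeps the
under-two boundary unambiguous.  Members under 24 months are assumed
breastfed, so their AME is multiplied by one minus the recommended
breastmilk energy share for their band: ×0.33 at 6–8 months, ×0.45 at 9–11
months, ×0.61 at 12–23 months, and ×0 below 6 months (exclusive
breastfeeding — no household food).  The index child's estimated intake of a
food is the household quantity times the child's share of the household's
total adjusted AME, divided by the recall days.  Member-wise shares sum to
one, so redistribution conserves mass exactly; this is tested to 1e-9
relative on 1,000 synthetic households.

Design choices where the procedure was genuinely open:

* **Lactation inference fills unknowns only.**  A non-pregnant woman of
  unrecorded status is assumed lactating iff an under-24-month child lives
  in the household; an explicit recorded "no" is never overridden.
* **All under-two members are breastmilk-adjusted**, not only the index
  child.  The exclusive-breastfeeding and breastfed-under-two assumptions
  apply to every such member; a config switch (`adjust_all_under2=False`)
  restricts the adjustment to 12–23-month-olds for sensitivity analyses.
* **Pregnancy/lactation increments are additive kcal/day entries** in the
  EER table (defaults +285 and +505), so alternative references drop in via
  `references.yaml` without code changes.
* The shipped EER and RNI defaults are placeholders in the spirit of the
  FAO/WHO references (adult male 18–29.9 y: 2,800 kcal/day; 12–23 mo: 894
  kcal/day; iron 11.6 mg and zinc 8.4 mg/day at low bioavailability).  Any
  serious application should supply its own `references.yaml`; every value
  is config, none is hard-coded in the pipeline.

## LP parameter generation

* **Food list**: foods consumed by ≥ `food_list_threshold` (default 5%) of
  eligible households (HCES; households containing a 12–23-month-old child,
  widenable to under-five households for small samples) or of children
  (24HR).  Non-nutritive items (water, tea, condiments) are excluded from
  both arms; items not typically consumed by young children (e.g. alcoholic
  drinks) are additionally excluded from HCES lists, since a household-level
  instrument cannot distinguish who consumed them.  Breastmilk is always
  included, with a fixed 7 servings/week.
* **Portions**: nearest-rank median daily grams over each food's consumers
  (zeros excluded).  The breastmilk portion is the energy requirement times
  the band's breastmilk share divided by 0.66 kcal/g (528 g/day at 894
  kcal).
* **Serving limits per food** come from an ordered consumer-fraction step
  table (default: <10% → 0–1 servings/week, 10–25% → 0–3, 25–50% → 0–5,
  50–75% → 0–7, ≥75% → 1–14; half-open tiers, boundary to the upper tier).
  This default is an explicit placeholder policy — the mapping used in
  published practice is external to the sources reimplemented here — and is
  fully configurable.
* **Subgroup/group bounds and goals**: nearest-rank 10th/90th percentiles
  of weekly servings over all children (non-consumers as zeros;
  configurable), and 50th-percentile group goals.  Nearest-rank (value at
  position `ceil(p/100·n)` of the ascending sort) is used everywhere —
  deterministic on small n, no interpolation convention to argue about.

HCES and 24HR parameter generation share every code path except the
consumer-fraction denominator and the grams-per-week derivation (household
quantities are redistributed first; child daily intakes are scaled ×7).

## Diet LP (modules 1–3)

Decision variables are continuous weekly servings per food (fractional
servings are standard LP practice at this level of aggregation).  All
solves use `scipy.optimize.linprog` with the HiGHS solver, a fixed variable
order, and default tolerances; objective values reproduce to well below
1e-7 across runs.

* **Energy** is constrained to ±`energy_tolerance` (default 1%) of the
  child's requirement rather than to exact equality, which is numerically
  brittle.
* **Module 1** solves min/max achievable daily energy under all non-energy
  constraints and reports infeasibility diagnostics by name (inverted
  bounds, subgroup minima exceeding the sum of member maxima, unreachable
  energy windows).
* **Module 2** ("nutritionally best" diet) is a three-stage lexicographic
  solve: (1) within-pattern only, minimize the maximum absolute deviation
  of group servings from the group goals, then cap deviations at the
  optimum (goal programming — hard equality to goals is frequently
  infeasible against the percentile bounds); (2) maximize the worst
  nutrient's share of its RNI, capped at 100%; (3) holding that maximin
  value, maximize the sum of capped shares.  This objective is a
  reconstruction of "nutritionally best" as used in diet-optimization
  practice; equivalence with any released software is not claimed.
* **Module 3** maximizes/minimizes one nutrient under the percentile-bound
  pattern (free-pattern mode).  FBRs are forced by raising the chosen
  subgroups' lower bounds to their upper bounds.  Degenerate ties between
  optimal vertices are resolved by the solver; downstream good-source
  classifications therefore carry a ±1-subgroup sensitivity at exact-tie
  thresholds, which the 1e-12 slack on the 5% source cut makes explicit.

Problem nutrients are those whose maximized diet content is strictly below
100% of the RNI (exactly 100% is adequate).  Minimized diets at or above
65% of the RNI are considered acceptable low-tail intakes.

## FBR selection

Candidate FBRs are the food subgroups supplying ≥ `source_threshold`
(default 5%) of at least one nutrient in the module-2 diet, ranked by the
number of such nutrients (ties: total summed share, then label).
Breastmilk is excluded — it is fixed at 7 servings/week in every diet, so
forcing it is vacuous.  Up to `max_fbr_candidates` (default 8) are kept;
the count universe defaults to all 13 nutrients and is configurable.  All
subsets of size ≥ 2 are evaluated (2^k − k − 1 sets; singletons are
excluded, consistent with the 247-set convention at eight candidates).
Infeasible forced sets are recorded and skipped, not fatal, because
raising several subgroup floors can conflict with the energy window.  The
final set maximizes the count of nutrients with minimized content ≥ 65%
RNI, using the fewest recommendations; exact ties break by summed
minimized %RNI, then lexicographically — every selection is deterministic.

## Agreement statistics

Overall agreement divides matched items by the items present in either arm
(or a fixed universe — the 13 nutrients for problem-nutrient status);
eligible agreement divides by the items present in both arms.  In overall
mode an item absent from one arm carries the negative status, so
"absent" versus "present but negative" counts as a match; this convention
reproduces the bundled regional tables' matched counts exactly.
Percentages are computed in full precision and rounded half-up to one
decimal; integer rounding is applied only for summary means.  Portion
agreement uses per-food ratios of maximum modeled weekly grams (maximum
weekly servings × portion), with a nearest-rank median and a share-within-
band summary.  The bundled tables' mean problem-nutrient agreement computes
to 92.3%; the package always reports computed means.

## Synthetic data: what it emulates, what it does not

The generator draws paired surveys from one fixed food environment: per
food, a subgroup/group assignment, household and child consumption
propensities, seasonal availability months, a log-normal portion
distribution (adult scale, truncated at 3σ to keep percentiles stable), and
a composition sampled from per-group nutrient ranges.  Household rosters
come from seven template compositions (sizes 2–8) with one guaranteed
12–23-month-old and siblings covering every AME branch.  HCES quantities
are built bottom-up — member pseudo-intakes proportional to adjusted AMEs,
summed over the recall period — so the redistribution stage has an exact
per-child truth to recover.

Divergence knobs control questionnaire coverage, the two survey windows,
recall length (7/14 days), propensity noise, and sample sizes.  At zero
divergence both arms measure the same truth, and the food-list agreement
recovers 100% in ≥95 of 100 replicates at n = 500/500.  Default propensities
are drawn from a rare/common mixture (0.4–2.5% and 10–90%) that leaves the
neighbourhood of the 5% food-list threshold empty; with propensities near
the cut, binomial sampling alone makes list membership unstable at realistic
sample sizes, which is a property of the threshold rule, not of the
generator.  No quantitative divergence magnitudes are published for real
survey pairs, so the knob defaults are qualitative: they reproduce the
observed direction of effects (HCES lists growing relative to 24HR lists as
coverage and windows diverge), not calibrated magnitudes.

The generator deliberately does not emulate: intra-household favoritism or
plate waste, food away from home, recipe disaggregation of composite
dishes, expenditure/price modules, or correlated day-to-day intake within
children.  Passing recovery tests therefore show that the pipeline's
arithmetic and classification rules are correct under the stated sampling
model — not that real HCES data are unbiased for child intakes.

## Problem sizes and runtimes

Default runs use 40-food environments, 300 households and 300 children per
region, and two regions; an end-to-end run takes a few seconds on one CPU,
and the full test suite (including the 200-problem LP oracle sweep and the
100-replicate recovery check) runs in under a minute.  The LP oracle suite
compares the solver against a dense 0.05-step grid search on a random
problem family constructed so that every optimal vertex provably lies on
the grid (integer box bounds, energy coefficients dividing 100, window
bounds on multiples of 5), plus an exact vertex-enumeration oracle for
problems with binding subgroup constraints that the grid family avoids.

## Known limitations

* The module-2 objective and the food-level serving-limit policy are
  documented reconstructions/placeholders, not reproductions of any
  proprietary implementation.
* Shipped EER/RNI defaults are placeholders; conclusions about real
  populations require real reference tables and composition data.
* Agreement statistics are descriptive; no chance-corrected coefficients or
  confidence intervals are computed.
* Module-4-style cost optimization is out of scope.
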