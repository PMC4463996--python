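# Methods

## Scope and data model

The package estimates food-group and nutrient intakes from FFQ-style
records, screens implausible reporters, scores each diet with an
11-component modified HEIFA (0–100), and reproduces standard cohort
analytics. It deliberately does not model any particular proprietary FFQ
instrument: a generic composition-table schema (per-item group/subgroup,
serve size, per-100 g nutrients) replaces the instrument's nutrient engine,
and weekly sugar-sweetened-beverage volume is a separate single-item field
that is never derived from FFQ items and contributes beverage volume but no
energy — it sits outside the nutrient engine by design.

Energy conversion uses the food-standards Atwater-style factors protein
17 kJ/g, fat 37 kJ/g, carbohydrate 16.7 kJ/g, alcohol 29 kJ/g, and
1 kcal = 4.184 kJ. The factors are config-exposed because published analyses
rarely state their factor set. A composition row is rejected when its energy
column deviates more than 10 % from the macronutrient-derived value, when the
fat split exceeds total fat, or when sugars + starch exceed carbohydrate
(tolerance 1e-6 throughout). Liquids are stored in grams; per-item density
converts millilitres.

## Misreporter screen

BMR comes from the weight-only Schofield equations (MJ/day): male 18–29
`0.063·w + 2.896`, male 30–59 `0.048·w + 3.653`, female 18–29
`0.062·w + 2.036`, female 30–59 `0.034·w + 3.538`. Age bands are half-open
([18, 30), [30, 60)), so age 30 falls in the older band; ages below 18 are
an error rather than an extrapolation. The screen excludes records with
EI/BMR < 0.5 (under-reporting) or > 2.0 (over-reporting); the boundaries
themselves are retained because the cuts are strict. Incompleteness is
checked first, so an incomplete record with implausible energy is logged as
incomplete. EI is converted kcal → kJ → MJ before the ratio; the choice of
unit is irrelevant as long as it is consistent, and the fixed (not
physical-activity-adjusted) cut-offs are intentional.

## Scoring rubric

Component structure: nine components out of 10 (vegetables, fruit, grains,
meat and alternatives, dairy and alternatives, discretionary foods,
saturated fat, sodium, total sugars) and two out of 5 (water, alcohol),
summing to 100. Sub-score splits and defaults:

| component | sub-scores | default targets / cuts |
|---|---|---|
| vegetables | 5 quantity + 5 variety | targets M 6 / F 5 serves/day; subgroups green, orange, legumes, starchy, other at 1 pt each |
| fruit | 5 quantity + 5 variety | target 2 serves/day; subgroups pome, citrus, berries, stone, tropical |
| grains | 5 quantity + 5 wholegrain | target 6 serves/day; full wholegrain credit at proportion ≥ 0.5 ("mostly wholegrain") |
| meat & alternatives | 10 quantity | targets M 3 / F 2.5; over-consumption not penalised |
| dairy & alternatives | 5 quantity + 5 low-fat | target 2.5; full low-fat credit at proportion ≥ 0.5 |
| discretionary | moderation on %E | full ≤ 20 %E, zero ≥ 60 %E |
| saturated fat | moderation on %E | full ≤ 10 %E, zero ≥ 15 %E |
| total sugars | moderation on %E | full ≤ 15 %E, zero ≥ 30 %E |
| sodium | moderation on mg/day | full ≤ 2300, zero ≥ 4600 |
| alcohol | moderation on g/day ethanol | full ≤ 20, zero ≥ 40 |
| water | proportion of beverage volume | full credit at ≥ 0.5 |

Quantity sub-scores are prorated (`max · min(serves/target, 1)`) with no
penalty above target; moderation components are linear between their cuts.
Serves are grams divided by the per-item serve size, summed per group; a
variety subgroup counts once it supplies ≥ 1 serve/week. The quantity
targets follow the 2013 Australian Guide to Healthy Eating adult
recommendations; the moderation cut-offs adopt the published dietary
recommendations where one exists (saturated fat < 10 %E, sugars < 15 %E,
sodium 2300 mg, discretionary 20 %E) with zero-score cuts at twice (or 1.5×
for saturated fat) the full-score cut. The exact cut-off table of the
original index is not public, so every number is a documented,
config-overridable default rather than a claim of equivalence — scores from
different cut-off sets are not comparable and the config travels with the
results.

"Met guideline" flags: quantity criterion met for the five food groups
(serves ≥ target), value ≤ full cut for moderation components, proportion at
full credit for water.

Degenerate inputs: a zero-energy record cannot have %E quantities; all five
moderation components score 0, the record is flagged, and no NaN propagates.
A record with no beverages at all has water proportion 0. Scoring is
invariant to the order of input rows and linear in amounts, which the tests
exercise as properties, plus a two-implementation agreement check against an
independently coded straight-line evaluator of the same rubric.

## Cohort statistics

Quartiles are a rank-based split (stable ties, lower quartiles absorb the
remainder, Q1 = least consistent with the guidelines). The linear trend of a
variable across quartiles is the slope *t* test from OLS on the quartile
index 1–4, which handles unequal group sizes; the balanced orthogonal linear
contrast (−3, −1, 1, 3) with the within-group ANOVA error term is retained
as a secondary route and is proportional to the slope on balanced data.
Gender comparisons use a Welch *t* test by default (pooled-variance
optional) and a Pearson chi-square without continuity correction (correction
optional) on met/not-met 2×2 tables; a zero margin returns (0, 1).
Behaviour associations are simple one-predictor OLS regressions of the total
score on weekly SSB millilitres and on the takeaway category coded 0–3.
No multiple-testing adjustment is applied. Reference comparisons are
side-by-side means against fixed survey constants with no inferential test;
the constants are labelled with their source and never recomputed.

## Synthetic cohorts

The generator emulates a young-adult (18–35), mostly overweight cohort:
female fraction 141/230, BMI lognormal with natural-scale mean 27.2 and SD
2.5 kg/m², heights normal by sex, weight derived from BMI. Food-group
intakes are lognormal — dietary intakes are right-skewed and nonnegative —
with sex-specific arithmetic means defaulting to the study population's
printed group means (e.g. vegetables M 119.8 / F 115.0 g/day) and geometric
SDs back-derived from the printed coefficients of variation (≈1.6–2.5 by
group). The lognormal is mean-parametrized (`mu = ln(mean) − sigma²/2`, with
the propensity loading mean-corrected the same way) so the configured value
is recovered as the sample mean.

A latent standard-normal diet-quality propensity per participant
multiplies core groups up (loadings 0.35 for vegetables/fruit down to 0.05
for dairy) and discretionary/alcohol down, shifts the wholegrain and low-fat
logit shares, reduces log-SSB volume (default slope −0.5), and lowers
takeaway frequency through an ordered logit (slope −1.2) whose cut-points
reproduce the observed category frequencies (≈41 / 46 / 13 / <1 %). A
configurable misreporter fraction (default 15/245) rescales a participant's
amounts to land EI/BMR in (0, 0.4] or [2.1, 3.0], exercising both exclusion
tails; a small incomplete fraction (default 2/250) blanks the takeaway
response. All randomness flows from `numpy.random.default_rng` (PCG64), so a
fixed seed reproduces a cohort bit-for-bit on any platform.

What the generator does **not** emulate: item-level correlation structure
within a food group beyond shared group totals (Dirichlet splits), seasonal
or day-to-day variance, selective under-reporting of socially undesirable
foods, and the sparse variety patterns of real FFQ data — every simulated
participant eats from all subgroups, so variety sub-scores (and hence mean
totals) run well above field values. Passing tests on synthetic cohorts
therefore demonstrate that the pipeline recovers structure it is pointed at,
not that real cohorts would score in any particular range. Because the
group spreads are realistic, a natural EI/BMR tail of a few percent exists
on top of the injected misreporters — as it does in real cohorts — and the
recovered exclusion fraction is compared with the configured one at a
3-binomial-SE band.

Two deterministic archetypes pin the scoring endpoints. `perfect` allocates
the quantity target of each group across every variety subgroup, uses only
wholegrain grains and low-fat dairy, and then, because fruit and dairy
sugars can push total sugars past the %E full cut even in a fully compliant
diet, adds extra serves of the lowest-sugar-density compliant foods
(over-consumption is never penalised) until every moderation value sits at
or below its full cut; it scores exactly 100. `null` holds no core foods and
no water, clears every zero cut with a deterministic greedy recipe (an
alcohol item scaled past the ethanol cut, saturated-fat and sugar specialist
items grown to a %E fixed point, then a global scale for the absolute sodium
cut) and scores exactly 0. Both constructions verify their post-conditions
and raise an explicit error when a configured target is unreachable with the
provided items.

## Problem sizes and numerical choices

Simulated checks use n = 230 (the emulated cohort size) for recovery of the
misreport fraction and the behaviour slopes, n = 2000 for group-mean
recovery at 3 simulation SEs, 10⁴ random diets for score bounds/additivity
fuzzing, and 50 balanced datasets for the trend-test oracle; these sizes
make each property decisive at the stated tolerance while keeping the suite
fast. Score identities are asserted to 1e-9, I/O round-trips to 1e-9,
closed-form statistical oracles to 1e-6. Ties in quartile assignment break
by stable input order; `float` arithmetic follows numpy defaults with no
custom rounding anywhere in the rubric.

## Known limitations

* The rubric's cut-offs are defensible defaults, not a certified replica of
  any published index appendix; absolute scores are only comparable under a
  shared config.
* Sodium and fiber from FFQ composition tables under-estimate true intake
  (no discretionary salt; limited item lists); the screen and score inherit
  that bias from their inputs.
* The EI/BMR screen uses fixed cuts, not activity-adjusted Goldberg limits.
* `compare_to_reference` is descriptive only; survey constants carry no
  sampling error here.
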