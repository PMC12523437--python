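# Methods

This note documents the models, conventions and design choices behind
`healthyplate`: what each stage computes, the assumptions it rests on, and
what the synthetic-data validation does and does not demonstrate.

## The plate model and sector geometry

The package treats a four-sector plate graphic (protein, grain, vegetable,
fruit) as a literal serving template across plates of 17, 20, 23, 26, 29 and
32 cm diameter, with 17 cm as the reference size.  Under the instruction to
fill each sector evenly without piling or compacting, served weight should be
proportional to sector area, so the expected weight on diameter *d* given a
reference serving *w*ref is

    E[w(d)] = w_ref · (d / d_ref)²

The sector's angular fraction cancels in the ratio, so the extrapolation is
identical for every food group and no volumetric correction is applied
(constant pile height is an assumption, not a measurement).  Default sector
fractions — vegetables 0.30, fruit 0.20, grains 0.25, protein 0.25 — follow
the visual proportions of the plate graphic (half the plate for produce) and
are configurable, since published plate graphics rarely state angles;
`sector_area` is exposed for workflows that need absolute areas.

**Serving bias** per food and diameter is the percent deviation of observed
from expected weight, positive for over-serving.  Two estimators are
provided:

- `per_participant` (default): each participant's own 17 cm serving is their
  reference — participants fill the smallest plate first, so this matches the
  data-generating order.  Per-record observed/expected ratios are averaged
  **on the log scale** (geometric mean).  The arithmetic mean of ratios is
  systematically inflated because the participant's noisy reference serving
  sits in every denominator: for multiplicative noise ε with mean 1 and
  coefficient of variation c, E[1/ε] = 1 + c², i.e. about +6 points of
  spurious bias at c = 0.25.  The geometric mean is free of this distortion
  under log-normal noise and recovers injected slopes consistently.
- `pooled`: the across-participant mean reference weight is extrapolated and
  compared with the across-participant mean observed weight; provided as a
  sensitivity analysis and for incomplete panels.

Bias at the reference diameter is pinned to exactly 0.

## Serving simulation

The generator draws, for participant *i*, food *f*, diameter *d*:

    w = w_ref_f · (d/d_ref)² · (1 + b_f · s(d)) · ε_{i,f,d}

- `b_f` — fractional bias reached at the largest diameter, |b| ≤ 1.  The ramp
  s(d) rises linearly from 0 at the reference to 1 at the largest diameter:
  observed bias gradients look monotone across plate sizes but no functional
  form is established, so linearity is the minimal recoverable assumption.
- `ε` — multiplicative log-normal noise with mean 1 and CV `c_f`
  (σ² = ln(1+c²), μ = −σ²/2).  Log-normal keeps weights strictly positive and
  is parameterised directly by the CV; a truncated normal was rejected
  because truncation would distort the very CV the model is supposed to
  inject.  Draws are independent across diameters — whether real participants
  anchor on their own earlier servings is unknown, so no within-participant
  correlation beyond the shared reference is modelled.
- Defaults span the empirically observed ranges: bias slopes from about
  −0.10 (foods like leaf salad that under-fill large plates) to +0.30 and
  beyond (fruit pieces), CVs from a few percent to ~0.50.

Seeding: one master seed; every (participant, food) pair gets its own
`numpy` `SeedSequence` sub-stream, so output is byte-identical under a fixed
seed and adding foods or participants never perturbs existing draws.

A separate null generator (`generate_null_servings`) draws i.i.d. log-normal
weights with **no** food or size structure.  It exists because the main
generator's area scaling makes plate size a genuine effect on raw weight —
a "b = 0" simulation is not a null for the size term — and significance-test
calibration needs a model where every term is truly absent.

## Variability statistics

The CV table uses the sample standard deviation (n−1 denominator; the
plain "SD/mean × 100" definition leaves this open) per (food, diameter)
cell; cells with fewer than two observations are marked undefined rather
than zero.

The two-factor model is an ordinary fixed-effects linear model
`weight ~ food * size` with both factors categorical, fit by OLS
(statsmodels) under **sum-to-zero contrasts**, the convention under which
Type III sums of squares are well-defined; each term's SS is its marginal
contribution given all other terms.  The response can be raw weight or the
per-participant percent bias (which removes the dominant area-scaling
component of the size effect).  Residual diagnostics (mean, SD, skewness,
kurtosis) are reported in the JSON output but never gate the computation —
the model is used descriptively, and the Monte-Carlo calibration below is
the operative check.  Calibration under the null generator (1000 replicates,
4 foods × 6 sizes × 3 participants per cell, α = 0.05) yields per-term
rejection rates near 5 %.

## Dish nutrition

Twenty-two nutrients are tracked with fixed canonical units (kcal for
energy; g for macronutrients, fibre and potassium; mg or µg for minerals and
vitamins; niacin in mg NE, vitamin A in µg RE, vitamin E in mg α-TE).
Contribution of an ingredient = per-100 g composition × weight/100; a dish is
the component-wise sum.  Missing composition values are NaN-backed markers
that propagate through addition and scaling, so an adequacy cell can report
"unknown" instead of silently treating an unmeasured nutrient as zero.

Cooking is handled by per-nutrient retention factors r ∈ [0, 1]
(multiplicative losses) and a weight-yield factor y ∈ (0, 2] (cooked/raw
mass; >1 for water-absorbing grains, <1 for meats and vegetables).  Retention
factors are supplied as data files, not hard-coded — published retention
schemes differ in whether factors are per-nutrient or per-food-group, so the
packaged `retention_factors.csv` is an **illustrative** table with typical
magnitudes (e.g. 50 % ascorbic-acid retention on boiling), not a transcription
of any authority's values.  A recipe's per-100 g composition divides the
retained totals by the final cooked weight (explicit, or Σ raw × yield).

On the potassium unit: the packaged lunchtime reference table carries
potassium as 1.71 for every group.  The printed source labels this "mg",
which is physiologically implausible (lunchtime potassium needs are on the
order of grams); the value is stored as printed and treated as **grams**
throughout, and the synthetic food compositions generate potassium in
g/100 g so that dish totals and references are unit-consistent.  The value
is flagged here rather than silently corrected.

## Adequacy scoring

Lunchtime DRIs cover 14 demographic groups (women/men × seven age bands from
14–19 to >70; pregnancy and lactation are out of scope).  A packaged table
provides the references directly; alternatively `derive_lunch_dri` builds
one as daily DRI × per-nutrient meal fraction (fractions in (0, 1]; the
derivation is an exact cell-wise product and inverts exactly).

Scoring conventions, stated explicitly because each was an open choice:

- "Meets" is **inclusive**: dish value ≥ reference.  Ties have measure zero
  for real compositions.
- A cell's percentage is 100 × meets/(meets + fails); unknown dishes leave
  the denominator and are reported separately, rather than counted as
  failures.
- Traffic-light bands read the boundary strictly: red < 50, green > 80,
  and both 50 and 80 are yellow.
- Display rounding is half-up to integers (7.94 → 8); full precision is kept
  internally.
- Sodium is scored by the same ≥ rule as every other nutrient — uniform
  treatment keeps the matrix interpretable as "reaches the reference
  amount" — with a caution note attached, since exceeding the sodium
  reference is not desirable.
- Vitamin D is representable but excluded from adequacy by default:
  food-composition databases are too patchy for it, and scoring it would
  systematically understate intake.  Trace elements with the same problem
  (Cu, Mn, I, Se, pantothenic acid, biotin) are outside the tracked panel
  entirely.
- Iron's group dependence (higher references for women under 60) comes
  purely from the reference table; there is no special-casing in code.

`headline_deficits` lists nutrients below a threshold (default 50 %) in
every group, or in at least one group with `scope="any"`.

## Combination enumeration

Canteen observations are pooled per ingredient by arithmetic mean (median
behind a flag), recording observation counts; one ingredient per sector is
enforced — a mixed preparation like "rice with vegetables" must enter
upstream as a single grain-sector item.  The combination space is the
Cartesian product of the four pools, enumerated lazily in lexicographic
(protein, grain, vegetable, fruit) order; with the default pools that is
36 × 18 × 13 × 8 = 67,392 dishes.  `combination_adequacy` accumulates
meets/fails/unknown counts chunk-by-chunk (one vectorised chunk per protein
member) and never materialises the dish list; per-nutrient min/median/max
summaries use the compact totals matrix (combinations × nutrients, ~12 MB at
the default scale).  A property test holds the streaming aggregate exactly
equal to scoring the materialised list across random pool shapes.

## Validation scope and problem sizes

Parameter-recovery checks simulate 500 participants (bias slope +0.30
recovered within ±5 points; CV 25 % within ±3 points); the ANOVA calibration
uses 1000 null replicates of a 72-observation design; the effect-detection
check uses 46 participants × 4 foods with slopes −0.10…+0.30, where both
main effects reach p < 0.001.  These sizes give Monte-Carlo error comfortably
inside the stated tolerances while keeping the full suite fast.

What passing these tests shows: the estimators recover the parameters of the
generating model, the test statistics are calibrated under their null, and
the combinatorial machinery is exact.  What they cannot show: anything about
real foods or real eaters.  The synthetic compositions are uniform draws
from plausible group-typical ranges — they reproduce the broad signatures
(protein foods rich in protein/Fe/Zn/B12, fruit and vegetables in vitamin
C/folate/potassium, grains in carbohydrate/thiamine) but not correlations
between nutrients within a food, seasonal or preparation variability, or any
specific database's values.  Adequacy percentages computed on synthetic
canteens are therefore illustrations of the pipeline, not nutritional
findings.

## Known limitations

- Weight ∝ area assumes constant pile height; foods whose geometry changes
  with plate size (whole fruits, rigid pieces) violate this in ways the bias
  term only partially absorbs.
- No nutrient bioavailability modelling, no upper-limit screening, and no
  discretionary seasoning (salt added at table or in the kitchen).
- The linear bias ramp and diameter-independent noise are modelling
  conveniences; real serving behaviour may anchor on previous plates.
- Liquid and mixed preparations (soups, stews, sauces) do not form sectors
  and are outside the plate model entirely.
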