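# healthyplate

Tools for the quantitative nutritional assessment of "healthy eating plate"
dietary graphics — plate models that divide a meal plate into four sectors
(protein foods, grains/cereals, vegetables, fruit) and ask the eater to fill
each sector, as in the AESAN/Harvard Healthy Eating Plate.  The package is
aimed at nutrition researchers and dietitians who want to test, rather than
assume, whether dishes composed this way deliver the nutrients a meal is
supposed to provide.

It implements the full analysis pipeline:

- **Plate geometry.** A serving that evenly fills its sector should scale with
  the sector area, i.e. with the squared plate diameter: the expected weight
  on a plate of diameter *d* given a reference serving *w*<sub>ref</sub> on a
  plate of diameter *d*<sub>ref</sub> is
  *w*<sub>ref</sub>·(*d*/*d*<sub>ref</sub>)².  The **serving bias** is the
  percent deviation of observed weights from this expectation (positive =
  over-serving on larger plates), estimated per food and diameter from
  participant serving records.
- **Intersubject variability.** Coefficient of variation
  CV = SD/mean × 100 of served weight per food and plate diameter, and a
  two-factor fixed-effects linear model *weight ~ food × size* with Type III
  sums of squares under sum-to-zero contrasts.
- **Dish nutrition.** A dish's nutrient vector is the sum of its ingredients'
  per-100 g compositions scaled by weight, with optional per-nutrient cooking
  retention factors *r* ∈ [0, 1] and a cooked/raw weight-yield factor.
  Twenty-two nutrients are tracked; missing composition values are a distinct
  state that propagates (never silently zero).
- **Adequacy scoring.** Dishes are scored against lunchtime dietary reference
  intakes (DRIs) for 14 sex × age demographic groups (a reference table ships
  with the package; lunch DRIs can also be derived as daily DRI × meal
  fraction).  Each (nutrient, group) cell reports the percentage of dishes
  meeting the reference, colour-banded red < 50 %, yellow 50–80 %,
  green > 80 %.
- **Exhaustive combination enumeration.** Canteen ingredient pools (by
  default 36 proteins, 18 grains, 13 vegetables, 8 fruits, repeated
  observations averaged) define a Cartesian space of
  36 × 18 × 13 × 8 = 67,392 one-per-sector dishes whose adequacy is
  aggregated in a single streaming pass.
- **Synthetic data.** A fully seeded generator for food compositions,
  canteen pools and serving records with controlled bias slopes and CVs, so
  every estimator in the pipeline can be validated by parameter recovery.

## Worked example

```python
import healthyplate as hp

# adequacy of every possible canteen combination dish
dri = hp.load_packaged_lunch_dri()                 # 22 nutrients x 14 groups
pools = hp.generate_canteen_pools(seed=1)          # 36/18/13/8 ingredients
print("combinations:", hp.count_combinations(pools))
summary = hp.combination_adequacy(pools, dri=dri)
print(summary.percent.loc[["energy_kcal", "protein_g", "fibre_g", "iron_mg"],
                          ["female_20-29", "female_60-69", "male_20-29"]].round(1))
print("deficits in every group:", hp.headline_deficits(summary))
```

```
combinations: 67392
             female_20-29  female_60-69  male_20-29
energy_kcal           6.0          31.3         0.0
protein_g           100.0         100.0        99.7
fibre_g              92.5          97.2        56.7
iron_mg              39.0          99.2        99.0
deficits in every group: ['energy_kcal', 'fat_g', 'carbohydrate_g', 'calcium_mg',
 'sodium_mg', 'potassium_g', 'vitamin_e_mg_ate']
```

Of the 67,392 synthetic combination dishes, only 6 % reach the lunchtime
energy reference for women aged 20–29 (none for young men), protein is met
essentially always, and iron separates sharply by group because women of
childbearing age carry a roughly double iron reference.  `headline_deficits`
lists the nutrients under 50 % adequacy in *every* demographic group.

```python
# serving bias across plate sizes, from simulated participants
foods = hp.generate_food_table({"protein": 4, "grain": 0, "vegetable": 0, "fruit": 0}, seed=2)
ids = [f.id for f in foods]
params = hp.ServingModelParams(
    bias_slope={ids[0]: -0.10, ids[1]: 0.05, ids[2]: 0.20, ids[3]: 0.30},
    cv={fid: 0.25 for fid in ids},
    ref_weight_g={ids[0]: 40.0, ids[1]: 55.0, ids[2]: 70.0, ids[3]: 90.0},
)
cfg = hp.SimulationConfig(n_participants=46, foods=tuple(foods), params=params, seed=3)
records = hp.generate_servings(cfg)
print(hp.bias_table(records, hp.PlateSpec()).pivot().round(1))
print(hp.two_way_anova(records).table.round(3))
```

```
diameter_cm  17.0  20.0  23.0  26.0  29.0  32.0
food_id
protein_00    0.0  -3.6  -3.1  -3.0  -9.4  -4.9
protein_01    0.0  11.1   9.2   5.4  15.5   5.0
protein_02    0.0  11.3  10.6  12.1  22.7  37.7
protein_03    0.0  -4.3   5.0   7.3  12.9  19.3

                sum_sq    df        F    p
size       5352699.751     5  448.598  0.0
food       3546528.269     3  495.378  0.0
size:food  1103234.970    15   30.820  0.0
residual   2577326.023  1080  NaN      NaN
```

Bias is zero at the 17 cm reference by construction and ramps with diameter
according to each food's slope (−10 % to +30 % here); with 46 participants
and 25 % intersubject CV each cell carries a Monte-Carlo error of about
±5 points.  Both main effects and the food × size interaction are highly
significant, as expected when foods differ in both typical serving and bias.

A `healthyplate` console script exposes the same pipeline as subcommands
(`simulate`, `bias`, `cv`, `anova`, `nutrients`, `adequacy`, `enumerate`,
`report`) over the CSV schemas the library reads and writes.

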