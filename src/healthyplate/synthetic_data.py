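"""Seeded synthetic inputs: food-composition tables, participant serving
records with controlled diameter bias and intersubject variability, and
canteen ingredient pools.

The serving model for participant *i*, food *f* and plate diameter *d* is

    weight = w_ref_f * (d / d_ref)^2 * (1 + b_f * s(d)) * eps_{i,f,d}

where ``w_ref_f`` is the food's typical serving on the reference (17 cm)
sector, the squared-diameter term is pure area scaling, ``b_f`` is a
fractional bias reached at the largest diameter (negative allowed; the ramp
``s(d)`` rises linearly from 0 at the reference diameter to 1 at the largest),
and ``eps`` is multiplicative log-normal noise with mean 1 and coefficient of
variation ``c_f``.  The observed bias gradients across plate sizes span
roughly -10 % to beyond +30 % depending on the ingredient, and intersubject
CVs range from a few percent up to ~50 %; the model's parameter ranges cover
both.

Randomness is fully deterministic: one master seed, with independent
sub-streams derived per (participant, food) so that adding foods or
participants never perturbs existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .combination_enumerator import IngredientPool, build_pools
from .data_model_io import (
    FOOD_GROUPS,
    NUTRIENT_KEYS,
    FoodItem,
    NutrientVector,
    PlateSpec,
    ServingRecord,
    ValidationError,
)

#: Default canteen pool sizes (proteins, grains, vegetables, fruits).
DEFAULT_POOL_SIZES: dict[str, int] = {
    "protein": 36,
    "grain": 18,
    "vegetable": 13,
    "fruit": 8,
}

#: Per-100 g composition ranges (uniform draw) per food group.  Chosen to
#: reflect the broad signatures of each plate sector: protein foods rich in
#: protein, Fe, Zn and B12; grains carbohydrate- and thiamine-dense; vegetables
#: and fruits light in energy but high in ascorbic acid, folate, K and
#: provitamin A.
COMPOSITION_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "protein": {
        "energy_kcal": (90, 250), "protein_g": (15, 30), "fat_g": (1, 15),
        "carbohydrate_g": (0, 15), "fibre_g": (0, 8), "calcium_mg": (10, 120),
        "magnesium_mg": (20, 60), "phosphorus_mg": (150, 300), "sodium_mg": (50, 120),
        "potassium_g": (0.20, 0.45), "iron_mg": (0.8, 3.5), "zinc_mg": (0.8, 4.5),
        "thiamine_mg": (0.05, 0.50), "riboflavin_mg": (0.05, 0.35),
        "niacin_mg_ne": (3, 12), "vitamin_b6_mg": (0.2, 0.7),
        "folic_acid_ug": (5, 100), "vitamin_b12_ug": (0.5, 3.0),
        "ascorbic_acid_mg": (0, 2), "vitamin_a_ug_re": (5, 50),
        "vitamin_d_ug": (0, 5), "vitamin_e_mg_ate": (0.2, 1.5),
    },
    "grain": {
        "energy_kcal": (110, 360), "protein_g": (3, 13), "fat_g": (0.5, 3),
        "carbohydrate_g": (20, 75), "fibre_g": (1, 10), "calcium_mg": (10, 50),
        "magnesium_mg": (20, 120), "phosphorus_mg": (80, 300), "sodium_mg": (1, 10),
        "potassium_g": (0.10, 0.35), "iron_mg": (0.5, 4.0), "zinc_mg": (0.5, 3.0),
        "thiamine_mg": (0.10, 0.50), "riboflavin_mg": (0.03, 0.20),
        "niacin_mg_ne": (1, 6), "vitamin_b6_mg": (0.1, 0.4),
        "folic_acid_ug": (10, 60), "vitamin_b12_ug": (0, 0),
        "ascorbic_acid_mg": (0, 0), "vitamin_a_ug_re": (0, 5),
        "vitamin_d_ug": (0, 0), "vitamin_e_mg_ate": (0.1, 1.0),
    },
    "vegetable": {
        "energy_kcal": (15, 60), "protein_g": (1, 4), "fat_g": (0.1, 0.8),
        "carbohydrate_g": (2, 10), "fibre_g": (1, 5), "calcium_mg": (10, 80),
        "magnesium_mg": (8, 30), "phosphorus_mg": (20, 80), "sodium_mg": (2, 80),
        "potassium_g": (0.15, 0.50), "iron_mg": (0.3, 2.0), "zinc_mg": (0.2, 1.0),
        "thiamine_mg": (0.03, 0.12), "riboflavin_mg": (0.03, 0.20),
        "niacin_mg_ne": (0.3, 1.5), "vitamin_b6_mg": (0.05, 0.30),
        "folic_acid_ug": (20, 150), "vitamin_b12_ug": (0, 0),
        "ascorbic_acid_mg": (5, 90), "vitamin_a_ug_re": (10, 600),
        "vitamin_d_ug": (0, 0), "vitamin_e_mg_ate": (0.1, 2.0),
    },
    "fruit": {
        "energy_kcal": (30, 95), "protein_g": (0.3, 1.5), "fat_g": (0.1, 0.5),
        "carbohydrate_g": (7, 22), "fibre_g": (1, 5), "calcium_mg": (5, 40),
        "magnesium_mg": (5, 30), "phosphorus_mg": (10, 40), "sodium_mg": (0, 5),
        "potassium_g": (0.15, 0.45), "iron_mg": (0.2, 0.8), "zinc_mg": (0.05, 0.30),
        "thiamine_mg": (0.02, 0.10), "riboflavin_mg": (0.02, 0.08),
        "niacin_mg_ne": (0.2, 0.8), "vitamin_b6_mg": (0.05, 0.40),
        "folic_acid_ug": (5, 40), "vitamin_b12_ug": (0, 0),
        "ascorbic_acid_mg": (5, 70), "vitamin_a_ug_re": (3, 100),
        "vitamin_d_ug": (0, 0), "vitamin_e_mg_ate": (0.1, 1.0),
    },
}

#: Typical reference-sector serving weight (g) per food group, used for
#: canteen observations and default serving-model parameters.
TYPICAL_SERVING_G: dict[str, float] = {
    "protein": 60.0,
    "grain": 70.0,
    "vegetable": 45.0,
    "fruit": 50.0,
}

# namespaces for sub-stream seed derivation
_NS_FOOD, _NS_SERVING, _NS_CANTEEN, _NS_NULL = 0, 1, 2, 3


def _rng(master_seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, path)]))


# --------------------------------------------------------------------------
# Model parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ServingModelParams:
    """Per-food serving-model parameters.

    ``bias_slope`` is the fractional deviation from area scaling reached at the
    largest diameter (|b| <= 1, negative = under-serving on big plates);
    ``cv`` the intersubject coefficient of variation (fraction >= 0);
    ``ref_weight_g`` the mean serving on the reference sector (> 0).
    Noise is multiplicative log-normal with mean 1.
    """

    bias_slope: Mapping[str, float]
    cv: Mapping[str, float]
    ref_weight_g: Mapping[str, float]

    def __post_init__(self) -> None:
        for fid, b in self.bias_slope.items():
            if abs(b) > 1:
                raise ValidationError(f"|bias slope| must be <= 1 for {fid}, got {b}")
        for fid, c in self.cv.items():
            if c < 0:
                raise ValidationError(f"CV must be >= 0 for {fid}, got {c}")
        for fid, w in self.ref_weight_g.items():
            if w <= 0:
                raise ValidationError(f"reference weight must be > 0 for {fid}, got {w}")

    @classmethod
    def uniform(
        cls, food_ids: Sequence[str], bias_slope: float, cv: float, ref_weight_g: float
    ) -> "ServingModelParams":
        return cls(
            bias_slope={f: bias_slope for f in food_ids},
            cv={f: cv for f in food_ids},
            ref_weight_g={f: ref_weight_g for f in food_ids},
        )


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int
    foods: tuple[FoodItem, ...]
    params: ServingModelParams
    seed: int
    plate: PlateSpec = field(default_factory=PlateSpec)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        for f in self.foods:
            for attr in ("bias_slope", "cv", "ref_weight_g"):
                if f.id not in getattr(self.params, attr):
                    raise ValidationError(f"params.{attr} missing food {f.id!r}")


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------


def generate_food_table(
    n_per_group: Mapping[str, int] | None = None, seed: int = 0
) -> list[FoodItem]:
    """Draw per-100 g compositions from the documented group ranges.

    Defaults to the canteen pool sizes 36/18/13/8 (75 foods).  Each food gets
    its own random sub-stream, so tables are reproducible and extending a
    group appends foods without changing earlier ones.
    """
    if n_per_group is None:
        n_per_group = DEFAULT_POOL_SIZES
    if any(n < 0 for n in n_per_group.values()):
        raise ValidationError("food counts must be >= 0")
    foods: list[FoodItem] = []
    for gi, group in enumerate(FOOD_GROUPS):
        ranges = COMPOSITION_RANGES[group]
        for fi in range(int(n_per_group.get(group, 0))):
            rng = _rng(seed, _NS_FOOD, gi, fi)
            amounts = {
                key: float(rng.uniform(lo, hi)) for key, (lo, hi) in ranges.items()
            }
            foods.append(
                FoodItem(
                    id=f"{group}_{fi:02d}",
                    name=f"synthetic {group} {fi}",
                    group=group,
                    composition=NutrientVector.from_dict(amounts, absent="zero"),
                )
            )
    return foods


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Log-normal draws with mean 1 and coefficient of variation *cv*."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def generate_servings(config: SimulationConfig) -> list[ServingRecord]:
    """Simulate every participant serving every food on every plate diameter.

    Participants alternate female/male deterministically.  All weights are
    strictly positive (log-normal noise) and byte-identical under a fixed seed.
    """
    plate = config.plate
    d_ref = plate.reference_diameter_cm
    d_max = plate.max_diameter_cm
    diameters = list(plate.diameters_cm)
    records: list[ServingRecord] = []
    for i in range(config.n_participants):
        sex = "female" if i % 2 == 0 else "male"
        pid = f"p{i:04d}"
        for fi, food in enumerate(config.foods):
            b = config.params.bias_slope[food.id]
            c = config.params.cv[food.id]
            w_ref = config.params.ref_weight_g[food.id]
            rng = _rng(config.seed, _NS_SERVING, i, fi)
            eps = _lognormal_unit_mean(rng, c, len(diameters))
            for di, d in enumerate(diameters):
                s = 0.0 if d_max == d_ref else (d - d_ref) / (d_max - d_ref)
                mean_w = w_ref * (d / d_ref) ** 2 * (1.0 + b * s)
                records.append(
                    ServingRecord(
                        participant_id=pid,
                        sex=sex,
                        diameter_cm=float(d),
                        food_id=food.id,
                        weight_g=float(mean_w * eps[di]),
                    )
                )
    return records


def generate_canteen_observations(
    seed: int = 0,
    n_per_group: Mapping[str, int] | None = None,
    duplicate_every: int = 4,
) -> list[tuple[FoodItem, float]]:
    """Canteen serving observations with deliberate repeats.

    Every ``duplicate_every``-th food in each group is observed twice with a
    small weight jitter, exercising the repetition-averaging path when the
    observations are pooled.  Weights are log-normal around the group-typical
    serving scaled to the 26 cm canteen plate.
    """
    foods = generate_food_table(n_per_group=n_per_group, seed=seed)
    obs: list[tuple[FoodItem, float]] = []
    scale_26cm = (26.0 / 17.0) ** 2  # canteen dishes were composed on 26 cm plates
    for fi, food in enumerate(foods):
        rng = _rng(seed, _NS_CANTEEN, fi)
        base = TYPICAL_SERVING_G[food.group] * scale_26cm
        w = float(base * _lognormal_unit_mean(rng, 0.15, 1)[0])
        obs.append((food, w))
        if duplicate_every > 0 and fi % duplicate_every == 0:
            jitter = float(rng.uniform(0.98, 1.02))
            obs.append((food, w * jitter))
    return obs


def generate_canteen_pools(
    seed: int = 0, n_per_group: Mapping[str, int] | None = None
) -> dict[str, IngredientPool]:
    """Pooled canteen ingredient pools (default sizes 36/18/13/8), with
    repeated observations collapsed to their mean weight."""
    return build_pools(generate_canteen_observations(seed=seed, n_per_group=n_per_group))


def generate_null_servings(
    n_participants: int,
    n_foods: int = 4,
    seed: int = 0,
    sigma_log: float = 0.1,
    base_weight_g: float = 100.0,
    plate: PlateSpec | None = None,
) -> list[ServingRecord]:
    """Pure-noise servings with no food or plate-size effect.

    Every (participant, food, diameter) weight is an i.i.d. log-normal draw
    around a common mean — the null model for significance-test calibration.
    """
    if plate is None:
        plate = PlateSpec()
    records = []
    for i in range(n_participants):
        sex = "female" if i % 2 == 0 else "male"
        for fi in range(n_foods):
            rng = _rng(seed, _NS_NULL, i, fi)
            draws = rng.lognormal(mean=0.0, sigma=sigma_log, size=len(plate.diameters_cm))
            for d, z in zip(plate.diameters_cm, draws):
                records.append(
                    ServingRecord(
                        participant_id=f"p{i:04d}",
                        sex=sex,
                        diameter_cm=float(d),
                        food_id=f"food_{fi}",
                        weight_g=float(base_weight_g * z),
                    )
                )
    return records


def generate_daily_dri_and_fractions(seed: int = 0):
    """A synthetic daily DRI table plus per-nutrient lunch fractions.

    Daily amounts are plausible positive values per nutrient and group;
    fractions are drawn in [0.25, 0.40], the conventional share of daily
    intake attributed to the midday meal.  Intended for exercising the
    daily-to-lunch derivation and its round-trip inverse.
    """
    from .adequacy_assessment import MealFractionTable
    from .data_model_io import GROUP_LABELS, load_packaged_lunch_dri

    rng = _rng(seed, 7)
    lunch = load_packaged_lunch_dri().table
    scale = rng.uniform(2.2, 4.0, size=(len(lunch.index), 1))
    daily = pd.DataFrame(
        lunch.to_numpy() * scale, index=lunch.index, columns=list(GROUP_LABELS)
    )
    fractions = MealFractionTable(
        {n: float(rng.uniform(0.25, 0.40)) for n in daily.index}
    )
    return daily, fractions
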