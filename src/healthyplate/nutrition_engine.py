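"""Dish nutrient calculation from per-100 g compositions, with cooking
retention and weight-yield factors.

The contribution of an ingredient is its composition scaled by weight/100;
a dish is the component-wise sum of its (retention-adjusted) contributions.
Retention factors are multiplicative per-nutrient losses in [0, 1] applied to
the raw contribution; the weight-yield factor converts raw to cooked mass and
only enters the per-100 g normalisation of a finished recipe.  Missing
nutrient values propagate through every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model_io import (
    NUTRIENT_KEYS,
    Dish,
    FoodItem,
    NutrientVector,
    SchemaError,
    ValidationError,
)


@dataclass(frozen=True)
class RetentionProfile:
    """Per-nutrient retention factors and a cooked/raw weight-yield factor.

    A nutrient absent from ``retention`` keeps factor 1.0 (no loss).
    """

    name: str = "raw"
    retention: Mapping[str, float] = field(default_factory=dict)
    yield_factor: float = 1.0

    def __post_init__(self) -> None:
        for key, r in self.retention.items():
            if key not in NUTRIENT_KEYS:
                raise SchemaError(f"retention profile {self.name!r}: unknown nutrient {key!r}")
            if not 0.0 <= r <= 1.0:
                raise ValidationError(
                    f"retention profile {self.name!r}: factor for {key} must be in [0, 1], got {r}"
                )
        if not 0.0 < self.yield_factor <= 2.0:
            raise ValidationError(
                f"retention profile {self.name!r}: yield factor must be in (0, 2], got {self.yield_factor}"
            )

    def factors(self) -> np.ndarray:
        arr = np.ones(len(NUTRIENT_KEYS))
        for key, r in self.retention.items():
            arr[NUTRIENT_KEYS.index(key)] = r
        return arr


IDENTITY_PROFILE = RetentionProfile()


def food_contribution(food: FoodItem, weight_g: float) -> NutrientVector:
    """Nutrients contributed by *weight_g* grams of a food (composition × w/100)."""
    if weight_g < 0:
        raise ValidationError(f"weight must be >= 0, got {weight_g}")
    return food.composition.scale(weight_g / 100.0)


def apply_retention(v: NutrientVector, profile: RetentionProfile) -> NutrientVector:
    """Apply per-nutrient cooking retention factors to a nutrient vector."""
    return NutrientVector(v.values * profile.factors())


def dish_nutrients(
    dish: Dish,
    foods: Mapping[str, FoodItem] | Sequence[FoodItem],
    retention: Mapping[str, RetentionProfile] | None = None,
) -> NutrientVector:
    """Total nutrients of a composed dish.

    *foods* resolves component food ids; *retention* optionally maps food id to
    the profile applied to that component's contribution.  An empty dish is the
    zero vector.
    """
    food_map = foods if isinstance(foods, Mapping) else {f.id: f for f in foods}
    total = NutrientVector.zero()
    for fid, weight in dish.components:
        if fid not in food_map:
            raise KeyError(f"dish {dish.label!r}: unknown food id {fid!r}")
        contrib = food_contribution(food_map[fid], weight)
        if retention and fid in retention:
            contrib = apply_retention(contrib, retention[fid])
        total = total + contrib
    return total


@dataclass(frozen=True)
class Recipe:
    """Raw ingredient weights with per-ingredient retention/yield profiles.

    ``final_weight_g`` is the cooked dish weight; when omitted it defaults to
    the sum of raw weights times their yield factors.
    """

    items: tuple[tuple[FoodItem, float, RetentionProfile], ...]
    final_weight_g: float | None = None

    def __post_init__(self) -> None:
        if any(w <= 0 for _, w, _ in self.items):
            raise ValidationError("recipe ingredient weights must be > 0")
        if self.final_weight_g is not None and self.final_weight_g <= 0:
            raise ValidationError("final dish weight must be > 0")


def recipe_nutrients(recipe: Recipe) -> tuple[NutrientVector, NutrientVector]:
    """(whole-dish, per-100 g cooked) nutrient vectors of a recipe."""
    total = NutrientVector.zero()
    cooked_weight = 0.0
    for food, raw_g, profile in recipe.items:
        total = total + apply_retention(food_contribution(food, raw_g), profile)
        cooked_weight += raw_g * profile.yield_factor
    final = recipe.final_weight_g if recipe.final_weight_g is not None else cooked_weight
    if final <= 0:
        raise ValidationError(f"final dish weight must be > 0, got {final}")
    return total, total.scale(100.0 / final)


# --------------------------------------------------------------------------
# Retention-factor tables
# --------------------------------------------------------------------------


def read_retention_table(path: str | Path) -> dict[str, RetentionProfile]:
    """Read a wide retention-factor CSV into profiles keyed by name.

    Columns: ``profile``, ``yield_factor``, then nutrient-key columns whose
    cells are retention factors; blank cells mean 1.0 (no loss).
    """
    df = pd.read_csv(path)
    for col in ("profile", "yield_factor"):
        if col not in df.columns:
            raise SchemaError(f"retention table missing column {col!r}")
    profiles: dict[str, RetentionProfile] = {}
    for _, row in df.iterrows():
        retention = {}
        for col in df.columns:
            if col in ("profile", "yield_factor"):
                continue
            if col not in NUTRIENT_KEYS:
                raise SchemaError(f"retention table: unknown nutrient column {col!r}")
            val = row[col]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            retention[col] = float(val)
        name = str(row["profile"])
        profiles[name] = RetentionProfile(
            name=name, retention=retention, yield_factor=float(row["yield_factor"])
        )
    return profiles


def load_packaged_retention_table() -> dict[str, RetentionProfile]:
    """Illustrative cooking retention profiles shipped with the package
    (typical magnitudes for boiling, grilling and raw preparation)."""
    ref = resources.files("healthyplate").joinpath("data/retention_factors.csv")
    with resources.as_file(ref) as p:
        return read_retention_table(p)
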