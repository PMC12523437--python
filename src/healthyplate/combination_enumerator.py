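"""Exhaustive enumeration of one-ingredient-per-sector dish combinations.

Repeated observations of the same canteen ingredient are pooled (arithmetic
mean of observed serving weights, median behind a flag), giving one fixed
weight per ingredient.  The full combination space is the Cartesian product of
the four group pools — with the default canteen pools of 36 proteins, 18
grains, 13 vegetables and 8 fruits that is 36 x 18 x 13 x 8 = 67,392 dishes.
Adequacy over the space is aggregated in a single streaming pass (chunked
vectorised counts); the combinations are never materialised as a list.
"""

from __future__ import annotations

import logging
import statistics
import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .adequacy_assessment import default_adequacy_nutrients
from .data_model_io import (
    FOOD_GROUPS,
    NUTRIENT_KEYS,
    Dish,
    FoodItem,
    LunchDRITable,
    NutrientVector,
    ValidationError,
)
from .nutrition_engine import dish_nutrients

logger = logging.getLogger("healthyplate")


@dataclass(frozen=True)
class PoolMember:
    food: FoodItem
    weight_g: float
    n_observations: int


@dataclass(frozen=True)
class IngredientPool:
    """One plate sector's ingredient pool with pooled serving weights."""

    group: str
    members: tuple[PoolMember, ...]

    def __post_init__(self) -> None:
        ids = [m.food.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"pool {self.group}: members must be unique by food id")

    def __len__(self) -> int:
        return len(self.members)


def build_pools(
    observations: Sequence[tuple[FoodItem, float]],
    average: str = "mean",
) -> dict[str, IngredientPool]:
    """Group observations by plate sector, collapsing repeated foods.

    Repeats of the same food id are pooled to their mean weight (or median
    with ``average="median"``), recording the observation count.
    """
    if average not in ("mean", "median"):
        raise ValueError(f"average must be 'mean' or 'median', got {average!r}")
    if any(w <= 0 for _, w in observations):
        raise ValidationError("observation weights must be > 0")
    by_food: dict[str, tuple[FoodItem, list[float]]] = {}
    order: dict[str, list[str]] = {g: [] for g in FOOD_GROUPS}
    for food, weight in observations:
        if food.group not in FOOD_GROUPS:  # unreachable for validated FoodItems
            raise ValidationError(f"food {food.id!r} has unknown group {food.group!r}")
        if food.id not in by_food:
            by_food[food.id] = (food, [])
            order[food.group].append(food.id)
        by_food[food.id][1].append(weight)

    agg = statistics.mean if average == "mean" else statistics.median
    pools = {}
    for group in FOOD_GROUPS:
        members = tuple(
            PoolMember(
                food=by_food[fid][0],
                weight_g=float(agg(by_food[fid][1])),
                n_observations=len(by_food[fid][1]),
            )
            for fid in order[group]
        )
        pools[group] = IngredientPool(group=group, members=members)
    return pools


def count_combinations(pools: Mapping[str, IngredientPool]) -> int:
    """Product of pool sizes — the number of one-per-sector dishes, computed
    without enumeration.  An empty pool yields 0 with a warning."""
    missing = [g for g in FOOD_GROUPS if g not in pools]
    if missing:
        raise ValidationError(f"pools missing groups: {missing}")
    total = 1
    for g in FOOD_GROUPS:
        n = len(pools[g])
        if n == 0:
            logger.warning("pool %s is empty; combination count is 0", g)
            return 0
        total *= n
    return total


def enumerate_dishes(
    pools: Mapping[str, IngredientPool],
    foods: Mapping[str, FoodItem] | Sequence[FoodItem] | None = None,
) -> Iterator[tuple[Dish, NutrientVector]]:
    """Lazily yield every one-per-sector combination with its nutrient vector.

    Order is lexicographic by (protein, grain, vegetable, fruit) member index.
    *foods* defaults to the pool members themselves; every member must resolve
    before streaming starts.
    """
    missing = [g for g in FOOD_GROUPS if g not in pools]
    if missing:
        raise ValidationError(f"pools missing groups: {missing}")
    if foods is None:
        food_map = {m.food.id: m.food for g in FOOD_GROUPS for m in pools[g].members}
    else:
        food_map = foods if isinstance(foods, Mapping) else {f.id: f for f in foods}
    unresolved = [
        m.food.id for g in FOOD_GROUPS for m in pools[g].members if m.food.id not in food_map
    ]
    if unresolved:
        raise KeyError(f"pool members not in food table: {unresolved}")

    # Pre-scale each member's contribution once; a dish is then a 4-way sum.
    contribs = {
        g: [
            (m, food_map[m.food.id].composition.values * (m.weight_g / 100.0))
            for m in pools[g].members
        ]
        for g in FOOD_GROUPS
    }
    # validation above runs eagerly; only the product stream is lazy
    return _stream_dishes(contribs)


def _stream_dishes(contribs) -> Iterator[tuple[Dish, NutrientVector]]:
    for mp, cp in contribs["protein"]:
        for mg, cg in contribs["grain"]:
            pg = cp + cg
            for mv, cv in contribs["vegetable"]:
                pgv = pg + cv
                for mf, cf in contribs["fruit"]:
                    dish = Dish(
                        components=(
                            (mp.food.id, mp.weight_g),
                            (mg.food.id, mg.weight_g),
                            (mv.food.id, mv.weight_g),
                            (mf.food.id, mf.weight_g),
                        ),
                        label=f"{mp.food.id}+{mg.food.id}+{mv.food.id}+{mf.food.id}",
                    )
                    yield dish, NutrientVector(pgv + cf)


@dataclass
class CombinationSummary:
    """Streaming adequacy aggregate over the full combination space."""

    n_combinations: int
    percent: pd.DataFrame  # nutrient x group, unknowns excluded from denominator
    meets: pd.DataFrame
    unknown: pd.DataFrame
    nutrient_range: pd.DataFrame  # per-nutrient min/median/max of dish totals
    run_id: str | None = None

    def get(self, nutrient: str, group: str) -> float:
        return float(self.percent.at[nutrient, group])


def combination_adequacy(
    pools: Mapping[str, IngredientPool],
    foods: Mapping[str, FoodItem] | Sequence[FoodItem] | None = None,
    dri: LunchDRITable | None = None,
    nutrients: Sequence[str] | None = None,
    run_id: str | None = None,
) -> CombinationSummary:
    """Adequacy percentages over every combination, in one streaming pass.

    Counts of meets/fails/unknown per (nutrient, group) are accumulated chunk
    by chunk (one chunk per protein-pool member), so memory stays bounded by a
    single chunk regardless of the total combination count.  Results are
    identical to scoring the fully materialised dish list.
    """
    if dri is None:
        raise ValidationError("combination_adequacy requires a DRI table")
    n_total = count_combinations(pools)
    if n_total == 0:
        raise ValidationError("cannot aggregate adequacy over an empty combination space")
    if nutrients is None:
        nutrients = default_adequacy_nutrients(dri)
    thresholds = dri.thresholds(nutrients)
    thr = thresholds.to_numpy()  # nutrient x group
    nidx = [NUTRIENT_KEYS.index(n) for n in nutrients]

    if foods is None:
        food_map = {m.food.id: m.food for g in FOOD_GROUPS for m in pools[g].members}
    else:
        food_map = foods if isinstance(foods, Mapping) else {f.id: f for f in foods}

    def member_matrix(group: str) -> np.ndarray:
        rows = []
        for m in pools[group].members:
            if m.food.id not in food_map:
                raise KeyError(f"pool member {m.food.id!r} not in food table")
            rows.append(food_map[m.food.id].composition.values * (m.weight_g / 100.0))
        return np.vstack(rows)[:, nidx]

    mat = {g: member_matrix(g) for g in FOOD_GROUPS}
    # base: grain + vegetable + fruit totals for every (g, v, f) triple
    base = (
        mat["grain"][:, None, None, :]
        + mat["vegetable"][None, :, None, :]
        + mat["fruit"][None, None, :, :]
    ).reshape(-1, len(nutrients))

    n_nut, n_grp = thr.shape
    meets = np.zeros((n_nut, n_grp), dtype=np.int64)
    unknown = np.zeros(n_nut, dtype=np.int64)
    chunks: list[np.ndarray] = []
    for p_row in mat["protein"]:
        totals = base + p_row  # chunk x nutrient
        unknown += np.isnan(totals).sum(axis=0)
        with np.errstate(invalid="ignore"):
            meets += (totals[:, :, None] >= thr[None, :, :]).sum(axis=0)
        chunks.append(totals)
    # per-nutrient distribution summary (the totals array is small relative to
    # the dish objects the streaming pass avoids materialising)
    all_totals = np.concatenate(chunks, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN nutrient columns
        mins = np.nanmin(all_totals, axis=0)
        medians = np.nanmedian(all_totals, axis=0)
        maxs = np.nanmax(all_totals, axis=0)

    known = np.broadcast_to((n_total - unknown).astype(float)[:, None], meets.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(known > 0, 100.0 * meets / known, np.nan)

    idx = list(nutrients)
    cols = list(thresholds.columns)
    return CombinationSummary(
        n_combinations=n_total,
        percent=pd.DataFrame(pct, index=idx, columns=cols),
        meets=pd.DataFrame(meets, index=idx, columns=cols),
        unknown=pd.DataFrame(
            np.broadcast_to(unknown[:, None], meets.shape).copy(), index=idx, columns=cols
        ),
        nutrient_range=pd.DataFrame(
            {"min": mins, "median": medians, "max": maxs}, index=idx
        ),
        run_id=run_id,
    )
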