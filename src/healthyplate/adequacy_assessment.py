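"""Scoring dishes against lunchtime dietary reference intakes.

A dish *meets* the requirement for a nutrient and demographic group when its
content is greater than or equal to the group's lunchtime DRI (inclusive
convention; ties are measure-zero for real compositions).  A dish whose value
for a nutrient is missing is *unknown* and drops out of that cell's
denominator rather than counting as a failure.  Cell percentages are
colour-banded with the traffic-light rule red < 50 %, yellow 50–80 %,
green > 80 % (both boundaries read strictly, so 50 and 80 are yellow).

Sodium is scored by the same "at least the reference" rule as every other
nutrient, even though exceeding the sodium reference is not nutritionally
desirable; reports attach a caution note to sodium cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model_io import (
    ADEQUACY_EXCLUDED_DEFAULT,
    GROUP_LABELS,
    NUTRIENT_KEYS,
    DemographicGroup,
    LunchDRITable,
    NutrientVector,
    ValidationError,
)

SODIUM_CAUTION = (
    "sodium is scored by the same >= rule as other nutrients; "
    "higher sodium intake is not nutritionally desirable"
)


def default_adequacy_nutrients(dri: LunchDRITable) -> tuple[str, ...]:
    """Nutrients scored by default: all DRI nutrients minus the excluded set."""
    return tuple(n for n in dri.nutrients if n not in ADEQUACY_EXCLUDED_DEFAULT)


@dataclass(frozen=True)
class MealFractionTable:
    """Fraction of daily intake attributed to the target meal, per nutrient."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        for key, f in self.fractions.items():
            if key not in NUTRIENT_KEYS:
                raise ValidationError(f"unknown nutrient {key!r} in meal fractions")
            if not 0.0 < f <= 1.0:
                raise ValidationError(f"meal fraction for {key} must be in (0, 1], got {f}")

    def get(self, nutrient: str) -> float:
        if nutrient not in self.fractions:
            raise KeyError(f"no meal fraction for nutrient {nutrient!r}")
        return self.fractions[nutrient]


def derive_lunch_dri(daily: pd.DataFrame, fractions: MealFractionTable) -> LunchDRITable:
    """Lunchtime DRI as the cell-wise product daily x meal fraction.

    *daily* is a nutrient x group frame (same layout as a lunch DRI table).
    Every daily nutrient must have a fraction; the result is flagged
    ``derived-from-daily``.
    """
    missing = [n for n in daily.index if n not in fractions.fractions]
    if missing:
        raise KeyError(f"no meal fraction for nutrients: {missing}")
    scaled = daily.mul(
        pd.Series({n: fractions.get(n) for n in daily.index}), axis=0
    )
    return LunchDRITable(scaled, provenance="derived-from-daily")


def meets_requirement(
    v: NutrientVector,
    group: DemographicGroup | str,
    dri: LunchDRITable,
    nutrient: str,
) -> str:
    """``"meets"`` / ``"fails"`` / ``"unknown"`` for one dish, group and nutrient."""
    threshold = dri.get(group, nutrient)  # KeyError if nutrient absent
    value = v[nutrient]
    if math.isnan(value):
        return "unknown"
    return "meets" if value >= threshold else "fails"


@dataclass
class AdequacyMatrix:
    """Percent of dishes meeting the lunchtime DRI per (nutrient, group).

    ``percent`` and ``unknown`` are nutrient x group frames; unknowns are
    excluded from a cell's denominator (a cell with every dish unknown is NaN).
    """

    percent: pd.DataFrame
    unknown: pd.DataFrame
    n_dishes: int
    run_id: str | None = None
    notes: Mapping[str, str] | None = None

    def classes(self) -> pd.DataFrame:
        return self.percent.map(lambda p: None if math.isnan(p) else classify_cell(p))

    def get(self, nutrient: str, group: DemographicGroup | str) -> float:
        label = group.label if isinstance(group, DemographicGroup) else group
        return float(self.percent.at[nutrient, label])


def adequacy_matrix(
    dishes: Sequence[NutrientVector],
    dri: LunchDRITable,
    nutrients: Sequence[str] | None = None,
    run_id: str | None = None,
) -> AdequacyMatrix:
    """Score every dish against every (nutrient, group) threshold.

    cell = 100 x #meets / (#meets + #fails); dishes with a missing value for
    the nutrient are counted separately in ``unknown``.  By default all DRI
    nutrients except the excluded set (vitamin D) are scored.
    """
    if len(dishes) == 0:
        raise ValidationError("adequacy_matrix requires at least one dish")
    if nutrients is None:
        nutrients = default_adequacy_nutrients(dri)
    thresholds = dri.thresholds(nutrients)  # nutrient x group
    idx = [NUTRIENT_KEYS.index(n) for n in nutrients]
    values = np.vstack([d.values for d in dishes])[:, idx]  # dish x nutrient

    thr = thresholds.to_numpy()  # nutrient x group
    vals = values.T[:, :, None]  # nutrient x dish x 1
    unknown_mask = np.isnan(vals)  # same for every group
    with np.errstate(invalid="ignore"):
        meets = (vals >= thr[:, None, :]).sum(axis=1)  # nutrient x group; NaN compares False
    known = (~unknown_mask).sum(axis=1).astype(float)  # nutrient x 1 broadcast
    known = np.broadcast_to(known, meets.shape).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(known > 0, 100.0 * meets / known, np.nan)

    unknown_counts = np.broadcast_to(
        unknown_mask.sum(axis=1).astype(int), meets.shape
    ).copy()
    percent = pd.DataFrame(pct, index=list(nutrients), columns=thresholds.columns)
    unknown = pd.DataFrame(unknown_counts, index=list(nutrients), columns=thresholds.columns)
    notes = {"sodium_mg": SODIUM_CAUTION} if "sodium_mg" in nutrients else None
    return AdequacyMatrix(
        percent=percent, unknown=unknown, n_dishes=len(dishes), run_id=run_id, notes=notes
    )


def classify_cell(percent: float) -> str:
    """Traffic-light class of an adequacy percentage: red < 50, yellow 50–80,
    green > 80 (boundaries 50 and 80 are yellow)."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    if percent < 50.0:
        return "red"
    if percent > 80.0:
        return "green"
    return "yellow"


def headline_deficits(
    matrix: AdequacyMatrix,
    threshold: float = 50.0,
    scope: str = "all",
) -> list[str]:
    """Nutrients below *threshold* percent in every group (``scope="all"``,
    default) or in at least one group (``scope="any"``).  NaN cells (all
    dishes unknown) are ignored."""
    if scope not in ("all", "any"):
        raise ValueError(f"scope must be 'all' or 'any', got {scope!r}")
    out = []
    for nutrient in matrix.percent.index:
        cells = matrix.percent.loc[nutrient].dropna()
        if cells.empty:
            continue
        below = cells < threshold
        if (scope == "all" and below.all()) or (scope == "any" and below.any()):
            out.append(nutrient)
    return out
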