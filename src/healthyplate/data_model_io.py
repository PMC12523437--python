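"""Domain types and tabular I/O for the Healthy Eating Plate assessment pipeline.

The pipeline tracks a fixed panel of 22 nutrients per food (per 100 g edible
portion), participant serving records across six plate diameters, and a
lunchtime dietary-reference-intake (DRI) table over 14 sex x age demographic
groups.  All files are plain UTF-8 CSV with a mandatory header row, comma
separators and "." decimals.

Missing nutrient values are a first-class state, distinct from zero: a blank
cell parses to the missing marker (NaN internally) and missing propagates
through addition and scaling, so downstream adequacy scoring can distinguish
"fails the requirement" from "cannot be assessed".
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("healthyplate")

# --------------------------------------------------------------------------
# Canonical nutrient panel
# --------------------------------------------------------------------------

#: (key, human label, canonical unit).  Potassium is carried in grams: the
#: source lunchtime reference table prints 1.71 under an "mg" heading, which is
#: physiologically implausible as milligrams; the value is stored as printed
#: and treated as grams throughout (see docs/methods.md).
NUTRIENT_DEFS: tuple[tuple[str, str, str], ...] = (
    ("energy_kcal", "Energy", "kcal"),
    ("protein_g", "Proteins", "g"),
    ("fat_g", "Fat", "g"),
    ("carbohydrate_g", "Carbohydrates", "g"),
    ("fibre_g", "Fibre", "g"),
    ("calcium_mg", "Ca", "mg"),
    ("magnesium_mg", "Mg", "mg"),
    ("phosphorus_mg", "P", "mg"),
    ("sodium_mg", "Na", "mg"),
    ("potassium_g", "K", "g"),
    ("iron_mg", "Fe", "mg"),
    ("zinc_mg", "Zn", "mg"),
    ("thiamine_mg", "Thiamine", "mg"),
    ("riboflavin_mg", "Riboflavin", "mg"),
    ("niacin_mg_ne", "Niacin", "mg NE"),
    ("vitamin_b6_mg", "Vitamin B6", "mg"),
    ("folic_acid_ug", "Folic Acid", "ug"),
    ("vitamin_b12_ug", "Vitamin B12", "ug"),
    ("ascorbic_acid_mg", "Ascorbic Acid", "mg"),
    ("vitamin_a_ug_re", "Vitamin A", "ug RE"),
    ("vitamin_d_ug", "Vitamin D", "ug"),
    ("vitamin_e_mg_ate", "Vitamin E", "mg alpha-TE"),
)

NUTRIENT_KEYS: tuple[str, ...] = tuple(d[0] for d in NUTRIENT_DEFS)
NUTRIENT_UNITS: dict[str, str] = {k: u for k, _, u in NUTRIENT_DEFS}
NUTRIENT_LABELS: dict[str, str] = {k: lbl for k, lbl, _ in NUTRIENT_DEFS}
_NUTRIENT_INDEX: dict[str, int] = {k: i for i, k in enumerate(NUTRIENT_KEYS)}
N_NUTRIENTS = len(NUTRIENT_KEYS)

#: Nutrients tracked but excluded from adequacy scoring by default: vitamin D
#: coverage in food-composition databases is too patchy for a fair comparison
#: and would be systematically underestimated.
ADEQUACY_EXCLUDED_DEFAULT: tuple[str, ...] = ("vitamin_d_ug",)

FOOD_GROUPS: tuple[str, ...] = ("protein", "grain", "vegetable", "fruit")

SEXES: tuple[str, ...] = ("female", "male")
AGE_BANDS: tuple[str, ...] = ("14-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70+")


class SchemaError(ValueError):
    """A required column or field is absent or malformed."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


# --------------------------------------------------------------------------
# NutrientVector
# --------------------------------------------------------------------------


class NutrientVector:
    """Amounts of the 22 tracked nutrients, with NaN marking *missing*.

    Supports component-wise addition and scalar scaling.  Missing values
    propagate: ``missing + x = missing`` and ``missing * k = missing``.
    Non-missing amounts must be finite and non-negative.
    """

    __slots__ = ("_values",)

    def __init__(self, values: np.ndarray | Sequence[float]):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (N_NUTRIENTS,):
            raise ValidationError(
                f"expected {N_NUTRIENTS} nutrient amounts, got shape {arr.shape}"
            )
        finite = np.isfinite(arr)
        if np.any(arr[finite] < 0):
            bad = [NUTRIENT_KEYS[i] for i in np.where(finite & (arr < 0))[0]]
            raise ValidationError(f"negative nutrient amounts: {bad}")
        if np.any(np.isinf(arr)):
            raise ValidationError("nutrient amounts must be finite or missing (NaN)")
        self._values = arr.copy()
        self._values.setflags(write=False)

    # construction ---------------------------------------------------------

    @classmethod
    def zero(cls) -> "NutrientVector":
        return cls(np.zeros(N_NUTRIENTS))

    @classmethod
    def from_dict(
        cls, mapping: Mapping[str, float], *, absent: str = "missing"
    ) -> "NutrientVector":
        """Build from a key -> amount mapping.

        Keys absent from *mapping* become missing (``absent="missing"``) or
        zero (``absent="zero"``).  Unknown keys raise :class:`SchemaError`.
        """
        unknown = set(mapping) - set(NUTRIENT_KEYS)
        if unknown:
            raise SchemaError(f"unknown nutrient keys: {sorted(unknown)}")
        fill = math.nan if absent == "missing" else 0.0
        arr = np.full(N_NUTRIENTS, fill)
        for key, val in mapping.items():
            arr[_NUTRIENT_INDEX[key]] = val
        return cls(arr)

    # access ---------------------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        """Read-only array of amounts in canonical nutrient order (NaN = missing)."""
        return self._values

    def __getitem__(self, key: str) -> float:
        return float(self._values[_NUTRIENT_INDEX[key]])

    def is_missing(self, key: str) -> bool:
        return math.isnan(self[key])

    def to_dict(self, *, drop_missing: bool = False) -> dict[str, float]:
        out = {k: float(v) for k, v in zip(NUTRIENT_KEYS, self._values)}
        if drop_missing:
            out = {k: v for k, v in out.items() if not math.isnan(v)}
        return out

    # arithmetic -----------------------------------------------------------

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, NutrientVector):
            return NotImplemented
        return NutrientVector(self._values + other._values)

    def scale(self, k: float) -> "NutrientVector":
        if k < 0:
            raise ValidationError("scale factor must be non-negative")
        return NutrientVector(self._values * k)

    def __mul__(self, k: float) -> "NutrientVector":
        return self.scale(k)

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NutrientVector):
            return NotImplemented
        a, b = self._values, other._values
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))

    def allclose(self, other: "NutrientVector", *, rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self._values, other._values, rtol=rtol, atol=atol, equal_nan=True))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        shown = {k: round(v, 4) for k, v in self.to_dict(drop_missing=True).items()}
        return f"NutrientVector({shown})"


# --------------------------------------------------------------------------
# Foods, servings, plates, demographics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FoodItem:
    """An ingredient with plate-sector membership and per-100 g composition."""

    id: str
    name: str
    group: str
    composition: NutrientVector
    retention_profile: str | None = None

    def __post_init__(self) -> None:
        if self.group not in FOOD_GROUPS:
            raise ValidationError(
                f"food {self.id!r}: group {self.group!r} not in {FOOD_GROUPS}"
            )


@dataclass(frozen=True)
class ServingRecord:
    """One participant's served weight of one food on one plate diameter."""

    participant_id: str
    sex: str
    diameter_cm: float
    food_id: str
    weight_g: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.weight_g > 0:
            raise ValidationError(f"weight_g must be > 0, got {self.weight_g}")


@dataclass(frozen=True)
class PlateSpec:
    """Plate diameters and the angular split of the four food sectors.

    The default sector fractions follow the plate graphic's visual proportions
    (half the plate for produce, split 30/20 between vegetables and fruit; the
    other half split evenly between grains and protein); they are configurable
    because the source graphic prints no angles.
    """

    diameters_cm: tuple[float, ...] = (17.0, 20.0, 23.0, 26.0, 29.0, 32.0)
    reference_diameter_cm: float = 17.0
    sector_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "vegetable": 0.30,
            "fruit": 0.20,
            "grain": 0.25,
            "protein": 0.25,
        }
    )

    def __post_init__(self) -> None:
        if self.reference_diameter_cm not in self.diameters_cm:
            raise ValidationError("reference diameter must be one of the plate diameters")
        if set(self.sector_fractions) != set(FOOD_GROUPS):
            raise ValidationError(f"sector_fractions must cover exactly {FOOD_GROUPS}")
        total = sum(self.sector_fractions.values())
        if any(f <= 0 for f in self.sector_fractions.values()) or abs(total - 1.0) > 1e-9:
            raise ValidationError("sector fractions must be positive and sum to 1")

    @property
    def max_diameter_cm(self) -> float:
        return max(self.diameters_cm)


@dataclass(frozen=True)
class DemographicGroup:
    sex: str
    age_band: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}")
        if self.age_band not in AGE_BANDS:
            raise ValidationError(f"age_band must be one of {AGE_BANDS}")

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.age_band}"

    @classmethod
    def from_label(cls, label: str) -> "DemographicGroup":
        sex, _, band = label.partition("_")
        return cls(sex=sex, age_band=band)


#: The full sex x age cross: 14 demographic groups, women first as in the
#: reference table layout.
ALL_GROUPS: tuple[DemographicGroup, ...] = tuple(
    DemographicGroup(sex, band) for sex in SEXES for band in AGE_BANDS
)
GROUP_LABELS: tuple[str, ...] = tuple(g.label for g in ALL_GROUPS)


@dataclass(frozen=True)
class Dish:
    """A composed plate: ingredient weights, optionally the plate it was built on."""

    components: tuple[tuple[str, float], ...]
    diameter_cm: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        ids = [fid for fid, _ in self.components]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"dish {self.label!r}: duplicate food ids")
        if any(w <= 0 for _, w in self.components):
            raise ValidationError(f"dish {self.label!r}: component weights must be > 0")


# --------------------------------------------------------------------------
# Lunchtime DRI table
# --------------------------------------------------------------------------


class LunchDRITable:
    """Lunchtime reference intakes per nutrient per demographic group.

    Wraps a nutrient x group DataFrame (rows in canonical nutrient order,
    columns in canonical group order) plus a per-table provenance flag:
    ``"given"`` when read directly from a lunchtime table, or
    ``"derived-from-daily"`` when built as daily DRI x meal fraction.
    """

    def __init__(self, table: pd.DataFrame, provenance: str = "given"):
        missing_groups = [g for g in GROUP_LABELS if g not in table.columns]
        if missing_groups:
            raise SchemaError(f"DRI table missing group columns: {missing_groups}")
        unknown_nutrients = [n for n in table.index if n not in NUTRIENT_KEYS]
        if unknown_nutrients:
            raise SchemaError(f"DRI table has unknown nutrients: {unknown_nutrients}")
        ordered = table.loc[[n for n in NUTRIENT_KEYS if n in table.index], list(GROUP_LABELS)]
        vals = ordered.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValidationError("all DRI amounts must be finite and > 0")
        if provenance not in ("given", "derived-from-daily"):
            raise ValidationError(f"unknown provenance {provenance!r}")
        self._table = ordered
        self.provenance = provenance

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def nutrients(self) -> tuple[str, ...]:
        return tuple(self._table.index)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self._table.columns)

    def get(self, group: DemographicGroup | str, nutrient: str) -> float:
        label = group.label if isinstance(group, DemographicGroup) else group
        if nutrient not in self._table.index:
            raise KeyError(f"nutrient {nutrient!r} not in DRI table")
        return float(self._table.at[nutrient, label])

    def thresholds(self, nutrients: Sequence[str] | None = None) -> pd.DataFrame:
        """Nutrient x group threshold matrix restricted to *nutrients*."""
        if nutrients is None:
            return self.table
        missing = [n for n in nutrients if n not in self._table.index]
        if missing:
            raise KeyError(f"nutrients not in DRI table: {missing}")
        return self._table.loc[list(nutrients)].copy()


# --------------------------------------------------------------------------
# Participant sheets and validation
# --------------------------------------------------------------------------


@dataclass
class ParticipantSheet:
    """Raw per-participant data sheet: one weight cell per (food, diameter).

    ``weights`` maps ``(food_id, diameter_cm)`` to grams; a missing cell may be
    absent from the mapping or present as ``None``.  ``submitted=False`` models
    a participant who declined, ``corrupted=True`` an unreadable file.
    """

    participant_id: str
    sex: str | None
    weights: dict[tuple[str, float], float | None] = field(default_factory=dict)
    submitted: bool = True
    corrupted: bool = False


EXCLUSION_REASONS: tuple[str, ...] = (
    "not_submitted",
    "corrupted",
    "missing_ingredient",
    "missing_sex",
    "incomplete_largest_plate",
)


@dataclass(frozen=True)
class ValidationReport:
    n_submitted: int
    n_valid: int
    exclusions: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.n_valid != self.n_submitted - len(self.exclusions):
            raise ValidationError("n_valid must equal n_submitted - |exclusions|")
        bad = [r for _, r in self.exclusions if r not in EXCLUSION_REASONS]
        if bad:
            raise ValidationError(f"unknown exclusion reasons: {bad}")


def validate_serving_sheets(
    sheets: Iterable[ParticipantSheet],
    plate: PlateSpec,
    expected_foods: Sequence[str] | None = None,
) -> ValidationReport:
    """Apply the closed exclusion rules to raw participant sheets.

    A sheet is excluded (first matching rule wins) if the participant did not
    submit it, the file was corrupted, any expected food is entirely omitted,
    the sex field is blank, or any weight is missing for the largest plate
    diameter.  Every remaining sheet counts as valid.  *expected_foods*
    defaults to the union of foods seen across all readable sheets.
    """
    sheets = list(sheets)
    if expected_foods is None:
        seen: set[str] = set()
        for sh in sheets:
            if sh.submitted and not sh.corrupted:
                seen.update(fid for fid, _ in sh.weights)
        expected_foods = sorted(seen)
    largest = plate.max_diameter_cm

    exclusions: list[tuple[str, str]] = []
    for sh in sheets:
        reason = None
        if not sh.submitted:
            reason = "not_submitted"
        elif sh.corrupted:
            reason = "corrupted"
        else:
            foods_present = {fid for (fid, _), w in sh.weights.items() if w is not None}
            if any(f not in foods_present for f in expected_foods):
                reason = "missing_ingredient"
            elif sh.sex is None or sh.sex == "":
                reason = "missing_sex"
            elif any(
                sh.weights.get((f, largest)) is None for f in expected_foods
            ):
                reason = "incomplete_largest_plate"
        if reason is not None:
            exclusions.append((sh.participant_id, reason))

    return ValidationReport(
        n_submitted=len(sheets),
        n_valid=len(sheets) - len(exclusions),
        exclusions=tuple(exclusions),
    )


# --------------------------------------------------------------------------
# CSV readers / writers
# --------------------------------------------------------------------------

_FOOD_META_COLUMNS = ("id", "name", "group")


def read_food_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[FoodItem]:
    """Read a per-100 g food-composition CSV into validated :class:`FoodItem`s.

    The file must carry ``id``, ``name`` and ``group`` columns plus nutrient
    columns.  By default nutrient columns are named by canonical key (e.g.
    ``energy_kcal``) in canonical units; *schema* may map file column names to
    canonical keys for files using other headings.  Blank cells become the
    missing marker (with a logged warning), never zero.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("food table %s is empty", path)
        return []
    for col in _FOOD_META_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"food table missing required column {col!r}")

    colmap: dict[str, str] = {}
    for col in df.columns:
        if col in _FOOD_META_COLUMNS:
            continue
        key = schema.get(col) if schema else col
        if key is None:
            continue  # column explicitly ignored by the schema
        if key not in NUTRIENT_KEYS:
            raise SchemaError(f"column {col!r} maps to unknown nutrient {key!r}")
        colmap[col] = key

    foods: list[FoodItem] = []
    for row_no, row in df.iterrows():
        amounts: dict[str, float] = {}
        for col, key in colmap.items():
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                logger.warning(
                    "food %s: nutrient %s unparseable/blank, marked missing",
                    row["id"], key,
                )
                continue
            try:
                val = float(raw)
            except ValueError:
                logger.warning(
                    "food %s: nutrient %s unparseable (%r), marked missing",
                    row["id"], key, raw,
                )
                continue
            if val < 0:
                raise ValidationError(
                    f"row {row_no} (food {row['id']!r}): negative {key} = {val}"
                )
            amounts[key] = val
        foods.append(
            FoodItem(
                id=str(row["id"]),
                name=str(row["name"]),
                group=str(row["group"]),
                composition=NutrientVector.from_dict(amounts, absent="missing"),
            )
        )
    if not foods:
        logger.warning("food table %s contains no rows", path)
    return foods


def write_food_table(foods: Sequence[FoodItem], path: str | Path) -> None:
    """Write foods as CSV (canonical nutrient columns; missing -> blank cell)."""
    rows = []
    for f in foods:
        row: dict[str, object] = {"id": f.id, "name": f.name, "group": f.group}
        for key, val in f.composition.to_dict().items():
            row[key] = "" if math.isnan(val) else repr(val)
        rows.append(row)
    cols = list(_FOOD_META_COLUMNS) + list(NUTRIENT_KEYS)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_lunch_dri(path: str | Path) -> LunchDRITable:
    """Read a lunchtime DRI CSV: ``nutrient`` column plus the 14 group columns."""
    df = pd.read_csv(path)
    if "nutrient" not in df.columns:
        raise SchemaError("DRI table missing 'nutrient' column")
    missing = [g for g in GROUP_LABELS if g not in df.columns]
    if missing:
        raise SchemaError(f"DRI table missing group columns: {missing}")
    df = df.set_index("nutrient")
    for nutrient in df.index:
        for group in GROUP_LABELS:
            try:
                float(df.at[nutrient, group])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"non-numeric DRI cell at ({nutrient}, {group}): "
                    f"{df.at[nutrient, group]!r}"
                ) from None
    return LunchDRITable(df[list(GROUP_LABELS)].astype(float), provenance="given")


def write_lunch_dri(dri: LunchDRITable, path: str | Path) -> None:
    out = dri.table
    out.insert(0, "nutrient", out.index)
    out.to_csv(path, index=False)


def load_packaged_lunch_dri() -> LunchDRITable:
    """Load the lunchtime DRI table that ships with the package (14 groups,
    22 nutrients, Spanish adult reference values scaled to the midday meal)."""
    ref = resources.files("healthyplate").joinpath("data/lunch_dri.csv")
    with resources.as_file(ref) as p:
        return read_lunch_dri(p)


def read_servings(path: str | Path) -> list[ServingRecord]:
    df = pd.read_csv(path)
    required = ("participant_id", "sex", "diameter_cm", "food_id", "weight_g")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"serving file missing columns: {missing}")
    return [
        ServingRecord(
            participant_id=str(r.participant_id),
            sex=str(r.sex),
            diameter_cm=float(r.diameter_cm),
            food_id=str(r.food_id),
            weight_g=float(r.weight_g),
        )
        for r in df.itertuples(index=False)
    ]


def write_servings(records: Sequence[ServingRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "sex", "diameter_cm", "food_id", "weight_g"])
        for r in records:
            w.writerow([r.participant_id, r.sex, repr(r.diameter_cm), r.food_id, repr(r.weight_g)])


def read_dishes(path: str | Path) -> list[Dish]:
    """Read dish compositions: columns label, food_id, weight_g [, diameter_cm]."""
    df = pd.read_csv(path)
    required = ("label", "food_id", "weight_g")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"dish file missing columns: {missing}")
    dishes = []
    for label, grp in df.groupby("label", sort=False):
        diam = None
        if "diameter_cm" in grp.columns:
            vals = grp["diameter_cm"].dropna().unique()
            if len(vals) == 1:
                diam = float(vals[0])
        dishes.append(
            Dish(
                components=tuple(
                    (str(r.food_id), float(r.weight_g)) for r in grp.itertuples(index=False)
                ),
                diameter_cm=diam,
                label=str(label),
            )
        )
    return dishes


def write_dishes(dishes: Sequence[Dish], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "food_id", "weight_g", "diameter_cm"])
        for d in dishes:
            for fid, wt in d.components:
                w.writerow([d.label, fid, repr(wt), "" if d.diameter_cm is None else d.diameter_cm])


# --------------------------------------------------------------------------
# Adequacy report output
# --------------------------------------------------------------------------


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves rounding up (display convention
    of the adequacy tables: 7.94 % prints as 8, 49.5 % as 50)."""
    return int(math.floor(x + 0.5))


def write_adequacy_report(matrix, path: str | Path) -> None:
    """Serialize an adequacy matrix as CSV: one nutrient per row, the 14 group
    columns as round-half-up integer percentages, then a parallel set of
    ``<group>_class`` traffic-light columns."""
    from .adequacy_assessment import classify_cell  # local import avoids a cycle

    pct = matrix.percent
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        groups = list(pct.columns)
        w.writerow(["nutrient"] + groups + [f"{g}_class" for g in groups])
        for nutrient in pct.index:
            row = [nutrient]
            cells = [pct.at[nutrient, g] for g in groups]
            row += ["" if math.isnan(c) else round_half_up(c) for c in cells]
            row += ["" if math.isnan(c) else classify_cell(c) for c in cells]
            w.writerow(row)
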