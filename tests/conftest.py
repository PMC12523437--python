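import math

import pytest

from healthyplate import (
    FoodItem,
    NutrientVector,
    ParticipantSheet,
    PlateSpec,
    load_packaged_lunch_dri,
)


@pytest.fixture(scope="session")
def dri():
    return load_packaged_lunch_dri()


@pytest.fixture(scope="session")
def plate():
    return PlateSpec()


def make_food(fid, group, **amounts):
    return FoodItem(
        id=fid,
        name=fid.replace("_", " "),
        group=group,
        composition=NutrientVector.from_dict(amounts, absent="zero"),
    )


@pytest.fixture
def hake():
    return make_food(
        "hake", "protein",
        energy_kcal=92, protein_g=17.8, fat_g=2.2, calcium_mg=33,
        iron_mg=1.0, vitamin_b12_ug=1.1, sodium_mg=101, potassium_g=0.29,
    )


@pytest.fixture
def simple_foods():
    """One food per plate sector with round-number compositions."""
    return [
        make_food("chicken", "protein", energy_kcal=120, protein_g=22, iron_mg=1.0,
                  zinc_mg=1.5, vitamin_b12_ug=0.8),
        make_food("rice", "grain", energy_kcal=130, carbohydrate_g=28, protein_g=2.5,
                  thiamine_mg=0.05, fibre_g=0.6),
        make_food("tomato", "vegetable", energy_kcal=20, carbohydrate_g=3.5,
                  ascorbic_acid_mg=14, folic_acid_ug=20, potassium_g=0.25),
        make_food("banana", "fruit", energy_kcal=90, carbohydrate_g=20,
                  ascorbic_acid_mg=10, potassium_g=0.35, vitamin_b6_mg=0.35),
    ]


def complete_sheet(pid, foods, plate, sex="female", weight=50.0):
    """A fully filled participant sheet (one weight per food per diameter)."""
    return ParticipantSheet(
        participant_id=pid,
        sex=sex,
        weights={(f, d): weight for f in foods for d in plate.diameters_cm},
    )


def nan_equal(a, b, tol=1e-9):
    return (math.isnan(a) and math.isnan(b)) or abs(a - b) <= tol
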