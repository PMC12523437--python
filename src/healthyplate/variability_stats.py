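"""Intersubject variability (CV) tables, the two-factor fixed-effects linear
model with Type III sums of squares, and report assembly.

The coefficient of variation per (food, diameter) cell is the sample standard
deviation (n-1 denominator) across participants divided by the cell mean,
times 100.  The linear model is ``weight ~ food * size`` with both factors
fixed and categorical; Type III sums of squares are computed under sum-to-zero
contrasts (the convention under which Type III is well-defined), each term's
SS being its marginal contribution given all other terms.  Model assumptions
(normal residuals, homoscedasticity) are reported as diagnostics but never
block the computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .data_model_io import PlateSpec, ServingRecord
from .plate_geometry import BiasTable

__all__ = [
    "CVTable",
    "AnovaTable",
    "cv_table",
    "two_way_anova",
    "build_report",
]


@dataclass
class CVTable:
    """Per-(food, diameter) weight variability across participants.

    ``data`` holds columns ``food_id``, ``diameter_cm``, ``n``, ``mean_g``,
    ``sd_g``, ``cv_pct``; cells with n < 2 have an undefined (NaN) SD and CV.
    """

    data: pd.DataFrame
    run_id: str | None = None

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot(index="food_id", columns="diameter_cm", values="cv_pct")

    def get(self, food_id: str, diameter_cm: float) -> float:
        sel = self.data[
            (self.data.food_id == food_id) & (self.data.diameter_cm == diameter_cm)
        ]
        if sel.empty:
            raise KeyError((food_id, diameter_cm))
        return float(sel.cv_pct.iloc[0])


def cv_table(records: Sequence[ServingRecord], run_id: str | None = None) -> CVTable:
    """Coefficient of variation (SD/mean x 100) per food and plate diameter."""
    df = pd.DataFrame(
        {
            "food_id": [r.food_id for r in records],
            "diameter_cm": [r.diameter_cm for r in records],
            "weight_g": [r.weight_g for r in records],
        }
    )
    if df.empty:
        raise ValueError("no serving records")
    grouped = df.groupby(["food_id", "diameter_cm"])["weight_g"]
    out = grouped.agg(n="count", mean_g="mean", sd_g=lambda x: x.std(ddof=1)).reset_index()
    out["cv_pct"] = out.sd_g / out.mean_g * 100.0
    out.loc[out.n < 2, ["sd_g", "cv_pct"]] = np.nan
    return CVTable(data=out, run_id=run_id)


@dataclass
class AnovaTable:
    """Type III ANOVA decomposition for the food x size fixed-effects model.

    ``table`` is indexed by term (``size``, ``food``, ``size:food``,
    ``residual``) with columns ``sum_sq``, ``df``, ``F``, ``p``.
    ``residual_diagnostics`` reports distributional summaries of the residuals.
    """

    table: pd.DataFrame
    response: str
    n_obs: int
    residual_diagnostics: dict[str, float]
    run_id: str | None = None

    def p_value(self, term: str) -> float:
        return float(self.table.at[term, "p"])

    def sum_sq(self, term: str) -> float:
        return float(self.table.at[term, "sum_sq"])


def _bias_response(records: Sequence[ServingRecord], plate: PlateSpec) -> pd.DataFrame:
    """Per-record percent bias relative to each participant's own reference serving."""
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "food": [r.food_id for r in records],
            "size": [r.diameter_cm for r in records],
            "weight_g": [r.weight_g for r in records],
        }
    )
    d_ref = plate.reference_diameter_cm
    ref = (
        df[df["size"] == d_ref]
        .groupby(["participant_id", "food"])["weight_g"]
        .mean()
        .rename("ref_weight_g")
    )
    merged = df.merge(ref, on=["participant_id", "food"], how="inner")
    expected = merged.ref_weight_g * (merged["size"] / d_ref) ** 2
    merged["y"] = (merged.weight_g - expected) / expected * 100.0
    return merged


def two_way_anova(
    records: Sequence[ServingRecord],
    response: str = "weight",
    plate: PlateSpec | None = None,
    run_id: str | None = None,
) -> AnovaTable:
    """Fixed-effects two-factor linear model with interaction, Type III SS.

    *response* is ``"weight"`` (raw served grams) or ``"bias"`` (percent
    deviation from each participant's area-scaled reference expectation; needs
    *plate*).  Factors are food and plate size.  Type III sums of squares are
    obtained by dropping each term from the full model under sum-to-zero
    contrasts; F and p come from the F distribution.
    """
    if response == "weight":
        df = pd.DataFrame(
            {
                "food": [r.food_id for r in records],
                "size": [r.diameter_cm for r in records],
                "y": [r.weight_g for r in records],
            }
        )
    elif response == "bias":
        if plate is None:
            plate = PlateSpec()
        df = _bias_response(records, plate)
    else:
        raise ValueError(f"response must be 'weight' or 'bias', got {response!r}")

    n_food = df["food"].nunique()
    n_size = df["size"].nunique()
    if n_food < 2 or n_size < 2:
        raise ValueError(
            f"need >= 2 levels per factor (food: {n_food}, size: {n_size})"
        )
    model_rank = n_food * n_size
    if len(df) - model_rank < 1:
        raise ValueError(
            "design is saturated or rank-deficient: no residual degrees of freedom "
            f"(N={len(df)}, cells={model_rank}); aliased terms: size:food"
        )

    fit = smf.ols("y ~ C(food, Sum) * C(size, Sum)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=3)

    def _row(label: str) -> pd.Series:
        return anova.loc[label]

    rows = {
        "food": _row("C(food, Sum)"),
        "size": _row("C(size, Sum)"),
        "size:food": _row("C(food, Sum):C(size, Sum)"),
        "residual": _row("Residual"),
    }
    table = pd.DataFrame(
        {
            "sum_sq": {k: float(v["sum_sq"]) for k, v in rows.items()},
            "df": {k: int(v["df"]) for k, v in rows.items()},
            "F": {k: float(v["F"]) for k, v in rows.items()},
            "p": {k: float(v["PR(>F)"]) for k, v in rows.items()},
        }
    ).loc[["size", "food", "size:food", "residual"]]

    resid = np.asarray(fit.resid)
    diagnostics = {
        "residual_mean": float(np.mean(resid)),
        "residual_sd": float(np.std(resid, ddof=1)),
        "residual_skew": float(sps.skew(resid)),
        "residual_kurtosis": float(sps.kurtosis(resid)),
    }
    return AnovaTable(
        table=table,
        response=response,
        n_obs=len(df),
        residual_diagnostics=diagnostics,
        run_id=run_id,
    )


def null_rejection_rates(
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_participants: int = 3,
    n_foods: int = 4,
) -> dict[str, float]:
    """Monte-Carlo type-I error of the two-factor model under a pure-noise null.

    Simulates *n_reps* serving datasets with no food or plate-size effect
    (i.i.d. log-normal weights) and returns the per-term fraction of p-values
    below *alpha*, as percentages.  A well-calibrated test sits near
    100 x alpha for every term.
    """
    from .synthetic_data import generate_null_servings

    rejections = {"size": 0, "food": 0, "size:food": 0}
    for rep in range(n_reps):
        records = generate_null_servings(
            n_participants=n_participants, n_foods=n_foods, seed=seed * n_reps + rep
        )
        result = two_way_anova(records, response="weight")
        for term in rejections:
            if result.p_value(term) < alpha:
                rejections[term] += 1
    return {term: 100.0 * k / n_reps for term, k in rejections.items()}


# --------------------------------------------------------------------------
# Report assembly
# --------------------------------------------------------------------------


def _check_run_ids(sections: dict[str, object]) -> None:
    ids = {
        name: getattr(obj, "run_id")
        for name, obj in sections.items()
        if obj is not None and getattr(obj, "run_id", None) is not None
    }
    if len(set(ids.values())) > 1:
        raise ValueError(f"inconsistent run identifiers across sections: {ids}")


def build_report(
    bias: BiasTable | None = None,
    cv: CVTable | None = None,
    anova: AnovaTable | None = None,
    adequacy=None,
    outdir: str | Path = ".",
    stem: str = "report",
) -> dict[str, Path]:
    """Write a machine-readable JSON plus CSV tables for whichever sections
    are available (bias and CV per food x diameter, the ANOVA decomposition,
    and the adequacy matrix with its traffic-light classes).

    All supplied sections must carry consistent run identifiers.  Returns the
    paths written, keyed by artifact name.
    """
    from .adequacy_assessment import classify_cell

    sections = {"bias": bias, "cv": cv, "anova": anova, "adequacy": adequacy}
    _check_run_ids(sections)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    payload: dict[str, object] = {}

    if bias is not None:
        p = outdir / f"{stem}_bias.csv"
        bias.data.to_csv(p, index=False)
        paths["bias"] = p
        payload["bias"] = {
            "mode": bias.mode,
            "reference_diameter_cm": bias.reference_diameter_cm,
            "cells": bias.data.to_dict(orient="records"),
        }
    if cv is not None:
        p = outdir / f"{stem}_cv.csv"
        cv.data.to_csv(p, index=False)
        paths["cv"] = p
        payload["cv"] = {"cells": cv.data.to_dict(orient="records")}
    if anova is not None:
        p = outdir / f"{stem}_anova.csv"
        anova.table.to_csv(p)
        paths["anova"] = p
        payload["anova"] = {
            "response": anova.response,
            "n_obs": anova.n_obs,
            "terms": anova.table.to_dict(orient="index"),
            "residual_diagnostics": anova.residual_diagnostics,
        }
    if adequacy is not None:
        from .data_model_io import write_adequacy_report

        pct = adequacy.percent
        p = outdir / f"{stem}_adequacy.csv"
        write_adequacy_report(adequacy, p)
        paths["adequacy"] = p
        color_counts: dict[str, int] = {"red": 0, "yellow": 0, "green": 0}
        for val in pct.to_numpy().ravel():
            if not math.isnan(val):
                color_counts[classify_cell(float(val))] += 1
        payload["adequacy"] = {
            "n_dishes": getattr(adequacy, "n_dishes", getattr(adequacy, "n_combinations", None)),
            "percent": {n: pct.loc[n].to_dict() for n in pct.index},
            "color_counts": color_counts,
        }

    for name in sections:
        payload.setdefault(name, None)  # absent sections are explicit
    jpath = outdir / f"{stem}.json"
    with open(jpath, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=float)
    paths["json"] = jpath
    return paths
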