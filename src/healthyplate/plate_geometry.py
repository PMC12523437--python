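"""Sector-area arithmetic and serving-bias estimation across plate diameters.

A serving that fills its sector evenly with constant pile height should scale
with the sector's area, i.e. with the square of the plate diameter.  Taking
each participant's serving on the smallest (reference) plate as their personal
baseline, the expected weight on a larger plate is ``w_ref * (d/d_ref)^2`` —
the sector fraction cancels, so the extrapolation is the same for every food
group.  Bias is the percent deviation of the observed weight from this
expectation; positive bias means over-serving on larger plates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model_io import PlateSpec, ServingRecord

logger = logging.getLogger("healthyplate")


def sector_area(diameter_cm: float, fraction: float) -> float:
    """Area (cm^2) of a circular sector covering *fraction* of a plate."""
    if diameter_cm <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter_cm}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return fraction * math.pi * (diameter_cm / 2.0) ** 2


def expected_weight(w_ref_g: float, d_ref_cm: float, d_cm: float) -> float:
    """Weight expected on a *d_cm* plate given *w_ref_g* on the reference plate.

    Pure area scaling: ``w_ref * (d/d_ref)^2``.  Independent of the sector
    fraction, which cancels in the area ratio.
    """
    if w_ref_g <= 0 or d_ref_cm <= 0 or d_cm <= 0:
        raise ValueError("w_ref_g, d_ref_cm and d_cm must all be > 0")
    return w_ref_g * (d_cm / d_ref_cm) ** 2


def bias_percent(observed_g: float, expected_g: float) -> float:
    """Percent deviation of observed from expected weight (over-serving > 0)."""
    if expected_g <= 0:
        raise ValueError(f"expected weight must be > 0, got {expected_g}")
    return (observed_g - expected_g) / expected_g * 100.0


@dataclass
class BiasTable:
    """Mean serving bias per (food, diameter).

    ``data`` is a long-form frame with columns ``food_id``, ``diameter_cm``,
    ``bias_pct`` (mean percent bias), ``observed_mean_g``, ``expected_mean_g``
    and ``n``.  Bias at the reference diameter is identically 0.
    """

    data: pd.DataFrame
    mode: str
    reference_diameter_cm: float
    run_id: str | None = None

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot(index="food_id", columns="diameter_cm", values="bias_pct")

    def get(self, food_id: str, diameter_cm: float) -> float:
        sel = self.data[
            (self.data.food_id == food_id) & (self.data.diameter_cm == diameter_cm)
        ]
        if sel.empty:
            raise KeyError((food_id, diameter_cm))
        return float(sel.bias_pct.iloc[0])


def bias_table(
    records: Sequence[ServingRecord],
    plate: PlateSpec,
    mode: str = "per_participant",
    run_id: str | None = None,
) -> BiasTable:
    """Estimate mean bias per (food, diameter) from serving records.

    ``per_participant`` (default) extrapolates each participant's expected
    weights from their own reference-diameter serving and averages the
    per-participant observed/expected ratios on the log scale (geometric
    mean) — each subject filled the smallest plate first, so their own 17 cm
    serving is the natural baseline, but since that noisy serving sits in the
    denominator of every ratio, an arithmetic mean of ratios would be inflated
    by E[1/eps] = 1 + CV^2; the geometric mean is free of that distortion.
    ``pooled`` extrapolates from the across-participant mean reference weight
    instead and compares it with the across-participant mean observed weight.
    Participants lacking a reference serving for a food are skipped with a
    warning.
    """
    if mode not in ("per_participant", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    d_ref = plate.reference_diameter_cm

    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "diameter_cm": [r.diameter_cm for r in records],
            "food_id": [r.food_id for r in records],
            "weight_g": [r.weight_g for r in records],
        }
    )
    if df.empty:
        raise ValueError("no serving records")

    ref = (
        df[df.diameter_cm == d_ref]
        .groupby(["participant_id", "food_id"])["weight_g"]
        .mean()
        .rename("ref_weight_g")
    )
    rows: list[dict[str, object]] = []

    if mode == "per_participant":
        merged = df.merge(ref, on=["participant_id", "food_id"], how="left")
        n_missing = merged.ref_weight_g.isna().sum()
        if n_missing:
            logger.warning(
                "%d serving records skipped: participant lacks a reference-diameter serving",
                n_missing,
            )
            merged = merged.dropna(subset=["ref_weight_g"])
        merged["expected_g"] = merged.ref_weight_g * (merged.diameter_cm / d_ref) ** 2
        merged["log_ratio"] = np.log(merged.weight_g / merged.expected_g)
        for (fid, d), grp in merged.groupby(["food_id", "diameter_cm"]):
            rows.append(
                {
                    "food_id": fid,
                    "diameter_cm": float(d),
                    "bias_pct": float((math.exp(grp.log_ratio.mean()) - 1.0) * 100.0),
                    "observed_mean_g": float(grp.weight_g.mean()),
                    "expected_mean_g": float(grp.expected_g.mean()),
                    "n": int(len(grp)),
                }
            )
    else:  # pooled
        pooled_ref = ref.groupby("food_id").mean()
        for (fid, d), grp in df.groupby(["food_id", "diameter_cm"]):
            if fid not in pooled_ref.index:
                logger.warning("food %s has no reference-diameter servings; skipped", fid)
                continue
            exp = expected_weight(float(pooled_ref[fid]), d_ref, float(d))
            obs = float(grp.weight_g.mean())
            rows.append(
                {
                    "food_id": fid,
                    "diameter_cm": float(d),
                    "bias_pct": bias_percent(obs, exp),
                    "observed_mean_g": obs,
                    "expected_mean_g": exp,
                    "n": int(len(grp)),
                }
            )

    out = pd.DataFrame(rows).sort_values(["food_id", "diameter_cm"]).reset_index(drop=True)
    # exact zero at the reference diameter (guard against float round-off)
    out.loc[out.diameter_cm == d_ref, "bias_pct"] = 0.0
    return BiasTable(data=out, mode=mode, reference_diameter_cm=d_ref, run_id=run_id)
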