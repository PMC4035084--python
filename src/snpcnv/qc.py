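"""Phenotype quality control: BMI computation, exclusion rules, bodyweight classes.

Exclusion bounds follow the study protocol: subjects with missing height or
weight, height < 1.4 or > 2.0 m, weight < 38 or > 166 kg, or BMI < 14.5 or
> 60 kg/m^2 are removed (data-entry errors or suggestive of eating/syndromic
disorders).  Bounds are strict, so boundary values are retained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ValidationError

logger = logging.getLogger("snpcnv")

HEIGHT_RANGE = (1.4, 2.0)     # meters
WEIGHT_RANGE = (38.0, 166.0)  # kilograms
BMI_RANGE = (14.5, 60.0)      # kg/m^2

# bodyweight classes nest: class III => II => I => overweight
BMI_CLASS_THRESHOLDS = {
    "overweight": 25.0,
    "obese_I": 30.0,
    "obese_II": 35.0,
    "obese_III": 40.0,
}
CATEGORY_LABELS = ["under/normal", "overweight", "obese I", "obese II", "obese III"]


def compute_bmi(height_m: float, weight_kg: float) -> float:
    """BMI = weight / height^2 (kg/m^2). Raises on non-positive height."""
    if not height_m > 0:
        raise ValidationError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


def classify_bodyweight(bmi: float) -> str:
    """Clinical bodyweight category by the greatest satisfied threshold (inclusive)."""
    if bmi >= 40.0:
        return "obese III"
    if bmi >= 35.0:
        return "obese II"
    if bmi >= 30.0:
        return "obese I"
    if bmi >= 25.0:
        return "overweight"
    return "under/normal"


def bodyweight_indicators(bmi) -> pd.DataFrame:
    """Cumulative binary indicators for each nested class.

    Returns columns overweight (>=25), obese_I (>=30), obese_II (>=35),
    obese_III (>=40); monotone by construction.
    """
    bmi = np.asarray(bmi, dtype=float)
    return pd.DataFrame({
        name: (bmi >= thr).astype(int)
        for name, thr in BMI_CLASS_THRESHOLDS.items()
    })


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the QC exclusion rules to a phenotype table.

    Requires ``height`` and ``weight`` columns.  BMI is recomputed from
    height/weight even when a ``bmi`` column is supplied; a mismatch above
    0.1 kg/m^2 is logged.  Returns (retained table with a fresh ``bmi`` and
    ``bodyweight_class`` column, exclusion log with one row per removal).

    Idempotent: re-applying to the retained table removes nothing.
    """
    records = records.copy()
    log_rows: list[dict] = []

    height = pd.to_numeric(records.get("height"), errors="coerce")
    weight = pd.to_numeric(records.get("weight"), errors="coerce")
    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = weight / height**2

    if "bmi" in records.columns:
        supplied = pd.to_numeric(records["bmi"], errors="coerce")
        mismatch = (supplied - bmi).abs() > 0.1
        for sid in records.loc[mismatch.fillna(False), "subject_id"]:
            logger.warning("subject %s: supplied BMI differs from recomputed by > 0.1", sid)

    rules = [
        ("missing_height_or_weight", height.isna() | weight.isna()),
        ("height_out_of_range", (height < HEIGHT_RANGE[0]) | (height > HEIGHT_RANGE[1])),
        ("weight_out_of_range", (weight < WEIGHT_RANGE[0]) | (weight > WEIGHT_RANGE[1])),
        ("bmi_out_of_range", (bmi < BMI_RANGE[0]) | (bmi > BMI_RANGE[1])),
    ]
    excluded = pd.Series(False, index=records.index)
    for rule, mask in rules:
        mask = mask.fillna(False) & ~excluded  # first triggering rule wins
        for idx in records.index[mask]:
            log_rows.append({
                "subject_id": records.at[idx, "subject_id"],
                "rule": rule,
                "height": height.at[idx],
                "weight": weight.at[idx],
                "bmi": bmi.at[idx],
            })
        excluded |= mask

    retained = records.loc[~excluded].copy()
    retained["bmi"] = bmi.loc[~excluded]
    retained["bodyweight_class"] = [classify_bodyweight(b) for b in retained["bmi"]]
    log = pd.DataFrame(log_rows, columns=["subject_id", "rule", "height", "weight", "bmi"])
    logger.info("phenotype QC: %d in, %d retained, %d excluded",
                len(records), len(retained), len(log))
    return retained, log
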