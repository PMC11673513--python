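"""Cohort phenotypes and the two-factor grouping scheme.

Subjects carry a continuous body-mass index (BMI, kg/m^2) and a continuous
physical-activity score (IPAQ, MET-min/week).  Each is dichotomized at a
fixed cutoff -- BMI at 25 kg/m^2 (lean vs overweight/obese) and IPAQ at
3066 MET-min/week (low vs high activity) -- and the cross of the two binary
factors yields the four interaction cells of the unbalanced 2x2 design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: BMI dichotomization cutoff, kg/m^2.  Values < 25 are lean, >= 25 obese.
BMI_CUTOFF: float = 25.0

#: IPAQ dichotomization cutoff, MET-min/week.  <= 3066 low, > 3066 high.
IPAQ_CUTOFF: float = 3066.0

LEAN = "lean"
OBESE = "overweight_obese"
LOW = "low"
HIGH = "high"

#: Canonical cell order: (bmi_class, ipaq_class) crossed, lean first.
CELLS: tuple[str, ...] = ("LeanLow", "LeanHigh", "ObeseLow", "ObeseHigh")

#: Phenotype columns summarized by descriptive group tables.
PHENOTYPE_VARIABLES: tuple[str, ...] = (
    "age",
    "body_mass",
    "height",
    "bmi_value",
    "ipaq_score",
)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "sex",
    "age",
    "body_mass",
    "height",
    "bmi_value",
    "ipaq_score",
    "bmi_class",
    "ipaq_class",
    "cell",
)


def bmi_class_of(bmi_value: float) -> str:
    """Classify a continuous BMI value at the 25 kg/m^2 cutoff."""
    return LEAN if bmi_value < BMI_CUTOFF else OBESE


def ipaq_class_of(ipaq_score: float) -> str:
    """Classify a continuous IPAQ score at the 3066 MET-min/week cutoff."""
    return LOW if ipaq_score <= IPAQ_CUTOFF else HIGH


def cell_of(bmi_value: float, ipaq_score: float) -> str:
    """Interaction cell label for a (BMI, IPAQ) pair."""
    b = "Lean" if bmi_class_of(bmi_value) == LEAN else "Obese"
    i = "Low" if ipaq_class_of(ipaq_score) == LOW else "High"
    return b + i


def classify_cohort(meta: pd.DataFrame) -> pd.DataFrame:
    """Derive ``bmi_class``, ``ipaq_class`` and ``cell`` from continuous values.

    Expects columns ``subject_id``, ``bmi_value`` and ``ipaq_score``; returns
    a copy with the three class columns (re)computed from the cutoffs.
    """
    out = meta.copy()
    out["bmi_class"] = np.where(out["bmi_value"] < BMI_CUTOFF, LEAN, OBESE)
    out["ipaq_class"] = np.where(out["ipaq_score"] <= IPAQ_CUTOFF, LOW, HIGH)
    out["cell"] = [
        cell_of(b, i) for b, i in zip(out["bmi_value"], out["ipaq_score"])
    ]
    return out


def validate_cohort(meta: pd.DataFrame) -> None:
    """Check the internal consistency of a cohort-metadata table.

    Raises ``ValueError`` when a class label disagrees with its continuous
    value under the fixed cutoffs, or when ``bmi_value`` is not
    ``body_mass / height**2`` (to 1e-9).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cohort metadata missing columns: {missing}")
    if meta["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in cohort metadata")

    recomputed = meta["body_mass"] / meta["height"] ** 2
    if not np.allclose(recomputed, meta["bmi_value"], atol=1e-9, rtol=0):
        raise ValueError("bmi_value inconsistent with body_mass / height^2")

    expect_bmi = np.where(meta["bmi_value"] < BMI_CUTOFF, LEAN, OBESE)
    if not (meta["bmi_class"] == expect_bmi).all():
        raise ValueError("bmi_class inconsistent with bmi_value cutoff")
    expect_ipaq = np.where(meta["ipaq_score"] <= IPAQ_CUTOFF, LOW, HIGH)
    if not (meta["ipaq_class"] == expect_ipaq).all():
        raise ValueError("ipaq_class inconsistent with ipaq_score cutoff")
    expect_cell = [
        cell_of(b, i) for b, i in zip(meta["bmi_value"], meta["ipaq_score"])
    ]
    if not (meta["cell"] == expect_cell).all():
        raise ValueError("cell labels inconsistent with class labels")
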