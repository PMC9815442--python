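"""Compressive strength parallel to grain and five-level larch grading.

The strength of a clear-wood specimen loaded axially to failure is

    sigma_w = P_max / (b * t)        [MPa = N / mm^2]

with ``P_max`` the failure load (N) and ``b``, ``t`` the specimen cross
section (mm), reported at 12 % moisture content and rounded to 0.1 MPa.
Specimens are then binned into five material grades Ic..Vc by strict
strength thresholds.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: Grade labels, strongest first.
GRADE_LABELS: tuple[str, ...] = ("Ic", "IIc", "IIIc", "IVc", "Vc")

#: Strict lower strength bound (MPa) per grade; Vc collects the remainder.
GRADE_THRESHOLDS_MPA: dict[str, float] = {
    "Ic": 22.5,
    "IIc": 18.9,
    "IIIc": 16.9,
    "IVc": 14.0,
}

#: Specimen counts per grade in the published reference larch survey
#: (200 clear-wood specimens from Greater Khingan larch).
REFERENCE_GRADE_COUNTS: dict[str, int] = {
    "Ic": 92,
    "IIc": 54,
    "IIIc": 17,
    "IVc": 8,
    "Vc": 29,
}

#: Total specimen count of the reference survey.
REFERENCE_SPECIMEN_TOTAL: int = 200


def compressive_strength(pmax_n: float, b_mm: float, t_mm: float) -> float:
    """Compressive strength parallel to grain, rounded to 0.1 MPa.

    Parameters
    ----------
    pmax_n : failure load in newtons (>= 0).
    b_mm, t_mm : specimen width and thickness in millimetres (> 0).

    Returns
    -------
    float
        ``pmax_n / (b_mm * t_mm)`` in MPa, rounded half-away-from-zero
        to one decimal place.
    """
    if b_mm <= 0 or t_mm <= 0:
        raise ValueError(f"specimen dimensions must be positive, got b={b_mm}, t={t_mm}")
    if pmax_n < 0:
        raise ValueError(f"failure load must be non-negative, got {pmax_n}")
    sigma = pmax_n / (b_mm * t_mm)
    # round half away from zero (sigma >= 0 here)
    return math.floor(sigma * 10 + 0.5) / 10


def classify_grade(sigma_w: float) -> str:
    """Assign the five-level material grade for a strength value in MPa.

    Thresholds are strict: a specimen at exactly 22.5 MPa falls to IIc.
    """
    if sigma_w < 0:
        raise ValueError(f"strength must be non-negative, got {sigma_w}")
    for label, bound in GRADE_THRESHOLDS_MPA.items():
        if sigma_w > bound:
            return label
    return "Vc"


def grade_table(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``sigma_w_MPa`` and ``grade`` columns to a specimen table.

    Expects columns ``Pmax_N``, ``b_mm``, ``t_mm`` (the CSV layout written
    by :mod:`tracheidnet.synth`).  Returns a copy.
    """
    out = records.copy()
    sigma = [
        compressive_strength(p, b, t)
        for p, b, t in zip(out["Pmax_N"], out["b_mm"], out["t_mm"])
    ]
    out["sigma_w_MPa"] = np.asarray(sigma)
    out["grade"] = [classify_grade(s) for s in sigma]
    return out
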