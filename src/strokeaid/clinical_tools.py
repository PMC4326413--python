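"""Bedside calculators: NIHSS total, rt-PA dosage, weight and glucose converters.

Dosing follows the standard alteplase licence arithmetic: 0.9 mg/kg up to a
90 mg cap, 10% given as a bolus, the remainder infused over 60 minutes at the
1 mg/ml reconstitution concentration, supplied in 50 mg vials.  The constants
are named and configurable; only the vial size is anchored in routine
practice documentation, the rest come from the product licence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Union

__all__ = [
    "NIHSS_ITEMS",
    "UNTESTABLE_ITEMS",
    "DosagePlan",
    "DOSE_MG_PER_KG",
    "DOSE_CAP_MG",
    "BOLUS_FRACTION",
    "CONCENTRATION_MG_PER_ML",
    "INFUSION_MINUTES",
    "VIAL_SIZE_MG",
    "GLUCOSE_MGDL_PER_MMOL",
    "LBS_PER_STONE",
    "KG_PER_LB",
    "nihss_total",
    "rtpa_dosage",
    "stones_lbs_to_kg",
    "mgdl_to_mmol",
]

#: The 15 standard scale items and their maximum scores (total 0–42).
NIHSS_ITEMS: tuple[tuple[str, str, int], ...] = (
    ("loc", "1a. Level of consciousness", 3),
    ("loc_questions", "1b. LOC questions", 2),
    ("loc_commands", "1c. LOC commands", 2),
    ("gaze", "2. Best gaze", 2),
    ("visual_fields", "3. Visual fields", 3),
    ("facial_palsy", "4. Facial palsy", 3),
    ("motor_arm_left", "5a. Motor arm, left", 4),
    ("motor_arm_right", "5b. Motor arm, right", 4),
    ("motor_leg_left", "6a. Motor leg, left", 4),
    ("motor_leg_right", "6b. Motor leg, right", 4),
    ("limb_ataxia", "7. Limb ataxia", 2),
    ("sensory", "8. Sensory", 2),
    ("language", "9. Best language", 3),
    ("dysarthria", "10. Dysarthria", 2),
    ("extinction", "11. Extinction and inattention", 2),
)

#: Items the scale allows to be recorded untestable ("UN"), scored 0.
UNTESTABLE_ITEMS = frozenset(
    {"motor_arm_left", "motor_arm_right", "motor_leg_left", "motor_leg_right",
     "limb_ataxia", "dysarthria"}
)

_ITEM_MAX = {key: mx for key, _, mx in NIHSS_ITEMS}


def nihss_total(items: Mapping[str, Union[int, str]]) -> int:
    """Sum the 15 NIHSS item scores; untestable items ("UN") score 0.

    Every item must be present and within its item-specific range; the total
    lies in 0–42.
    """
    missing = [key for key, _, _ in NIHSS_ITEMS if key not in items]
    if missing:
        raise ValueError(f"missing NIHSS items: {', '.join(missing)}")
    unknown = set(items) - set(_ITEM_MAX)
    if unknown:
        raise ValueError(f"unknown NIHSS items: {', '.join(sorted(unknown))}")
    total = 0
    for key, label, mx in NIHSS_ITEMS:
        v = items[key]
        if isinstance(v, str):
            if v.upper() == "UN" and key in UNTESTABLE_ITEMS:
                continue
            raise ValueError(f"item {label!r}: {v!r} is not a score or an allowed UN code")
        if isinstance(v, bool) or int(v) != v or not (0 <= v <= mx):
            raise ValueError(f"item {label!r}: score {v!r} outside range 0–{mx}")
        total += int(v)
    return total


# --- rt-PA dosing constants (product-licence values; configurable) ---------
DOSE_MG_PER_KG = 0.9
DOSE_CAP_MG = 90.0
BOLUS_FRACTION = 0.1
CONCENTRATION_MG_PER_ML = 1.0
INFUSION_MINUTES = 60.0
VIAL_SIZE_MG = 50.0


@dataclass(frozen=True)
class DosagePlan:
    total_dose_mg: float
    bolus_ml: float
    infusion_ml_per_hr: float
    vials: int

    def __post_init__(self):
        if min(self.total_dose_mg, self.bolus_ml, self.infusion_ml_per_hr) < 0 or self.vials < 0:
            raise ValueError("dosage quantities must be non-negative")


def rtpa_dosage(weight_kg: float, *, cap_mg: float = DOSE_CAP_MG) -> DosagePlan:
    """Weight-based alteplase dosage: total dose, bolus, infusion rate, vials.

    total = min(0.9 mg/kg × weight, cap); 10% as bolus; the remaining volume
    (at 1 mg/ml) infused over 60 minutes; vials = ceil(total / 50 mg).
    """
    if not (weight_kg > 0):
        raise ValueError(f"weight must be positive, got {weight_kg!r}")
    total = min(DOSE_MG_PER_KG * weight_kg, cap_mg)
    total_ml = total / CONCENTRATION_MG_PER_ML
    bolus_ml = BOLUS_FRACTION * total_ml
    infusion_ml_per_hr = (total_ml - bolus_ml) * (60.0 / INFUSION_MINUTES)
    vials = math.ceil(total / VIAL_SIZE_MG)
    return DosagePlan(
        total_dose_mg=total,
        bolus_ml=bolus_ml,
        infusion_ml_per_hr=infusion_ml_per_hr,
        vials=vials,
    )


# --- unit converters --------------------------------------------------------
LBS_PER_STONE = 14
KG_PER_LB = 0.45359237
#: Conventional clinical factor for glucose mg/dl → mmol/L (molar mass ≈ 180).
GLUCOSE_MGDL_PER_MMOL = 18.0


def stones_lbs_to_kg(stones: int, lbs: float = 0.0) -> float:
    """Convert a stones-and-pounds weight to kilograms."""
    if stones < 0:
        raise ValueError("stones must be non-negative")
    if not (0 <= lbs < LBS_PER_STONE):
        raise ValueError(f"lbs must be in [0, {LBS_PER_STONE}); carry excess into stones")
    return (LBS_PER_STONE * stones + lbs) * KG_PER_LB


def mgdl_to_mmol(glucose_mgdl: float) -> float:
    """Convert blood glucose from mg/dl to mmol/L (factor 18.0)."""
    if glucose_mgdl < 0:
        raise ValueError("glucose must be non-negative")
    return glucose_mgdl / GLUCOSE_MGDL_PER_MMOL
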