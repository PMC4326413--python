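"""Patient details: parsing, normalisation, and instant licence validation.

Each entered field is classified into one of three states mirroring the
bedside traffic-light contract: ``within_licence`` (green tick),
``outwith_licence`` (orange exclamation mark — a relative contraindication,
advisory rather than blocking), or ``invalid`` (red cross — unparseable or
implausible, no licence judgement attached).

Clock times accept three entry dialects — ``hhmm``, ``hh:mm`` and ``hh.mm`` —
which parse identically.  The onset-to-treatment interval wraps once past
midnight when the target treatment time precedes the onset time on the clock,
so durations are always in [0, 24) hours.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, fields as dataclass_fields, replace
from datetime import time
from typing import Optional

from .model_spec import LicenceCriteriaTable, ModelSpec, ModelSpecError

__all__ = [
    "PatientDetails",
    "FieldStatus",
    "Status",
    "ValidationResult",
    "InvalidEntryError",
    "parse_clock_time",
    "onset_to_treatment",
    "check_digits",
    "validate_field",
    "validate_patient",
    "edit_field",
]


class InvalidEntryError(ValueError):
    """Raised when a free-text entry cannot be parsed to its semantic type."""


class Status(str, enum.Enum):
    WITHIN_LICENCE = "within_licence"
    OUTWITH_LICENCE = "outwith_licence"
    INVALID = "invalid"


@dataclass(frozen=True)
class FieldStatus:
    field: str
    status: Status
    message: str = ""

    def __post_init__(self):
        if self.status is Status.OUTWITH_LICENCE and not self.message:
            raise ValueError(f"outwith-licence status for {self.field!r} requires a message")
        if self.status is Status.INVALID and "licence" in self.message.lower():
            raise ValueError("invalid entries carry no licence judgement")


@dataclass(frozen=True)
class ValidationResult:
    statuses: tuple[FieldStatus, ...]
    overall_within_licence: bool
    warnings: tuple[str, ...]
    missing_fields: tuple[str, ...] = ()

    def status_for(self, name: str) -> Optional[FieldStatus]:
        for fs in self.statuses:
            if fs.field == name:
                return fs
        return None


#: Boolean medical-history / imaging fields.
FLAG_FIELDS = (
    "diabetes",
    "prior_stroke",
    "clopidogrel_use",
    "hypertension_history",
    "antiplatelet_use",
    "infarction_on_imaging",
)


@dataclass(frozen=True)
class PatientDetails:
    """The input record: demographics, history, bloods, examination, imaging.

    Fields default to ``None`` (not yet entered); validation reports on
    populated fields and lists required-but-missing ones without raising.
    """

    age: Optional[float] = None
    sex: Optional[str] = None                      # "male" | "female"
    onset_time: Optional[time] = None
    target_treatment_time: Optional[time] = None
    nihss: Optional[int] = None                    # 0–42
    systolic_bp: Optional[float] = None            # mmHg
    glucose: Optional[float] = None                # mmol/L
    weight: Optional[float] = None                 # kg
    diabetes: Optional[bool] = None
    prior_stroke: Optional[bool] = None
    clopidogrel_use: Optional[bool] = None
    hypertension_history: Optional[bool] = None
    antiplatelet_use: Optional[bool] = None
    pre_stroke_mrs: Optional[int] = None           # 0–5
    infarction_on_imaging: Optional[bool] = None   # optional until imaging available

    def populated(self) -> dict[str, object]:
        return {
            f.name: getattr(self, f.name)
            for f in dataclass_fields(self)
            if getattr(self, f.name) is not None
        }


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

# the three accepted dialects: hhmm, hh:mm, hh.mm (single-digit hour allowed
# in the separator dialects; bare digits need 3-4 so minutes are unambiguous)
_TIME_RE = re.compile(r"^(?:(\d{1,2})[:.](\d{2})|(\d{3,4}))$")


def parse_clock_time(entry: str) -> time:
    """Parse a clock-time entry in any of the dialects hhmm / hh:mm / hh.mm."""
    if not entry or not entry.strip():
        raise InvalidEntryError("empty time entry")
    m = _TIME_RE.match(entry.strip())
    if not m:
        raise InvalidEntryError(f"unrecognised time entry {entry!r} (use hhmm, hh:mm or hh.mm)")
    if m.group(3) is not None:
        digits = m.group(3)
        hour, minute = int(digits[:-2]), int(digits[-2:])
    else:
        hour, minute = int(m.group(1)), int(m.group(2))
    if not (0 <= hour <= 23 and 0 <= minute <= 59):
        raise InvalidEntryError(f"time {entry!r} out of range (hour 0–23, minute 0–59)")
    return time(hour, minute)


def onset_to_treatment(onset: time, target: time) -> float:
    """Onset-to-treatment interval in hours; wraps once past midnight."""
    minutes = (target.hour * 60 + target.minute) - (onset.hour * 60 + onset.minute)
    return (minutes % 1440) / 60.0


def check_digits(field_name: str, entry: str, table: LicenceCriteriaTable) -> bool:
    """Apply the field's digit-count rule to a free-text numeric entry.

    Accepted iff the digit count is strictly inside the configured
    (min, max) bounds; fields with no rule accept any digit count.
    """
    if not entry.isdigit():
        raise InvalidEntryError(f"entry {entry!r} for {field_name} contains non-digit characters")
    rule = table.rule(field_name)
    if rule.digits is None:
        return True
    lo, hi = rule.digits
    return lo < len(entry) < hi


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_field(field_name: str, value: float, table: LicenceCriteriaTable) -> FieldStatus:
    """Classify one parsed numeric value against the licence-criteria table.

    Pure function of (value, table): outside the validity range → invalid;
    valid but outside the licence range or inside a warning range →
    outwith_licence with message; otherwise within_licence.
    """
    rule = table.rule(field_name)  # raises ModelSpecError for unknown fields
    if rule.validity is None:
        return FieldStatus(field_name, Status.WITHIN_LICENCE)
    lo, hi = rule.validity
    if not (lo <= value <= hi):
        return FieldStatus(
            field_name,
            Status.INVALID,
            f"value {value:g} for {field_name} is outside the plausible range {lo:g}–{hi:g}",
        )
    warning = rule.warning_message(value)
    if rule.licence is not None and not (rule.licence[0] <= value <= rule.licence[1]):
        msg = warning or (
            f"value {value:g} for {field_name} is outwith the licensing criteria "
            f"({rule.licence[0]:g}–{rule.licence[1]:g})"
        )
        return FieldStatus(field_name, Status.OUTWITH_LICENCE, msg)
    if warning:
        return FieldStatus(field_name, Status.OUTWITH_LICENCE, warning)
    return FieldStatus(field_name, Status.WITHIN_LICENCE)


def _required_predictors(spec: ModelSpec) -> set[str]:
    names: set[str] = set()
    for eq in spec.equations:
        names.update(t.predictor for t in eq.terms)
    names.update(i.predictor for i in spec.sich.items)
    if "onset_to_treatment" in names:
        names.discard("onset_to_treatment")
        names.update({"onset_time", "target_treatment_time"})
    return names


def validate_patient(patient: PatientDetails, spec: ModelSpec) -> ValidationResult:
    """Validate every populated field plus the derived onset-to-treatment time.

    ``overall_within_licence`` is true iff every populated field that has a
    configured rule is within_licence.  Required-but-missing predictors are
    listed in ``missing_fields`` rather than raised.
    """
    statuses: list[FieldStatus] = []
    warnings: list[str] = []
    populated = patient.populated()

    for name, value in populated.items():
        if name in FLAG_FIELDS or name in ("sex",):
            continue
        if name in ("onset_time", "target_treatment_time"):
            continue  # covered by the derived duration below
        if name not in spec.licence:
            continue
        fs = validate_field(name, float(value), spec.licence)
        statuses.append(fs)
        if fs.message:
            warnings.append(fs.message)

    if patient.onset_time is not None and patient.target_treatment_time is not None:
        ott = onset_to_treatment(patient.onset_time, patient.target_treatment_time)
        fs = validate_field("onset_to_treatment", ott, spec.licence)
        statuses.append(fs)
        if fs.message:
            warnings.append(fs.message)

    missing = tuple(sorted(_required_predictors(spec) - set(populated)))
    overall = all(fs.status is Status.WITHIN_LICENCE for fs in statuses)
    return ValidationResult(
        statuses=tuple(statuses),
        overall_within_licence=overall,
        warnings=tuple(warnings),
        missing_fields=missing,
    )


# ---------------------------------------------------------------------------
# Editing
# ---------------------------------------------------------------------------

_INT_FIELDS = ("nihss", "pre_stroke_mrs")
_FLOAT_FIELDS = ("age", "systolic_bp", "glucose", "weight")
_TIME_FIELDS = ("onset_time", "target_treatment_time")
_TRUE_WORDS = ("1", "true", "yes", "y")
_FALSE_WORDS = ("0", "false", "no", "n")


def parse_field_value(field_name: str, raw: str):
    """Parse a raw text entry to the field's semantic type."""
    raw = raw.strip()
    if field_name in _TIME_FIELDS:
        return parse_clock_time(raw)
    if field_name in _INT_FIELDS:
        if not re.fullmatch(r"[+-]?\d+", raw):
            raise InvalidEntryError(f"entry {raw!r} for {field_name} is not an integer")
        return int(raw)
    if field_name in _FLOAT_FIELDS:
        try:
            return float(raw)
        except ValueError:
            raise InvalidEntryError(f"entry {raw!r} for {field_name} is not a number") from None
    if field_name in FLAG_FIELDS:
        low = raw.lower()
        if low in _TRUE_WORDS:
            return True
        if low in _FALSE_WORDS:
            return False
        raise InvalidEntryError(f"entry {raw!r} for {field_name} is not a yes/no value")
    if field_name == "sex":
        low = raw.lower()
        if low in ("male", "m"):
            return "male"
        if low in ("female", "f"):
            return "female"
        raise InvalidEntryError(f"entry {raw!r} for sex is not male/female")
    raise InvalidEntryError(f"unknown patient field {field_name!r}")


def edit_field(patient: PatientDetails, field_name: str, raw: str) -> tuple[PatientDetails, bool]:
    """Re-parse one field from raw text; any cached prediction becomes stale.

    Returns ``(updated_patient, prediction_stale)``.  The stale signal is
    always True — conservatively, even when the re-entered value is unchanged —
    so a presentation is never shown against edited inputs.
    """
    if field_name not in {f.name for f in dataclass_fields(PatientDetails)}:
        raise InvalidEntryError(f"unknown patient field {field_name!r}")
    value = parse_field_value(field_name, raw)
    return replace(patient, **{field_name: value}), True
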