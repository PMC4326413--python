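"""The decision-analytic engine: patient-specific 3-month outcome predictions.

Outcome probabilities with and without thrombolysis come from logistic
equations for functional independence (mRS 0–2) and death; dependence
(mRS 3–5) is the complement.  For the treated arm, the equations are read as
conditional on no symptomatic intracranial haemorrhage (SICH); the final
treated distribution is the mixture

    treated = (1 − p_sich) · base_treated + p_sich · post_sich

where ``p_sich`` comes from the additive score table and ``post_sich`` is the
fixed outcome distribution among SICH sufferers.  Net benefit is the absolute
difference in probability of independence, treated minus untreated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .model_spec import ModelSpec, OutcomeEquation, PostSichDistribution
from .validation import PatientDetails, onset_to_treatment

__all__ = [
    "OutcomeDistribution",
    "Prediction",
    "TimelineCurve",
    "MissingPredictorError",
    "CATEGORIES",
    "linear_predictor",
    "logistic",
    "predict_arm",
    "sich_probability",
    "sich_score",
    "apply_sich_mixture",
    "predict",
    "timeline",
    "categorize_mrs",
]

#: Fixed presentation order of outcome categories.
CATEGORIES = ("independent", "dependent", "dead")

_SUM_TOL = 1e-9


class MissingPredictorError(ValueError):
    """A predictor required by an equation or score item is not populated."""


@dataclass(frozen=True)
class OutcomeDistribution:
    """Probabilities over {independent (mRS 0–2), dependent (mRS 3–5), dead}."""

    p_independent: float
    p_dependent: float
    p_dead: float

    def __post_init__(self):
        for name in ("p_independent", "p_dependent", "p_dead"):
            v = getattr(self, name)
            if not (-_SUM_TOL <= v <= 1.0 + _SUM_TOL):
                raise ValueError(f"{name}={v} outside [0,1]")
        total = self.p_independent + self.p_dependent + self.p_dead
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"outcome probabilities sum to {total!r}, not 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_independent, self.p_dependent, self.p_dead)


@dataclass(frozen=True)
class Prediction:
    untreated: OutcomeDistribution
    treated: OutcomeDistribution
    p_sich: float
    net_benefit: float
    frequencies: dict              # per-100 integer counts, see risk_render
    time_horizon_label: str
    sich_horizon_label: str
    post_sich: tuple[float, float, float] = (0.0, 0.0, 1.0)
    degenerate: bool = False       # complement rescaling was triggered

    def to_json(self) -> str:
        """Serialise with probabilities to 4 d.p. and integer frequencies."""
        def dist(d: OutcomeDistribution) -> dict:
            return {
                "independent": round(d.p_independent, 4),
                "dependent": round(d.p_dependent, 4),
                "dead": round(d.p_dead, 4),
            }

        doc = {
            "time_horizon": self.time_horizon_label,
            "sich_horizon": self.sich_horizon_label,
            "untreated": dist(self.untreated),
            "treated": dist(self.treated),
            "p_sich": round(self.p_sich, 4),
            "net_benefit": round(self.net_benefit, 4),
            "frequencies_per_100": self.frequencies,
            "degenerate": self.degenerate,
        }
        return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


@dataclass(frozen=True)
class TimelineCurve:
    """Net benefit as a function of onset-to-treatment time."""

    grid_hours: tuple[float, ...]
    net_benefit: tuple[float, ...]

    def __post_init__(self):
        if len(self.grid_hours) != len(self.net_benefit):
            raise ValueError("grid and curve lengths differ")
        if any(b <= a for a, b in zip(self.grid_hours, self.grid_hours[1:])):
            raise ValueError("timeline grid must be strictly increasing")


# ---------------------------------------------------------------------------
# Predictor resolution
# ---------------------------------------------------------------------------

def _resolve_predictor(patient: PatientDetails, name: str, ott_override: Optional[float]):
    if name == "onset_to_treatment":
        if ott_override is not None:
            return ott_override
        if patient.onset_time is None or patient.target_treatment_time is None:
            raise MissingPredictorError(
                "predictor 'onset_to_treatment' requires onset_time and target_treatment_time"
            )
        return onset_to_treatment(patient.onset_time, patient.target_treatment_time)
    if not hasattr(patient, name):
        raise MissingPredictorError(f"unknown predictor {name!r}")
    value = getattr(patient, name)
    if value is None:
        raise MissingPredictorError(f"predictor {name!r} is not populated")
    return value


def linear_predictor(
    equation: OutcomeEquation,
    patient: PatientDetails,
    ott_override: Optional[float] = None,
) -> float:
    """intercept + Σ coefficient × transformed predictor value."""
    lp = equation.intercept
    for term in equation.terms:
        value = _resolve_predictor(patient, term.predictor, ott_override)
        if term.transform == "indicator":
            x = 1.0 if value else 0.0
        else:  # identity / linear
            x = float(value)
        lp += term.coefficient * x
    return lp


def logistic(lp: float) -> float:
    """Overflow-safe inverse logit, strictly in (0, 1)."""
    if not math.isfinite(lp):
        raise ValueError("linear predictor must be finite")
    if lp >= 0:
        return 1.0 / (1.0 + math.exp(-lp))
    e = math.exp(lp)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# Arm prediction and the SICH branch
# ---------------------------------------------------------------------------

def predict_arm(
    patient: PatientDetails,
    spec: ModelSpec,
    arm: str,
    ott_override: Optional[float] = None,
) -> tuple[OutcomeDistribution, bool]:
    """Three-category distribution for one arm from its two logistic equations.

    p_independent and p_dead are modelled directly; p_dependent is the
    complement.  In the rare degenerate case where the two modelled
    probabilities exceed 1, both are rescaled proportionally to sum to
    1 − 1e-9 and the event is flagged in the second return value.
    """
    p_ind = logistic(linear_predictor(spec.equation("independent", arm), patient, ott_override))
    p_dead = logistic(linear_predictor(spec.equation("dead", arm), patient, ott_override))
    degenerate = False
    if p_ind + p_dead > 1.0:
        scale = (1.0 - _SUM_TOL) / (p_ind + p_dead)
        p_ind *= scale
        p_dead *= scale
        degenerate = True
    p_dep = 1.0 - p_ind - p_dead
    return OutcomeDistribution(p_ind, max(p_dep, 0.0), p_dead), degenerate


def sich_score(
    patient: PatientDetails, spec: ModelSpec, ott_override: Optional[float] = None
) -> int:
    """Total points over satisfied SICH score items."""
    return sum(
        item.points
        for item in spec.sich.items
        if item.holds(_resolve_predictor(patient, item.predictor, ott_override))
    )


def sich_probability(
    patient: PatientDetails, spec: ModelSpec, ott_override: Optional[float] = None
) -> float:
    """Patient-specific probability of SICH via the score table's risk map."""
    return spec.sich.probability_for_score(sich_score(patient, spec, ott_override))


def apply_sich_mixture(
    base_treated: OutcomeDistribution,
    p_sich: float,
    post_sich: PostSichDistribution,
) -> OutcomeDistribution:
    """Mix the no-SICH treated distribution with post-SICH outcome proportions."""
    if not (0.0 <= p_sich <= 1.0):
        raise ValueError(f"p_sich={p_sich} outside [0,1]")
    q = 1.0 - p_sich
    return OutcomeDistribution(
        q * base_treated.p_independent + p_sich * post_sich.p_independent,
        q * base_treated.p_dependent + p_sich * post_sich.p_dependent,
        q * base_treated.p_dead + p_sich * post_sich.p_dead,
    )


def predict(
    patient: PatientDetails,
    spec: ModelSpec,
    ott_override: Optional[float] = None,
) -> Prediction:
    """Full patient-specific prediction: both arms, SICH branch, net benefit."""
    from .render import to_frequencies  # render depends only on duck-typed predictions

    untreated, degen_u = predict_arm(patient, spec, "untreated", ott_override)
    base_treated, degen_t = predict_arm(patient, spec, "treated", ott_override)
    p_sich = sich_probability(patient, spec, ott_override)
    treated = apply_sich_mixture(base_treated, p_sich, spec.post_sich)
    net_benefit = treated.p_independent - untreated.p_independent

    freq_untreated = to_frequencies(untreated.as_tuple(), 100)
    freq_treated = to_frequencies(treated.as_tuple(), 100)
    sich_count = to_frequencies((p_sich, 1.0 - p_sich), 100)[0]
    frequencies = {
        "untreated": dict(zip(CATEGORIES, freq_untreated)),
        "treated": dict(zip(CATEGORIES, freq_treated)),
        "sich": sich_count,
        "net_benefit": freq_treated[0] - freq_untreated[0],
        "denominator": 100,
    }
    return Prediction(
        untreated=untreated,
        treated=treated,
        p_sich=p_sich,
        net_benefit=net_benefit,
        frequencies=frequencies,
        time_horizon_label=spec.time_horizon_label,
        sich_horizon_label=spec.sich_horizon_label,
        post_sich=spec.post_sich.as_tuple(),
        degenerate=degen_u or degen_t,
    )


def timeline(
    patient: PatientDetails, spec: ModelSpec, grid: Sequence[float]
) -> TimelineCurve:
    """Net benefit recomputed across a grid of onset-to-treatment times.

    All other patient fields are held fixed; the grid must lie within the
    validity range configured for onset-to-treatment time.
    """
    rule = spec.licence.rule("onset_to_treatment")
    if rule.validity is not None:
        lo, hi = rule.validity
        for t in grid:
            if not (lo <= t <= hi):
                raise ValueError(f"grid time {t} h outside validity range {lo}–{hi} h")
    values = tuple(predict(patient, spec, ott_override=t).net_benefit for t in grid)
    return TimelineCurve(grid_hours=tuple(float(t) for t in grid), net_benefit=values)


def categorize_mrs(mrs: int) -> str:
    """Map a modified Rankin Scale grade to its outcome category.

    0–2 → independent, 3–5 → dependent, 6 → dead.
    """
    if not isinstance(mrs, int) or isinstance(mrs, bool) or not (0 <= mrs <= 6):
        raise ValueError(f"mRS grade must be an integer 0–6, got {mrs!r}")
    if mrs <= 2:
        return "independent"
    if mrs <= 5:
        return "dependent"
    return "dead"
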