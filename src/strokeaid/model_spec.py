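"""Model specification: the configurable clinical content behind every prediction.

A :class:`ModelSpec` bundles the logistic outcome equations (probability of
functional independence, mRS 0–2, and of death at three months, each with and
without thrombolysis), the additive score table mapping patient features to a
probability of symptomatic intracranial haemorrhage (SICH), the outcome
proportions following SICH, and the licence-criteria table used for instant
field validation.  The spec is read from and written to JSON with a stable key
order so that serialisation round-trips losslessly and byte-identically.

The bundled default spec is illustrative: its coefficients have clinically
sensible signs and magnitudes but are not fitted to any registry.  Substitute
published coefficients by editing the JSON document and loading it with
:func:`load_model_spec`.
"""

from __future__ import annotations

import importlib.resources
import json
import math

import numpy as np
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "EquationTerm",
    "OutcomeEquation",
    "SichScoreItem",
    "SichScoreTable",
    "PostSichDistribution",
    "FieldRule",
    "LicenceCriteriaTable",
    "ModelSpec",
    "ModelSpecError",
    "RecalibrationError",
    "default_model_spec",
    "load_model_spec",
    "write_model_spec",
    "recalibrate_intercepts",
]

OUTCOMES = ("independent", "dead")
ARMS = ("treated", "untreated")
#: Every spec must contain one equation per (outcome, arm) pair.
REQUIRED_EQUATIONS = tuple((o, a) for o in OUTCOMES for a in ARMS)

TRANSFORMS = ("identity", "indicator", "linear")

#: Bisection bracket (+/-) and tolerance for intercept recalibration.
RECAL_BRACKET = 10.0
RECAL_TOL = 1e-8
RECAL_MAX_ITER = 200


class ModelSpecError(ValueError):
    """A model-spec document violates the schema or an invariant."""


class RecalibrationError(RuntimeError):
    """Intercept recalibration failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquationTerm:
    predictor: str
    transform: str
    coefficient: float

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ModelSpecError(
                f"term for {self.predictor!r}: unknown transform {self.transform!r}"
            )
        if not math.isfinite(self.coefficient):
            raise ModelSpecError(
                f"term for {self.predictor!r}: coefficient is not finite"
            )


@dataclass(frozen=True)
class OutcomeEquation:
    """One logistic equation: logit(p) = intercept + sum(coef * x)."""

    outcome: str
    arm: str
    intercept: float
    terms: tuple[EquationTerm, ...]

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ModelSpecError(f"unknown outcome {self.outcome!r}")
        if self.arm not in ARMS:
            raise ModelSpecError(f"unknown arm {self.arm!r}")
        if not math.isfinite(self.intercept):
            raise ModelSpecError(
                f"equation ({self.outcome}, {self.arm}): intercept is not finite"
            )
        names = [t.predictor for t in self.terms]
        if len(names) != len(set(names)):
            raise ModelSpecError(
                f"equation ({self.outcome}, {self.arm}): duplicate predictor names"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.outcome, self.arm)


@dataclass(frozen=True)
class SichScoreItem:
    """One additive score item: points awarded when the condition holds.

    Conditions are either a boolean ``flag`` on the named patient field or a
    numeric threshold (``ge``/``gt``/``le``/``lt``) on it.
    """

    predictor: str
    condition: Mapping[str, object]
    points: int

    def __post_init__(self):
        ctype = self.condition.get("type")
        if ctype not in ("flag", "ge", "gt", "le", "lt"):
            raise ModelSpecError(
                f"SICH item {self.predictor!r}: unknown condition type {ctype!r}"
            )
        if ctype != "flag" and "threshold" not in self.condition:
            raise ModelSpecError(
                f"SICH item {self.predictor!r}: threshold condition missing 'threshold'"
            )
        if int(self.points) != self.points or self.points < 0:
            raise ModelSpecError(
                f"SICH item {self.predictor!r}: points must be a non-negative integer"
            )

    def holds(self, value) -> bool:
        ctype = self.condition["type"]
        if ctype == "flag":
            return bool(value)
        t = self.condition["threshold"]
        return {
            "ge": value >= t,
            "gt": value > t,
            "le": value <= t,
            "lt": value < t,
        }[ctype]


@dataclass(frozen=True)
class SichScoreTable:
    items: tuple[SichScoreItem, ...]
    #: ordered list of ((min_score, max_score), probability)
    risk_map: tuple[tuple[tuple[int, int], float], ...]

    def __post_init__(self):
        max_points = sum(it.points for it in self.items)
        covered = []
        for (lo, hi), p in self.risk_map:
            if lo > hi:
                raise ModelSpecError(f"SICH risk band [{lo},{hi}] is empty")
            if not (0.0 <= p <= 1.0):
                raise ModelSpecError(f"SICH band [{lo},{hi}]: probability {p} not in [0,1]")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(0, max_points + 1)):
            raise ModelSpecError(
                "SICH risk bands must partition the achievable score range "
                f"0..{max_points} without gaps or overlap"
            )
        probs = [p for _, p in self.risk_map]
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ModelSpecError("SICH band probabilities must be non-decreasing with score")

    @property
    def max_score(self) -> int:
        return sum(it.points for it in self.items)

    def probability_for_score(self, score: int) -> float:
        for (lo, hi), p in self.risk_map:
            if lo <= score <= hi:
                return p
        raise ModelSpecError(f"SICH score {score} falls outside every risk band")


@dataclass(frozen=True)
class PostSichDistribution:
    """Outcome proportions at three months among patients who suffer a SICH."""

    p_independent: float
    p_dependent: float
    p_dead: float

    def __post_init__(self):
        for name in ("p_independent", "p_dependent", "p_dead"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ModelSpecError(f"post-SICH {name}={v} not in [0,1]")
        total = self.p_independent + self.p_dependent + self.p_dead
        if abs(total - 1.0) > 1e-9:
            raise ModelSpecError(f"post-SICH proportions sum to {total}, not 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_independent, self.p_dependent, self.p_dead)


@dataclass(frozen=True)
class FieldRule:
    """Validation rules for one patient-detail field.

    ``validity`` is the hard parseable/plausible range; ``licence`` the
    treatment-licence range (a subset of validity); ``warnings`` attach message
    text to sub-ranges; ``digits`` is the (exclusive) digit-count rule for
    free-text numeric entry, e.g. (1, 4) accepts 2–3 digits.
    """

    name: str
    validity: tuple[float, float] | None
    licence: tuple[float, float] | None
    warnings: tuple[tuple[tuple[float, float], str], ...] = ()
    digits: tuple[int, int] | None = None

    def __post_init__(self):
        if self.licence is not None:
            if self.validity is None:
                raise ModelSpecError(f"field {self.name!r}: licence range without validity range")
            if self.licence[0] < self.validity[0] or self.licence[1] > self.validity[1]:
                raise ModelSpecError(
                    f"field {self.name!r}: licence range must lie within the validity range"
                )
        for (lo, hi), msg in self.warnings:
            if not msg:
                raise ModelSpecError(f"field {self.name!r}: warning range [{lo},{hi}] has empty message")

    def warning_message(self, value: float) -> str | None:
        for (lo, hi), msg in self.warnings:
            if lo <= value <= hi:
                return msg
        return None


@dataclass(frozen=True)
class LicenceCriteriaTable:
    fields: Mapping[str, FieldRule]

    def rule(self, name: str) -> FieldRule:
        try:
            return self.fields[name]
        except KeyError:
            raise ModelSpecError(f"no licence-criteria rule configured for field {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.fields


@dataclass(frozen=True)
class ModelSpec:
    version: str
    production_date: str
    equations: tuple[OutcomeEquation, ...]
    sich: SichScoreTable
    post_sich: PostSichDistribution
    licence: LicenceCriteriaTable
    time_horizon_label: str = "3 months"
    sich_horizon_label: str = "within 24–36 hours after clot-busting treatment"
    comment: str = ""

    def __post_init__(self):
        keys = [eq.key for eq in self.equations]
        if len(keys) != len(set(keys)):
            raise ModelSpecError("duplicate (outcome, arm) equation pairs")
        missing = [pair for pair in REQUIRED_EQUATIONS if pair not in keys]
        if missing:
            raise ModelSpecError(
                "model spec is missing required equations: "
                + ", ".join(f"({o}, {a})" for o, a in missing)
            )

    def equation(self, outcome: str, arm: str) -> OutcomeEquation:
        for eq in self.equations:
            if eq.key == (outcome, arm):
                return eq
        raise ModelSpecError(f"no equation for ({outcome}, {arm})")


# ---------------------------------------------------------------------------
# JSON (de)serialisation
# ---------------------------------------------------------------------------

def _spec_from_dict(doc: Mapping) -> ModelSpec:
    def need(key):
        if key not in doc:
            raise ModelSpecError(f"model-spec document is missing required field {key!r}")
        return doc[key]

    equations = tuple(
        OutcomeEquation(
            outcome=e["outcome"],
            arm=e["arm"],
            intercept=float(e["intercept"]),
            terms=tuple(
                EquationTerm(t["predictor"], t["transform"], float(t["coefficient"]))
                for t in e.get("terms", [])
            ),
        )
        for e in need("equations")
    )
    sich_doc = need("sich")
    sich = SichScoreTable(
        items=tuple(
            SichScoreItem(i["predictor"], dict(i["condition"]), int(i["points"]))
            for i in sich_doc["items"]
        ),
        risk_map=tuple(
            ((int(b["band"][0]), int(b["band"][1])), float(b["probability"]))
            for b in sich_doc["risk_map"]
        ),
    )
    ps = need("post_sich")
    post_sich = PostSichDistribution(
        float(ps["p_independent"]), float(ps["p_dependent"]), float(ps["p_dead"])
    )
    fields = {}
    for name, f in need("licence")["fields"].items():
        fields[name] = FieldRule(
            name=name,
            validity=tuple(f["validity"]) if f.get("validity") else None,
            licence=tuple(f["licence"]) if f.get("licence") else None,
            warnings=tuple(
                ((float(w["range"][0]), float(w["range"][1])), str(w["message"]))
                for w in f.get("warnings", [])
            ),
            digits=tuple(f["digits"]) if f.get("digits") else None,
        )
    return ModelSpec(
        version=str(need("version")),
        production_date=str(need("production_date")),
        equations=equations,
        sich=sich,
        post_sich=post_sich,
        licence=LicenceCriteriaTable(fields=fields),
        time_horizon_label=str(doc.get("time_horizon_label", "3 months")),
        sich_horizon_label=str(
            doc.get("sich_horizon_label", "within 24–36 hours after clot-busting treatment")
        ),
        comment=str(doc.get("_comment", "")),
    )


def _spec_to_dict(spec: ModelSpec) -> dict:
    doc: dict = {}
    if spec.comment:
        doc["_comment"] = spec.comment
    doc["version"] = spec.version
    doc["production_date"] = spec.production_date
    doc["time_horizon_label"] = spec.time_horizon_label
    doc["sich_horizon_label"] = spec.sich_horizon_label
    doc["equations"] = [
        {
            "outcome": eq.outcome,
            "arm": eq.arm,
            "intercept": eq.intercept,
            "terms": [
                {"predictor": t.predictor, "transform": t.transform, "coefficient": t.coefficient}
                for t in eq.terms
            ],
        }
        for eq in spec.equations
    ]
    doc["sich"] = {
        "items": [
            {"predictor": i.predictor, "condition": dict(i.condition), "points": i.points}
            for i in spec.sich.items
        ],
        "risk_map": [
            {"band": [lo, hi], "probability": p} for (lo, hi), p in spec.sich.risk_map
        ],
    }
    doc["post_sich"] = {
        "p_independent": spec.post_sich.p_independent,
        "p_dependent": spec.post_sich.p_dependent,
        "p_dead": spec.post_sich.p_dead,
    }
    doc["licence"] = {
        "fields": {
            name: {
                "validity": list(rule.validity) if rule.validity else None,
                "licence": list(rule.licence) if rule.licence else None,
                "warnings": [
                    {"range": [lo, hi], "message": msg} for (lo, hi), msg in rule.warnings
                ],
                "digits": list(rule.digits) if rule.digits else None,
            }
            for name, rule in spec.licence.fields.items()
        }
    }
    return doc


def load_model_spec(source: str | Path | Mapping | None = None) -> ModelSpec:
    """Load and validate a model spec.

    ``source`` may be a path to a JSON document, an already-parsed mapping, or
    ``None`` for the bundled illustrative default.  All structural invariants
    (required equations present, risk bands partitioning, licence ⊆ validity,
    post-SICH proportions summing to one) are checked on load.
    """
    if source is None:
        return default_model_spec()
    if isinstance(source, Mapping):
        return _spec_from_dict(source)
    text = Path(source).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelSpecError(f"model-spec document is not valid JSON: {exc}") from exc
    return _spec_from_dict(doc)


def write_model_spec(spec: ModelSpec, path: str | Path | None = None) -> str:
    """Serialise ``spec`` to its canonical JSON text (stable key order).

    Two serialisations of the same spec are byte-identical, and
    ``load_model_spec`` inverts the output exactly.  If ``path`` is given the
    document is also written there.
    """
    text = json.dumps(_spec_to_dict(spec), indent=2, ensure_ascii=False) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def default_model_spec() -> ModelSpec:
    """The bundled illustrative default spec (placeholder clinical content)."""
    ref = importlib.resources.files("strokeaid").joinpath("data/default_spec.json")
    return _spec_from_dict(json.loads(ref.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Recalibration
# ---------------------------------------------------------------------------

def _cohort_linear_predictors(equation: OutcomeEquation, cohort: Sequence):
    # local import: engine depends on this module, not the reverse
    from .engine import linear_predictor

    return np.array([linear_predictor(equation, patient) for patient in cohort])


def recalibrate_intercepts(
    spec: ModelSpec,
    cohort: Sequence,
    observed: Mapping[tuple[str, str], float],
) -> ModelSpec:
    """Shift equation intercepts so cohort-mean predictions match ``observed``.

    For each (outcome, arm) key in ``observed`` the corresponding equation's
    intercept is adjusted — no slope changes — so that the mean predicted
    probability over ``cohort`` equals the observed proportion.  Because the
    mean of logistic curves is strictly increasing in the shared intercept,
    the 1-D root is found by bisection on a ±10 bracket to tolerance 1e-8.

    Raises :class:`RecalibrationError` if a target proportion is unattainable
    within the bracket or bisection fails to converge.
    """
    if not cohort:
        raise ValueError("recalibration requires a non-empty cohort")
    for key, target in observed.items():
        if not (0.0 < target < 1.0):
            raise ValueError(f"observed proportion for {key} must be in (0,1), got {target}")

    new_equations = list(spec.equations)
    for (outcome, arm), target in observed.items():
        eq = spec.equation(outcome, arm)
        lps = _cohort_linear_predictors(eq, cohort)

        def mean_p(delta: float) -> float:
            # numerically safe inverse logit on the shifted linear predictors
            x = lps + delta
            out = np.empty_like(x)
            pos = x >= 0
            out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
            e = np.exp(x[~pos])
            out[~pos] = e / (1.0 + e)
            return float(out.mean())

        lo, hi = -RECAL_BRACKET, RECAL_BRACKET
        f_lo = mean_p(lo) - target
        f_hi = mean_p(hi) - target
        if f_lo > 0 or f_hi < 0:
            residual = min(abs(f_lo), abs(f_hi))
            raise RecalibrationError(
                f"target {target} for ({outcome}, {arm}) unattainable within intercept "
                f"shift ±{RECAL_BRACKET}; residual {residual:.3g}",
                residual,
            )
        delta = 0.0
        for _ in range(RECAL_MAX_ITER):
            delta = 0.5 * (lo + hi)
            f_mid = mean_p(delta) - target
            if abs(f_mid) <= RECAL_TOL or (hi - lo) / 2 <= RECAL_TOL * 1e-2:
                break
            if f_mid < 0:
                lo = delta
            else:
                hi = delta
        else:
            residual = abs(mean_p(delta) - target)
            raise RecalibrationError(
                f"bisection did not converge for ({outcome}, {arm}); residual {residual:.3g}",
                residual,
            )
        idx = new_equations.index(eq)
        new_equations[idx] = replace(eq, intercept=eq.intercept + delta)
    return replace(spec, equations=tuple(new_equations))
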