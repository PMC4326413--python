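"""Synthetic patient cohorts for testing, recalibration and demonstration.

Continuous covariates are drawn from truncated normal distributions so every
generated record lies inside the validity ranges by construction; history
flags are independent Bernoulli draws.  Covariates are sampled independently
of one another — a documented simplification relative to real stroke
registries, where age, severity and comorbidity are correlated.  Outcome
labels can be simulated from any model spec's predicted distributions, which
is what the recalibration parameter-recovery tests exercise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import CATEGORIES, apply_sich_mixture, predict_arm, sich_probability
from .model_spec import ModelSpec
from .validation import PatientDetails

__all__ = ["CohortParams", "generate_cohort", "simulate_outcomes",
           "cohort_to_dataframe", "cohort_to_csv", "cohort_from_csv"]


@dataclass(frozen=True)
class TruncNormal:
    mean: float
    sd: float
    low: float
    high: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n,
                                   random_state=rng)


@dataclass(frozen=True)
class CohortParams:
    """Covariate distribution settings for the fixture generator.

    Defaults describe a plausible thrombolysis-eligible acute-stroke
    population: mean age ~70, moderate severity (NIHSS ~10), elevated blood
    pressure, and onset-to-treatment times concentrated inside the 4.5 h
    licence window.
    """

    n: int = 100
    seed: int = 0
    age: TruncNormal = TruncNormal(70.0, 12.5, 45.0, 95.0)  # symmetric ±2 sd keeps the mean
    nihss: TruncNormal = TruncNormal(10.0, 6.0, 0.0, 42.0)
    systolic_bp: TruncNormal = TruncNormal(150.0, 20.0, 90.0, 220.0)
    glucose: TruncNormal = TruncNormal(6.5, 2.0, 3.0, 20.0)
    weight: TruncNormal = TruncNormal(78.0, 15.0, 40.0, 150.0)
    onset_to_treatment: TruncNormal = TruncNormal(2.5, 1.0, 0.5, 4.5)
    p_male: float = 0.55
    p_diabetes: float = 0.20
    p_prior_stroke: float = 0.15
    p_clopidogrel: float = 0.10
    p_hypertension: float = 0.50
    p_antiplatelet: float = 0.30
    p_infarction_on_imaging: float = 0.15
    #: probabilities of pre-stroke mRS 0, 1, 2
    pre_stroke_mrs_probs: tuple[float, ...] = (0.6, 0.25, 0.15)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        for name in ("p_male", "p_diabetes", "p_prior_stroke", "p_clopidogrel",
                     "p_hypertension", "p_antiplatelet", "p_infarction_on_imaging"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} not in [0,1]")
        if abs(sum(self.pre_stroke_mrs_probs) - 1.0) > 1e-9:
            raise ValueError("pre_stroke_mrs_probs must sum to 1")


def _minutes_to_time(minutes: int) -> time:
    return time(int(minutes) // 60 % 24, int(minutes) % 60)


def generate_cohort(params: CohortParams) -> list[PatientDetails]:
    """Reproducibly sample ``params.n`` valid patient records."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    age = params.age.sample(n, rng)
    nihss = np.clip(np.rint(params.nihss.sample(n, rng)), 0, 42).astype(int)
    bp = params.systolic_bp.sample(n, rng)
    glucose = params.glucose.sample(n, rng)
    weight = params.weight.sample(n, rng)
    ott_hours = params.onset_to_treatment.sample(n, rng)
    onset_minutes = rng.integers(0, 1440, size=n)
    sex = np.where(rng.random(n) < params.p_male, "male", "female")
    flags = {
        "diabetes": rng.random(n) < params.p_diabetes,
        "prior_stroke": rng.random(n) < params.p_prior_stroke,
        "clopidogrel_use": rng.random(n) < params.p_clopidogrel,
        "hypertension_history": rng.random(n) < params.p_hypertension,
        "antiplatelet_use": rng.random(n) < params.p_antiplatelet,
        "infarction_on_imaging": rng.random(n) < params.p_infarction_on_imaging,
    }
    mrs = rng.choice(len(params.pre_stroke_mrs_probs), size=n, p=params.pre_stroke_mrs_probs)

    cohort = []
    for i in range(n):
        onset = int(onset_minutes[i])
        target = onset + int(round(ott_hours[i] * 60))
        cohort.append(
            PatientDetails(
                age=round(float(age[i]), 1),
                sex=str(sex[i]),
                onset_time=_minutes_to_time(onset),
                target_treatment_time=_minutes_to_time(target),
                nihss=int(nihss[i]),
                systolic_bp=round(float(bp[i]), 0),
                glucose=round(float(glucose[i]), 1),
                weight=round(float(weight[i]), 1),
                diabetes=bool(flags["diabetes"][i]),
                prior_stroke=bool(flags["prior_stroke"][i]),
                clopidogrel_use=bool(flags["clopidogrel_use"][i]),
                hypertension_history=bool(flags["hypertension_history"][i]),
                antiplatelet_use=bool(flags["antiplatelet_use"][i]),
                pre_stroke_mrs=int(mrs[i]),
                infarction_on_imaging=bool(flags["infarction_on_imaging"][i]),
            )
        )
    return cohort


def simulate_outcomes(
    cohort: Sequence[PatientDetails],
    spec: ModelSpec,
    arm: str,
    seed: int,
    include_sich: bool = False,
) -> list[str]:
    """Draw one outcome label per patient from their predicted distribution.

    By default labels come from the arm's equation-level distribution
    (``predict_arm``); with ``include_sich=True`` the treated arm's SICH
    mixture is applied first.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    labels = []
    for patient in cohort:
        dist, _ = predict_arm(patient, spec, arm)
        if include_sich and arm == "treated":
            dist = apply_sich_mixture(dist, sich_probability(patient, spec), spec.post_sich)
        labels.append(str(rng.choice(CATEGORIES, p=np.asarray(dist.as_tuple()))))
    return labels


# ---------------------------------------------------------------------------
# CSV round-trip (documented header = PatientDetails field names)
# ---------------------------------------------------------------------------

def cohort_to_dataframe(cohort: Sequence[PatientDetails]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = asdict(p)
        for key in ("onset_time", "target_treatment_time"):
            t = row[key]
            row[key] = None if t is None else f"{t.hour:02d}:{t.minute:02d}"
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_to_csv(cohort: Sequence[PatientDetails], path: str | Path) -> None:
    cohort_to_dataframe(cohort).to_csv(path, index=False)


def cohort_from_csv(path: str | Path) -> list[PatientDetails]:
    from .validation import parse_clock_time

    df = pd.read_csv(path)
    cohort = []
    for _, row in df.iterrows():
        kwargs = {}
        for name, value in row.items():
            if pd.isna(value):
                kwargs[name] = None
            elif name in ("onset_time", "target_treatment_time"):
                kwargs[name] = parse_clock_time(str(value))
            elif name in ("nihss", "pre_stroke_mrs"):
                kwargs[name] = int(value)
            elif name in ("age", "systolic_bp", "glucose", "weight"):
                kwargs[name] = float(value)
            elif name == "sex":
                kwargs[name] = str(value)
            else:
                kwargs[name] = bool(value)
        cohort.append(PatientDetails(**kwargs))
    return cohort
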