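# Methods

## The decision-analytic model

The engine predicts a three-category outcome distribution at 3 months —
functional independence (mRS 0–2), dependence (mRS 3–5), death — for each
treatment arm, from two binary logistic equations per arm (independence and
death). Dependence is derived by complement. This two-equation-plus-
complement construction is a deliberate design choice: the lineage of
thrombolysis prediction instruments is binary logistic models, and the
complement is the minimal construction consistent with a three-state
presentation. Its one failure mode — the two modelled probabilities summing
above 1 for extreme inputs — is handled by proportional rescaling of both to
sum to 1 − 1e-9, and the event is flagged on the returned prediction
(`degenerate=True`) rather than silently absorbed.

The treated-arm equations are interpreted as **conditional on no SICH**. The
final treated distribution is the mixture
`(1 − p_sich)·base + p_sich·post_sich`. This interpretation avoids
double-counting haemorrhage harm that would occur if the base equations were
read as marginal and the SICH branch were added on top; it is an
interpretation, not a mathematical necessity, and is stated here prominently
for that reason.

SICH risk is an additive integer score: each satisfied item (boolean flag or
numeric threshold) contributes its points, and the total maps through an
ordered band table to a probability. Invariants enforced at load time: the
bands partition the achievable score range 0..max exactly, and band
probabilities are non-decreasing, which gives the engine's monotonicity
property (setting any risk flag never lowers the SICH probability).

Net benefit is the absolute difference in probability of independence,
treated minus untreated. It deliberately ignores the dependence category;
mortality is reported alongside, never folded into a single index. No
probability clamping occurs beyond the overflow-safe inverse logit: extreme
inputs produce extreme probabilities plus licence warnings — plausibility is
owned by the validation layer, not the arithmetic.

## The model spec and its JSON schema

All clinical content is configuration, never code: the four outcome
equations (outcome × arm), the SICH score table, the post-SICH outcome
proportions, the licence-criteria table, a semantic version and production
date, and the two horizon labels. The document is JSON with a stable key
order; `write_model_spec` ∘ `load_model_spec` is the identity on the parsed
tree and serialisation is byte-deterministic. Top-level keys: `version`,
`production_date`, `time_horizon_label`, `sich_horizon_label`, `equations`
(list of `{outcome, arm, intercept, terms:[{predictor, transform,
coefficient}]}` with transforms `identity` | `indicator` | `linear`), `sich`
(`items:[{predictor, condition:{type, threshold?}, points}]`,
`risk_map:[{band:[lo,hi], probability}]`), `post_sich`, and `licence`
(`fields.<name>` → `validity`, `licence`, `warnings:[{range, message}]`,
`digits`).

**The bundled default spec is illustrative.** The signs and rough magnitudes
are clinically sensible — independence decreasing with age, stroke severity
(NIHSS), glucose, diabetes, prior stroke and (treated arm) onset-to-treatment
time; mortality increasing with age and severity; 90-day mortality nearly
equal between arms before the SICH branch — but the numbers are not fitted
to any dataset. The SICH table follows the structure of published
routine-practice haemorrhage scores (dual antiplatelet exposure, severity
bands, hyperglycaemia, age, blood pressure, weight, treatment delay); its
points and band probabilities are likewise placeholders. The file's
`_comment` field says so, and the README repeats it.

## Recalibration

`recalibrate_intercepts` shifts an equation's intercept so the cohort-mean
predicted probability equals an observed proportion ("calibration in the
large"). Slopes never change. Because a mean of logistic curves is strictly
increasing in a shared intercept shift, the root is unique; it is found by
bisection on a ±10 bracket (tolerance 1e-8 on the residual, with an interval
safeguard two orders tighter). The per-patient linear predictors are computed
once and the bisection iterates on the vectorised mean, so a 10,000-patient
recalibration takes well under a second. Unattainable targets (outside the
bracket's image) raise an error carrying the residual.

## Validation layer

Every entered field is classified into exactly three states: `invalid`
(outside the hard validity range — no licence judgement is attached),
`outwith_licence` (valid but outside the licence range or inside a
configured warning range; always carries a message), `within_licence`.
Printed rules: the 4.5 h onset-to-treatment window; NIHSS warnings below 5
and above 25 carrying the licence's relative-contraindication text verbatim
(the single message covers both the minor-deficit and severe-stroke cases);
systolic BP free-text entry restricted to 2–3 digits. The remaining bounds
(age 18–80, BP ≤ 185 mmHg, glucose 2.8–22.2 mmol/L, digit rules for other
fields) come from the alteplase product licence and are configurable table
entries, not engine constants. Pre-stroke mRS 3–5 attaches the advisory note
that predictions apply to pre-stroke mRS 0–2; it does not block computation.

Clock times accept `hhmm`, `hh:mm` and `hh.mm` dialects
(grammar `^(\d{1,2})[:.]\d{2}$ | ^\d{3,4}$`, last two digits are minutes,
hour ≤ 23, minute ≤ 59). When the target treatment time precedes onset on
the clock the duration wraps exactly once past midnight — onset-to-treatment
intervals are hours-scale, so durations are always in [0, 24). Editing any
field marks a cached prediction stale unconditionally, even when the
re-entered value is identical: a presentation must never be shown against
edited inputs.

## Natural frequencies and presentations

All "out of 100 patients" counts use largest-remainder rounding: floor each
quota, then give the shortfall to the largest fractional remainders, ties
broken by the fixed category order (independent, dependent, dead). This is
the standard exact-sum apportionment method; per-category error is below one
icon and each panel's counts sum to exactly 100. The SICH count is the
two-category rounding of (p_sich, 1 − p_sich) — so a 1% risk is always
exactly 1 icon.

The pictograph is two 10×10 grids in reading order, icons grouped by
category. H-marked (SICH-attributable) icons in the treated grid are
allocated across categories by the same rounding rule applied to the
post-SICH proportions, nested at the end of each category block, clamped so
no category carries more H icons than it has icons (overflow spills to
categories with room). This nesting preserves both the outcome totals and
the SICH count; the exact visual arrangement is this package's documented
convention, not a claim about any particular deployed layout. Colour tokens:
green for independence, amber for dependence, dark grey for death,
configurable.

The clustered bar chart shows percentages to 0.1; the flowchart juxtaposes
the SICH / no-SICH branch counts with stacked bars whose segments sum to
100. All three presentations derive from the same prediction and agree on
the per-arm counts. Renderers (SVG 1.1 and plain text, one character per
icon with H overrides) are pure string builders — identical input yields
byte-identical output.

## Clinical calculators

NIHSS: the published 15-item scale with per-item maxima encoded in a data
table (sum of maxima 42); the motor, ataxia and dysarthria items accept the
scale's untestable code "UN", scored 0. rt-PA dosage: 0.9 mg/kg capped at
90 mg, 10% bolus, remainder infused over 60 minutes at 1 mg/ml, vials of
50 mg (`ceil(total/50)`); all constants are named module-level values. The
glucose converter uses the conventional clinical factor 18.0 rather than the
exact molar 18.016 — determinism and convention over false precision; weight
conversion uses the exact 0.45359237 kg/lb.

## Synthetic cohorts

The generator emulates a thrombolysis-eligible acute-stroke population:
age ~ truncated normal (70, 12.5) on [45, 95] (symmetric ±2 sd about the
mean, so truncation does not bias it), NIHSS ~ rounded truncated normal
(10, 6) on [0, 42], systolic BP (150, 20) on [90, 220] mmHg, glucose
(6.5, 2.0) on [3, 20] mmol/L, weight (78, 15) on [40, 150] kg,
onset-to-treatment (2.5, 1.0) h truncated to the licence window [0.5, 4.5];
flag prevalences: diabetes 0.20, prior stroke 0.15, clopidogrel 0.10,
hypertension 0.50, antiplatelet 0.30, visible infarction 0.15; pre-stroke
mRS 0/1/2 with probabilities 0.6/0.25/0.15. Covariates are sampled
**independently** — real registries show correlation between age, severity
and comorbidity, so passing tests demonstrate engine correctness on
realistic marginals, not calibration to any real population. Outcome
simulation draws each patient's label from their predicted distribution
(equation-level by default; optionally after the SICH mixture), reproducibly
by seed.

## Problem sizes and numerical choices

Distribution conservation is asserted to 1e-9 everywhere. Recalibration
tolerance is 1e-8 (bisection, bracket ±10). The recalibration recovery
experiment — perturb all intercepts by +0.5, simulate outcomes from the true
spec, recalibrate on the empirical proportions — uses n = 10,000 patients,
at which the recovered intercepts land within ~0.04 of the truth (binomial
noise in the simulated proportions, shrinking as 1/√n); the residual between
recalibrated mean prediction and target is at the optimiser tolerance. Test
cohorts elsewhere use n = 25–5,000 as appropriate to the property checked.

## Known limitations

- The default spec's coefficients, SICH table and post-SICH proportions are
  placeholders; every number downstream of them is illustrative.
- The licence-criteria table ships the printed rules plus standard licence
  bounds; institutions must review and extend it (it is config, so no code
  change is needed).
- The three-category construction via complement is an interpretation (see
  above), as is the conditional-on-no-SICH reading of the treated equations.
- Synthetic cohorts have independent covariates and are not calibrated to
  any registry's marginals.
- The session log mirrors a deployed tool's usage categories but the CLI is
  single-shot; "time in use" is only meaningful across logged invocations
  sharing a session id.
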