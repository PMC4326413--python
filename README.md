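# strokeaid

Patient-specific decision support for intravenous thrombolysis (rt-PA /
alteplase) in acute ischaemic stroke. The package is a library plus CLI for
stroke physicians, nurse practitioners and researchers who need, at the
bedside or in simulation, a personalised answer to: *out of 100 patients like
this one, how many would be independent, dependent or dead at 3 months — with
and without clot-busting treatment?*

## The model

For each treatment arm $a \in \{\text{treated}, \text{untreated}\}$, two
logistic equations predict the 3-month probability of functional independence
(modified Rankin Scale 0–2) and of death:

$$\operatorname{logit} p_{\text{ind}}^{(a)} = \beta_0^{(a)} + \boldsymbol{\beta}^{(a)\top}\mathbf{x}, \qquad
\operatorname{logit} p_{\text{dead}}^{(a)} = \gamma_0^{(a)} + \boldsymbol{\gamma}^{(a)\top}\mathbf{x},$$

with dependence (mRS 3–5) the complement $1 - p_{\text{ind}} - p_{\text{dead}}$.
Predictors $\mathbf{x}$ include age, NIHSS, glucose, history flags and — in the
treated arm — onset-to-treatment time, whose negative coefficient makes
benefit decay with delay.

The principal harm of treatment, symptomatic intracranial haemorrhage (SICH,
typically within 24–36 h), enters as a branch: an additive score over patient
features (clopidogrel use, antiplatelet use, hypertension history, NIHSS,
glucose, age, blood pressure, weight, time to treatment) maps through a
banded risk table to $p_{\text{SICH}}$, and the treated distribution is the
mixture

$$\text{treated} = (1 - p_{\text{SICH}})\cdot\text{treated}\mid\text{no SICH} \;+\; p_{\text{SICH}}\cdot\text{post-SICH},$$

where the post-SICH outcome proportions are fixed configuration. The
headline statistic is **net benefit**
$\Delta = p_{\text{ind}}^{\text{treated}} - p_{\text{ind}}^{\text{untreated}}$,
presented as natural frequencies out of 100 patients (exact
largest-remainder rounding).

All clinical content — coefficients, SICH table, post-SICH proportions,
licence criteria — lives in a versioned JSON model spec. **The bundled
default is illustrative** (plausible signs and magnitudes, not fitted to any
registry); substitute published, validated coefficients before any clinical
use. Equation intercepts can be recalibrated so cohort-mean predictions match
observed outcome proportions.

Around the engine sit the supporting features of a bedside tool: instant
three-state field validation against the treatment licence (within licence /
outwith licence / invalid, with the relative-contraindication warnings for
NIHSS < 5 and > 25 and the 4.5 h window), pictograph / clustered-bar /
flowchart risk presentations with the letter H marking SICH-attributable
icons, a timeline of net benefit against onset-to-treatment time, the NIHSS
calculator, the rt-PA dosage calculator, and weight/glucose unit converters.

## Worked example

A 70-year-old man, NIHSS 12, systolic BP 150 mmHg, glucose 6.0 mmol/L,
80 kg, hypertensive, treated 1.5 h after onset:

```sh
strokeaid predict \
  --age 70 --sex male --onset-time 10:00 --target-treatment-time 11:30 \
  --nihss 12 --systolic-bp 150 --glucose 6.0 --weight 80 \
  --diabetes no --prior-stroke no --clopidogrel-use no \
  --hypertension-history yes --antiplatelet-use no \
  --pre-stroke-mrs 0 --infarction-on-imaging no
```

prints (abridged):

```json
{
  "time_horizon": "3 months",
  "untreated": {"independent": 0.3543, "dependent": 0.3996, "dead": 0.246},
  "treated":   {"independent": 0.5331, "dependent": 0.2532, "dead": 0.2137},
  "p_sich": 0.01,
  "net_benefit": 0.1787
}
```

Under the illustrative default spec, 35 of 100 such patients would be
independent at 3 months without treatment and 53 with it — a net benefit of
18 per 100 — while 1 in 100 treated patients suffers a SICH (his score of 3
points comes from NIHSS ≥ 7, BP ≥ 146 and the hypertension history). Add
`--render pictograph` for the two 10×10 icon grids (H marks the SICH icon)
and the summary box. The timeline shows the benefit decaying with delay,
crossing zero near 4 h:

```
$ strokeaid timeline ... (same patient flags)
ott_hours,net_benefit_per_100
0.5,25.12
1.5,17.87
3,6.54
4.5,-3.75
```

And the dosage calculator:

```
$ strokeaid dose --weight 70
total dose: 63.0 mg
bolus: 6.3 ml
IV infusion: 56.7 ml/hr over 60 minutes
50 mg vials needed: 2
```

Other subcommands: `validate`, `nihss`, `convert-weight`, `convert-glucose`,
`cohort` (synthetic patients as CSV), `recalibrate`, `log-summary`.

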