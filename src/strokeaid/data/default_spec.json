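{
  "_comment": "Illustrative default model specification. The outcome-equation coefficients, SICH score table and post-SICH proportions shipped here are plausible placeholder content with clinically sensible signs (benefit decreasing with age, stroke severity and onset-to-treatment time; mortality increasing with age and severity). They are NOT fitted to any registry and must be replaced with externally published, validated coefficients before any clinical use. Licence bounds beyond the 4.5 h treatment window and the NIHSS <5 / >25 relative-contraindication warnings are taken from the product licence for alteplase and are configurable.",
  "version": "1.0.0",
  "production_date": "2026-09-23",
  "time_horizon_label": "3 months",
  "sich_horizon_label": "within 24–36 hours after clot-busting treatment",
  "equations": [
    {
      "outcome": "independent",
      "arm": "untreated",
      "intercept": 5.0,
      "terms": [
        {"predictor": "age", "transform": "identity", "coefficient": -0.05},
        {"predictor": "nihss", "transform": "identity", "coefficient": -0.15},
        {"predictor": "glucose", "transform": "identity", "coefficient": -0.05},
        {"predictor": "diabetes", "transform": "indicator", "coefficient": -0.3},
        {"predictor": "prior_stroke", "transform": "indicator", "coefficient": -0.25}
      ]
    },
    {
      "outcome": "independent",
      "arm": "treated",
      "intercept": 6.2,
      "terms": [
        {"predictor": "age", "transform": "identity", "coefficient": -0.05},
        {"predictor": "nihss", "transform": "identity", "coefficient": -0.15},
        {"predictor": "glucose", "transform": "identity", "coefficient": -0.05},
        {"predictor": "diabetes", "transform": "indicator", "coefficient": -0.3},
        {"predictor": "prior_stroke", "transform": "indicator", "coefficient": -0.25},
        {"predictor": "onset_to_treatment", "transform": "identity", "coefficient": -0.3}
      ]
    },
    {
      "outcome": "dead",
      "arm": "untreated",
      "intercept": -6.0,
      "terms": [
        {"predictor": "age", "transform": "identity", "coefficient": 0.05},
        {"predictor": "nihss", "transform": "identity", "coefficient": 0.1},
        {"predictor": "glucose", "transform": "identity", "coefficient": 0.03}
      ]
    },
    {
      "outcome": "dead",
      "arm": "treated",
      "intercept": -6.2,
      "terms": [
        {"predictor": "age", "transform": "identity", "coefficient": 0.05},
        {"predictor": "nihss", "transform": "identity", "coefficient": 0.1},
        {"predictor": "glucose", "transform": "identity", "coefficient": 0.03}
      ]
    }
  ],
  "sich": {
    "items": [
      {"predictor": "clopidogrel_use", "condition": {"type": "flag"}, "points": 2},
      {"predictor": "antiplatelet_use", "condition": {"type": "flag"}, "points": 1},
      {"predictor": "hypertension_history", "condition": {"type": "flag"}, "points": 1},
      {"predictor": "nihss", "condition": {"type": "ge", "threshold": 7}, "points": 1},
      {"predictor": "nihss", "condition": {"type": "ge", "threshold": 13}, "points": 1},
      {"predictor": "glucose", "condition": {"type": "ge", "threshold": 10.0}, "points": 2},
      {"predictor": "age", "condition": {"type": "ge", "threshold": 72}, "points": 1},
      {"predictor": "systolic_bp", "condition": {"type": "ge", "threshold": 146}, "points": 1},
      {"predictor": "weight", "condition": {"type": "ge", "threshold": 95}, "points": 1},
      {"predictor": "onset_to_treatment", "condition": {"type": "ge", "threshold": 3.0}, "points": 1}
    ],
    "risk_map": [
      {"band": [0, 1], "probability": 0.004},
      {"band": [2, 3], "probability": 0.01},
      {"band": [4, 5], "probability": 0.018},
      {"band": [6, 8], "probability": 0.035},
      {"band": [9, 12], "probability": 0.09}
    ]
  },
  "post_sich": {"p_independent": 0.1, "p_dependent": 0.4, "p_dead": 0.5},
  "licence": {
    "fields": {
      "age": {
        "validity": [0, 120],
        "licence": [18, 80],
        "warnings": [],
        "digits": [0, 4]
      },
      "systolic_bp": {
        "validity": [40, 300],
        "licence": [40, 185],
        "warnings": [
          {"range": [186, 300], "message": "Systolic blood pressure above 185 mmHg is outwith the licensing criteria for rt-PA; blood pressure should be lowered before treatment is considered."}
        ],
        "digits": [1, 4]
      },
      "glucose": {
        "validity": [0.5, 40.0],
        "licence": [2.8, 22.2],
        "warnings": [],
        "digits": [0, 4]
      },
      "nihss": {
        "validity": [0, 42],
        "licence": [5, 25],
        "warnings": [
          {"range": [0, 4], "message": "The license states that a minor neurological deficit or severe stroke as assessed clinically (NIHSS > 25) are relative contraindications to treatment with rt-PA. For patients with mild stroke the risks may outweigh the expected benefit. Patients with very severe stroke are at increased risk of intra-cerebral haemorrhage."},
          {"range": [26, 42], "message": "The license states that a minor neurological deficit or severe stroke as assessed clinically (NIHSS > 25) are relative contraindications to treatment with rt-PA. For patients with mild stroke the risks may outweigh the expected benefit. Patients with very severe stroke are at increased risk of intra-cerebral haemorrhage."}
        ],
        "digits": [0, 3]
      },
      "onset_to_treatment": {
        "validity": [0.0, 24.0],
        "licence": [0.0, 4.5],
        "warnings": [],
        "digits": null
      },
      "weight": {
        "validity": [20, 300],
        "licence": [20, 300],
        "warnings": [],
        "digits": [1, 4]
      },
      "pre_stroke_mrs": {
        "validity": [0, 5],
        "licence": [0, 2],
        "warnings": [
          {"range": [3, 5], "message": "Please note: predicted clinical outcomes at 3 months apply to patients with pre-stroke modified Rankin scores of 0 to 2"}
        ],
        "digits": [0, 2]
      },
      "onset_time": {
        "validity": null,
        "licence": null,
        "warnings": [],
        "digits": [2, 5]
      },
      "target_treatment_time": {
        "validity": null,
        "licence": null,
        "warnings": [],
        "digits": [2, 5]
      }
    }
  }
}
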