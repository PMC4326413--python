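"""The decision-analytic engine: linear predictors, SICH branch, conservation."""

import dataclasses
import math

import pytest
from hypothesis import given, settings, strategies as st

from strokeaid import (
    MissingPredictorError,
    OutcomeDistribution,
    PatientDetails,
    apply_sich_mixture,
    categorize_mrs,
    linear_predictor,
    logistic,
    predict,
    predict_arm,
    sich_probability,
    sich_score,
    timeline,
)
from strokeaid.model_spec import EquationTerm, OutcomeEquation, PostSichDistribution


def make_equation(intercept, terms=(), outcome="independent", arm="treated"):
    return OutcomeEquation(
        outcome=outcome, arm=arm, intercept=intercept,
        terms=tuple(EquationTerm(*t) for t in terms),
    )


class TestLinearPredictor:
    def test_intercept_only(self, patient):
        assert linear_predictor(make_equation(1.2), patient) == 1.2

    def test_single_term_arithmetic(self, patient):
        eq = make_equation(0.0, [("age", "identity", 0.5)])
        assert linear_predictor(eq, patient) == pytest.approx(35.0)

    def test_default_spec_equation_matches_dot_product_oracle(self, spec, patient):
        eq = spec.equation("independent", "treated")
        # spreadsheet-style oracle: resolve each predictor by hand
        values = {"age": 70.0, "nihss": 12.0, "glucose": 6.0,
                  "diabetes": 0.0, "prior_stroke": 0.0, "onset_to_treatment": 1.5}
        expected = eq.intercept + sum(
            t.coefficient * values[t.predictor] for t in eq.terms
        )
        assert linear_predictor(eq, patient) == pytest.approx(expected, abs=1e-12)

    def test_indicator_transform_maps_flags_to_unit_values(self, patient):
        eq = make_equation(0.0, [("hypertension_history", "indicator", 2.0)])
        assert linear_predictor(eq, patient) == 2.0  # flag is True

    def test_missing_predictor_named_in_error(self, spec):
        sparse = PatientDetails(age=70.0)
        with pytest.raises(MissingPredictorError, match="nihss"):
            linear_predictor(spec.equation("dead", "untreated"), sparse)


class TestLogistic:
    def test_symmetry_point(self):
        assert logistic(0.0) == 0.5

    def test_value_at_one_to_seven_decimals(self):
        # e/(1+e), high-precision reference value
        assert logistic(1.0) == pytest.approx(0.7310586, abs=5e-8)

    @settings(deadline=None, derandomize=True)
    @given(x=st.floats(-700, 700, allow_nan=False))
    def test_symmetry_identity_and_open_interval(self, x):
        assert logistic(x) + logistic(-x) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= logistic(x) <= 1.0

    def test_overflow_safe_at_extremes(self):
        assert logistic(1000.0) == pytest.approx(1.0)
        assert logistic(-1000.0) == pytest.approx(0.0)


class TestPredictArm:
    def _forced_spec(self, spec, p_ind, p_dead, arm="untreated"):
        lp_ind = math.log(p_ind / (1 - p_ind))
        lp_dead = math.log(p_dead / (1 - p_dead))
        eqs = []
        for eq in spec.equations:
            if eq.arm == arm and eq.outcome == "independent":
                eqs.append(make_equation(lp_ind, outcome="independent", arm=arm))
            elif eq.arm == arm and eq.outcome == "dead":
                eqs.append(make_equation(lp_dead, outcome="dead", arm=arm))
            else:
                eqs.append(eq)
        return dataclasses.replace(spec, equations=tuple(eqs))

    def test_dependence_is_the_complement(self, spec, patient):
        forced = self._forced_spec(spec, 0.4, 0.2)
        dist, degenerate = predict_arm(patient, forced, "untreated")
        assert not degenerate
        assert dist.as_tuple() == pytest.approx((0.4, 0.4, 0.2), abs=1e-9)

    def test_negative_complement_rescales_proportionally(self, spec, patient):
        forced = self._forced_spec(spec, 0.7, 0.5)
        dist, degenerate = predict_arm(patient, forced, "untreated")
        assert degenerate
        scale = (1 - 1e-9) / 1.2
        assert dist.p_independent == pytest.approx(0.7 * scale, rel=1e-9)
        assert dist.p_dead == pytest.approx(0.5 * scale, rel=1e-9)
        assert sum(dist.as_tuple()) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        b_ind=st.floats(-4, 4), b_dead=st.floats(-4, 4),
        age_coef=st.floats(-0.1, 0.1), nihss_coef=st.floats(-0.3, 0.3),
    )
    def test_distribution_always_sums_to_one(self, spec, b_ind, b_dead, age_coef, nihss_coef):
        patient = PatientDetails(age=70.0, nihss=12, glucose=6.0,
                                 diabetes=False, prior_stroke=False)
        eqs = []
        for eq in spec.equations:
            terms = [("age", "identity", age_coef), ("nihss", "identity", nihss_coef)]
            b = b_ind if eq.outcome == "independent" else b_dead
            eqs.append(make_equation(b, terms, outcome=eq.outcome, arm=eq.arm))
        random_spec = dataclasses.replace(spec, equations=tuple(eqs))
        for arm in ("treated", "untreated"):
            dist, _ = predict_arm(patient, random_spec, arm)
            assert sum(dist.as_tuple()) == pytest.approx(1.0, abs=1e-9)


class TestSich:
    def test_no_item_satisfied_maps_to_lowest_band(self, spec):
        calm = PatientDetails(
            age=50.0, nihss=4, glucose=5.0, systolic_bp=120.0, weight=70.0,
            onset_time=None, target_treatment_time=None,
            clopidogrel_use=False, hypertension_history=False, antiplatelet_use=False,
        )
        assert sich_score(calm, spec, ott_override=1.0) == 0
        assert sich_probability(calm, spec, ott_override=1.0) == spec.sich.risk_map[0][1]

    def test_points_sum_and_band_lookup(self, spec, patient):
        # fixture patient: nihss 12 (>=7: 1 pt), BP 150 (>=146: 1 pt),
        # hypertension history (1 pt) -> score 3
        assert sich_score(patient, spec) == 3
        expected = next(p for (lo, hi), p in spec.sich.risk_map if lo <= 3 <= hi)
        assert sich_probability(patient, spec) == expected

    def test_scoring_flags_never_decrease_probability(self, spec, patient):
        base = sich_probability(patient, spec)
        for flag in ("clopidogrel_use", "antiplatelet_use"):
            riskier = dataclasses.replace(patient, **{flag: True})
            assert sich_probability(riskier, spec) >= base


class TestSichMixture:
    POST = PostSichDistribution(0.1, 0.5, 0.4)

    def test_zero_probability_is_identity(self):
        base = OutcomeDistribution(0.5, 0.3, 0.2)
        assert apply_sich_mixture(base, 0.0, self.POST) == base

    def test_certain_sich_is_absorbing(self):
        base = OutcomeDistribution(0.5, 0.3, 0.2)
        mixed = apply_sich_mixture(base, 1.0, self.POST)
        assert mixed.as_tuple() == pytest.approx(self.POST.as_tuple())

    def test_mixture_arithmetic(self):
        mixed = apply_sich_mixture(OutcomeDistribution(0.5, 0.3, 0.2), 0.05, self.POST)
        assert mixed.as_tuple() == pytest.approx((0.48, 0.31, 0.21), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(p_sich=st.floats(0, 1), a=st.floats(0.01, 0.98))
    def test_conservation_for_any_sich_probability(self, p_sich, a):
        b = (1 - a) / 2
        mixed = apply_sich_mixture(OutcomeDistribution(a, b, 1 - a - b), p_sich, self.POST)
        assert sum(mixed.as_tuple()) == pytest.approx(1.0, abs=1e-9)


class TestPredict:
    def test_composes_the_component_operations(self, spec, patient):
        pred = predict(patient, spec)
        untreated, _ = predict_arm(patient, spec, "untreated")
        base_treated, _ = predict_arm(patient, spec, "treated")
        p_sich = sich_probability(patient, spec)
        treated = apply_sich_mixture(base_treated, p_sich, spec.post_sich)
        assert pred.untreated == untreated
        assert pred.treated == treated
        assert pred.p_sich == p_sich
        assert pred.net_benefit == treated.p_independent - untreated.p_independent

    def test_net_benefit_ignores_the_dependent_category(self, spec, patient):
        pred = predict(patient, spec)
        assert pred.net_benefit == pred.treated.p_independent - pred.untreated.p_independent

    def test_identical_arms_and_no_sich_gives_zero_net_benefit(self, spec, patient):
        eqs = []
        for eq in spec.equations:
            source = spec.equation(eq.outcome, "untreated")
            eqs.append(dataclasses.replace(source, arm=eq.arm))
        zero_sich = dataclasses.replace(
            spec.sich,
            risk_map=tuple(((lo, hi), 0.0) for (lo, hi), _ in spec.sich.risk_map),
        )
        same = dataclasses.replace(spec, equations=tuple(eqs), sich=zero_sich)
        pred = predict(patient, same)
        assert pred.net_benefit == pytest.approx(0.0, abs=1e-12)
        assert pred.treated == pred.untreated

    def test_natural_frequency_phrasing_example(self, spec, patient):
        pred = predict(patient, spec)
        f = pred.frequencies
        assert f["denominator"] == 100
        assert f["net_benefit"] == f["treated"]["independent"] - f["untreated"]["independent"]


class TestTimeline:
    def test_single_point_grid_matches_predict(self, spec, patient):
        ott = 1.5
        curve = timeline(patient, spec, [ott])
        assert curve.net_benefit[0] == predict(patient, spec).net_benefit

    def test_grid_length_contract(self, spec, patient):
        grid = [1.0 + 0.5 * i for i in range(8)]   # 1.0 … 4.5
        curve = timeline(patient, spec, grid)
        assert len(curve.grid_hours) == len(curve.net_benefit) == 8

    def test_benefit_decays_with_onset_to_treatment_time(self, spec, patient):
        # the default treated-independence equation has a negative OTT slope
        grid = [0.5 * (i + 1) for i in range(9)]
        curve = timeline(patient, spec, grid)
        diffs = [b - a for a, b in zip(curve.net_benefit, curve.net_benefit[1:])]
        assert all(d <= 0 for d in diffs)

    def test_grid_outside_validity_rejected(self, spec, patient):
        with pytest.raises(ValueError, match="validity"):
            timeline(patient, spec, [25.0])


class TestCategorizeMrs:
    @pytest.mark.parametrize("mrs, category", [
        (0, "independent"), (2, "independent"),
        (3, "dependent"), (5, "dependent"),
        (6, "dead"),
    ])
    def test_printed_boundaries(self, mrs, category):
        assert categorize_mrs(mrs) == category

    @pytest.mark.parametrize("bad", [-1, 7, 2.5, "2"])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            categorize_mrs(bad)
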