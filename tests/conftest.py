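import pytest

from strokeaid import PatientDetails, default_model_spec, parse_clock_time


@pytest.fixture(scope="session")
def spec():
    return default_model_spec()


@pytest.fixture
def patient():
    """A mid-range thrombolysis-eligible patient (OTT 1.5 h)."""
    return PatientDetails(
        age=70.0,
        sex="male",
        onset_time=parse_clock_time("10:00"),
        target_treatment_time=parse_clock_time("11:30"),
        nihss=12,
        systolic_bp=150.0,
        glucose=6.0,
        weight=80.0,
        diabetes=False,
        prior_stroke=False,
        clopidogrel_use=False,
        hypertension_history=True,
        antiplatelet_use=False,
        pre_stroke_mrs=0,
        infarction_on_imaging=False,
    )
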