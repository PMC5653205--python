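import pytest

from epoct.clinical_model import PatientPresentation, default_standards


@pytest.fixture(scope="session")
def standards():
    return default_standards()


def build_patient(**overrides) -> PatientPresentation:
    """Afebrile-symptom-free eligible child; nested dicts merge over defaults."""
    base = dict(
        patient_id="t-001",
        age_months=24,
        sex="male",
        weight_kg=11.0,
        muac_mm=140.0,
        temperature_c=38.0,
        fever_duration_days=2,
        symptoms={},
        vitals=dict(respiratory_rate_per_min=30.0, heart_rate_per_min=120.0, sao2_percent=98.0),
        poct=dict(
            mrdt_positive=False,
            hb_g_per_l=110.0,
            glucose_mmol_per_l=5.0,
            crp_band="lt10",
            pct_ug_per_l=0.3,
            urine_dipstick_positive=False,
            typhidot_positive=False,
        ),
    )
    for key, value in overrides.items():
        if key in ("symptoms", "vitals", "poct") and isinstance(value, dict):
            base[key] = {**base[key], **value}
        else:
            base[key] = value
    return PatientPresentation(**base)


@pytest.fixture
def make_patient():
    return build_patient
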