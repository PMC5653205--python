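"""The e-POCT classification cascade.

Severe triage runs first (CNS danger signs, severe respiratory distress,
severe anemia by hemoglobin, severe malnutrition by anthropometry, severe
dehydration, hypoglycemia, corneal clouding / severe mouth ulcers); any
severe classification forces referral with a pre-referral intramuscular
antibiotic, and adds severe malaria when the malaria rapid test is
positive. Non-severe patients proceed through the staged point-of-care
cascade: malaria test, hemoglobin and oximetry for everyone; glucometer
when a danger branch fires; CRP for coughing children with
age/temperature-corrected tachypnea and for fever without source with a
negative malaria test; procalcitonin only when CRP stays below the
bacterial band. Antibiotics are restricted to severe disease, bacterial
lower respiratory infection (CRP >= 80 mg/l), fever without source with
CRP >= 80 mg/l and/or PCT >= 4 ug/l, and bacterial skin diagnoses.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .classification import (
    SEVERE_CLASSIFICATIONS,
    Classification,
    ClassificationResult,
    fever_without_source,
    significant_diarrhea_vomiting,
)
from .clinical_model import (
    BACTERIAL_SKIN_KINDS,
    CRPBand,
    PatientPresentation,
    ReferenceStandards,
    SpeechLevel,
    weight_for_age_z,
)
from .errors import IncompleteWorkupError

__all__ = [
    "TEST_MRDT",
    "TEST_HB",
    "TEST_SAO2",
    "TEST_GLUCOSE",
    "TEST_CRP",
    "TEST_PCT",
    "ManagementConfig",
    "required_tests_epoct",
    "classify_epoct",
]

TEST_MRDT = "mrdt"
TEST_HB = "hb"
TEST_SAO2 = "sao2"
TEST_GLUCOSE = "glucose"
TEST_CRP = "crp"
TEST_PCT = "pct"

# canonical ordering used for the antibiotic_reason of severe patients
_SEVERE_ORDER = (
    Classification.CNS_DANGER,
    Classification.SEVERE_RESPIRATORY,
    Classification.SEVERE_ANEMIA,
    Classification.SEVERE_MALNUTRITION,
    Classification.SEVERE_DEHYDRATION,
    Classification.HYPOGLYCEMIA,
    Classification.OTHER_SEVERE,
    Classification.SEVERE_MALARIA,
)


@dataclass(frozen=True)
class ManagementConfig:
    """Classification -> treatment mapping, encoded as replaceable data."""

    severe_antibiotic: str = "im_antibiotic"
    oral_antibiotic: str = "oral_antibiotic"
    supportive: dict[Classification, tuple[str, ...]] = field(
        default_factory=lambda: {
            Classification.UNCOMPLICATED_MALARIA: ("antimalarial",),
            Classification.SEVERE_MALARIA: ("antimalarial",),
            Classification.GI_DEHYDRATION: ("ors",),
            Classification.VIRAL_LRTI: ("bronchodilator",),
            Classification.NON_SEVERE_ANEMIA: ("iron",),
            Classification.SKIN_INFECTION: ("skin_topical",),
        }
    )


_DEFAULT_MANAGEMENT = ManagementConfig()


def _severe_clinical(
    patient: PatientPresentation, standards: ReferenceStandards
) -> dict[Classification, bool]:
    """Severe rules that need no glucometer reading."""
    s = patient.symptoms
    v = patient.vitals
    p = patient.poct
    rr97 = standards.rr_curve_p97(patient.age_months, patient.temperature_c)
    hr90 = standards.hr_curve_p90(patient.age_months, patient.temperature_c)
    wfa_z = weight_for_age_z(patient.age_months, patient.sex, patient.weight_kg, standards)

    severe_resp = (
        s.speech_level == SpeechLevel.SINGLE_WORDS_OR_GRUNTS
        or (
            s.speech_level == SpeechLevel.SHORT_PHRASES_OR_SHORT_CRIES
            and s.lower_chest_indrawing
        )
        or v.respiratory_rate_per_min >= rr97
        or (v.sao2_percent is not None and v.sao2_percent < standards.sao2_severe_percent)
    )
    return {
        Classification.CNS_DANGER: (
            s.severe_lethargy
            or s.stiff_neck
            or s.convulsions_count >= standards.epoct_convulsion_threshold
        ),
        Classification.SEVERE_RESPIRATORY: severe_resp,
        Classification.SEVERE_ANEMIA: (
            p.hb_g_per_l is not None and p.hb_g_per_l < standards.hb_severe_g_l
        ),
        Classification.SEVERE_MALNUTRITION: (
            wfa_z < standards.wfa_z_severe
            or (
                patient.muac_mm is not None
                and patient.muac_mm < standards.muac_severe_mm
                and patient.age_months > standards.muac_min_age_months
            )
        ),
        Classification.SEVERE_DEHYDRATION: (
            s.not_tolerating_oral_liquids
            and v.heart_rate_per_min is not None
            and v.heart_rate_per_min >= hr90
        ),
        Classification.OTHER_SEVERE: s.clouding_cornea or s.severe_mouth_ulcers,
    }


def required_tests_epoct(
    patient: PatientPresentation,
    performed: Iterable[str] = (),
    standards: ReferenceStandards | None = None,
) -> Optional[str]:
    """Next point-of-care test demanded by the cascade, or ``None``.

    Total function: malaria rapid test, hemoglobin and oximetry for all
    patients; glucometer once a danger branch fires; CRP for cough with
    tachypnea (>= 75th percentile) or fever without source with negative
    malaria test; procalcitonin when such fever-without-source CRP stays
    below the bacterial band.
    """
    standards = standards or ReferenceStandards()
    done = set(performed)
    for token in (TEST_MRDT, TEST_HB, TEST_SAO2):
        if token not in done:
            return token
    severe = _severe_clinical(patient, standards)
    if any(severe.values()):
        if TEST_GLUCOSE not in done:
            return TEST_GLUCOSE
        return None  # severe path: cascade complete, biomarkers not needed
    s = patient.symptoms
    rr75 = standards.rr_curve_p75(patient.age_months, patient.temperature_c)
    if s.cough and patient.vitals.respiratory_rate_per_min >= rr75:
        if TEST_CRP not in done:
            return TEST_CRP
        return None
    if fever_without_source(patient, standards) and not patient.poct.mrdt_positive:
        if TEST_CRP not in done:
            return TEST_CRP
        if (
            patient.poct.crp_band != standards.crp_bacterial_band
            and TEST_PCT not in done
        ):
            return TEST_PCT
    return None


_VALUE_ACCESSORS = {
    TEST_MRDT: lambda p: p.poct.mrdt_positive,
    TEST_HB: lambda p: p.poct.hb_g_per_l,
    TEST_SAO2: lambda p: p.vitals.sao2_percent,
    TEST_GLUCOSE: lambda p: p.poct.glucose_mmol_per_l,
    TEST_CRP: lambda p: p.poct.crp_band,
    TEST_PCT: lambda p: p.poct.pct_ug_per_l,
}


def _run_cascade(patient: PatientPresentation, standards: ReferenceStandards) -> list[str]:
    performed: list[str] = []
    while True:
        nxt = required_tests_epoct(patient, performed, standards)
        if nxt is None:
            return performed
        if _VALUE_ACCESSORS[nxt](patient) is None:
            raise IncompleteWorkupError(
                f"patient {patient.patient_id}: cascade demands '{nxt}' "
                "but no result is recorded"
            )
        performed.append(nxt)


def classify_epoct(
    patient: PatientPresentation,
    standards: ReferenceStandards | None = None,
    management: ManagementConfig = _DEFAULT_MANAGEMENT,
) -> ClassificationResult:
    """Classify one presentation and derive the management plan."""
    standards = standards or ReferenceStandards()
    tests = _run_cascade(patient, standards)
    trace: list[tuple[str, bool]] = []

    def fire(rule_id: str, value: bool) -> bool:
        trace.append((rule_id, bool(value)))
        return bool(value)

    s = patient.symptoms
    v = patient.vitals
    p = patient.poct

    severe = {
        cls for cls, hit in _severe_clinical(patient, standards).items() if hit
    }
    for cls in _SEVERE_ORDER[:-1]:
        if cls == Classification.HYPOGLYCEMIA:
            continue
        fire(f"severe.{cls.value}", cls in severe)
    if TEST_GLUCOSE in tests:
        if fire(
            "severe.hypoglycemia",
            p.glucose_mmol_per_l is not None
            and p.glucose_mmol_per_l < standards.glucose_hypo_mmol_l,
        ):
            severe.add(Classification.HYPOGLYCEMIA)
    if severe and fire("severe.severe_malaria", p.mrdt_positive):
        severe.add(Classification.SEVERE_MALARIA)

    if severe:
        reason = next(c for c in _SEVERE_ORDER if c in severe)
        treatments = [management.severe_antibiotic, "antipyretic"]
        if Classification.SEVERE_MALARIA in severe:
            treatments.extend(management.supportive[Classification.SEVERE_MALARIA])
        return ClassificationResult(
            patient_id=patient.patient_id,
            algorithm="epoct",
            classifications=frozenset(severe),
            referral=True,
            antibiotic_day0=True,
            antibiotic_reason=reason,
            treatments=tuple(dict.fromkeys(treatments)),
            tests_performed=tuple(tests),
            rule_trace=tuple(trace),
        )

    # --- non-severe cascade ------------------------------------------------
    classifications: set[Classification] = set()
    antibiotic_reason: Optional[Classification] = None

    rr75 = standards.rr_curve_p75(patient.age_months, patient.temperature_c)
    if fire("resp.cough", s.cough):
        if fire("resp.tachypnea_p75", v.respiratory_rate_per_min >= rr75):
            if fire("resp.crp_bacterial", p.crp_band == standards.crp_bacterial_band):
                classifications.add(Classification.BACTERIAL_LRTI)
                antibiotic_reason = antibiotic_reason or Classification.BACTERIAL_LRTI
            else:
                classifications.add(Classification.VIRAL_LRTI)
        else:
            classifications.add(Classification.URTI)

    if fire("gi.significant_diarrhea_vomiting", significant_diarrhea_vomiting(patient, standards)):
        classifications.add(Classification.GI_DEHYDRATION)

    if fire("skin.lesion_present", s.skin_lesion is not None):
        classifications.add(Classification.SKIN_INFECTION)
        if fire("skin.bacterial_subtype", s.skin_lesion.kind in BACTERIAL_SKIN_KINDS):
            antibiotic_reason = antibiotic_reason or Classification.SKIN_INFECTION

    if fire("malaria.mrdt_positive", p.mrdt_positive):
        classifications.add(Classification.UNCOMPLICATED_MALARIA)

    if fire("fws.branch", fever_without_source(patient, standards) and not p.mrdt_positive):
        bacterial = fire("fws.crp_bacterial", p.crp_band == standards.crp_bacterial_band)
        if not bacterial and TEST_PCT in tests:
            bacterial = fire(
                "fws.pct_bacterial",
                p.pct_ug_per_l is not None
                and p.pct_ug_per_l >= standards.pct_bacterial_ug_l,
            )
        if bacterial:
            classifications.add(Classification.FWS_BACTERIAL)
            antibiotic_reason = antibiotic_reason or Classification.FWS_BACTERIAL
        else:
            classifications.add(Classification.FWS_VIRAL)

    if p.hb_g_per_l is not None:
        cutoff = standards.hb_anemia_cutoff(patient.age_months)
        if fire(
            "anemia.non_severe",
            standards.hb_severe_g_l <= p.hb_g_per_l < cutoff,
        ):
            classifications.add(Classification.NON_SEVERE_ANEMIA)

    # antibiotic priority: bacterial LRTI > FWS bacterial > bacterial skin
    if Classification.BACTERIAL_LRTI in classifications:
        antibiotic_reason = Classification.BACTERIAL_LRTI
    elif Classification.FWS_BACTERIAL in classifications:
        antibiotic_reason = Classification.FWS_BACTERIAL

    treatments: list[str] = ["antipyretic"]
    if antibiotic_reason is not None:
        treatments.insert(0, management.oral_antibiotic)
    for cls in classifications:
        supportive = management.supportive.get(cls, ())
        if cls == Classification.SKIN_INFECTION and antibiotic_reason == cls:
            supportive = ()  # bacterial lesions get the systemic course instead
        treatments.extend(supportive)

    return ClassificationResult(
        patient_id=patient.patient_id,
        algorithm="epoct",
        classifications=frozenset(classifications),
        referral=False,
        antibiotic_day0=antibiotic_reason is not None,
        antibiotic_reason=antibiotic_reason,
        treatments=tuple(dict.fromkeys(treatments)),
        tests_performed=tuple(tests),
        rule_trace=tuple(trace),
    )
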