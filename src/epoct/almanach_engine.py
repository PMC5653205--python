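"""The ALMANACH control cascade (electronic IMCI-derived algorithm).

Purely clinical severe triage (lethargy/stiff neck/any convulsion, chest
indrawing/cyanosis/stridor, severe palmar pallor, the IMCI dehydration
sign combinations, visible severe wasting or bilateral pedal edema,
jaundice / mastoid swelling / large or complicated skin lesions), then the
IMCI non-severe branches. The only point-of-care inputs are the malaria
rapid test for everyone, urine dipstick for under-2s with fever without
source (or any child with dysuria), and the rapid typhoid assay for
2-year-olds and older with fever without source. The engine never reads
CRP, PCT, oximetry, hemoglobin, or glucose.
"""
from __future__ import annotations

from typing import Iterable, Optional

from .classification import (
    Classification,
    ClassificationResult,
    fever_without_source,
    significant_diarrhea_vomiting,
)
from .clinical_model import (
    PatientPresentation,
    ReferenceStandards,
    SkinPinch,
)
from .errors import IncompleteWorkupError

__all__ = [
    "TEST_MRDT",
    "TEST_URINE_DIPSTICK",
    "TEST_TYPHIDOT",
    "required_tests_almanach",
    "classify_almanach",
]

TEST_MRDT = "mrdt"
TEST_URINE_DIPSTICK = "urine_dipstick"
TEST_TYPHIDOT = "typhidot"

_SEVERE_ORDER = (
    Classification.CNS_DANGER,
    Classification.SEVERE_RESPIRATORY,
    Classification.SEVERE_ANEMIA,
    Classification.SEVERE_DEHYDRATION,
    Classification.SEVERE_MALNUTRITION,
    Classification.OTHER_SEVERE,
)

#: dipstick applies to under-2s, typhoid testing from the 2nd birthday on
FWS_TEST_AGE_SPLIT_MONTHS = 24


def _fws_branch(patient: PatientPresentation, standards: ReferenceStandards) -> bool:
    # ear discharge / dysuria stay inside the branch: they define its
    # likely-bacterial outcome rather than excluding it
    return fever_without_source(patient, standards, ignore_urinary_ear=True)


def required_tests_almanach(
    patient: PatientPresentation,
    performed: Iterable[str] = (),
    standards: ReferenceStandards | None = None,
) -> Optional[str]:
    """Next test demanded by the control cascade, or ``None``."""
    standards = standards or ReferenceStandards()
    done = set(performed)
    if TEST_MRDT not in done:
        return TEST_MRDT
    fws = _fws_branch(patient, standards)
    if (
        (fws and patient.age_months < FWS_TEST_AGE_SPLIT_MONTHS)
        or patient.symptoms.dysuria
    ) and TEST_URINE_DIPSTICK not in done:
        return TEST_URINE_DIPSTICK
    if (
        fws
        and patient.age_months >= FWS_TEST_AGE_SPLIT_MONTHS
        and TEST_TYPHIDOT not in done
    ):
        return TEST_TYPHIDOT
    return None


_VALUE_ACCESSORS = {
    TEST_MRDT: lambda p: p.poct.mrdt_positive,
    TEST_URINE_DIPSTICK: lambda p: p.poct.urine_dipstick_positive,
    TEST_TYPHIDOT: lambda p: p.poct.typhidot_positive,
}


def _run_cascade(patient: PatientPresentation, standards: ReferenceStandards) -> list[str]:
    performed: list[str] = []
    while True:
        nxt = required_tests_almanach(patient, performed, standards)
        if nxt is None:
            return performed
        if _VALUE_ACCESSORS[nxt](patient) is None:
            raise IncompleteWorkupError(
                f"patient {patient.patient_id}: cascade demands '{nxt}' "
                "but no result is recorded"
            )
        performed.append(nxt)


def _severe_set(
    patient: PatientPresentation, standards: ReferenceStandards
) -> set[Classification]:
    s = patient.symptoms
    severe: set[Classification] = set()
    if (
        s.severe_lethargy
        or s.stiff_neck
        or s.convulsions_count >= standards.almanach_convulsion_threshold
    ):
        severe.add(Classification.CNS_DANGER)
    if s.lower_chest_indrawing or s.cyanosis or s.stridor:
        severe.add(Classification.SEVERE_RESPIRATORY)
    if s.severe_palmar_pallor:
        severe.add(Classification.SEVERE_ANEMIA)
    dehydration_signs = sum(
        (
            s.severe_lethargy,
            s.sunken_eyes,
            s.unable_to_drink,
            s.skin_pinch == SkinPinch.VERY_SLOW,
        )
    )
    if s.vomits_everything or dehydration_signs >= 2:
        severe.add(Classification.SEVERE_DEHYDRATION)
    if s.visible_severe_wasting or s.edema_both_feet:
        severe.add(Classification.SEVERE_MALNUTRITION)
    lesion = s.skin_lesion
    severe_lesion = lesion is not None and (
        lesion.largest_diameter_cm > standards.skin_lesion_severe_cm
        or lesion.red_streaks
        or lesion.tender_nodes
        or lesion.multiple_abscesses
    )
    if s.jaundice or s.tender_swelling_behind_ear or severe_lesion:
        severe.add(Classification.OTHER_SEVERE)
    return severe


def classify_almanach(
    patient: PatientPresentation,
    standards: ReferenceStandards | None = None,
) -> ClassificationResult:
    """Classify one presentation with the control cascade."""
    standards = standards or ReferenceStandards()
    tests = _run_cascade(patient, standards)
    trace: list[tuple[str, bool]] = []

    def fire(rule_id: str, value: bool) -> bool:
        trace.append((rule_id, bool(value)))
        return bool(value)

    s = patient.symptoms
    severe = _severe_set(patient, standards)
    for cls in _SEVERE_ORDER:
        fire(f"severe.{cls.value}", cls in severe)

    if severe:
        reason = next(c for c in _SEVERE_ORDER if c in severe)
        treatments = ["im_antibiotic", "antipyretic"]
        if patient.poct.mrdt_positive:
            treatments.append("antimalarial")
        return ClassificationResult(
            patient_id=patient.patient_id,
            algorithm="almanach",
            classifications=frozenset(severe),
            referral=True,
            antibiotic_day0=True,
            antibiotic_reason=reason,
            treatments=tuple(dict.fromkeys(treatments)),
            tests_performed=tuple(tests),
            rule_trace=tuple(trace),
        )

    classifications: set[Classification] = set()
    antibiotic_reason: Optional[Classification] = None

    if fire("resp.cough", s.cough):
        if fire(
            "resp.very_fast_breathing",
            patient.vitals.respiratory_rate_per_min
            >= standards.almanach_very_fast_breathing,
        ):
            classifications.add(Classification.CLINICAL_PNEUMONIA)
            antibiotic_reason = Classification.CLINICAL_PNEUMONIA
        else:
            classifications.add(Classification.URTI)

    gi_signs = sum(
        (
            s.restless_irritable,
            s.sunken_eyes,
            s.drinks_eagerly,
            s.skin_pinch == SkinPinch.SLOW,
        )
    )
    if fire(
        "gi.dehydration",
        (s.diarrhea_stools_24h >= 1 or s.vomiting_episodes_24h >= 1) and gi_signs >= 2,
    ):
        classifications.add(Classification.GI_DEHYDRATION)

    if fire("skin.non_severe_lesion", s.skin_lesion is not None):
        # severe lesion features were excluded above
        classifications.add(Classification.SKIN_INFECTION)
        antibiotic_reason = antibiotic_reason or Classification.SKIN_INFECTION

    if fire("malaria.mrdt_positive", patient.poct.mrdt_positive):
        classifications.add(Classification.UNCOMPLICATED_MALARIA)

    if fire("fws.branch", _fws_branch(patient, standards) and not patient.poct.mrdt_positive):
        bacterial = fire("fws.purulent_ear_discharge", s.ear_discharge)
        if TEST_URINE_DIPSTICK in tests:
            bacterial = (
                fire("fws.urine_dipstick_positive", bool(patient.poct.urine_dipstick_positive))
                or bacterial
            )
        if TEST_TYPHIDOT in tests:
            bacterial = (
                fire("fws.typhidot_positive", bool(patient.poct.typhidot_positive))
                or bacterial
            )
        if bacterial:
            classifications.add(Classification.FWS_BACTERIAL)
            antibiotic_reason = antibiotic_reason or Classification.FWS_BACTERIAL
        else:
            classifications.add(Classification.FWS_VIRAL)

    # antibiotic priority: pneumonia > FWS bacterial > skin
    if Classification.CLINICAL_PNEUMONIA in classifications:
        antibiotic_reason = Classification.CLINICAL_PNEUMONIA
    elif Classification.FWS_BACTERIAL in classifications:
        antibiotic_reason = Classification.FWS_BACTERIAL

    treatments: list[str] = ["antipyretic"]
    if antibiotic_reason is not None:
        treatments.insert(0, "oral_antibiotic")
    if Classification.UNCOMPLICATED_MALARIA in classifications:
        treatments.append("antimalarial")
    if Classification.GI_DEHYDRATION in classifications:
        treatments.append("ors")

    return ClassificationResult(
        patient_id=patient.patient_id,
        algorithm="almanach",
        classifications=frozenset(classifications),
        referral=False,
        antibiotic_day0=antibiotic_reason is not None,
        antibiotic_reason=antibiotic_reason,
        treatments=tuple(dict.fromkeys(treatments)),
        tests_performed=tuple(tests),
        rule_trace=tuple(trace),
    )
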