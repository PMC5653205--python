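"""Trial outcome definitions: clinical failure by day 7, the "not cured"
re-treatment rule, and severe adverse events by day 30.

Clinical failure is a composite: development of severe symptoms at any
time through the day-7 assessment (coma, more than 2 convulsions in 24 h,
inability to drink or breastfeed, SaO2 < 90%, severe tachypnea or severe
tachycardia against the same age/temperature percentile curves the triage
engines use), clinical pneumonia or significant dehydration at the day-3
contact, or persistent illness at the day-7 contact (fever, clinical
pneumonia, >= 3 liquid stools/day, significant dehydration, serious skin
infection, or a new significant symptom absent at day 0). Scheduled-visit
day windows default to the observed ranges (day 3: days 2-5; day 7: days
6-12) and are configurable through the standards registry.
"""
from __future__ import annotations

import enum
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .clinical_model import (
    FollowUpObservation,
    PatientPresentation,
    ReferenceStandards,
    validate_observation_sequence,
)
from .errors import RecordValidationError

__all__ = ["SAEKind", "OutcomeAssessment", "assess_failure", "not_cured", "assess_sae"]

#: convulsion count above which the severe criterion fires ("more than 2")
_FAILURE_CONVULSIONS_GT = 2

FOLLOW_UP_HORIZON_DAY = 30


class SAEKind(str, enum.Enum):
    SECONDARY_ADMISSION = "secondary_admission"
    DEATH = "death"


class OutcomeAssessment(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patient_id: str
    clinical_failure: Optional[bool]  # None when lost to follow-up
    failure_day: Optional[int] = None
    failure_criteria: tuple[str, ...] = ()
    not_cured_flags: dict[int, bool] = {}
    severe_adverse_event: bool = False
    sae_kind: Optional[SAEKind] = None
    lost_to_followup: bool = False

    @model_validator(mode="after")
    def _check(self) -> "OutcomeAssessment":
        if self.clinical_failure and not self.failure_criteria:
            raise RecordValidationError("clinical failure requires at least one criterion")
        if (self.sae_kind is not None) != self.severe_adverse_event:
            raise RecordValidationError("sae_kind must be set iff severe_adverse_event")
        return self


def _severe_criteria(
    obs: FollowUpObservation,
    baseline: PatientPresentation,
    standards: ReferenceStandards,
) -> list[str]:
    """Severe-disease failure criteria, applicable at any contact."""
    hits: list[str] = []
    if obs.coma:
        hits.append("coma")
    if obs.convulsions_24h > _FAILURE_CONVULSIONS_GT:
        hits.append("convulsions")
    if obs.unable_to_drink_or_breastfeed:
        hits.append("unable_to_drink")
    if obs.sao2_percent is not None and obs.sao2_percent < standards.sao2_severe_percent:
        hits.append("hypoxemia")
    # percentile thresholds reuse the engines' curves; afebrile contacts
    # are evaluated at the lower edge of the temperature grid
    temp = obs.temperature_c if obs.temperature_c is not None else 37.5
    if obs.respiratory_rate_per_min is not None:
        if obs.respiratory_rate_per_min >= standards.rr_curve_p97(
            baseline.age_months, temp
        ):
            hits.append("severe_tachypnea")
    if obs.heart_rate_per_min is not None:
        if obs.heart_rate_per_min >= standards.hr_curve_p90(baseline.age_months, temp):
            hits.append("severe_tachycardia")
    return hits


def _clinical_pneumonia(
    obs: FollowUpObservation,
    baseline: PatientPresentation,
    standards: ReferenceStandards,
) -> bool:
    if not obs.cough_history:
        return False
    if obs.lower_chest_indrawing:
        return True
    return (
        obs.respiratory_rate_per_min is not None
        and obs.respiratory_rate_per_min
        >= standards.failure_tachypnea(baseline.age_months)
    )


def _day3_criteria(
    obs: FollowUpObservation,
    baseline: PatientPresentation,
    standards: ReferenceStandards,
) -> list[str]:
    hits: list[str] = []
    if _clinical_pneumonia(obs, baseline, standards):
        hits.append("clinical_pneumonia_day3")
    if obs.dehydration_requiring_facility_care:
        hits.append("significant_dehydration_day3")
    return hits


def _day7_criteria(
    obs: FollowUpObservation,
    baseline: PatientPresentation,
    standards: ReferenceStandards,
) -> list[str]:
    hits: list[str] = []
    if obs.fever_reported or (
        obs.temperature_c is not None
        and obs.temperature_c >= standards.fever_followup_c
    ):
        hits.append("fever_day7")
    if _clinical_pneumonia(obs, baseline, standards):
        hits.append("clinical_pneumonia_day7")
    if obs.diarrhea_stools_per_day >= standards.diarrhea_failure_stools_per_day:
        hits.append("diarrhea_day7")
    if obs.dehydration_requiring_facility_care:
        hits.append("significant_dehydration_day7")
    if obs.skin_infection_requiring_systemic_or_facility_care:
        hits.append("serious_skin_infection_day7")
    if obs.new_significant_symptom:
        hits.append("new_significant_symptom_day7")
    return hits


def assess_failure(
    observations: Sequence[FollowUpObservation],
    baseline: PatientPresentation,
    standards: ReferenceStandards | None = None,
) -> OutcomeAssessment:
    """Evaluate the composite clinical-failure outcome for one patient.

    Observations must be sorted by day. A patient with no contact inside
    the day-7 window (and no earlier qualifying event or death) is flagged
    lost to follow-up with ``clinical_failure=None``.
    """
    standards = standards or ReferenceStandards()
    validate_observation_sequence(observations)
    d3_lo, d3_hi = standards.day3_window
    d7_lo, d7_hi = standards.day7_window

    failure_day: Optional[int] = None
    criteria: list[str] = []
    not_cured_flags: dict[int, bool] = {}
    died = False
    day7_contact = False

    for obs in observations:
        if obs.day > d7_hi:
            if obs.died:
                died = True
            continue
        died = died or obs.died
        day7_contact = day7_contact or (d7_lo <= obs.day <= d7_hi)
        not_cured_flags[obs.day] = not_cured(obs, standards)

        hits = _severe_criteria(obs, baseline, standards)
        if d3_lo <= obs.day <= d3_hi:
            hits.extend(_day3_criteria(obs, baseline, standards))
        if d7_lo <= obs.day <= d7_hi:
            hits.extend(_day7_criteria(obs, baseline, standards))
        if hits:
            if failure_day is None:
                failure_day = obs.day
            criteria.extend(h for h in hits if h not in criteria)

    sae, sae_kind = assess_sae(observations)
    lost = not day7_contact and not died
    if failure_day is not None:
        clinical_failure: Optional[bool] = True
    elif lost:
        clinical_failure = None
    else:
        clinical_failure = False
    return OutcomeAssessment(
        patient_id=baseline.patient_id,
        clinical_failure=clinical_failure,
        failure_day=failure_day,
        failure_criteria=tuple(criteria),
        not_cured_flags=not_cured_flags,
        severe_adverse_event=sae,
        sae_kind=sae_kind,
        lost_to_followup=lost and failure_day is None,
    )


def not_cured(
    observation: FollowUpObservation, standards: ReferenceStandards | None = None
) -> bool:
    """Re-treatment trigger: caregiver considers the child still ill, or fever."""
    standards = standards or ReferenceStandards()
    return (
        observation.caregiver_considers_ill
        or observation.fever_reported
        or (
            observation.temperature_c is not None
            and observation.temperature_c >= standards.fever_enrollment_c
        )
    )


def assess_sae(
    observations: Sequence[FollowUpObservation],
) -> tuple[bool, Optional[SAEKind]]:
    """Severe adverse events by day 30: death, else secondary admission.

    Day-0 admissions following a primary referral do not count as
    secondary admissions.
    """
    for obs in observations:
        if obs.day <= FOLLOW_UP_HORIZON_DAY and obs.died:
            return True, SAEKind.DEATH
    for obs in observations:
        if 0 < obs.day <= FOLLOW_UP_HORIZON_DAY and obs.hospitalized:
            return True, SAEKind.SECONDARY_ADMISSION
    return False, None
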