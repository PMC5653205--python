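"""Disease classifications and the management-plan result shared by both engines."""
from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .clinical_model import PatientPresentation, ReferenceStandards
from .errors import RecordValidationError


class Classification(str, enum.Enum):
    # severe block — any of these forces referral
    CNS_DANGER = "cns_danger"
    SEVERE_RESPIRATORY = "severe_respiratory"
    SEVERE_ANEMIA = "severe_anemia"
    SEVERE_MALNUTRITION = "severe_malnutrition"
    SEVERE_DEHYDRATION = "severe_dehydration"
    HYPOGLYCEMIA = "hypoglycemia"
    OTHER_SEVERE = "other_severe"
    SEVERE_MALARIA = "severe_malaria"
    # non-severe
    URTI = "urti"
    VIRAL_LRTI = "viral_lrti"
    BACTERIAL_LRTI = "bacterial_lrti"
    CLINICAL_PNEUMONIA = "clinical_pneumonia"
    FWS_VIRAL = "fws_viral"
    FWS_BACTERIAL = "fws_bacterial"
    UNCOMPLICATED_MALARIA = "uncomplicated_malaria"
    GI_DEHYDRATION = "gi_dehydration"
    SKIN_INFECTION = "skin_infection"
    NON_SEVERE_ANEMIA = "non_severe_anemia"


SEVERE_CLASSIFICATIONS = frozenset(
    {
        Classification.CNS_DANGER,
        Classification.SEVERE_RESPIRATORY,
        Classification.SEVERE_ANEMIA,
        Classification.SEVERE_MALNUTRITION,
        Classification.SEVERE_DEHYDRATION,
        Classification.HYPOGLYCEMIA,
        Classification.OTHER_SEVERE,
        Classification.SEVERE_MALARIA,
    }
)


class ClassificationResult(BaseModel):
    """Classifications plus the management plan and an audit trail.

    Invariants: ``referral`` is true exactly when a severe classification
    is present; an antibiotic on day 0 always carries the classification
    that justified it.
    """

    model_config = ConfigDict(extra="forbid")

    patient_id: str
    algorithm: str
    classifications: frozenset[Classification]
    referral: bool
    antibiotic_day0: bool
    antibiotic_reason: Optional[Classification] = None
    treatments: tuple[str, ...] = ()
    tests_performed: tuple[str, ...] = ()
    rule_trace: tuple[tuple[str, bool], ...] = Field(default=(), repr=False)

    @model_validator(mode="after")
    def _check_invariants(self) -> "ClassificationResult":
        severe = bool(self.classifications & SEVERE_CLASSIFICATIONS)
        if self.referral != severe:
            raise RecordValidationError(
                "referral flag must equal presence of a severe classification"
            )
        if self.antibiotic_day0:
            if self.antibiotic_reason is None:
                raise RecordValidationError("antibiotic_day0 without antibiotic_reason")
            if self.antibiotic_reason not in self.classifications:
                raise RecordValidationError(
                    "antibiotic_reason must be one of the classifications"
                )
        return self


def significant_diarrhea_vomiting(
    patient: PatientPresentation, standards: ReferenceStandards
) -> bool:
    """Significant diarrhea and/or vomiting over the past 24 hours.

    >5 loose stools, or >=3 loose stools together with any emesis, or
    >3 emeses.
    """
    s = patient.symptoms
    return (
        s.diarrhea_stools_24h > standards.significant_diarrhea_stools_gt
        or (
            s.diarrhea_stools_24h >= standards.combined_diarrhea_stools_ge
            and s.vomiting_episodes_24h >= 1
        )
        or s.vomiting_episodes_24h > standards.combined_emesis_gt
    )


def fever_without_source(
    patient: PatientPresentation,
    standards: ReferenceStandards,
    *,
    ignore_urinary_ear: bool = False,
) -> bool:
    """Fever with no localizing complaint.

    Operationalized as: no cough, no significant diarrhea/vomiting and no
    skin lesion; unless ``ignore_urinary_ear``, ear discharge and dysuria
    also count as localizing. (The control cascade keeps ear discharge and
    urinary complaints inside its fever-without-source branch, where they
    define the likely-bacterial outcome.)
    """
    s = patient.symptoms
    if s.cough or s.skin_lesion is not None:
        return False
    if significant_diarrhea_vomiting(patient, standards):
        return False
    if not ignore_urinary_ear and (s.ear_discharge or s.dysuria):
        return False
    return True
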