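"""Seeded generative model of a pediatric febrile outpatient cohort.

Each simulated child carries a latent etiology (viral URTI/LRTI, bacterial
pneumonia, malaria, urinary infection, typhoid, severe anemia, severe
malnutrition, gastroenteritis, skin disease, or fever without source of
viral/bacterial origin). The latent condition drives the presentation:
symptoms, age-appropriate vitals with condition offsets, and the full
staged panel of point-of-care results (malaria rapid test with configured
sensitivity, hemoglobin, oximetry, glucose, semi-quantitative CRP band,
procalcitonin, urine dipstick, rapid typhoid test). Follow-up trajectories
depend on the match between the care the condition requires (antibiotic,
referral, supportive treatment) and the management actually delivered:
missing required care multiplies the failure probability by a configured
factor, and unnecessary antibiotics carry a smaller configured penalty.

All rates and effect sizes are illustrative calibrations chosen to mimic
the marginal structure of a low-malaria-endemicity urban outpatient
cohort (about 44/33/23% in the 2-11/12-23/24-59 month age bands, ~12%
malaria-test positive, a few percent with severe disease); they are
config, not estimates. Randomness follows a one-root-seed contract with
hierarchical per-patient substreams, so enlarging a cohort never
reshuffles already-generated patients.
"""
from __future__ import annotations

import math
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .classification import Classification, ClassificationResult
from .clinical_model import (
    CRPBand,
    ContactType,
    FollowUpObservation,
    PatientPresentation,
    POCTResults,
    ReferenceStandards,
    Sex,
    SkinLesion,
    SkinLesionKind,
    SymptomSet,
    VitalSigns,
)
from .errors import ConfigurationError
from . import trial_stats
from .outcome_engine import assess_failure

__all__ = [
    "CONDITIONS",
    "REQUIRED_CARE",
    "CohortConfig",
    "OutcomeModel",
    "generate_cohort",
    "simulate_followup",
    "simulate_trial",
    "epoct_policy",
    "almanach_policy",
    "routine_care_policy",
]

CONDITIONS = (
    "viral_urti",
    "viral_lrti",
    "bacterial_pneumonia",
    "malaria",
    "uti",
    "typhoid",
    "severe_anemia_state",
    "severe_malnutrition_state",
    "gastroenteritis",
    "skin_condition",
    "fws_viral_state",
    "fws_bacterial_state",
)

#: latent condition -> (needs_antibiotic, needs_referral, supportive token)
REQUIRED_CARE: dict[str, tuple[bool, bool, Optional[str]]] = {
    "viral_urti": (False, False, None),
    "viral_lrti": (False, False, "bronchodilator"),
    "bacterial_pneumonia": (True, False, None),
    "malaria": (False, False, "antimalarial"),
    "uti": (True, False, None),
    "typhoid": (True, False, None),
    "severe_anemia_state": (True, True, None),
    "severe_malnutrition_state": (True, True, None),
    "gastroenteritis": (False, False, "ors"),
    "skin_condition": (False, False, "skin_topical"),
    "fws_viral_state": (False, False, None),
    "fws_bacterial_state": (True, False, None),
}

_AGE_BANDS = {"2_11": (2, 11), "12_23": (12, 23), "24_59": (24, 59)}

_BACTERIAL_CONDITIONS = frozenset(
    {"bacterial_pneumonia", "uti", "typhoid", "fws_bacterial_state"}
)


class OutcomeModel(BaseModel):
    """Management-dependent follow-up model (illustrative calibration)."""

    model_config = ConfigDict(extra="forbid")

    base_failure_prob: dict[str, float] = {
        "viral_urti": 0.015,
        "viral_lrti": 0.030,
        "bacterial_pneumonia": 0.080,
        "malaria": 0.020,
        "uti": 0.040,
        "typhoid": 0.050,
        "severe_anemia_state": 0.060,
        "severe_malnutrition_state": 0.050,
        "gastroenteritis": 0.030,
        "skin_condition": 0.015,
        "fws_viral_state": 0.010,
        "fws_bacterial_state": 0.060,
    }
    #: factor applied when required antibiotic/referral care is withheld
    inappropriate_multiplier: float = Field(default=3.0, ge=1.0)
    #: factor applied when an antibiotic is given without need
    unnecessary_antibiotic_multiplier: float = Field(default=1.5, ge=1.0)
    sae_given_failure: float = Field(default=0.15, ge=0, le=1)
    death_given_sae: float = Field(default=0.10, ge=0, le=1)
    #: daily probability that fever resolves
    fever_resolution_p: float = Field(default=0.45, gt=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "OutcomeModel":
        missing = [c for c in CONDITIONS if c not in self.base_failure_prob]
        if missing:
            raise ConfigurationError(
                "base_failure_prob missing condition(s): " + ", ".join(missing)
            )
        for c, p in self.base_failure_prob.items():
            if not (0 <= p <= 1):
                raise ConfigurationError(f"base_failure_prob[{c}] outside [0, 1]")
        return self


class CohortConfig(BaseModel):
    """Everything the generator needs; defaults are the study conditions."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(gt=0)
    seed: int = 0
    etiology_mix: dict[str, float] = {
        "viral_urti": 0.202,
        "viral_lrti": 0.23,
        "bacterial_pneumonia": 0.02,
        "malaria": 0.11,
        "uti": 0.015,
        "typhoid": 0.005,
        "severe_anemia_state": 0.012,
        "severe_malnutrition_state": 0.008,
        "gastroenteritis": 0.110,
        "skin_condition": 0.045,
        "fws_viral_state": 0.220,
        "fws_bacterial_state": 0.023,
    }
    age_distribution: dict[str, float] = {"2_11": 0.44, "12_23": 0.33, "24_59": 0.23}
    sex_male_prob: float = Field(default=0.55, ge=0, le=1)
    mrdt_sensitivity: float = Field(default=0.97, ge=0, le=1)
    mrdt_false_positive: float = Field(default=0.01, ge=0, le=1)
    ltf_probability: float = Field(default=0.004, ge=0, le=1)
    outcome_model: OutcomeModel = Field(default_factory=OutcomeModel)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        for name, mix in (("etiology_mix", self.etiology_mix), ("age_distribution", self.age_distribution)):
            bad = [k for k, v in mix.items() if not (0 <= v <= 1)]
            if bad:
                raise ConfigurationError(f"{name} has probabilities outside [0, 1]: {bad}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")
        unknown = set(self.etiology_mix) - set(CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown conditions in etiology_mix: {sorted(unknown)}")
        if set(self.age_distribution) != set(_AGE_BANDS):
            raise ConfigurationError(
                f"age_distribution must use bands {sorted(_AGE_BANDS)}"
            )
        return self


def _patient_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    """Hierarchical substream: stable under cohort extension."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream, index)))


_FEVER_DURATION_DAYS = np.arange(1, 8)
_FEVER_DURATION_P = np.array([0.63, 0.15, 0.12, 0.08, 0.01, 0.007, 0.003])

_RR_BASE = {"2_11": 40.0, "12_23": 35.0, "24_59": 30.0}
_HR_BASE = {"2_11": 150.0, "12_23": 145.0, "24_59": 135.0}

_CRP_BANDS = (CRPBand.LT10, CRPBand.B10_39, CRPBand.B40_79, CRPBand.GE80)
_CRP_P_VIRAL = np.array([0.70, 0.24, 0.05, 0.01])
_CRP_P_BACTERIAL = np.array([0.10, 0.20, 0.20, 0.50])


def _draw_band(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    keys = sorted(dist)
    return keys[rng.choice(len(keys), p=np.array([dist[k] for k in keys]))]


def _generate_patient(
    index: int, condition: str, config: CohortConfig, standards: ReferenceStandards
) -> PatientPresentation:
    rng = _patient_rng(config.seed, 0, index)
    band = _draw_band(rng, config.age_distribution)
    lo, hi = _AGE_BANDS[band]
    age = int(rng.integers(lo, hi + 1))
    sex = Sex.MALE if rng.random() < config.sex_male_prob else Sex.FEMALE

    # anthropometry through the growth reference (weight-for-age z-scale)
    if condition == "severe_malnutrition_state":
        z = rng.normal(-3.6, 0.4)
        muac = rng.normal(108.0, 6.0)
    else:
        z = rng.normal(-0.8, 1.3)
        muac = rng.normal(145.0, 12.0)
    z = float(np.clip(z, -4.5, 4.0))
    weight = max(2.5, standards.wfa_reference.weight_at_z(age, sex, z))
    muac = max(80.0, muac)

    temp = 37.5 + rng.gamma(2.0, 0.35)
    if condition in ("malaria", "typhoid", "bacterial_pneumonia"):
        temp += 0.4
    temp = float(np.clip(temp, 37.5, 41.0))

    rr = rng.normal(_RR_BASE[band], 6.0)
    hr = rng.normal(_HR_BASE[band], 15.0)
    sao2 = 99.0 - abs(rng.normal(0.0, 1.2))

    update: dict = {}
    if condition == "viral_urti":
        update.update(cough=True, cough_duration_days=int(rng.integers(1, 4)))
        if rng.random() < 0.7:
            update["rhinorrhea"] = True
    elif condition == "viral_lrti":
        update.update(cough=True, cough_duration_days=int(rng.integers(1, 5)))
        rr += 12.0
    elif condition == "bacterial_pneumonia":
        update.update(cough=True, cough_duration_days=int(rng.integers(2, 6)))
        rr += 14.0
        if rng.random() < 0.05:
            sao2 = rng.uniform(85.0, 89.5)
    elif condition == "gastroenteritis":
        update["diarrhea_stools_24h"] = 3 + int(rng.poisson(3.0))
        update["vomiting_episodes_24h"] = int(rng.poisson(1.2))
        for flag, p in (
            ("restless_irritable", 0.5),
            ("sunken_eyes", 0.3),
            ("drinks_eagerly", 0.3),
        ):
            if rng.random() < p:
                update[flag] = True
        if rng.random() < 0.3:
            update["skin_pinch"] = "slow"
    elif condition == "skin_condition":
        kinds = list(SkinLesionKind)
        update["skin_lesion"] = SkinLesion(
            kind=kinds[int(rng.integers(0, len(kinds)))],
            largest_diameter_cm=float(np.clip(rng.lognormal(0.5, 0.5), 0.2, 8.0)),
            red_streaks=rng.random() < 0.03,
            tender_nodes=rng.random() < 0.03,
            multiple_abscesses=rng.random() < 0.02,
        )
    elif condition == "severe_anemia_state":
        if rng.random() < 0.6:
            update["severe_palmar_pallor"] = True
    elif condition == "severe_malnutrition_state":
        if rng.random() < 0.4:
            update["visible_severe_wasting"] = True
    elif condition == "uti":
        if age >= 24 and rng.random() < 0.5:
            update["dysuria"] = True
    symptoms = SymptomSet(**update)

    # point-of-care panel (full panel generated; engines stage what they use)
    if condition == "malaria":
        mrdt = rng.random() < config.mrdt_sensitivity
    else:
        mrdt = rng.random() < config.mrdt_false_positive
    if condition == "severe_anemia_state":
        hb = float(np.clip(rng.normal(50.0, 7.0), 25.0, 59.5))
    else:
        hb = float(np.clip(rng.normal(97.0, 15.0), 61.0, 180.0))
    glucose = float(np.clip(rng.normal(5.0, 0.9), 1.5, 12.0))
    crp_p = _CRP_P_BACTERIAL if condition in _BACTERIAL_CONDITIONS else _CRP_P_VIRAL
    crp = _CRP_BANDS[rng.choice(4, p=crp_p)]
    if condition in _BACTERIAL_CONDITIONS:
        pct = float(rng.lognormal(1.5, 0.8))
    else:
        pct = float(rng.lognormal(-1.0, 0.8))
    dipstick = (
        rng.random() < 0.85 if condition == "uti" else rng.random() < 0.05
    )
    typhidot = rng.random() < 0.7 if condition == "typhoid" else rng.random() < 0.01

    return PatientPresentation(
        patient_id=f"sim-{index:06d}",
        age_months=age,
        sex=sex,
        weight_kg=round(weight, 2),
        muac_mm=round(muac, 1),
        temperature_c=round(temp, 1),
        fever_duration_days=int(rng.choice(_FEVER_DURATION_DAYS, p=_FEVER_DURATION_P)),
        symptoms=symptoms,
        vitals=VitalSigns(
            respiratory_rate_per_min=round(max(15.0, rr), 1),
            heart_rate_per_min=round(max(60.0, hr), 1),
            sao2_percent=round(min(100.0, sao2), 1),
        ),
        poct=POCTResults(
            mrdt_positive=bool(mrdt),
            hb_g_per_l=round(hb, 1),
            glucose_mmol_per_l=round(glucose, 2),
            crp_band=crp,
            pct_ug_per_l=round(pct, 2),
            urine_dipstick_positive=bool(dipstick),
            typhidot_positive=bool(typhidot),
        ),
    )


def generate_cohort(
    config: CohortConfig, standards: ReferenceStandards | None = None
) -> list[tuple[PatientPresentation, str]]:
    """Generate ``config.n`` presentations with their latent conditions.

    Deterministic under (config, seed); patient ``i`` depends only on the
    config and its own substream, so cohorts extend without reshuffling.
    """
    standards = standards or ReferenceStandards()
    cohort: list[tuple[PatientPresentation, str]] = []
    for i in range(config.n):
        rng = _patient_rng(config.seed, 3, i)
        condition = _draw_band(rng, config.etiology_mix)
        cohort.append((_generate_patient(i, condition, config, standards), condition))
    return cohort


def _care_mismatch(condition: str, management: ClassificationResult) -> tuple[bool, bool]:
    """(required care withheld, antibiotic given without need)."""
    needs_ab, needs_ref, _ = REQUIRED_CARE[condition]
    withheld = (needs_ab and not management.antibiotic_day0) or (
        needs_ref and not management.referral
    )
    unnecessary = management.antibiotic_day0 and not needs_ab
    return withheld, unnecessary


def simulate_followup(
    patient: PatientPresentation,
    condition: str,
    management: ClassificationResult,
    config: CohortConfig,
    index: int | None = None,
) -> list[FollowUpObservation]:
    """Sample the day-3/day-7/day-30 trajectory given delivered management.

    The failure probability is the condition's base rate, multiplied by
    the configured factor when required antibiotic or referral care was
    withheld and by a smaller factor for unnecessary antibiotics. Failures
    manifest as day-3 clinical pneumonia, an unscheduled severe contact,
    or persistent fever at day 7; a configured fraction progress to a
    severe adverse event (secondary admission, occasionally death).
    """
    if index is None:
        index = int(patient.patient_id.split("-")[-1]) if "-" in patient.patient_id else 0
    rng = _patient_rng(config.seed, 1, index)
    om = config.outcome_model

    withheld, unnecessary = _care_mismatch(condition, management)
    p_fail = om.base_failure_prob[condition]
    if withheld:
        p_fail *= om.inappropriate_multiplier
    if unnecessary:
        p_fail *= om.unnecessary_antibiotic_multiplier
    p_fail = min(p_fail, 0.95)

    fails = rng.random() < p_fail
    lost = rng.random() < config.ltf_probability
    pid = patient.patient_id

    benign3 = dict(
        patient_id=pid, day=3, contact_type=ContactType.VISIT, temperature_c=36.9
    )
    benign7 = dict(
        patient_id=pid, day=7, contact_type=ContactType.VISIT, temperature_c=36.8
    )
    obs: list[FollowUpObservation] = []
    sae = fails and rng.random() < om.sae_given_failure
    dies = sae and rng.random() < om.death_given_sae

    resolution_day = 1 + int(rng.geometric(om.fever_resolution_p))
    if not fails:
        resolution_day = min(resolution_day, 6)

    if fails:
        mode = rng.choice(3, p=np.array([0.35, 0.15, 0.50]))
        if mode == 0:  # clinical pneumonia at the day-3 visit
            obs.append(
                FollowUpObservation(
                    **benign3
                    | dict(
                        temperature_c=37.9,
                        fever_reported=resolution_day > 3,
                        cough_history=True,
                        lower_chest_indrawing=True,
                        caregiver_considers_ill=True,
                        hospitalized=sae,
                    )
                )
            )
            if not lost:
                obs.append(FollowUpObservation(**benign7))
        elif mode == 1:  # unscheduled severe contact (hypoxemia)
            day = int(rng.integers(1, 7))
            obs.append(
                FollowUpObservation(
                    patient_id=pid,
                    day=day,
                    contact_type=ContactType.VISIT,
                    temperature_c=38.8,
                    fever_reported=True,
                    caregiver_considers_ill=True,
                    sao2_percent=87.0,
                    hospitalized=sae,
                )
            )
            if day < 3:
                obs.append(FollowUpObservation(**benign3 | dict(hospitalized=sae)))
            if not lost:
                obs.append(FollowUpObservation(**benign7))
        else:  # persistent fever at day 7
            obs.append(
                FollowUpObservation(
                    **benign3
                    | dict(temperature_c=38.2, fever_reported=True, caregiver_considers_ill=True)
                )
            )
            if not lost:
                obs.append(
                    FollowUpObservation(
                        **benign7
                        | dict(
                            temperature_c=38.4,
                            fever_reported=True,
                            caregiver_considers_ill=True,
                            hospitalized=sae,
                        )
                    )
                )
    else:
        obs.append(
            FollowUpObservation(
                **benign3
                | dict(
                    temperature_c=38.1 if resolution_day > 3 else 36.9,
                    fever_reported=resolution_day > 3,
                )
            )
        )
        if not lost:
            obs.append(FollowUpObservation(**benign7))

    if dies:
        obs.append(
            FollowUpObservation(
                patient_id=pid,
                day=int(rng.integers(8, 29)),
                contact_type=ContactType.TRACED,
                died=True,
            )
        )
    elif not lost:
        obs.append(
            FollowUpObservation(patient_id=pid, day=30, contact_type=ContactType.PHONE)
        )
    return obs


# ---------------------------------------------------------------------------
# Management policies
# ---------------------------------------------------------------------------

Policy = Callable[[PatientPresentation, np.random.Generator], ClassificationResult]


def epoct_policy(standards: ReferenceStandards | None = None) -> Policy:
    from .epoct_engine import classify_epoct

    std = standards or ReferenceStandards()
    return lambda patient, rng: classify_epoct(patient, std)


def almanach_policy(standards: ReferenceStandards | None = None) -> Policy:
    from .almanach_engine import classify_almanach

    std = standards or ReferenceStandards()
    return lambda patient, rng: classify_almanach(patient, std)


def routine_care_policy(
    p_antibiotic: float = 0.949, p_referral: float = 0.004
) -> Policy:
    """Stub mirroring observed routine prescriber behavior.

    Prescribes an antibiotic with the configured probability (the observed
    routine-care rate is the default) and refers rarely; it ignores the
    presentation entirely.
    """

    def policy(patient: PatientPresentation, rng: np.random.Generator) -> ClassificationResult:
        refer = rng.random() < p_referral
        antibiotic = refer or rng.random() < p_antibiotic
        if refer:
            cls = frozenset({Classification.OTHER_SEVERE})
            reason = Classification.OTHER_SEVERE
        else:
            cls = frozenset({Classification.URTI})
            reason = Classification.URTI if antibiotic else None
        return ClassificationResult(
            patient_id=patient.patient_id,
            algorithm="routine",
            classifications=cls,
            referral=refer,
            antibiotic_day0=antibiotic,
            antibiotic_reason=reason,
            treatments=("oral_antibiotic",) if antibiotic else (),
        )

    return policy


def simulate_trial(
    config: CohortConfig,
    engine_a: Policy,
    engine_b: Policy,
    standards: ReferenceStandards | None = None,
) -> dict:
    """Full trial loop: randomize, classify, follow up, assess, analyze.

    Returns per-patient records plus an analysis report (per-protocol
    risk difference/ratio for clinical failure, antibiotic and referral
    contrasts, and the non-inferiority verdict at the registry margin).
    """
    standards = standards or ReferenceStandards()
    cohort = generate_cohort(config, standards)
    arm_rng = _patient_rng(config.seed, 2, 0)
    arms = trial_stats.block_randomize(config.n, 4, arm_rng)

    records: list[dict] = []
    for i, ((patient, condition), arm) in enumerate(zip(cohort, arms)):
        policy = engine_a if arm == "a" else engine_b
        management = policy(patient, _patient_rng(config.seed, 4, i))
        followups = simulate_followup(patient, condition, management, config, index=i)
        assessment = assess_failure(followups, patient, standards)
        records.append(
            {
                "patient_id": patient.patient_id,
                "arm": arm,
                "condition": condition,
                "withdrew": False,
                "lost_to_followup": assessment.lost_to_followup,
                "clinical_failure": assessment.clinical_failure,
                "severe_adverse_event": assessment.severe_adverse_event,
                "antibiotic_day0": management.antibiotic_day0,
                "referral": management.referral,
            }
        )

    itt, pp = trial_stats.build_populations(records)
    failure_pp = trial_stats.two_by_two_from_outcomes(pp, "clinical_failure")
    rd = trial_stats.risk_difference(failure_pp)
    report = {
        "n_randomized": config.n,
        "n_pp": len(pp),
        "failure_pp": failure_pp.model_dump(),
        "risk_difference_pp": rd.model_dump(),
        "noninferiority": trial_stats.noninferiority_decision(
            rd, standards.noninferiority_margin_pp
        ).value,
        "antibiotic": trial_stats.two_by_two_from_outcomes(pp, "antibiotic_day0").model_dump(),
        "referral": trial_stats.two_by_two_from_outcomes(pp, "referral").model_dump(),
    }
    try:
        report["risk_ratio"] = trial_stats.risk_ratio(failure_pp).model_dump()
        report["chi2_p"] = trial_stats.chi_squared(failure_pp)
    except Exception:
        report["risk_ratio"] = None
        report["chi2_p"] = None
    return {"records": records, "itt": itt, "pp": pp, "report": report}
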