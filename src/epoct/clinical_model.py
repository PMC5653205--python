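"""Domain types and the threshold/reference-curve registry.

Everything numeric that the triage engines and the outcome engine
threshold against lives in :class:`ReferenceStandards` — there is a single
home for every clinical cutoff (hemoglobin 60 g/l, glucose 3.3 mmol/l,
CRP >= 80 mg/l, PCT >= 4 ug/l, SaO2 90%, MUAC 115 mm, WFA z < -3, ...),
for the age/temperature percentile curves, and for the growth reference.
Patient presentations and follow-up observations are validated pydantic
records; eligibility invariants (age 2-59 months, axillary temperature
>= 37.5 C, weight >= 2.5 kg, fever history <= 7 days) are enforced at
construction.

Units are fixed package-wide: hemoglobin g/l, glucose mmol/l,
procalcitonin ug/l, MUAC mm, temperature deg C, respiratory rate
breaths/min, heart rate beats/min.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pydantic
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import _default_curves
from ._growth_reference_synthetic import default_lms_table
from .errors import ConfigurationError, RangeError, RecordValidationError

__all__ = [
    "Sex",
    "SkinPinch",
    "SpeechLevel",
    "CRPBand",
    "SkinLesionKind",
    "ContactType",
    "SkinLesion",
    "SymptomSet",
    "VitalSigns",
    "POCTResults",
    "PatientPresentation",
    "FollowUpObservation",
    "PercentileCurve",
    "GrowthReference",
    "ReferenceStandards",
    "load_reference_standards",
    "default_standards",
    "weight_for_age_z",
    "rr_percentile",
    "hr_percentile_90",
]


# ---------------------------------------------------------------------------
# Enumerations (serialized as lowercase tokens in the CSV schema)
# ---------------------------------------------------------------------------


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class SkinPinch(str, enum.Enum):
    NORMAL = "normal"
    SLOW = "slow"
    VERY_SLOW = "very_slow"


class SpeechLevel(str, enum.Enum):
    NORMAL = "normal"
    SHORT_PHRASES_OR_SHORT_CRIES = "short_phrases_or_short_cries"
    SINGLE_WORDS_OR_GRUNTS = "single_words_or_grunts"


class CRPBand(str, enum.Enum):
    """Semi-quantitative lateral-flow CRP readout (mg/l bands)."""

    LT10 = "lt10"
    B10_39 = "10_39"
    B40_79 = "40_79"
    GE80 = "ge80"


class SkinLesionKind(str, enum.Enum):
    ABSCESS = "abscess"
    CELLULITIS = "cellulitis"
    IMPETIGO_PYODERMA = "impetigo_pyoderma"
    TINEA_CORPORIS = "tinea_corporis"
    PITYRIASIS_VERSICOLOR = "pityriasis_versicolor"
    CANDIDIASIS = "candidiasis"
    TINEA_CAPITIS = "tinea_capitis"
    SCABIES = "scabies"
    CHICKEN_POX = "chicken_pox"
    HERPES = "herpes"
    LARVA_MIGRANS = "larva_migrans"
    ECZEMA = "eczema"
    URTICARIA = "urticaria"


#: Skin diagnoses whose first-line treatment is a systemic antibiotic.
BACTERIAL_SKIN_KINDS = frozenset(
    {SkinLesionKind.ABSCESS, SkinLesionKind.CELLULITIS, SkinLesionKind.IMPETIGO_PYODERMA}
)


class ContactType(str, enum.Enum):
    VISIT = "visit"
    PHONE = "phone"
    TRACED = "traced"


# ---------------------------------------------------------------------------
# Patient records
# ---------------------------------------------------------------------------


class _Record(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SkinLesion(_Record):
    kind: SkinLesionKind
    largest_diameter_cm: float = Field(ge=0)
    red_streaks: bool = False
    tender_nodes: bool = False
    multiple_abscesses: bool = False


class SymptomSet(_Record):
    cough: bool = False
    cough_duration_days: int = Field(default=0, ge=0)
    rhinorrhea: bool = False
    diarrhea_stools_24h: int = Field(default=0, ge=0)
    vomiting_episodes_24h: int = Field(default=0, ge=0)
    dysuria: bool = False
    ear_discharge: bool = False
    severe_lethargy: bool = False
    stiff_neck: bool = False
    convulsions_count: int = Field(default=0, ge=0)
    unable_to_drink: bool = False
    not_tolerating_oral_liquids: bool = False
    vomits_everything: bool = False
    sunken_eyes: bool = False
    drinks_eagerly: bool = False
    restless_irritable: bool = False
    skin_pinch: SkinPinch = SkinPinch.NORMAL
    lower_chest_indrawing: bool = False
    speech_level: SpeechLevel = SpeechLevel.NORMAL
    stridor: bool = False
    cyanosis: bool = False
    severe_palmar_pallor: bool = False
    jaundice: bool = False
    tender_swelling_behind_ear: bool = False
    visible_severe_wasting: bool = False
    edema_both_feet: bool = False
    clouding_cornea: bool = False
    severe_mouth_ulcers: bool = False
    skin_lesion: Optional[SkinLesion] = None
    caregiver_reports_other: str = ""


class VitalSigns(_Record):
    respiratory_rate_per_min: float = Field(gt=0)
    heart_rate_per_min: Optional[float] = Field(default=None, gt=0)
    sao2_percent: Optional[float] = Field(default=None, gt=0, le=100)


class POCTResults(_Record):
    mrdt_positive: bool
    hb_g_per_l: Optional[float] = Field(default=None, gt=0)
    glucose_mmol_per_l: Optional[float] = Field(default=None, gt=0)
    crp_band: Optional[CRPBand] = None
    pct_ug_per_l: Optional[float] = Field(default=None, ge=0)
    urine_dipstick_positive: Optional[bool] = None
    typhidot_positive: Optional[bool] = None
    hiv_ab_positive: Optional[bool] = None


class PatientPresentation(_Record):
    """One child at the day-0 consultation.

    Eligibility: age 2-59 months, axillary temperature >= 37.5 C, fever
    history <= 7 days, weight >= 2.5 kg.
    """

    patient_id: str
    age_months: int = Field(ge=2, le=59)
    sex: Sex
    weight_kg: float = Field(ge=2.5)
    muac_mm: Optional[float] = Field(default=None, gt=0)
    temperature_c: float = Field(ge=37.5)
    fever_duration_days: int = Field(ge=0, le=7)
    symptoms: SymptomSet = Field(default_factory=SymptomSet)
    vitals: VitalSigns
    poct: POCTResults
    enrollment_day: Optional[str] = None


class FollowUpObservation(_Record):
    """Symptoms and vitals at a follow-up contact (day 0-30)."""

    patient_id: str
    day: int = Field(ge=0, le=30)
    contact_type: ContactType = ContactType.VISIT
    temperature_c: Optional[float] = Field(default=None, gt=30, lt=45)
    fever_reported: bool = False
    caregiver_considers_ill: bool = False
    respiratory_rate_per_min: Optional[float] = Field(default=None, gt=0)
    heart_rate_per_min: Optional[float] = Field(default=None, gt=0)
    sao2_percent: Optional[float] = Field(default=None, gt=0, le=100)
    cough_history: bool = False
    lower_chest_indrawing: bool = False
    coma: bool = False
    convulsions_24h: int = Field(default=0, ge=0)
    unable_to_drink_or_breastfeed: bool = False
    diarrhea_stools_per_day: int = Field(default=0, ge=0)
    dehydration_requiring_facility_care: bool = False
    skin_infection_requiring_systemic_or_facility_care: bool = False
    new_significant_symptom: bool = False
    hb_g_per_l: Optional[float] = Field(default=None, gt=0)
    hospitalized: bool = False
    died: bool = False
    antibiotic_given: bool = False


def validate_observation_sequence(observations: Sequence[FollowUpObservation]) -> None:
    """Enforce: observations sorted by day; death terminates the record."""
    days = [o.day for o in observations]
    if days != sorted(days):
        raise RecordValidationError("follow-up observations must be sorted by day")
    for i, obs in enumerate(observations):
        if obs.died and i != len(observations) - 1:
            raise RecordValidationError(
                f"patient {obs.patient_id}: death at day {obs.day} "
                "must be the final observation"
            )


# ---------------------------------------------------------------------------
# Reference curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PercentileCurve:
    """Tabulated vital-sign percentile over an age x temperature grid.

    Lookups interpolate bilinearly inside the grid and clamp at its
    edges; values must be non-decreasing along the temperature axis.
    """

    ages_months: np.ndarray
    temps_c: np.ndarray
    values: np.ndarray  # shape (n_ages, n_temps)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages_months, dtype=float)
        temps = np.asarray(self.temps_c, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages_months", ages)
        object.__setattr__(self, "temps_c", temps)
        object.__setattr__(self, "values", values)
        if values.shape != (ages.size, temps.size):
            raise ConfigurationError(
                f"curve grid shape {values.shape} does not match "
                f"{ages.size} age nodes x {temps.size} temperature nodes"
            )
        if np.any(np.diff(ages) <= 0) or np.any(np.diff(temps) <= 0):
            raise ConfigurationError("curve grid nodes must be strictly increasing")
        if np.any(np.diff(values, axis=1) < 0):
            raise ConfigurationError(
                "percentile curve is non-monotone in temperature"
            )

    def __call__(self, age_months: float, temperature_c: float) -> float:
        a = float(np.clip(age_months, self.ages_months[0], self.ages_months[-1]))
        t = float(np.clip(temperature_c, self.temps_c[0], self.temps_c[-1]))
        # interpolate along temperature at each age node, then along age
        by_age = np.array(
            [np.interp(t, self.temps_c, row) for row in self.values]
        )
        return float(np.interp(a, self.ages_months, by_age))


@dataclass(frozen=True)
class GrowthReference:
    """Weight-for-age LMS reference, month-by-month per sex."""

    months: np.ndarray
    table: Mapping[str, Mapping[str, np.ndarray]]  # sex -> {"L","M","S"}

    def _lms(self, age_months: float, sex: Sex) -> tuple[float, float, float]:
        if not (self.months[0] <= age_months <= self.months[-1]):
            raise RangeError(
                f"age {age_months} months outside growth-reference range "
                f"[{self.months[0]}, {self.months[-1]}]"
            )
        entry = self.table[Sex(sex).value]
        L = float(np.interp(age_months, self.months, entry["L"]))
        M = float(np.interp(age_months, self.months, entry["M"]))
        S = float(np.interp(age_months, self.months, entry["S"]))
        return L, M, S

    def z_score(self, age_months: float, sex: Sex, weight_kg: float) -> float:
        L, M, S = self._lms(age_months, sex)
        if weight_kg <= 0:
            raise RecordValidationError("weight must be positive")
        if abs(L) < 1e-8:
            return float(np.log(weight_kg / M) / S)
        return float(((weight_kg / M) ** L - 1.0) / (L * S))

    def weight_at_z(self, age_months: float, sex: Sex, z: float) -> float:
        """Inverse transform; the weight whose z-score equals ``z``."""
        L, M, S = self._lms(age_months, sex)
        if abs(L) < 1e-8:
            return float(M * np.exp(S * z))
        return float(M * (1.0 + L * S * z) ** (1.0 / L))


def _default_rr_p75() -> PercentileCurve:
    return PercentileCurve(
        _default_curves.AGE_NODES_MONTHS, _default_curves.TEMP_NODES_C, _default_curves.RR_P75
    )


def _default_rr_p97() -> PercentileCurve:
    return PercentileCurve(
        _default_curves.AGE_NODES_MONTHS, _default_curves.TEMP_NODES_C, _default_curves.RR_P97
    )


def _default_hr_p90() -> PercentileCurve:
    return PercentileCurve(
        _default_curves.AGE_NODES_MONTHS, _default_curves.TEMP_NODES_C, _default_curves.HR_P90
    )


def _default_growth_reference() -> GrowthReference:
    from ._growth_reference_synthetic import MONTHS

    return GrowthReference(months=MONTHS.copy(), table=default_lms_table())


# ---------------------------------------------------------------------------
# The threshold registry
# ---------------------------------------------------------------------------


class ReferenceStandards(BaseModel):
    """Single home of every clinical cutoff and reference curve.

    Scalar defaults are the published algorithm thresholds; the percentile
    curves and growth reference default to bundled approximations and are
    replaceable via :func:`load_reference_standards`.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True, extra="forbid")

    # severe-disease cutoffs
    sao2_severe_percent: float = Field(default=90.0, gt=0)
    hb_severe_g_l: float = Field(default=60.0, gt=0)
    glucose_hypo_mmol_l: float = Field(default=3.3, gt=0)
    crp_bacterial_band: CRPBand = CRPBand.GE80
    pct_bacterial_ug_l: float = Field(default=4.0, gt=0)
    wfa_z_severe: float = -3.0
    muac_severe_mm: float = Field(default=115.0, gt=0)
    muac_min_age_months: int = Field(default=6, ge=0)
    skin_lesion_severe_cm: float = Field(default=4.0, gt=0)

    # anemia bands: closed month intervals -> cutoff g/l
    hb_anemia_cutoffs_by_age: tuple[tuple[int, int, float], ...] = (
        (2, 6, 90.0),
        (7, 24, 100.0),
        (25, 59, 110.0),
    )

    # convulsion thresholds differ between the two cascades
    epoct_convulsion_threshold: int = Field(default=2, ge=1)
    almanach_convulsion_threshold: int = Field(default=1, ge=1)

    # ALMANACH breathing-rate cutoffs (breaths/min)
    almanach_very_fast_breathing: float = Field(default=50.0, gt=0)
    almanach_fast_breathing_lt12mo: float = Field(default=50.0, gt=0)
    almanach_fast_breathing_ge12mo: float = Field(default=40.0, gt=0)

    # day-3/day-7 clinical-pneumonia tachypnea cutoffs (breaths/min)
    failure_tachypnea_lt12mo: float = Field(default=60.0, gt=0)
    failure_tachypnea_ge12mo: float = Field(default=50.0, gt=0)

    # fever thresholds (deg C)
    fever_enrollment_c: float = Field(default=37.5, gt=0)
    fever_followup_c: float = Field(default=38.0, gt=0)

    # significant diarrhea/vomiting rule (per 24 h)
    significant_diarrhea_stools_gt: int = Field(default=5, ge=0)
    combined_diarrhea_stools_ge: int = Field(default=3, ge=0)
    combined_emesis_gt: int = Field(default=3, ge=0)

    diarrhea_failure_stools_per_day: int = Field(default=3, ge=1)

    # follow-up window tolerances (inclusive day ranges)
    day3_window: tuple[int, int] = (2, 5)
    day7_window: tuple[int, int] = (6, 12)

    noninferiority_margin_pp: float = Field(default=3.0, gt=0)

    # curves
    rr_curve_p75: PercentileCurve = Field(default_factory=_default_rr_p75)
    rr_curve_p97: PercentileCurve = Field(default_factory=_default_rr_p97)
    hr_curve_p90: PercentileCurve = Field(default_factory=_default_hr_p90)
    wfa_reference: GrowthReference = Field(default_factory=_default_growth_reference)

    @model_validator(mode="after")
    def _check_bands(self) -> "ReferenceStandards":
        lo, hi = self.day3_window
        if lo > hi:
            raise ConfigurationError("day3_window lower bound exceeds upper bound")
        lo, hi = self.day7_window
        if lo > hi:
            raise ConfigurationError("day7_window lower bound exceeds upper bound")
        return self

    # -- registry lookups ---------------------------------------------------

    def hb_anemia_cutoff(self, age_months: int) -> float:
        for lo, hi, cutoff in self.hb_anemia_cutoffs_by_age:
            if lo <= age_months <= hi:
                return cutoff
        raise RangeError(f"no anemia cutoff band covers age {age_months} months")

    def almanach_fast_breathing(self, age_months: int) -> float:
        if age_months < 12:
            return self.almanach_fast_breathing_lt12mo
        return self.almanach_fast_breathing_ge12mo

    def failure_tachypnea(self, age_months: int) -> float:
        if age_months < 12:
            return self.failure_tachypnea_lt12mo
        return self.failure_tachypnea_ge12mo


#: Scalar fields that an explicit config document must supply in full.
_SCALAR_FIELDS = (
    "sao2_severe_percent",
    "hb_severe_g_l",
    "glucose_hypo_mmol_l",
    "crp_bacterial_band",
    "pct_bacterial_ug_l",
    "wfa_z_severe",
    "muac_severe_mm",
    "muac_min_age_months",
    "skin_lesion_severe_cm",
    "epoct_convulsion_threshold",
    "almanach_convulsion_threshold",
    "almanach_very_fast_breathing",
    "almanach_fast_breathing_lt12mo",
    "almanach_fast_breathing_ge12mo",
    "failure_tachypnea_lt12mo",
    "failure_tachypnea_ge12mo",
    "fever_enrollment_c",
    "fever_followup_c",
    "diarrhea_failure_stools_per_day",
    "noninferiority_margin_pp",
)

_CURVE_FIELDS = {
    "rr_curve_p75": _default_rr_p75,
    "rr_curve_p97": _default_rr_p97,
    "hr_curve_p90": _default_hr_p90,
}


def default_standards() -> ReferenceStandards:
    """The registry populated with the built-in defaults."""
    return ReferenceStandards()


def _curve_from_config(spec: Any) -> PercentileCurve:
    if isinstance(spec, PercentileCurve):
        return spec
    try:
        return PercentileCurve(
            np.asarray(spec["ages_months"], dtype=float),
            np.asarray(spec["temps_c"], dtype=float),
            np.asarray(spec["values"], dtype=float),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(
            "curve config must supply 'ages_months', 'temps_c' and 'values'"
        ) from exc


def load_reference_standards(config: Mapping[str, Any] | None = None) -> ReferenceStandards:
    """Build a validated :class:`ReferenceStandards` registry.

    ``config=None`` returns the built-in defaults. An explicit mapping
    must supply *every* scalar threshold (a missing one raises
    :class:`ConfigurationError` naming the field); percentile curves may
    be supplied as ``{ages_months, temps_c, values}`` grids and default
    to the bundled approximations when omitted.
    """
    if config is None:
        return default_standards()
    if not isinstance(config, Mapping):
        raise ConfigurationError("standards config must be a mapping")
    missing = [k for k in _SCALAR_FIELDS if k not in config]
    if missing:
        raise ConfigurationError(
            "standards config missing required threshold(s): " + ", ".join(missing)
        )
    kwargs: dict[str, Any] = {k: config[k] for k in _SCALAR_FIELDS}
    for opt in (
        "hb_anemia_cutoffs_by_age",
        "significant_diarrhea_stools_gt",
        "combined_diarrhea_stools_ge",
        "combined_emesis_gt",
        "day3_window",
        "day7_window",
    ):
        if opt in config:
            value = config[opt]
            if opt == "hb_anemia_cutoffs_by_age":
                value = tuple(tuple(band) for band in value)
            elif opt in ("day3_window", "day7_window"):
                value = tuple(value)
            kwargs[opt] = value
    for name, default_factory in _CURVE_FIELDS.items():
        kwargs[name] = (
            _curve_from_config(config[name]) if name in config else default_factory()
        )
    if "wfa_table" in config:
        tbl = config["wfa_table"]
        kwargs["wfa_reference"] = GrowthReference(
            months=np.asarray(tbl["months"], dtype=float),
            table={
                sex: {k: np.asarray(v, dtype=float) for k, v in entry.items()}
                for sex, entry in tbl["table"].items()
            },
        )
    try:
        return ReferenceStandards(**kwargs)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Shared lookup operations
# ---------------------------------------------------------------------------


def weight_for_age_z(
    age_months: float, sex: Sex, weight_kg: float, standards: ReferenceStandards
) -> float:
    """Weight-for-age z-score via the registry's LMS growth reference."""
    return standards.wfa_reference.z_score(age_months, sex, weight_kg)


def rr_percentile(
    age_months: float,
    temperature_c: float,
    percentile: int,
    standards: ReferenceStandards,
) -> float:
    """Respiratory-rate threshold (breaths/min) at the 75th or 97th percentile."""
    if percentile == 75:
        return standards.rr_curve_p75(age_months, temperature_c)
    if percentile == 97:
        return standards.rr_curve_p97(age_months, temperature_c)
    raise ConfigurationError(f"unknown respiratory-rate percentile: {percentile}")


def hr_percentile_90(
    age_months: float, temperature_c: float, standards: ReferenceStandards
) -> float:
    """Heart-rate threshold (beats/min) at the 90th percentile."""
    return standards.hr_curve_p90(age_months, temperature_c)
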