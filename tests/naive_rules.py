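"""Independent straight-line re-implementations of both triage cascades.

Deliberately naive: every published criterion is transcribed as a flat
``if``; no staging, no rule tracing, no shared helpers with the package
engines. Used as the oracle for the exhaustive lattice-equivalence check.
"""
from __future__ import annotations

from epoct.clinical_model import PatientPresentation, ReferenceStandards

BACTERIAL_SKIN = {"abscess", "cellulitis", "impetigo_pyoderma"}


def _sig_gi(p: PatientPresentation) -> bool:
    s = p.symptoms
    return (
        s.diarrhea_stools_24h > 5
        or (s.diarrhea_stools_24h >= 3 and s.vomiting_episodes_24h >= 1)
        or s.vomiting_episodes_24h > 3
    )


def naive_epoct(p: PatientPresentation, std: ReferenceStandards):
    """Returns (classification token set, antibiotic_day0, referral)."""
    s, v, t = p.symptoms, p.vitals, p.poct
    rr75 = std.rr_curve_p75(p.age_months, p.temperature_c)
    rr97 = std.rr_curve_p97(p.age_months, p.temperature_c)
    hr90 = std.hr_curve_p90(p.age_months, p.temperature_c)
    wfa = std.wfa_reference.z_score(p.age_months, p.sex, p.weight_kg)

    severe = set()
    if s.severe_lethargy or s.stiff_neck or s.convulsions_count >= 2:
        severe.add("cns_danger")
    if (
        s.speech_level == "single_words_or_grunts"
        or (s.speech_level == "short_phrases_or_short_cries" and s.lower_chest_indrawing)
        or v.respiratory_rate_per_min >= rr97
        or (v.sao2_percent is not None and v.sao2_percent < 90)
    ):
        severe.add("severe_respiratory")
    if t.hb_g_per_l is not None and t.hb_g_per_l < 60:
        severe.add("severe_anemia")
    if wfa < -3 or (p.muac_mm is not None and p.muac_mm < 115 and p.age_months > 6):
        severe.add("severe_malnutrition")
    if (
        s.not_tolerating_oral_liquids
        and v.heart_rate_per_min is not None
        and v.heart_rate_per_min >= hr90
    ):
        severe.add("severe_dehydration")
    if s.clouding_cornea or s.severe_mouth_ulcers:
        severe.add("other_severe")
    if severe and t.glucose_mmol_per_l is not None and t.glucose_mmol_per_l < 3.3:
        severe.add("hypoglycemia")
    if severe and t.mrdt_positive:
        severe.add("severe_malaria")
    if severe:
        return severe, True, True

    cls = set()
    antibiotic = False
    if s.cough:
        if v.respiratory_rate_per_min >= rr75:
            if t.crp_band == "ge80":
                cls.add("bacterial_lrti")
                antibiotic = True
            else:
                cls.add("viral_lrti")
        else:
            cls.add("urti")
    if _sig_gi(p):
        cls.add("gi_dehydration")
    if s.skin_lesion is not None:
        cls.add("skin_infection")
        if s.skin_lesion.kind in BACTERIAL_SKIN:
            antibiotic = True
    if t.mrdt_positive:
        cls.add("uncomplicated_malaria")
    fws = (
        not s.cough
        and not _sig_gi(p)
        and s.skin_lesion is None
        and not s.ear_discharge
        and not s.dysuria
    )
    if fws and not t.mrdt_positive:
        if t.crp_band == "ge80" or (t.pct_ug_per_l is not None and t.pct_ug_per_l >= 4.0):
            cls.add("fws_bacterial")
            antibiotic = True
        else:
            cls.add("fws_viral")
    if t.hb_g_per_l is not None:
        cutoff = 90 if p.age_months <= 6 else (100 if p.age_months <= 24 else 110)
        if 60 <= t.hb_g_per_l < cutoff:
            cls.add("non_severe_anemia")
    return cls, antibiotic, False


def naive_almanach(p: PatientPresentation, std: ReferenceStandards):
    """Returns (classification token set, antibiotic_day0, referral)."""
    s, v, t = p.symptoms, p.vitals, p.poct

    severe = set()
    if s.severe_lethargy or s.stiff_neck or s.convulsions_count >= 1:
        severe.add("cns_danger")
    if s.lower_chest_indrawing or s.cyanosis or s.stridor:
        severe.add("severe_respiratory")
    if s.severe_palmar_pallor:
        severe.add("severe_anemia")
    n_severe_dehydr = sum(
        [
            s.severe_lethargy,
            s.sunken_eyes,
            s.unable_to_drink,
            s.skin_pinch == "very_slow",
        ]
    )
    if s.vomits_everything or n_severe_dehydr >= 2:
        severe.add("severe_dehydration")
    if s.visible_severe_wasting or s.edema_both_feet:
        severe.add("severe_malnutrition")
    big_lesion = s.skin_lesion is not None and (
        s.skin_lesion.largest_diameter_cm > 4
        or s.skin_lesion.red_streaks
        or s.skin_lesion.tender_nodes
        or s.skin_lesion.multiple_abscesses
    )
    if s.jaundice or s.tender_swelling_behind_ear or big_lesion:
        severe.add("other_severe")
    if severe:
        return severe, True, True

    cls = set()
    antibiotic = False
    if s.cough:
        if v.respiratory_rate_per_min >= 50:
            cls.add("clinical_pneumonia")
            antibiotic = True
        else:
            cls.add("urti")
    n_gi = sum(
        [
            s.restless_irritable,
            s.sunken_eyes,
            s.drinks_eagerly,
            s.skin_pinch == "slow",
        ]
    )
    if (s.diarrhea_stools_24h >= 1 or s.vomiting_episodes_24h >= 1) and n_gi >= 2:
        cls.add("gi_dehydration")
    if s.skin_lesion is not None:
        cls.add("skin_infection")
        antibiotic = True
    if t.mrdt_positive:
        cls.add("uncomplicated_malaria")
    fws = not s.cough and not _sig_gi(p) and s.skin_lesion is None
    if fws and not t.mrdt_positive:
        bacterial = s.ear_discharge
        if p.age_months < 24 or s.dysuria:
            bacterial = bacterial or bool(t.urine_dipstick_positive)
        if p.age_months >= 24:
            bacterial = bacterial or bool(t.typhidot_positive)
        if bacterial:
            cls.add("fws_bacterial")
            antibiotic = True
        else:
            cls.add("fws_viral")
    return cls, antibiotic, False
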