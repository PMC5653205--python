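"""Unit tests for both triage cascades: staged test ordering, published
branch behavior, boundary semantics, and engine isolation."""
import pytest

from epoct.almanach_engine import classify_almanach, required_tests_almanach
from epoct.classification import Classification as C
from epoct.epoct_engine import classify_epoct, required_tests_epoct
from epoct.errors import IncompleteWorkupError


def tokens(result):
    return {c.value for c in result.classifications}


class TestEpoctCascade:
    def test_universal_tests_first(self, make_patient, standards):
        p = make_patient()
        assert required_tests_epoct(p, (), standards) == "mrdt"
        assert required_tests_epoct(p, ("mrdt",), standards) == "hb"
        assert required_tests_epoct(p, ("mrdt", "hb"), standards) == "sao2"

    def test_urti_branch_needs_no_crp(self, make_patient, standards):
        p = make_patient(symptoms=dict(cough=True), vitals=dict(respiratory_rate_per_min=30))
        assert required_tests_epoct(p, ("mrdt", "hb", "sao2"), standards) is None

    def test_fws_low_crp_demands_pct(self, make_patient, standards):
        p = make_patient(poct=dict(crp_band="10_39"))
        assert required_tests_epoct(p, ("mrdt", "hb", "sao2", "crp"), standards) == "pct"

    def test_fws_mrdt_positive_skips_biomarkers(self, make_patient, standards):
        p = make_patient(poct=dict(mrdt_positive=True))
        assert required_tests_epoct(p, ("mrdt", "hb", "sao2"), standards) is None

    def test_severe_branch_demands_glucose(self, make_patient, standards):
        p = make_patient(symptoms=dict(stiff_neck=True))
        assert required_tests_epoct(p, ("mrdt", "hb", "sao2"), standards) == "glucose"

    def test_missing_demanded_test_raises(self, make_patient, standards):
        p = make_patient(poct=dict(crp_band=None))
        with pytest.raises(IncompleteWorkupError, match="crp"):
            classify_epoct(p, standards)

    def test_trace_only_references_performed_tests(self, make_patient, standards):
        p = make_patient(symptoms=dict(cough=True), vitals=dict(respiratory_rate_per_min=30))
        res = classify_epoct(p, standards)
        assert "pct" not in res.tests_performed
        assert not any("pct" in rid for rid, _ in res.rule_trace)


class TestEpoctClassification:
    def test_fws_bacterial_by_pct(self, make_patient, standards):
        p = make_patient(poct=dict(crp_band="10_39", pct_ug_per_l=5.1))
        res = classify_epoct(p, standards)
        assert tokens(res) == {"fws_bacterial"}
        assert res.antibiotic_day0 and not res.referral

    def test_severe_anemia_refers(self, make_patient, standards):
        res = classify_epoct(make_patient(poct=dict(hb_g_per_l=55.0)), standards)
        assert tokens(res) == {"severe_anemia"}
        assert res.referral and res.antibiotic_day0

    def test_uncomplicated_malaria_gets_antimalarial_not_antibiotic(
        self, make_patient, standards
    ):
        res = classify_epoct(make_patient(poct=dict(mrdt_positive=True)), standards)
        assert tokens(res) == {"uncomplicated_malaria"}
        assert not res.antibiotic_day0
        assert "antimalarial" in res.treatments

    def test_viral_lrti_no_antibiotic_gets_bronchodilator(self, make_patient, standards):
        p = make_patient(
            symptoms=dict(cough=True), vitals=dict(respiratory_rate_per_min=45, sao2_percent=97)
        )
        res = classify_epoct(p, standards)
        assert tokens(res) == {"viral_lrti"}
        assert not res.antibiotic_day0
        assert "bronchodilator" in res.treatments

    def test_muac_criterion_applies_above_six_months(self, make_patient, standards):
        young = make_patient(age_months=5, weight_kg=6.5, muac_mm=110.0)
        older = make_patient(age_months=8, weight_kg=7.5, muac_mm=110.0)
        assert "severe_malnutrition" not in tokens(classify_epoct(young, standards))
        res = classify_epoct(older, standards)
        assert "severe_malnutrition" in tokens(res) and res.referral

    def test_default_branch_is_fws_viral(self, make_patient, standards):
        res = classify_epoct(make_patient(), standards)
        assert tokens(res) == {"fws_viral"}
        assert not res.antibiotic_day0

    def test_severe_malaria_added_on_positive_mrdt(self, make_patient, standards):
        p = make_patient(symptoms=dict(stiff_neck=True), poct=dict(mrdt_positive=True))
        res = classify_epoct(p, standards)
        assert {"cns_danger", "severe_malaria"} <= tokens(res)
        assert "antimalarial" in res.treatments

    def test_non_severe_anemia_flagged_alongside(self, make_patient, standards):
        res = classify_epoct(make_patient(age_months=36, poct=dict(hb_g_per_l=95.0)), standards)
        assert "non_severe_anemia" in tokens(res)
        assert not res.referral


class TestBoundaries:
    """Exact threshold semantics: < vs >= at the published cutoffs."""

    def test_hb_60_not_severe(self, make_patient, standards):
        assert "severe_anemia" not in tokens(
            classify_epoct(make_patient(age_months=36, poct=dict(hb_g_per_l=60.0)), standards)
        )
        assert "severe_anemia" in tokens(
            classify_epoct(make_patient(poct=dict(hb_g_per_l=59.9)), standards)
        )

    def test_pct_4_is_bacterial(self, make_patient, standards):
        res = classify_epoct(
            make_patient(poct=dict(crp_band="10_39", pct_ug_per_l=4.0)), standards
        )
        assert "fws_bacterial" in tokens(res)
        res = classify_epoct(
            make_patient(poct=dict(crp_band="10_39", pct_ug_per_l=3.99)), standards
        )
        assert "fws_viral" in tokens(res)

    def test_crp_ge80_band_is_bacterial(self, make_patient, standards):
        p = make_patient(
            symptoms=dict(cough=True),
            vitals=dict(respiratory_rate_per_min=45, sao2_percent=97),
            poct=dict(crp_band="ge80"),
        )
        res = classify_epoct(p, standards)
        assert "bacterial_lrti" in tokens(res) and res.antibiotic_day0

    def test_rr_50_is_almanach_pneumonia(self, make_patient, standards):
        at = make_patient(symptoms=dict(cough=True), vitals=dict(respiratory_rate_per_min=50))
        below = make_patient(symptoms=dict(cough=True), vitals=dict(respiratory_rate_per_min=49.9))
        assert "clinical_pneumonia" in tokens(classify_almanach(at, standards))
        assert tokens(classify_almanach(below, standards)) == {"urti"}

    def test_muac_115_not_severe(self, make_patient, standards):
        at = make_patient(age_months=12, muac_mm=115.0)
        assert "severe_malnutrition" not in tokens(classify_epoct(at, standards))
        below = make_patient(age_months=12, muac_mm=114.9)
        assert "severe_malnutrition" in tokens(classify_epoct(below, standards))

    def test_sao2_90_not_hypoxemic(self, make_patient, standards):
        at = make_patient(vitals=dict(sao2_percent=90.0))
        assert "severe_respiratory" not in tokens(classify_epoct(at, standards))
        below = make_patient(vitals=dict(sao2_percent=89.9))
        assert "severe_respiratory" in tokens(classify_epoct(below, standards))


class TestAlmanachCascade:
    def test_fws_age_split_for_tests(self, make_patient, standards):
        older = make_patient(age_months=30)
        young = make_patient(age_months=10, weight_kg=8.0)
        assert required_tests_almanach(older, ("mrdt",), standards) == "typhidot"
        assert required_tests_almanach(young, ("mrdt",), standards) == "urine_dipstick"

    def test_pneumonia_branch_needs_no_further_poct(self, make_patient, standards):
        p = make_patient(
            age_months=10,
            weight_kg=8.0,
            symptoms=dict(cough=True),
            vitals=dict(respiratory_rate_per_min=55),
        )
        assert required_tests_almanach(p, ("mrdt",), standards) is None

    def test_single_convulsion_severe_under_almanach_only(self, make_patient, standards):
        p = make_patient(symptoms=dict(convulsions_count=1))
        assert "cns_danger" in tokens(classify_almanach(p, standards))
        assert "cns_danger" not in tokens(classify_epoct(p, standards))

    def test_dipstick_uti_is_fws_bacterial(self, make_patient, standards):
        p = make_patient(
            age_months=18, weight_kg=10.0, poct=dict(urine_dipstick_positive=True)
        )
        res = classify_almanach(p, standards)
        assert "fws_bacterial" in tokens(res) and res.antibiotic_day0

    def test_ear_discharge_counts_as_fws_bacterial(self, make_patient, standards):
        res = classify_almanach(make_patient(symptoms=dict(ear_discharge=True)), standards)
        assert "fws_bacterial" in tokens(res)

    def test_engine_isolation_from_biomarkers(self, make_patient, standards):
        """ALMANACH output is invariant to CRP/PCT/SaO2/Hb/glucose values."""
        rich = make_patient(
            poct=dict(crp_band="ge80", pct_ug_per_l=99.0, hb_g_per_l=40.0, glucose_mmol_per_l=1.6),
            vitals=dict(sao2_percent=70.0),
        )
        plain = make_patient()
        a, b = classify_almanach(rich, standards), classify_almanach(plain, standards)
        assert tokens(a) == tokens(b)
        assert a.antibiotic_day0 == b.antibiotic_day0
        assert a.referral == b.referral


class TestManagementInvariants:
    def test_severe_forces_referral_and_antibiotic(self, make_patient, standards):
        for overrides in (
            dict(symptoms=dict(severe_lethargy=True)),
            dict(poct=dict(hb_g_per_l=45.0)),
            dict(vitals=dict(sao2_percent=85.0)),
        ):
            res = classify_epoct(make_patient(**overrides), standards)
            assert res.referral and res.antibiotic_day0
            assert res.antibiotic_reason in res.classifications

    def test_rule_trace_records_fired_and_unfired(self, make_patient, standards):
        res = classify_epoct(make_patient(), standards)
        fired = dict(res.rule_trace)
        assert fired["fws.branch"] is True
        assert fired["severe.cns_danger"] is False
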