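import math

import numpy as np
import pytest

from epoct.errors import (
    ConfigurationError,
    DegenerateTableError,
    UndefinedEstimateError,
)
from epoct.trial_stats import (
    EffectEstimate,
    NonInferiorityVerdict,
    TwoByTwo,
    block_randomize,
    build_populations,
    chi_squared,
    kaplan_meier,
    mantel_haenszel_rr,
    nnt,
    noninferiority_decision,
    noninferiority_sample_size,
    risk_difference,
    risk_ratio,
)


def table(a, na, b, nb):
    return TwoByTwo(events_a=a, total_a=na, events_b=b, total_b=nb)


class TestRiskRatio:
    def test_equal_proportions_centered_at_one(self):
        est = risk_ratio(table(5, 100, 5, 100))
        assert est.point == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_zero_reference_events_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            risk_ratio(table(5, 100, 0, 100))

    def test_matches_statsmodels_log_method(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for _ in range(50):
            na, nb = rng.integers(20, 400, size=2)
            a = rng.integers(1, na)
            b = rng.integers(1, nb)
            est = risk_ratio(table(a, na, b, nb))
            t22 = sm.stats.Table2x2(
                np.array([[a, na - a], [b, nb - b]]), shift_zeros=False
            )
            assert est.point == pytest.approx(t22.riskratio)
            lo, hi = t22.riskratio_confint()
            assert est.ci_low == pytest.approx(lo)
            assert est.ci_high == pytest.approx(hi)


class TestRiskDifference:
    def test_identical_arms_zero_and_symmetric(self):
        est = risk_difference(table(8, 200, 8, 200))
        assert est.point == 0.0
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_wald_formula_against_direct_arithmetic(self):
        est = risk_difference(table(37, 1586, 65, 1583))
        pa, pb = 37 / 1586, 65 / 1583
        se = math.sqrt(pa * (1 - pa) / 1586 + pb * (1 - pb) / 1583)
        assert est.point == pytest.approx(100 * (pa - pb))
        assert est.ci_high == pytest.approx(100 * (pa - pb) + 100 * 1.959964 * se, abs=1e-4)


class TestChiSquared:
    def test_identical_proportions_p_one(self):
        assert chi_squared(table(10, 100, 10, 100)) == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_squared(table(0, 50, 0, 50))

    def test_matches_scipy_uncorrected(self):
        from scipy.stats import chi2_contingency

        p = chi_squared(table(30, 120, 12, 110))
        expected = chi2_contingency(
            np.array([[30, 90], [12, 98]]), correction=False
        ).pvalue
        assert p == pytest.approx(expected)


class TestNonInferiority:
    def test_strictly_inside_margin(self):
        est = EffectEstimate(measure="risk_difference_pp", point=-1.7, ci_low=-3.0, ci_high=-0.5)
        assert noninferiority_decision(est, 3.0) == NonInferiorityVerdict.NON_INFERIOR

    def test_boundary_is_inconclusive(self):
        est = EffectEstimate(measure="risk_difference_pp", point=1.0, ci_low=-1.0, ci_high=3.0)
        assert noninferiority_decision(est, 3.0) == NonInferiorityVerdict.INCONCLUSIVE

    def test_just_under_margin(self):
        est = EffectEstimate(measure="risk_difference_pp", point=1.0, ci_low=-1.0, ci_high=2.9)
        assert noninferiority_decision(est, 3.0) == NonInferiorityVerdict.NON_INFERIOR

    def test_nonpositive_margin_rejected(self):
        est = EffectEstimate(measure="risk_difference_pp", point=0.0, ci_low=-1.0, ci_high=1.0)
        with pytest.raises(ConfigurationError):
            noninferiority_decision(est, 0.0)


class TestNNT:
    @pytest.mark.parametrize("rd_pp, expected", [(-50.0, 2), (-0.9, 112), (2.5, 40)])
    def test_ceiling_of_reciprocal(self, rd_pp, expected):
        est = EffectEstimate(
            measure="risk_difference_pp", point=rd_pp, ci_low=rd_pp - 1, ci_high=rd_pp + 1
        )
        assert nnt(est) == expected

    def test_zero_rd_undefined(self):
        est = EffectEstimate(measure="risk_difference_pp", point=0.0, ci_low=-1, ci_high=1)
        with pytest.raises(UndefinedEstimateError):
            nnt(est)


class TestSampleSize:
    def test_independent_formula_evaluation(self):
        # (z_0.975 + z_0.80)^2 * 2 * 0.05*0.95 / 0.05^2 = 298.3 -> 299/arm
        assert noninferiority_sample_size(0.05, 0.05, 0.05) == 598

    def test_monotone_in_margin(self):
        n1 = noninferiority_sample_size(0.10, 0.10, 0.03)
        n2 = noninferiority_sample_size(0.10, 0.10, 0.06)
        assert n2 < n1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            noninferiority_sample_size(0.0, 0.1, 0.03)
        with pytest.raises(ConfigurationError):
            noninferiority_sample_size(0.1, 0.1, -1.0)


def _brute_force_mh(strata):
    """Textbook Mantel-Haenszel pooled risk ratio, written independently."""
    num = sum(t.events_a * t.total_b / (t.total_a + t.total_b) for t in strata)
    den = sum(t.events_b * t.total_a / (t.total_a + t.total_b) for t in strata)
    return num / den


class TestMantelHaenszel:
    def test_single_stratum_reduces_to_crude_rr(self):
        t = table(37, 1586, 65, 1583)
        pooled, _ = mantel_haenszel_rr([t])
        crude = risk_ratio(t)
        assert pooled.point == pytest.approx(crude.point)

    def test_identical_strata_keep_common_rr(self):
        t = table(20, 200, 40, 200)
        pooled, p_het = mantel_haenszel_rr([t, t])
        assert pooled.point == pytest.approx(0.5)
        assert p_het == pytest.approx(1.0, abs=1e-6)

    def test_random_strata_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            strata = []
            for _ in range(5):
                na, nb = rng.integers(30, 300, size=2)
                strata.append(
                    table(int(rng.integers(1, na)), int(na), int(rng.integers(1, nb)), int(nb))
                )
            pooled, _ = mantel_haenszel_rr(strata)
            assert pooled.point == pytest.approx(_brute_force_mh(strata))

    def test_matches_statsmodels_pooled_riskratio(self):
        import statsmodels.api as sm

        strata = [table(12, 100, 20, 110), table(5, 80, 9, 90), table(30, 250, 44, 240)]
        pooled, _ = mantel_haenszel_rr(strata)
        tables = [
            np.array([[t.events_a, t.total_a - t.events_a], [t.events_b, t.total_b - t.events_b]])
            for t in strata
        ]
        st = sm.stats.StratifiedTable(tables)
        assert pooled.point == pytest.approx(float(st.riskratio_pooled))


def _manual_product_limit(times):
    """Hand-rolled product-limit table used as the oracle."""
    events = sorted({t for t, e in times if e})
    survival = {}
    s = 1.0
    for t in events:
        at_risk = sum(1 for ti, _ in times if ti >= t)
        d = sum(1 for ti, e in times if ti == t and e)
        s *= 1 - d / at_risk
        survival[t] = s
    return survival


class TestKaplanMeier:
    def test_all_events_day1(self):
        km = kaplan_meier([(1, True)] * 5)
        assert km.survival(1) == 0.0

    def test_all_censored_stays_at_one(self):
        km = kaplan_meier([(3, False), (5, False), (9, False)])
        assert km.survival(9) == 1.0

    def test_mixed_fixture_matches_manual_table(self):
        times = [
            (1, True), (2, True), (2, False), (3, True), (4, False),
            (5, True), (5, True), (6, False), (7, True), (8, False),
        ]
        km = kaplan_meier(times)
        for day, s in _manual_product_limit(times).items():
            assert km.survival(day) == pytest.approx(s)

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateTableError):
            kaplan_meier([])


class TestRandomizationAndPopulations:
    def test_blocks_balanced(self):
        arms = block_randomize(8, 4, seed=3)
        for i in range(0, 8, 4):
            block = arms[i : i + 4]
            assert block.count("a") == 2 and block.count("b") == 2

    def test_deterministic_under_seed(self):
        assert block_randomize(100, 4, seed=9) == block_randomize(100, 4, seed=9)

    def test_odd_block_rejected(self):
        with pytest.raises(ConfigurationError):
            block_randomize(10, 3, seed=0)

    def test_itt_imputes_lost_as_failures(self):
        records = [
            {"arm": "a", "withdrew": False, "lost_to_followup": False, "clinical_failure": False}
            for _ in range(95)
        ] + [
            {"arm": "a", "withdrew": False, "lost_to_followup": True, "clinical_failure": None}
            for _ in range(5)
        ]
        itt, pp = build_populations(records)
        assert len(itt) == 100 and len(pp) == 95
        itt_failures = sum(r["clinical_failure"] for r in itt)
        pp_failures = sum(r["clinical_failure"] for r in pp)
        assert itt_failures == pp_failures + 5

    def test_withdrawals_excluded_from_pp_only(self):
        records = [
            {"arm": "b", "withdrew": True, "lost_to_followup": False, "clinical_failure": False},
            {"arm": "b", "withdrew": False, "lost_to_followup": False, "clinical_failure": True},
        ]
        itt, pp = build_populations(records)
        assert len(itt) == 2 and len(pp) == 1


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def tables(draw):
    na = draw(st.integers(min_value=2, max_value=2000))
    nb = draw(st.integers(min_value=2, max_value=2000))
    # keep both margins non-degenerate so every estimator is defined
    a = draw(st.integers(min_value=1, max_value=na - 1))
    b = draw(st.integers(min_value=1, max_value=nb - 1))
    return table(a, na, b, nb)


@settings(max_examples=200, derandomize=True)
@given(tables())
def test_estimates_bracket_their_point(t):
    for est in (risk_ratio(t), risk_difference(t)):
        assert est.ci_low <= est.point <= est.ci_high


@settings(max_examples=200, derandomize=True)
@given(tables())
def test_arm_swap_symmetry(t):
    swapped = table(t.events_b, t.total_b, t.events_a, t.total_a)
    rr, rr_swap = risk_ratio(t), risk_ratio(swapped)
    assert rr.point * rr_swap.point == pytest.approx(1.0)
    assert rr.ci_low == pytest.approx(1.0 / rr_swap.ci_high)
    rd, rd_swap = risk_difference(t), risk_difference(swapped)
    assert rd.point == pytest.approx(-rd_swap.point)
    assert chi_squared(t) == pytest.approx(chi_squared(swapped))
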