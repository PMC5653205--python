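"""Effect estimation and non-inferiority trial design math.

Conventions follow the classical epidemiological toolkit for 2x2 tables:
risk ratios carry Katz log-method confidence intervals,

    CI = exp( ln RR  +/-  z * sqrt(1/a - 1/n_a + 1/b - 1/n_b) ),

risk differences (reported in percentage points) carry Wald intervals,
association is tested with the Pearson chi-squared statistic without
continuity correction, and stratified risk ratios are pooled with the
Mantel-Haenszel estimator with a Greenland-Robins variance. Non-inferiority
of arm A versus arm B at margin m is declared when the upper bound of the
two-sided 95% CI of the risk difference lies strictly below m percentage
points (equivalently a one-sided 97.5% interval). The two-proportion
non-inferiority sample size under an alternative of equality is

    n/arm = ceil( (z_{1-alpha} + z_{power})^2 (p_a q_a + p_b q_b) / m^2 ).

No continuity or zero-cell corrections are applied unless explicitly
requested.
"""
from __future__ import annotations

import enum
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .errors import ConfigurationError, DegenerateTableError, UndefinedEstimateError

__all__ = [
    "TwoByTwo",
    "EffectEstimate",
    "NonInferiorityVerdict",
    "risk_ratio",
    "risk_difference",
    "chi_squared",
    "noninferiority_decision",
    "nnt",
    "noninferiority_sample_size",
    "mantel_haenszel_rr",
    "kaplan_meier",
    "KaplanMeierCurve",
    "block_randomize",
    "build_populations",
    "two_by_two_from_outcomes",
    "noninferiority_power_sim",
    "katz_coverage_sim",
]


class TwoByTwo(BaseModel):
    """Arm-level event/total counts; arm A is the comparator of interest."""

    model_config = ConfigDict(extra="forbid")

    events_a: int = Field(ge=0)
    total_a: int = Field(gt=0)
    events_b: int = Field(ge=0)
    total_b: int = Field(gt=0)
    label_a: str = "a"
    label_b: str = "b"

    @model_validator(mode="after")
    def _check(self) -> "TwoByTwo":
        if self.events_a > self.total_a or self.events_b > self.total_b:
            raise DegenerateTableError("events exceed totals")
        return self

    @property
    def risk_a(self) -> float:
        return self.events_a / self.total_a

    @property
    def risk_b(self) -> float:
        return self.events_b / self.total_b


class EffectEstimate(BaseModel):
    model_config = ConfigDict(extra="forbid")

    measure: str  # "risk_ratio" | "risk_difference_pp"
    point: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    p_value: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "EffectEstimate":
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ConfigurationError("confidence interval must bracket the point estimate")
        return self


class NonInferiorityVerdict(str, enum.Enum):
    NON_INFERIOR = "non_inferior"
    INCONCLUSIVE = "inconclusive"


def risk_ratio(t: TwoByTwo, alpha: float = 0.05) -> EffectEstimate:
    """Risk ratio with the Katz log-method CI (no zero-cell correction)."""
    if t.events_b == 0:
        raise UndefinedEstimateError(
            "risk ratio undefined: zero events in the reference arm"
        )
    point = t.risk_a / t.risk_b
    z = stats.norm.ppf(1 - alpha / 2)
    if t.events_a == 0:
        # ln RR = -inf; the interval collapses to [0, exp-limit]
        raise UndefinedEstimateError(
            "risk ratio CI undefined: zero events in arm a (enable a correction upstream)"
        )
    se = math.sqrt(
        1 / t.events_a - 1 / t.total_a + 1 / t.events_b - 1 / t.total_b
    )
    log_rr = math.log(point)
    return EffectEstimate(
        measure="risk_ratio",
        point=point,
        ci_low=math.exp(log_rr - z * se),
        ci_high=math.exp(log_rr + z * se),
        alpha=alpha,
    )


def risk_difference(t: TwoByTwo, alpha: float = 0.05) -> EffectEstimate:
    """Risk difference in percentage points with a Wald CI."""
    pa, pb = t.risk_a, t.risk_b
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(pa * (1 - pa) / t.total_a + pb * (1 - pb) / t.total_b)
    point = 100.0 * (pa - pb)
    half = 100.0 * z * se
    return EffectEstimate(
        measure="risk_difference_pp",
        point=point,
        ci_low=point - half,
        ci_high=point + half,
        alpha=alpha,
    )


def chi_squared(t: TwoByTwo) -> float:
    """Pearson chi-squared p-value on the 2x2, no continuity correction."""
    table = np.array(
        [
            [t.events_a, t.total_a - t.events_a],
            [t.events_b, t.total_b - t.events_b],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("chi-squared undefined: zero margin")
    if t.risk_a == t.risk_b:
        return 1.0  # expected == observed
    result = stats.chi2_contingency(table, correction=False)
    return float(result.pvalue)


def noninferiority_decision(
    rd: EffectEstimate, margin_pp: float
) -> NonInferiorityVerdict:
    """Declare non-inferiority iff the RD CI upper bound < margin (strict)."""
    if margin_pp <= 0:
        raise ConfigurationError("non-inferiority margin must be positive")
    if rd.measure != "risk_difference_pp":
        raise ConfigurationError("non-inferiority decision requires a risk difference")
    if rd.ci_high < margin_pp:
        return NonInferiorityVerdict.NON_INFERIOR
    return NonInferiorityVerdict.INCONCLUSIVE


def nnt(rd: EffectEstimate) -> int:
    """Number needed to treat: ceil(100 / |risk difference in pp|)."""
    if rd.measure != "risk_difference_pp":
        raise ConfigurationError("NNT requires a risk difference in percentage points")
    if rd.point == 0:
        raise UndefinedEstimateError("NNT undefined at zero risk difference")
    return math.ceil(100.0 / abs(rd.point))


def noninferiority_sample_size(
    p_a: float,
    p_b: float,
    margin: float,
    power: float = 0.80,
    one_sided_alpha: float = 0.025,
) -> int:
    """Total N (both arms) for a two-proportion non-inferiority design."""
    for name, v in (("p_a", p_a), ("p_b", p_b), ("power", power), ("one_sided_alpha", one_sided_alpha)):
        if not (0 < v < 1):
            raise ConfigurationError(f"{name} must lie in (0, 1)")
    if not (margin > 0 and math.isfinite(margin)):
        raise ConfigurationError("margin must be positive and finite")
    z_alpha = stats.norm.ppf(1 - one_sided_alpha)
    z_beta = stats.norm.ppf(power)
    n_per_arm = math.ceil(
        (z_alpha + z_beta) ** 2 * (p_a * (1 - p_a) + p_b * (1 - p_b)) / margin**2
    )
    return 2 * n_per_arm


def mantel_haenszel_rr(
    strata: Sequence[TwoByTwo], alpha: float = 0.05
) -> tuple[EffectEstimate, float]:
    """Mantel-Haenszel pooled risk ratio across strata.

    Returns the pooled estimate (Greenland-Robins variance for the CI)
    together with a chi-squared heterogeneity p-value (Cochran Q over the
    per-stratum log risk ratios; 1.0 for a single stratum).
    """
    if not strata:
        raise DegenerateTableError("at least one stratum required")
    num = 0.0  # sum a_i * n_b_i / N_i
    den = 0.0  # sum b_i * n_a_i / N_i
    gr_num = 0.0
    for t in strata:
        N = t.total_a + t.total_b
        num += t.events_a * t.total_b / N
        den += t.events_b * t.total_a / N
        m = t.events_a + t.events_b
        gr_num += (t.total_a * t.total_b * m - t.events_a * t.events_b * N) / N**2
    if den == 0 or num == 0:
        raise UndefinedEstimateError("Mantel-Haenszel risk ratio undefined (zero events)")
    rr_mh = num / den
    var_log = gr_num / (num * den)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(var_log)
    estimate = EffectEstimate(
        measure="risk_ratio",
        point=rr_mh,
        ci_low=math.exp(math.log(rr_mh) - z * se),
        ci_high=math.exp(math.log(rr_mh) + z * se),
        alpha=alpha,
    )
    # Cochran Q heterogeneity over strata with events in both arms
    q = 0.0
    df = -1
    for t in strata:
        if t.events_a == 0 or t.events_b == 0:
            continue
        log_rr_i = math.log(t.risk_a / t.risk_b)
        var_i = 1 / t.events_a - 1 / t.total_a + 1 / t.events_b - 1 / t.total_b
        if var_i <= 0:
            continue
        q += (log_rr_i - math.log(rr_mh)) ** 2 / var_i
        df += 1
    p_het = float(stats.chi2.sf(q, df)) if df >= 1 else 1.0
    return estimate, p_het


class KaplanMeierCurve:
    """Product-limit survival curve, queryable at any day."""

    def __init__(self, times: Sequence[tuple[float, bool]]):
        if not times:
            raise DegenerateTableError("Kaplan-Meier requires at least one subject")
        from lifelines import KaplanMeierFitter

        arr = np.asarray([(float(t), bool(e)) for t, e in times], dtype=float)
        if (arr[:, 0] < 0).any():
            raise ConfigurationError("event/censoring times must be non-negative")
        self._fitter = KaplanMeierFitter()
        self._fitter.fit(arr[:, 0], event_observed=arr[:, 1])

    def survival(self, day: float) -> float:
        return float(self._fitter.predict(day))

    @property
    def median_time(self) -> float:
        return float(self._fitter.median_survival_time_)

    def as_table(self) -> list[tuple[float, float]]:
        sf = self._fitter.survival_function_
        return [(float(i), float(v)) for i, v in zip(sf.index, sf.iloc[:, 0])]


def kaplan_meier(times: Sequence[tuple[float, bool]]) -> KaplanMeierCurve:
    """Product-limit estimator; ``times`` are (day, event_observed) pairs.

    ``event_observed=True`` marks the event (e.g., fever resolution);
    ``False`` marks right-censoring.
    """
    return KaplanMeierCurve(times)


def block_randomize(
    n: int, block_size: int = 4, seed: int | np.random.Generator = 0
) -> list[str]:
    """Balanced block randomization to arms 'a' and 'b'.

    Within each block of ``block_size`` (even), exactly half go to each
    arm; a trailing partial block is drawn from a shuffled full block.
    """
    if block_size % 2 != 0 or block_size <= 0:
        raise ConfigurationError("block size must be a positive even number")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    assignments: list[str] = []
    block = ["a"] * (block_size // 2) + ["b"] * (block_size // 2)
    while len(assignments) < n:
        perm = list(rng.permutation(block))
        assignments.extend(perm)
    return assignments[:n]


def build_populations(records: Sequence[dict]) -> tuple[list[dict], list[dict]]:
    """Construct the ITT and PP analysis populations.

    Each record is a mapping with keys ``arm``, ``withdrew`` (bool),
    ``lost_to_followup`` (bool) and ``clinical_failure`` (bool or None).
    ITT keeps every randomized patient and imputes failure for those lost
    to follow-up; PP keeps only patients who received the intervention and
    completed the day-7 assessment.
    """
    itt: list[dict] = []
    pp: list[dict] = []
    for rec in records:
        r = dict(rec)
        if r.get("lost_to_followup"):
            r["clinical_failure"] = True
        else:
            r["clinical_failure"] = bool(r["clinical_failure"])
        itt.append(r)
        if not rec.get("withdrew") and not rec.get("lost_to_followup"):
            pp.append(dict(rec, clinical_failure=bool(rec["clinical_failure"])))
    return itt, pp


def two_by_two_from_outcomes(
    records: Sequence[dict],
    outcome_key: str = "clinical_failure",
    arm_a: str = "a",
    arm_b: str = "b",
) -> TwoByTwo:
    """Collapse per-patient records into arm-level event/total counts."""

    def count(arm: str) -> tuple[int, int]:
        sub = [r for r in records if r["arm"] == arm]
        return sum(bool(r[outcome_key]) for r in sub), len(sub)

    ea, na = count(arm_a)
    eb, nb = count(arm_b)
    return TwoByTwo(
        events_a=ea, total_a=na, events_b=eb, total_b=nb, label_a=arm_a, label_b=arm_b
    )


# ---------------------------------------------------------------------------
# Design-point simulation harnesses (vectorized)
# ---------------------------------------------------------------------------


def noninferiority_power_sim(
    p_a: float,
    p_b: float,
    n_per_arm: int,
    margin_pp: float,
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical probability of declaring non-inferiority.

    Each replicate draws binomial event counts in both arms and applies
    the Wald risk-difference CI decision rule. Returns the declaration
    rate over ``reps`` replicates.
    """
    rng = np.random.default_rng(seed)
    a = rng.binomial(n_per_arm, p_a, size=reps)
    b = rng.binomial(n_per_arm, p_b, size=reps)
    pa, pb = a / n_per_arm, b / n_per_arm
    z = stats.norm.ppf(0.975)
    se = np.sqrt(pa * (1 - pa) / n_per_arm + pb * (1 - pb) / n_per_arm)
    upper_pp = 100.0 * (pa - pb) + 100.0 * z * se
    return float(np.mean(upper_pp < margin_pp))


def katz_coverage_sim(
    p_a: float,
    p_b: float,
    n_per_arm: int,
    reps: int = 2000,
    seed: int = 0,
) -> float:
    """Empirical coverage of the 95% Katz log-method risk-ratio CI.

    Tables with a zero cell (where the interval is undefined) are
    excluded from the denominator, matching the estimator's domain.
    """
    rng = np.random.default_rng(seed)
    a = rng.binomial(n_per_arm, p_a, size=reps)
    b = rng.binomial(n_per_arm, p_b, size=reps)
    ok = (a > 0) & (b > 0)
    a, b = a[ok], b[ok]
    true_rr = p_a / p_b
    log_rr = np.log((a / n_per_arm) / (b / n_per_arm))
    se = np.sqrt(1 / a - 1 / n_per_arm + 1 / b - 1 / n_per_arm)
    z = stats.norm.ppf(0.975)
    lo, hi = np.exp(log_rr - z * se), np.exp(log_rr + z * se)
    return float(np.mean((lo <= true_rr) & (true_rr <= hi)))
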