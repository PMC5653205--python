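# epoct

Executable clinical decision-support algorithms for pediatric febrile
illness, with the trial machinery to evaluate them.

In low-resource outpatient settings, most febrile children under five
have self-limiting viral infections, yet antibiotic prescription rates
approach 95% while the few children with severe disease are often
missed. `epoct` implements, as testable rule engines, two electronic
triage algorithms for children aged 2–59 months presenting with fever
(axillary temperature ≥ 37.5 °C):

- **e-POCT** — a biomarker-assisted cascade that combines a few clinical
  signs with staged point-of-care tests: malaria rapid test, hemoglobin
  and pulse oximetry for every child; glucometer for danger-sign
  patients; C-reactive protein (semi-quantitative bands, bacterial at
  ≥ 80 mg/l) for coughing children with age/temperature-corrected
  tachypnea and for fever without source; procalcitonin (bacterial at
  ≥ 4 µg/l) when CRP is below the bacterial band.
- **ALMANACH** — an IMCI-derived control cascade using clinical signs
  plus malaria rapid test, urine dipstick and a rapid typhoid assay.

Around the engines the package provides the trial outcome definitions
(composite clinical failure by day 7, the "not cured" re-treatment rule,
severe adverse events by day 30), the non-inferiority statistics, and a
seeded synthetic-cohort simulator so the full pipeline — randomize,
classify, simulate follow-up, assess, analyze — runs end-to-end with no
external data.

## Statistics

For arm-level counts (a/n_a vs b/n_b) the package computes risk ratios
with Katz log-method intervals,

    CI = exp( ln RR ± z · √(1/a − 1/n_a + 1/b − 1/n_b) ),

risk differences in percentage points with Wald intervals, Pearson
chi-squared (no continuity correction), Mantel–Haenszel pooled risk
ratios (Greenland–Robins variance), Kaplan–Meier curves, and the
two-proportion non-inferiority sample size

    n/arm = ⌈(z₁₋α + z_power)² (p_a q_a + p_b q_b) / m²⌉.

Non-inferiority at margin m is declared when the upper bound of the
two-sided 95% RD interval lies strictly below m percentage points.

## Worked example

```python
from epoct import *

p = PatientPresentation(
    patient_id="child-17", age_months=14, sex="female", weight_kg=9.1,
    muac_mm=138, temperature_c=38.6, fever_duration_days=2,
    symptoms=dict(cough=True),
    vitals=dict(respiratory_rate_per_min=52, heart_rate_per_min=148, sao2_percent=97),
    poct=dict(mrdt_positive=False, hb_g_per_l=104, crp_band="10_39"),
)
for fn in (classify_epoct, classify_almanach):
    r = fn(p)
    print(f"{r.algorithm:9s} {sorted(c.value for c in r.classifications)} "
          f"antibiotic={r.antibiotic_day0} referral={r.referral} tests={list(r.tests_performed)}")

t = TwoByTwo(events_a=37, total_a=1586, events_b=65, total_b=1583)
rr, rd = risk_ratio(t), risk_difference(t)
print(f"RR {rr.point:.2f} (95% CI {rr.ci_low:.2f}, {rr.ci_high:.2f})")
print(f"RD {rd.point:.1f} pp (95% CI {rd.ci_low:.1f}, {rd.ci_high:.1f})")
print("verdict:", noninferiority_decision(rd, margin_pp=3.0).value, "| NNT:", nnt(rd))
print("design N:", noninferiority_sample_size(0.10, 0.10, 0.03))
```

prints

```
epoct     ['viral_lrti'] antibiotic=False referral=False tests=['mrdt', 'hb', 'sao2', 'crp']
almanach  ['clinical_pneumonia'] antibiotic=True referral=False tests=['mrdt']
RR 0.57 (95% CI 0.38, 0.85)
RD -1.8 pp (95% CI -3.0, -0.5)
verdict: non_inferior | NNT: 57
design N: 3140
```

The same 14-month-old with cough and 52 breaths/min is a non-severe
viral lower respiratory infection under the biomarker cascade (CRP below
80 mg/l; bronchodilator, no antibiotic) but "clinical pneumonia" with an
antibiotic under the IMCI-derived cascade (respiratory rate ≥ 50/min).
The 2×2 block reproduces the trial arithmetic for clinical-failure
counts of 37/1,586 vs 65/1,583: a 43% relative-risk reduction whose risk
difference stays inside the 3-percentage-point non-inferiority margin,
one failure averted per 57 children managed, and the 3,140-patient
design that powers the comparison at 80%.

## Command line

```
epoct simulate  --n 500 --seed 42 --out-patients patients.csv \
                --out-followups followups.csv --truth latents.csv
epoct classify  --algorithm epoct --patients patients.csv --out classified.json --trace
epoct assess    --patients patients.csv --followups followups.csv --out outcomes.csv
epoct analyze   --outcomes outcomes.csv --margin 3 --out report.json
epoct randomize --n 100 --block-size 4 --seed 7 --out arms.csv
```

All verbs are deterministic given their inputs and seed. Exit codes:
0 ok, 2 validation error, 3 incomplete workup.

Every clinical threshold resolves through a single configurable registry
(`ReferenceStandards`, YAML-loadable via `--standards`); the bundled
respiratory/heart-rate percentile grids and the weight-for-age growth
table are documented approximations intended to be replaced with
published curves for real analyses (see `docs/methods.md`).

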