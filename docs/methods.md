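# Methods

## Scope

`epoct` makes a pediatric fever-triage study fully executable at desk
scale. It contains four things: (1) two clinical decision-support rule
engines — the biomarker-assisted e-POCT cascade and the IMCI-derived
ALMANACH control cascade — expressed as pure functions over validated
patient records; (2) the trial's outcome definitions (clinical failure by
day 7, the "not cured" re-treatment rule, severe adverse events by day
30); (3) the non-inferiority trial statistics (risk difference/ratio with
CIs, chi-squared, Mantel–Haenszel pooling, Kaplan–Meier, sample size,
block randomization, ITT/PP population construction); and (4) a seeded
synthetic-cohort generator so that the entire pipeline — randomize,
classify, follow up, assess, analyze — runs without any real data.

## The rule engines

Both engines consume the same `PatientPresentation` record and the same
`ReferenceStandards` registry. Every numeric cutoff lives in the
registry and nowhere else: hemoglobin < 60 g/l (severe anemia), blood
glucose < 3.3 mmol/l, CRP band ≥ 80 mg/l and procalcitonin ≥ 4 µg/l
(likely bacterial), SaO2 < 90%, MUAC < 115 mm (only above 6 months of
age), weight-for-age z < −3, skin lesion > 4 cm, and the respiratory- and
heart-rate percentile curves (75th/97th and 90th percentile for age and
temperature). Boundary semantics are exact: severity criteria are strict
(`<`) and bacterial criteria inclusive (`≥`), so Hb = 60 is not severe
while PCT = 4.0 is bacterial.

e-POCT evaluates its severe block first (CNS danger signs with a
two-convulsion threshold, severe respiratory distress, severe anemia by
measured hemoglobin, anthropometric severe malnutrition, severe
dehydration as intolerance of oral liquids plus severe tachycardia,
hypoglycemia, corneal clouding / severe mouth ulcers, and severe malaria
when any severe classification co-occurs with a positive rapid test).
Once any severe classification fires the patient is referred with a
pre-referral intramuscular antibiotic and the non-severe branches are not
evaluated: the published flow routes severe patients to referral before
the outpatient branches, and this convention also keeps the
fever-without-source operationalization ("no localizing complaint and not
severe") well founded. Non-severe patients pass through the staged
point-of-care cascade: malaria rapid test, hemoglobin and oximetry for
everyone; glucometer once a danger branch fires; CRP only for coughing
children with age/temperature-corrected tachypnea (≥ 75th percentile) or
fever without source with a negative malaria test; procalcitonin only
when that CRP stays below the bacterial band. Antibiotics are limited to
severe disease, bacterial lower respiratory infection, biomarker-positive
fever without source, and the three bacterial skin diagnoses (abscess,
cellulitis, impetigo/pyoderma). The classification→treatment map is data
(`ManagementConfig`), not code.

ALMANACH uses clinical signs only (single-convulsion threshold, chest
indrawing/cyanosis/stridor, severe palmar pallor, the IMCI two-of-four
dehydration sign sets, visible severe wasting or bilateral edema,
jaundice/mastoid swelling/complicated skin lesions) plus three
point-of-care tests: malaria rapid test for all, urine dipstick for
under-2s with fever without source or any child with dysuria, and a
rapid typhoid assay for older children with fever without source. Cough
with a respiratory rate ≥ 50/min at any age is clinical pneumonia and is
treated with an antibiotic — the central behavioral contrast with the
biomarker cascade, which classifies the same child as viral LRTI when
CRP < 80 mg/l. The engine never reads CRP, PCT, SaO2, hemoglobin, or
glucose (asserted by an invariance test).

Operationalizations the source material leaves open, fixed here and
configurable where meaningful: "fever without source" = no cough, no
significant diarrhea/vomiting (> 5 loose stools/24 h, or ≥ 3 stools with
any emesis, or > 3 emeses), no skin lesion — and, for the e-POCT branch,
no ear discharge or dysuria, whereas the control cascade keeps ear and
urinary findings inside its fever-without-source branch where they define
the likely-bacterial outcome. ALMANACH's non-severe gastrointestinal
dehydration requires at least one loose stool or emesis before the
two-of-four sign rule applies. "Severe wasting" maps to a
clinician-judgment boolean. Non-severe anemia (Hb below the age cutoff of
90/100/110 g/l but ≥ 60) is a classification with a configurable iron
token.

## Reference curves and growth standard

The age/temperature percentile curves for respiratory and heart rate are
not published as tables; the bundled grids are declared approximations
with the correct shape (rates fall with age, rise roughly 2 breaths/min
and 10 beats/min per °C of fever) chosen so that the 97th respiratory
percentile lies above the 50/min IMCI cutoff across the grid — otherwise
the two algorithms' documented behavioral contrast could not exist.
Lookups interpolate bilinearly, clamp at grid edges, are exact at nodes,
and are validated monotone non-decreasing in temperature. Users should
substitute published curves through the standards config for any real
analysis.

Weight-for-age uses the standard LMS transform
`z = ((w/M)^L − 1)/(L·S)` over a bundled **synthetic** month-by-month
L/M/S table (PCHIP interpolation through published summary medians of the
WHO 2006 standard; see `_growth_reference_synthetic.py`). It is
self-consistent (median ⇒ z = 0; the −3 line reads back to −3) and
accurate to a few hundred grams in the median, but it is not the official
reference; an official table can be supplied via the `wfa_table` config
key.

## Outcome definitions

Clinical failure is the composite of (a) severe disease at any contact
through the day-7 window: coma, more than 2 convulsions/24 h, inability
to drink or breastfeed, SaO2 < 90%, respiratory rate ≥ 97th or heart rate
≥ 90th percentile (same registry curves as the engines, asserted by
identity); (b) at the day-3 contact (window days 2–5): history of cough
with tachypnea (≥ 60/min under 12 months, ≥ 50/min from 12 months) or
lower chest indrawing, or dehydration requiring facility care; (c) at the
day-7 contact (window days 6–12): fever (reported or ≥ 38.0 °C),
clinical pneumonia by the same rule, ≥ 3 liquid stools/day, significant
dehydration, serious skin infection, or a new significant symptom (a
recorded assessor judgment, not derived). The earliest qualifying day and
every fired criterion are retained. Patients with no contact in the
day-7 window and no earlier qualifying event or death are lost to
follow-up: failure is undefined (`None`) for the per-protocol population
and imputed as failure in intention-to-treat construction. A severe
adverse event is death by day 30, else any admission after day 0 (a
day-0 admission that follows a primary referral is not "secondary").

## Trial statistics

Risk ratios carry Katz log-method CIs, risk differences (percentage
points) Wald CIs, association the Pearson chi-squared without continuity
correction — the conventions of the classical `cs`-style epidemiological
toolkit, validated against the published estimates (e.g., the Katz CI
4.42–72.02 on the 17.83 referral ratio). No zero-cell corrections are
applied; undefined estimates raise typed errors. Non-inferiority of the
new strategy is declared when the upper bound of the two-sided 95% RD CI
is strictly below the 3 pp margin (equivalently one-sided 97.5%); a CI
touching the margin is inconclusive. The two-proportion non-inferiority
sample size under an alternative of equality is
`n/arm = ceil((z_{1−α}+z_{power})²(p_a q_a + p_b q_b)/m²)`, which at
p = 0.10 both arms, m = 3 pp, 80% power and one-sided α = 0.025 gives
1,570/arm (3,140 total). NNT = ceil(100/|RD pp|). Mantel–Haenszel pooled
risk ratios use the Greenland–Robins variance and a Cochran-Q
heterogeneity p-value; Kaplan–Meier is the product-limit estimator
(backed by `lifelines`) with right-censoring. Block randomization fills
even-sized blocks exactly half-and-half.

Display rounding: risk ratios at 2 d.p., risk differences at 1 d.p. Two
published displays disagree with full-precision computation at the last
digit (the primary RD −1.77 is printed as −1.7; the 17.836 referral
ratio as 17.83); the package reports computed values and documents rather
than force-matches the displays.

## The synthetic cohort

Each simulated child draws a latent etiology from a configurable mix
(defaults: ~40% non-severe respiratory, ~24% fever without source, 11%
malaria, 11% gastroenteritis, ~4.5% skin disease, ~2% severe states, ~6%
bacterial conditions), an age from 44/33/23% weights over the
2–11/12–23/24–59-month bands, anthropometry on the weight-for-age z
scale (background z ~ N(−0.8, 1.3), so ~4% fall below −3 without any
latent malnutrition state), vitals from age-band baselines plus condition
offsets, and a full point-of-care panel conditioned on the etiology
(malaria-test sensitivity 0.97 / false-positive 0.01; CRP band and
procalcitonin distributions shifted upward for bacterial conditions;
hemoglobin ~ N(97, 15) g/l, ~N(50, 7) under the severe-anemia state).
Follow-up depends on management appropriateness: each condition carries
required care (antibiotic, referral, supportive token) and a base failure
probability (1–8%); withholding required antibiotic/referral care
multiplies the failure probability by 3, an unnecessary antibiotic by
1.5. Failures manifest as day-3 clinical pneumonia, an unscheduled
hypoxemic contact, or persistent day-7 fever — precisely the grammar the
outcome engine evaluates — and a configured fraction progress to a
secondary admission or death. All of these numbers are illustrative
calibrations of the marginal structure of an urban low-endemicity
outpatient cohort; they are configuration, not estimates, and the sign of
the simulated arm contrast (fewer antibiotics and no more failures under
the biomarker cascade) is a structural consequence of the
appropriateness model, while its magnitude is config-dependent.

Randomness follows a one-root-seed contract with hierarchical
per-patient substreams (`SeedSequence(seed, spawn_key=(stream, i))`), so
a cohort of size n is a prefix of the cohort of size m > n at the same
seed, and presentation, follow-up and randomization noise never
cross-contaminate.

## Numerical and testing choices

- Percentile lookups clamp rather than extrapolate; afebrile follow-up
  contacts are evaluated at the lower temperature edge (37.5 °C).
- The LMS transform falls back to the log form when |L| < 1e-8.
- Validation is total: malformed records, missing thresholds, degenerate
  tables and incomplete workups raise typed errors, never defaults.
- The engine-equivalence suite compares both engines against naive
  straight-line re-implementations over an exhaustive 155,520-point
  lattice crossing every cutoff at its exact boundary; the stochastic
  suite checks the design-point non-inferiority rate (1,000 replicates)
  against the 80% the sample-size formula promises, the empirical
  coverage of the Katz CI (2,000 replicates, 95% ± 1.5 pp), and recovery
  of a configured flat 10% failure probability through the full pipeline
  at n = 5,000 within three binomial standard errors (an exact-Bernoulli
  mechanism makes a one-SE band fail a third of correct runs).
- Problem sizes in the tests and acceptance script (lattice ~1.6 × 10⁵
  evaluations, simulated trials of 3,000–5,000 patients, 1,000–2,000
  Monte-Carlo replicates) were chosen so the whole suite completes in
  about a minute on one CPU while keeping Monte-Carlo error well inside
  the asserted tolerances.

## Limitations

Passing tests show the cascades and statistics are internally faithful
and mutually consistent — not that the synthetic cohort reproduces any
real population. The generator has no seasonality, no co-infection
structure beyond independent false positives, no HIV/malnutrition
interaction, and management-to-outcome coupling through a single
multiplier; the default percentile grids and growth table are declared
approximations. Real-data percentages that depend on the actual cohort
(classification shares, biomarker marginals) are calibration references
only.
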