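# Methods

This note records the clinical model implemented by `ckdphen`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was genuinely
open.

## Phenotype model

### eGFR and the CKD-EPI equation

Serum creatinine is stored in µmol/L (the Australian laboratory
convention; mg/dL inputs are multiplied by 88.4 at ingest) and converted
to eGFR with the 2009 CKD-EPI creatinine equation in its single-equation
form: scale 141, κ = 0.7 (female) / 0.9 (male) mg/dL, α = −0.329 /
−0.411, high-creatinine exponent −1.209, age factor 0.993 per year, and a
1.018 multiplier for females. No race coefficient is applied, matching
how Australian laboratories report eGFR. Results are rounded to one
decimal place, as laboratories print them. The coefficient set is a
config block (`ckd_epi:`), so the 2021 refit can be swapped in without
code changes.

Two published renderings of the 2009 equation differ in the fourth
significant figure: the single-equation form (141 × 1.018 = 143.54 for
females) versus the per-sex table constants (144). We implement the
single-equation form; at κ exactly (female, age 50, Scr 61.9 µmol/L) it
yields 101.0 where the table form yields 101.4. The difference (< 0.4%)
is far below clinical resolution but matters when freezing test values —
all frozen values in the suite come from an independently coded
evaluation of the single-equation form.

The equation is for adults; creatinine drawn before age 18 is skipped
when building eGFR series. Laboratory-reported eGFR fills dates with no
creatinine, computed values winning same-day collisions; values reported
as "> 90" are stored at 90 with a censor flag and never count as evidence
of *reduced* eGFR.

### Chronicity and persistence

"Duration > 3 months" is operationalised as ≥ 90 days throughout.

* **Reduced eGFR** — at least two readings below 60 mL/min/1.73 m² at
  least 90 days apart, **and** the most recent reading below 60. The
  second condition (the resolved-AKI guard) is the minimal rule that
  stops a recovered episode of acute kidney injury — two old low readings
  followed by normal function — from satisfying chronicity; AKI and eGFR
  fluctuation are the classic causes of algorithm/clinician discordance
  in this setting. The guard is switchable
  (`thresholds.require_latest_low_egfr`).
* **Albuminuria** — at least two uACR readings ≥ 3 mg/mmol (the A2
  boundary). The default imposes no minimum spacing; the *stringent*
  definition variant additionally requires two elevated readings ≥ 90
  days apart, and applies only to the stage 1–2 arm. A single elevated
  uACR is never sufficient: a patient with one elevated uACR and one eGFR
  of 60–89 is "no CKD" (a G2 result with unconfirmed albuminuria is not
  disease under the persistence rules).

### CKD rule priority

1. RRT codes → stage `RRT`, suppressing all numeric stages (mutual
   exclusivity). Transplant codes dominate dialysis codes for modality; a
   maintenance-dialysis modality additionally requires ≥ 3
   dialysis-coded events in the 90 days before the as-of date (count and
   window config-exposed). Sparse or historic dialysis coding still sets
   RRT-positive with modality *unspecified* — episodic haemodialysis is a
   real presentation and should not be labelled maintenance.
2. Laboratory staging: chronically reduced eGFR stages CKD 3a–5 from the
   **most recent** eGFR; otherwise persistent albuminuria with preserved
   eGFR stages CKD 1 (eGFR ≥ 90 or absent) or CKD 2 (60–89). Staging
   from the most recent value (rather than a recent-window aggregate) is
   a deliberate choice: it is the value a clinician reviews, and
   fluctuation-driven disagreement is accepted as a known discordance
   source.
3. Code-only: any other CKD-related diagnosis code → pooled-positive.
   Stage-granular codes (N18.1–N18.5 style; the most severe wins when
   several are present) supply a stage only here — laboratory evidence
   always wins when present. ICD-10-AM "N18.3" maps to CKD 3a, the
   conservative end of the printed "stage 3" slot.

Definition variants: `stage3a_plus` disables arm 2's albuminuria-only
branch (CKD = eGFR < 60 or RRT); `stringent_uacr` applies the 90-day
albuminuria spacing in the stage 1–2 branch. Both are, by construction,
restrictions of the default `stage1_plus` definition, so their positives
nest inside the default's — a property the tests verify cohort-wide.

### Comorbid phenotypes

* T2DM: ≥ 2 HbA1c ≥ 48 mmol/mol (6.5%, the diagnostic standard), OR any
  ATC A10 medication, OR a diabetes code. Requiring two elevated HbA1c
  means a single historic elevation among normal readings, with no other
  evidence, is "no diabetes".
* Hypertension: code, OR antihypertensive medication (C02/C03/C07/C08/
  C09), OR ≥ 2 clinic BP readings on distinct dates with systolic ≥ 140
  or diastolic ≥ 90. The 140/90 thresholds and the two-reading minimum
  follow contemporary Australian guideline practice and are
  config-exposed.
* CVD: diagnosis codes only. This is the one phenotype with no
  laboratory or medication arm, which makes its measured sensitivity
  track coding quality directly — useful as the canary in degradation
  experiments.
* At-risk-of-CKD: diabetes OR hypertension OR any renal/AKI code OR an
  externally supplied five-year cardiovascular risk score strictly
  greater than 15%. Risk-score computation itself is out of scope; the
  score is an input.

### Code sets

All code logic is prefix matching (case-insensitive, ICD dots removed)
within a coding system — ICD-10-AM/ICPC-2/ATC hierarchies are
prefix-structured, so prefixes express "this chapter/class" naturally.
The shipped YAML defaults use standard chapter prefixes (N18 CKD, E11
diabetes, I10–I15 hypertension, I20–I73 CVD, Z49/Z94.0 RRT, A10
glucose-lowering, …) and are explicitly stand-ins: production
deployments carry curated local lists and should override the config.
The default ICPC-2 stage map is empty because ICPC-2 has no
stage-granular CKD rubrics; the coded-comparator averaging rule
(ceil of the mean ICD/ICPC ordinal stage) activates only when a
deployment supplies one.

## Validation machinery

* Confidence intervals are Wald ("asymptotic") intervals
  p ± z·√(p(1−p)/n), clipped to [0, 1] — chosen over Wilson/exact
  because zero-width intervals at 100% are the intended behaviour for
  this reporting style. Wald under-coverage is acknowledged: the suite
  checks empirical coverage at p = 0.9, n = 200 falls in [0.90, 0.97]
  rather than asserting nominal 95%.
* Specificity is TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN); any
  zero-denominator metric is flagged undefined rather than propagating
  NaN. `auc` is the balanced accuracy (Se+Sp)/2 of a binary classifier.
* Buderer sample size: n_Se = ⌈z²·Se(1−Se)/d² / P⌉ and
  n_Sp = ⌈z²·Sp(1−Sp)/d² / (1−P)⌉, study size the maximum. The ceiling
  is applied **after** the prevalence division (146 and 277 at
  Se = 0.95, Sp = 0.90, P = 0.5, d = 0.05, z = 1.96); ceiling before
  division would give 278. z defaults to the conventional 1.96; the
  exact quantile is available via `SampleSizeSpec(z=None)`.
* Cohen's kappa uses marginal-product expected agreement; kappa is
  undefined (returned as `None`) when expected agreement is 1.
* Validation subgroups are assigned in priority order 1→6 (at-risk
  without CKD; stages 1–3a; 3b–4; stage 5 or RRT; ≥ 2 coded
  comorbidities; ≥ 3 chronic-disease medications), after an eligibility
  floor of ≥ 3 laboratory-plus-observation entries. The priority order
  resolves overlaps deterministically (a diabetic CKD 3a patient is a
  stage-2 subgroup member, not a comorbidity one). "Coded comorbidity"
  counts diseases with at least one ICD/ICPC code; "medications" counts
  distinct ATC codes within the chronic-disease classes.

## Completeness

Five data types are tracked (labs, observations, ICD codes, ICPC codes,
medications). Density is entries per patient-year with the span floored
at one year, so single-visit patients do not produce unbounded rates.
The four completeness flags form a nested ladder; only the strictest is
externally specified (3 labs, 3 observations, 1 coded diagnosis — either
system — and 1 medication), so metrics 1–3 are package defaults chosen to
nest (≥ 1 entry; ≥ 1 lab + 1 coded; ≥ 3 labs + 1 coded + 1 medication)
and are config-overridable. An *active* patient has any entry within the
two years before the census date.

## Synthetic cohort generator

The generator is the package's test bed, not an epidemiological model.
Each profile fixes the truth; the record is then constructed so the
corresponding definitions hold exactly at zero noise and perfect coding:

* eGFR trajectories are linear in time (default slope 0, mid-band
  targets: 95/95/75/52/38/22/10 mL/min/1.73 m² for
  none/CKD1/CKD2/3a/3b/4/5), with creatinine obtained by closed-form
  inversion of CKD-EPI at the patient's age on each visit date, times
  multiplicative log-normal noise (default CV 0; the noise study uses
  5%).
* Visits are a Poisson process (default 4/year) over 1–24 years of
  follow-up, anchored at the first and last day so persistence spans
  exist; the index date defaults to 2021-02-07.
* Coding imperfection is per-disease Bernoulli: a true condition is
  coded with probability `coding_sensitivity`, a false one with
  `1 − coding_specificity` (defaults 1 and 1). Lab and observation
  evidence for T2DM/hypertension is emitted deterministically, so
  code-independent arms keep working as coding degrades — mirroring the
  central empirical point that codes under-detect disease while
  laboratory criteria do not.
* An optional `aki_episode` flag injects a resolved low-eGFR dip (two
  readings ≥ 90 days apart, ending 200 days before index) to exercise
  the resolved-AKI guard.
* `degrade` removes an exact count (fixed-count subsampling, not
  Bernoulli) per entity type so completeness tests are deterministic.

The default validation cohort reproduces the six-subgroup census
{50, 49, 51, 50, 45, 43} (total 288). One structural consequence of the
subgroup priorities is worth recording: any CKD-negative patient with
diabetes or hypertension is captured by the at-risk subgroup first, so
the comorbidity (5) and polypharmacy (6) subgroups can only be populated
by pooled-positive patients without a laboratory stage. The generator
therefore gives those subgroups a CKD-related code with no qualifying
labs — clinically, coded CKD without laboratory confirmation, a common
real-world pattern.

**What passing tests do and do not show.** The generator's records are
far cleaner than real EHR data: no inter-disease correlation structure,
no unit errors or duplicated feeds, no missing demographics, linear
trajectories, and coding errors independent across diseases and
patients. Perfect recovery on the noise-free cohort demonstrates that the
classifiers implement their definitions exactly; it says nothing about
accuracy against human chart review on real data, which depends on data
quality and clinician interpretation and can only be measured in a real
validation study.

## Numerical and degenerate-input choices

* Dates are day-resolution; same-day ties keep stable input order;
  same-day creatinine beats reported eGFR.
* Stage binning is half-open with inclusive lower bounds (60 → G2,
  45 → G3a); uACR A2 is the closed interval [3, 30].
* Empty series never satisfy persistence rules; empty label maps and
  empty agreement tables are hard errors; mismatched patient sets in
  gold/predicted comparisons are hard errors listing the symmetric
  difference.
* Ingest drops (and counts, per reason) rows with unparseable dates,
  negative values, dates on/before birth, or unknown units; unknown
  analytes/observation kinds are kept as `other` with a warning count,
  so `loaded + dropped = rows` holds per table.
* Problem sizes in the test suite were chosen to keep the full run
  around ten seconds while still exercising every rule: 10,000 random
  records for the CKD oracle-equivalence check, exhaustive low/high
  patterns to length 8 for chronicity, 5,000 replicates for Wald
  coverage, 1,000 patients for stage recovery under 5% creatinine noise.

## Known limitations

* Pediatric and cystatin-C eGFR equations, body-surface-area
  de-indexing, and proteinuria proxies (urinalysis, uPCR) are not
  implemented; uACR is the only albuminuria measure.
* Type 1 / gestational diabetes are not distinguished from T2DM by the
  code-arm defaults; the KDIGO G×A risk-grid presentation is not
  emitted (G and A stages are).
* Record linkage is assumed done upstream: one `patient_id` is one
  person.
* The coded-stage comparator collapses 3a/3b into one ordinal slot,
  which is how stage-coded diagnoses are printed; deployments with
  3a/3b-granular local codes should extend the stage map instead.
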