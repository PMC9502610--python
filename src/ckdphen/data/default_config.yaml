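# Default ckdphen configuration: clinical thresholds and code sets.
#
# The code sets below are documented stand-ins built from standard
# ICD-10-AM chapter prefixes, ICPC-2 rubrics and ATC classes; production
# deployments are expected to override them with locally curated lists
# (pass --config / load_config(path)).  Prefix-match semantics: an entry
# matches if its normalised code (uppercase, dots removed) begins with a
# configured prefix, within the same coding system.
version: 1

thresholds:
  # KDIGO G-stage boundaries (mL/min/1.73m2), strictly decreasing:
  # G1 >=90, G2 [60,90), G3a [45,60), G3b [30,45), G4 [15,30), G5 <15
  g_stage_boundaries: [90, 60, 45, 30, 15]
  # KDIGO A-stage boundaries (mg/mmol): A1 <3, A2 [3,30], A3 >30
  a_stage_boundaries: [3.0, 30.0]
  # chronicity: 2+ eGFR readings < 60 at least 90 days apart
  egfr_chronic_threshold: 60.0
  chronicity_min_span_days: 90
  # most recent eGFR must itself be below threshold (resolved-AKI guard)
  require_latest_low_egfr: true
  # persistent albuminuria: 2+ readings >= 3 mg/mmol; the stringent
  # variant additionally requires two readings >= 90 days apart
  uacr_elevated: 3.0
  uacr_min_count: 2
  uacr_min_span_days: 0
  uacr_stringent_span_days: 90
  # diabetes lab arm: 2+ HbA1c >= 48 mmol/mol (6.5%)
  hba1c_elevated: 48.0
  hba1c_min_count: 2
  # hypertension observation arm: 2+ readings on distinct dates with
  # systolic >= 140 or diastolic >= 90 (clinic BP)
  bp_systolic_elevated: 140.0
  bp_diastolic_elevated: 90.0
  bp_min_count: 2
  # maintenance dialysis: >= 3 dialysis-coded events in the 90 days
  # before the as-of date; older isolated events -> modality unspecified
  dialysis_maintenance_count: 3
  dialysis_maintenance_window_days: 90
  # externally supplied five-year cardiovascular risk (%); strict >
  cvd_risk_threshold: 15.0

# 2009 CKD-EPI creatinine equation, no race coefficient (Australian
# laboratory reporting convention).  Serum creatinine in mg/dL inside the
# equation; ingest stores umol/L and the implementation divides by 88.4.
ckd_epi:
  scale: 141.0
  kappa_female: 0.7      # mg/dL
  kappa_male: 0.9
  alpha_female: -0.329
  alpha_male: -0.411
  beta_high: -1.209
  age_factor: 0.993
  female_multiplier: 1.018

codesets:
  ckd_related:
    ICD10AM: [N18, N19, N03, N04, N05, N08, N11, N14, N16, Q61]
    ICPC2: [U99]
  aki:
    ICD10AM: [N17]
    ICPC2: []
  rrt_haemodialysis:
    ICD10AM: ["Z49.1", "Z99.2"]
    ICPC2: []
    ICD10AM_procedure: ["13100"]
    MBS: ["13100"]
  rrt_peritoneal_dialysis:
    ICD10AM: ["Z49.2"]
    ICPC2: []
    ICD10AM_procedure: ["13104"]
    MBS: ["13104"]
  rrt_transplant:
    ICD10AM: ["Z94.0", T86.1]
    ICPC2: []
    ICD10AM_procedure: ["36503"]
    MBS: ["36503"]
  t2dm:
    ICD10AM: [E11]
    ICPC2: [T90]
  hypertension:
    ICD10AM: [I10, I11, I12, I13, I15]
    ICPC2: [K86, K87]
  cvd:
    ICD10AM: [I20, I21, I22, I23, I24, I25, I60, I61, I62, I63, I64,
              I65, I66, I67, I68, I69, I70, I71, I73]
    ICPC2: [K74, K75, K76, K89, K90, K91, K92]
  glucose_lowering_med:
    ATC: [A10]
  antihypertensive_med:
    ATC: [C02, C03, C07, C08, C09]
  chronic_disease_med:
    ATC: [A10, B01, C01, C02, C03, C07, C08, C09, C10]

# Diagnosis codes that imply a CKD stage when no laboratory staging is
# possible.  ICPC-2 has no stage-granular CKD rubrics, so its map is
# empty by default; the coded-comparator stage-averaging rule activates
# only when a deployment supplies an ICPC stage map.
stage_codes:
  ICD10AM:
    "N18.1": CKD1
    "N18.2": CKD2
    "N18.3": CKD3a
    "N18.4": CKD4
    "N18.5": CKD5
  ICPC2: {}
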