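# ckdphen

Electronic phenotyping of chronic kidney disease (CKD) and its common
comorbidities from longitudinal electronic health record (EHR) extracts,
together with the statistical machinery needed to *validate* such
phenotype algorithms against a chart-review gold standard.

`ckdphen` is aimed at clinical informaticians and epidemiologists who
maintain multi-source EHR registries (hospital ICD-10-AM coding, primary
care ICPC-2 coding, laboratory feeds, medication lists) and need
reproducible, explainable disease labels for clinical decision support or
epidemiological research. Administrative codes alone under-detect kidney
disease — early stages are clinically silent, and even dialysis-dependent
patients are often miscoded — so the classifiers here combine codes with
strict laboratory criteria and temporal persistence rules.

## What it computes

**CKD staging (KDIGO).** eGFR is computed from serum creatinine with the
2009 CKD-EPI equation (no race coefficient),

```
eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^Age · 1.018 [female]
```

with κ = 0.7/0.9 mg/dL and α = −0.329/−0.411 (female/male). G-stages
follow the KDIGO cut-offs (G1 ≥ 90, G2 60–89, G3a 45–59, G3b 30–44,
G4 15–29, G5 < 15 mL/min/1.73 m²) and A-stages the uACR cut-offs
(A1 < 3, A2 3–30, A3 > 30 mg/mmol). A CKD diagnosis by eGFR requires
*chronicity* — two or more readings < 60 at least 90 days apart, with the
most recent reading still low (so a resolved acute kidney injury does not
qualify). Stages 1–2 require *persistent* albuminuria (≥ 2 elevated
uACR) with preserved eGFR. Renal replacement therapy (RRT) is detected
from diagnosis/procedure codes, sub-typed into haemodialysis, peritoneal
dialysis and transplant, and is mutually exclusive with the numeric
stages. Any other CKD-related code makes the pooled phenotype positive
without a laboratory stage.

**Comorbid phenotypes.** Type 2 diabetes (≥ 2 HbA1c ≥ 48 mmol/mol, OR
glucose-lowering medication, OR diagnosis code), hypertension (code, OR
antihypertensive medication, OR ≥ 2 clinic BP readings ≥ 140/90 on
distinct dates), cardiovascular disease (diagnosis codes only), and an
at-risk-of-CKD flag (diabetes, hypertension, renal/AKI history, or an
externally supplied five-year cardiovascular risk score > 15%).

**Validation machinery.** 2×2 confusion counts against a gold standard;
sensitivity/specificity/PPV/NPV with asymptotic (Wald) 95% CIs; Cohen's
kappa; the Buderer sample-size formula for diagnostic accuracy studies;
an 8-level CKD stage confusion matrix; six-subgroup stratified
validation-cohort construction; and an administrative-code comparator
that stages CKD from codes alone, averaging ICD and ICPC implied stages
(rounded up) when they disagree.

**Data completeness.** Documentation, breadth and density metrics over
five data types, a four-level nested completeness ladder (the strictest
flag: 3 laboratory results, 3 observations, 1 coded diagnosis,
1 medication), and a two-year activity window.

**Synthetic cohorts.** A ground-truth generator builds patient records
that satisfy the phenotype definitions by construction: creatinine is
back-solved from a target eGFR trajectory through the closed-form inverse
of CKD-EPI, visit dates follow a Poisson process over up to 24 years of
follow-up, and coding imperfection is modelled as per-disease Bernoulli
sensitivity/specificity. Every classifier can therefore be tested
end-to-end without any patient data.

## Worked example

A 54-year-old woman with rising creatinine over 13 months, persistently
elevated uACR, and a hospital N18.3 code:

```python
import datetime
from ckdphen import *
from ckdphen.phenotypes import AlgorithmConfig, classify_ckd

as_of = datetime.date(2021, 2, 7)
cfg = AlgorithmConfig(as_of=as_of)
pid = "NT-000123"
demo = PatientDemographics(pid, Sex.FEMALE, datetime.date(1966, 3, 15))
def lab(analyte, value, days_back, units):
    return LabResult(pid, analyte, value, units,
                     as_of - datetime.timedelta(days=days_back))
record = PatientRecord(
    demographics=demo,
    labs=(lab(Analyte.SERUM_CREATININE, 142.0, 400, "umol/L"),
          lab(Analyte.SERUM_CREATININE, 150.0, 120, "umol/L"),
          lab(Analyte.SERUM_CREATININE, 155.0,   0, "umol/L"),
          lab(Analyte.UACR, 12.0, 120, "mg/mmol"),
          lab(Analyte.UACR, 15.0,   0, "mg/mmol")),
    codes=(CodedEntry(pid, CodeSystem.ICD10AM, "N18.3",
                      as_of - datetime.timedelta(days=90)),),
)
for p in egfr_series(record):
    print(p.date, p.egfr, p.source.value)
res = classify_ckd(record, cfg)
print("pooled:", res.pooled_positive, "| stage:", res.stage.value,
      "| G:", res.g_stage.value, "| A:", res.a_stage.value,
      "| basis:", sorted(b.value for b in res.basis))
```

prints

```
2020-01-04 36.0 computed_ckd_epi
2020-10-10 33.5 computed_ckd_epi
2021-02-07 32.2 computed_ckd_epi
pooled: True | stage: CKD3b | G: G3b | A: A2 | basis: ['egfr_criteria']
```

Three eGFR values below 60 span well over 90 days and the latest is still
low, so chronicity is met; the most recent eGFR (32.2) falls in G3b, so
the patient is staged CKD 3b on laboratory evidence — the coarser N18.3
code is not needed and does not override the laboratory stage.

Planning a validation study expecting 95% sensitivity and 90% specificity
at 50% prevalence with a ± 5% margin:

```
$ ckdphen samplesize --se 0.95 --sp 0.90 --prev 0.5
{"n_sensitivity": 146, "n_specificity": 277, "n_required": 277}
```

The CLI also provides `ckdphen simulate` (write a synthetic cohort with
ground truth), `classify`, `validate`, `sample` and `completeness`; see
`ckdphen --help`.

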