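"""Ground-truth synthetic EHR cohort generator.

Each :class:`SyntheticProfile` states what a patient *truly* has — CKD
stage (or RRT with a modality), diabetes, hypertension, cardiovascular
disease — together with follow-up length, visit rate, laboratory noise
and coding imperfection.  :func:`generate_patient` turns a profile into a
:class:`~ckdphen.model.PatientRecord` whose structured data satisfies the
corresponding phenotype definitions *by construction* when noise is zero
and coding is perfect:

* visit dates follow a Poisson process over the follow-up window, always
  including the first and last day so persistence criteria have the span
  they need;
* serum creatinine is back-solved from the target eGFR trajectory via the
  closed-form inverse of the CKD-EPI equation, with optional
  multiplicative log-normal noise;
* uACR readings are drawn log-normally around the profile level;
* elevated HbA1c pairs, blood-pressure series, diagnosis codes and
  medications are emitted according to the target phenotypes, each code
  subject to a per-disease Bernoulli coding sensitivity (true conditions
  may go uncoded) and specificity (false conditions may be miscoded) —
  emulating how administrative coding under-detects disease in real
  records;
* RRT targets emit dialysis code clusters dense enough to satisfy the
  maintenance-dialysis rule, or a transplant code.

:func:`generate_validation_cohort` assembles profiles so the validation
subgroup assignment reproduces a requested census (by default the
288-patient, six-subgroup design {50, 49, 51, 50, 45, 43}).  Patients for
subgroups 5 and 6 are code-only CKD positives: any CKD-negative patient
with diabetes or hypertension is captured by the at-risk subgroup 1
first, so the comorbidity and polypharmacy subgroups can only be
populated by pooled-positive patients without a laboratory stage.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .config import AppConfig, CREATININE_UMOL_PER_MGDL, CkdEpiCoefficients, default_config
from .model import (
    Analyte,
    CANONICAL_UNITS,
    CareSetting,
    CodeSystem,
    CodedEntry,
    LabResult,
    MedicationRecord,
    Observation,
    ObservationKind,
    PatientDemographics,
    PatientRecord,
    Sex,
)
from .phenotypes import CkdStage, RrtModality
from .renal import DAYS_PER_YEAR

DEFAULT_INDEX_DATE = datetime.date(2021, 2, 7)

#: (eGFR at index, uACR level mg/mmol) per target stage, chosen mid-band.
STAGE_DEFAULTS: Mapping[CkdStage, tuple[float, float]] = {
    CkdStage.NONE: (95.0, 1.0),
    CkdStage.CKD1: (95.0, 10.0),
    CkdStage.CKD2: (75.0, 10.0),
    CkdStage.CKD3A: (52.0, 1.0),
    CkdStage.CKD3B: (38.0, 1.0),
    CkdStage.CKD4: (22.0, 1.0),
    CkdStage.CKD5: (10.0, 1.0),
    CkdStage.RRT: (8.0, 1.0),
}

_DISEASE_CODES = {"t2dm": "E11", "hypertension": "I10", "cvd": "I25"}


@dataclass(frozen=True)
class SyntheticProfile:
    """Ground-truth specification from which one patient record is generated."""

    patient_id: str
    seed: int
    sex: Sex = Sex.FEMALE
    age_years: float = 55.0            # at the index date
    followup_years: float = 10.0       # 1-24
    visit_rate: float = 4.0            # visits per year (Poisson)
    index_date: datetime.date = DEFAULT_INDEX_DATE
    ckd_stage: CkdStage = CkdStage.NONE
    ckd_code_only: bool = False        # CKD-related code without lab staging
    rrt_modality: RrtModality = RrtModality.NONE
    t2dm: bool = False
    hypertension: bool = False
    cvd: bool = False
    egfr_index: Optional[float] = None     # eGFR at index date; stage default if None
    egfr_slope: float = 0.0                # mL/min/1.73m2 per year
    uacr_level: Optional[float] = None     # mg/mmol; stage default if None
    creatinine_cv: float = 0.0             # multiplicative log-normal sigma
    uacr_sigma: float = 0.0                # log-normal sigma
    coding_sensitivity: float = 1.0        # P(code | true condition)
    coding_specificity: float = 1.0        # P(no code | no condition)
    aki_episode: bool = False              # transient resolved low-eGFR dip
    extra_medications: tuple[str, ...] = ()

    def resolved_egfr_index(self) -> float:
        return STAGE_DEFAULTS[self.ckd_stage][0] if self.egfr_index is None else self.egfr_index

    def resolved_uacr(self) -> float:
        return STAGE_DEFAULTS[self.ckd_stage][1] if self.uacr_level is None else self.uacr_level

    def validate(self) -> None:
        if not 1.0 <= self.followup_years <= 24.0:
            raise ValueError("followup_years must lie in [1, 24]")
        if self.visit_rate <= 0:
            raise ValueError("visit_rate must be positive")
        if self.age_years - self.followup_years < 18.0:
            raise ValueError("patient must be an adult for the whole follow-up")
        for name in ("coding_sensitivity", "coding_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        egfr = self.resolved_egfr_index()
        egfr_first = egfr - self.egfr_slope * self.followup_years
        uacr = self.resolved_uacr()
        stage = self.ckd_stage
        if self.ckd_code_only and stage is not CkdStage.NONE:
            raise ValueError("ckd_code_only requires ckd_stage=none")
        if stage is CkdStage.RRT and self.rrt_modality is RrtModality.NONE:
            raise ValueError("RRT stage requires a modality")
        if stage is not CkdStage.RRT and self.rrt_modality is not RrtModality.NONE:
            raise ValueError("rrt_modality set without RRT stage")
        bands = {
            CkdStage.CKD3A: (45.0, 60.0), CkdStage.CKD3B: (30.0, 45.0),
            CkdStage.CKD4: (15.0, 30.0), CkdStage.CKD5: (2.0, 15.0),
        }
        if stage in (CkdStage.CKD1, CkdStage.CKD2):
            if uacr < 3.0:
                raise ValueError(
                    f"{stage.value} requires an elevated uACR level, got {uacr}")
            lo = 90.0 if stage is CkdStage.CKD1 else 60.0
            hi = float("inf") if stage is CkdStage.CKD1 else 90.0
            if not (lo <= egfr and egfr < hi and egfr_first >= lo):
                raise ValueError(
                    f"{stage.value} needs eGFR in [{lo}, {hi}) throughout, "
                    f"got {egfr_first:.1f}..{egfr:.1f}")
        elif stage in bands:
            lo, hi = bands[stage]
            if not (lo <= egfr < hi and egfr_first < 60.0):
                raise ValueError(
                    f"{stage.value} needs index eGFR in [{lo}, {hi}) and a "
                    f"persistently reduced trajectory, got {egfr_first:.1f}..{egfr:.1f}")
        elif stage is CkdStage.NONE:
            if min(egfr, egfr_first) < 60.0:
                raise ValueError("stage none requires eGFR >= 60 throughout")
            if uacr >= 3.0:
                raise ValueError("stage none requires a non-elevated uACR level")


@dataclass(frozen=True)
class GroundTruth:
    patient_id: str
    ckd_pooled: bool
    ckd_stage: CkdStage
    rrt_modality: RrtModality
    t2dm: bool
    hypertension: bool
    cvd: bool
    subgroup: Optional[int] = None

    def as_bool_labels(self) -> dict[str, bool]:
        return {
            "ckd_pooled": self.ckd_pooled,
            "t2dm": self.t2dm,
            "hypertension": self.hypertension,
            "cvd": self.cvd,
            "rrt": self.rrt_modality is not RrtModality.NONE,
        }


def inverse_ckd_epi(
    sex: Sex,
    age_years: float,
    target_egfr: float,
    coefficients: CkdEpiCoefficients = CkdEpiCoefficients(),
) -> float:
    """Serum creatinine (µmol/L) that yields *target_egfr* under CKD-EPI.

    Closed-form inversion of the single-equation form: the equation is a
    two-piece power law in Scr/κ, continuous and strictly decreasing, so
    each target maps to exactly one creatinine.
    """
    if target_egfr <= 0:
        raise ValueError("target eGFR must be positive")
    c = coefficients
    if sex is Sex.FEMALE:
        kappa, alpha = c.kappa_female, c.alpha_female
        anchor = c.scale * c.female_multiplier
    else:
        kappa, alpha = c.kappa_male, c.alpha_male
        anchor = c.scale
    anchor *= c.age_factor ** age_years  # eGFR at Scr = kappa
    if target_egfr >= anchor:
        ratio = (target_egfr / anchor) ** (1.0 / alpha)
    else:
        ratio = (target_egfr / anchor) ** (1.0 / c.beta_high)
    return ratio * kappa * CREATININE_UMOL_PER_MGDL


def _visit_dates(rng: np.random.Generator, start: datetime.date,
                 end: datetime.date, rate_per_year: float) -> list[datetime.date]:
    total_days = (end - start).days
    n = int(rng.poisson(rate_per_year * total_days / DAYS_PER_YEAR))
    offsets = sorted(set(
        [0, total_days] + [int(x) for x in rng.uniform(1, total_days, size=max(0, n - 2))]
    ))
    return [start + datetime.timedelta(days=o) for o in offsets]


def generate_patient(
    profile: SyntheticProfile,
    config: Optional[AppConfig] = None,
) -> tuple[PatientRecord, GroundTruth]:
    """Materialise one patient record plus its ground-truth labels."""
    profile.validate()
    cfg = config if config is not None else default_config()
    rng = np.random.default_rng(profile.seed)
    pid = profile.patient_id
    index = profile.index_date
    start = index - datetime.timedelta(days=round(profile.followup_years * DAYS_PER_YEAR))
    birth = index - datetime.timedelta(days=round(profile.age_years * DAYS_PER_YEAR))
    demo = PatientDemographics(pid, profile.sex, birth)
    visits = _visit_dates(rng, start, index, profile.visit_rate)

    labs: list[LabResult] = []
    observations: list[Observation] = []
    codes: list[CodedEntry] = []
    medications: list[MedicationRecord] = []

    egfr_index = profile.resolved_egfr_index()
    for d in visits:
        years_to_index = (index - d).days / DAYS_PER_YEAR
        target = max(2.0, egfr_index - profile.egfr_slope * years_to_index)
        age = (d - birth).days / DAYS_PER_YEAR
        scr = inverse_ckd_epi(profile.sex, age, target, cfg.ckd_epi)
        if profile.creatinine_cv > 0:
            scr *= float(rng.lognormal(0.0, profile.creatinine_cv))
        labs.append(LabResult(pid, Analyte.SERUM_CREATININE, scr,
                              CANONICAL_UNITS[Analyte.SERUM_CREATININE], d))
        if profile.hypertension:
            sys_bp, dia_bp = 152.0, 96.0
        else:
            sys_bp, dia_bp = 118.0, 72.0
        observations.append(Observation(pid, ObservationKind.SYSTOLIC_BP, sys_bp, d))
        observations.append(Observation(pid, ObservationKind.DIASTOLIC_BP, dia_bp, d))

    def _uacr(on: datetime.date) -> LabResult:
        value = profile.resolved_uacr()
        if profile.uacr_sigma > 0:
            value *= float(rng.lognormal(0.0, profile.uacr_sigma))
        return LabResult(pid, Analyte.UACR, value,
                         CANONICAL_UNITS[Analyte.UACR], on)

    if profile.ckd_stage in (CkdStage.CKD1, CkdStage.CKD2):
        labs.append(_uacr(visits[0]))
        labs.append(_uacr(visits[-1]))
    else:
        labs.append(_uacr(visits[-1]))

    if profile.t2dm:
        hba1c_values = (62.0, 60.0)
    else:
        hba1c_values = (38.0, 40.0)
    for v, d in zip(hba1c_values, visits[-2:] if len(visits) >= 2 else visits):
        labs.append(LabResult(pid, Analyte.HBA1C, v,
                              CANONICAL_UNITS[Analyte.HBA1C], d))

    if profile.aki_episode:
        # transient dip well before the index date, resolved afterwards:
        # must never satisfy the chronicity rule
        dip_end = index - datetime.timedelta(days=200)
        dip_start = dip_end - datetime.timedelta(days=120)
        for d in (dip_start, dip_end):
            if d > birth:
                age = (d - birth).days / DAYS_PER_YEAR
                labs.append(LabResult(
                    pid, Analyte.SERUM_CREATININE,
                    inverse_ckd_epi(profile.sex, age, 35.0, cfg.ckd_epi),
                    CANONICAL_UNITS[Analyte.SERUM_CREATININE], d))

    def _emit_code(code: str, on: datetime.date,
                   system: CodeSystem = CodeSystem.ICD10AM) -> None:
        codes.append(CodedEntry(pid, system, code, on,
                                CareSetting.HOSPITAL if system is CodeSystem.ICD10AM
                                else CareSetting.PRIMARY_CARE))

    # comorbidity coding with Bernoulli sensitivity/specificity
    for disease, code in _DISEASE_CODES.items():
        truly_has = getattr(profile, {"t2dm": "t2dm", "hypertension": "hypertension",
                                      "cvd": "cvd"}[disease])
        p_code = profile.coding_sensitivity if truly_has else 1.0 - profile.coding_specificity
        if rng.random() < p_code:
            _emit_code(code, visits[int(rng.integers(len(visits)))])

    # CKD coding
    stage_code = {CkdStage.CKD1: "N18.1", CkdStage.CKD2: "N18.2",
                  CkdStage.CKD3A: "N18.3", CkdStage.CKD3B: "N18.3",
                  CkdStage.CKD4: "N18.4", CkdStage.CKD5: "N18.5"}
    if profile.ckd_code_only:
        _emit_code("N18.9", visits[int(rng.integers(len(visits)))])
    elif profile.ckd_stage in stage_code:
        if rng.random() < profile.coding_sensitivity:
            _emit_code(stage_code[profile.ckd_stage],
                       visits[int(rng.integers(len(visits)))])
    elif profile.ckd_stage is CkdStage.NONE:
        if rng.random() < 1.0 - profile.coding_specificity:
            _emit_code("N18.9", visits[int(rng.integers(len(visits)))])

    # RRT coding: dense recent dialysis events for maintenance modalities,
    # a single transplant code for transplant recipients
    if profile.ckd_stage is CkdStage.RRT:
        if profile.rrt_modality is RrtModality.TRANSPLANT:
            _emit_code("Z94.0", index - datetime.timedelta(days=400))
        else:
            code = ("Z49.1" if profile.rrt_modality is RrtModality.HAEMODIALYSIS
                    else "Z49.2")
            for days_back in (10, 30, 50, 70):
                _emit_code(code, index - datetime.timedelta(days=days_back))

    if profile.t2dm:
        medications.append(MedicationRecord(pid, "A10BA02", visits[-1]))
    if profile.hypertension:
        medications.append(MedicationRecord(pid, "C09AA02", visits[-1]))
    for atc in profile.extra_medications:
        medications.append(MedicationRecord(pid, atc, visits[-1]))

    record = PatientRecord(
        demographics=demo,
        labs=tuple(labs),
        observations=tuple(observations),
        codes=tuple(codes),
        medications=tuple(medications),
    )
    truth = GroundTruth(
        patient_id=pid,
        ckd_pooled=profile.ckd_stage is not CkdStage.NONE or profile.ckd_code_only,
        ckd_stage=profile.ckd_stage,
        rrt_modality=profile.rrt_modality,
        t2dm=profile.t2dm,
        hypertension=profile.hypertension,
        cvd=profile.cvd,
    )
    return record, truth


#: Final validation-cohort census: subgroup -> patient count (total 288).
DEFAULT_SUBGROUP_SIZES: Mapping[int, int] = {1: 50, 2: 49, 3: 51, 4: 50, 5: 45, 6: 43}


def _subgroup_profiles(
    group: int, count: int, rng: np.random.Generator, base: dict
) -> list[SyntheticProfile]:
    """Deterministic profile mix per validation subgroup."""
    profiles = []
    for i in range(count):
        kw = dict(base)
        kw.update(
            patient_id=f"SG{group}-{i:03d}",
            seed=int(rng.integers(2 ** 31)),
            sex=Sex.FEMALE if (i % 2 == 0) else Sex.MALE,
            age_years=float(rng.integers(45, 76)),
            followup_years=float(rng.uniform(3.0, 15.0)),
        )
        if group == 1:  # at risk of CKD, no CKD
            kw.update(ckd_stage=CkdStage.NONE,
                      hypertension=(i % 2 == 0), t2dm=(i % 2 == 1))
        elif group == 2:  # CKD stages 1-3a
            kw.update(ckd_stage=(CkdStage.CKD1, CkdStage.CKD2, CkdStage.CKD3A)[i % 3])
        elif group == 3:  # CKD stages 3b-4
            kw.update(ckd_stage=(CkdStage.CKD3B, CkdStage.CKD4)[i % 2])
        elif group == 4:  # CKD stage 5 or RRT
            variant = i % 3
            if variant == 0:
                kw.update(ckd_stage=CkdStage.CKD5)
            else:
                kw.update(ckd_stage=CkdStage.RRT,
                          rrt_modality=(RrtModality.HAEMODIALYSIS,
                                        RrtModality.TRANSPLANT)[variant - 1],
                          egfr_index=8.0 if variant == 1 else None)
        elif group == 5:  # >= 2 coded comorbidities, code-only CKD
            pair = ((True, True, False), (True, False, True), (False, True, True))[i % 3]
            kw.update(ckd_stage=CkdStage.NONE, ckd_code_only=True,
                      t2dm=pair[0], hypertension=pair[1], cvd=pair[2])
        elif group == 6:  # >= 3 chronic-disease medications, code-only CKD
            kw.update(ckd_stage=CkdStage.NONE, ckd_code_only=True,
                      hypertension=True,
                      extra_medications=("C10AA01", "C07AB02"))
        else:
            raise ValueError(f"unknown subgroup {group}")
        profiles.append(SyntheticProfile(**kw))
    return profiles


def generate_validation_cohort(
    n_per_subgroup: Optional[Mapping[int, int]] = None,
    seed: int = 0,
    index_date: datetime.date = DEFAULT_INDEX_DATE,
    creatinine_cv: float = 0.0,
    uacr_sigma: float = 0.0,
    coding_sensitivity: float = 1.0,
    coding_specificity: float = 1.0,
    visit_rate: float = 4.0,
    config: Optional[AppConfig] = None,
) -> tuple[dict[str, PatientRecord], dict[str, GroundTruth]]:
    """Synthetic validation cohort whose subgroup census matches the request.

    Defaults reproduce the six-subgroup, 288-patient design with perfect
    laboratories and coding, under which every phenotype definition is
    satisfied exactly by construction.
    """
    sizes = dict(DEFAULT_SUBGROUP_SIZES if n_per_subgroup is None else n_per_subgroup)
    rng = np.random.default_rng(seed)
    cfg = config if config is not None else default_config()
    base = dict(
        index_date=index_date,
        visit_rate=visit_rate,
        creatinine_cv=creatinine_cv,
        uacr_sigma=uacr_sigma,
        coding_sensitivity=coding_sensitivity,
        coding_specificity=coding_specificity,
    )
    cohort: dict[str, PatientRecord] = {}
    truths: dict[str, GroundTruth] = {}
    for group in sorted(sizes):
        for profile in _subgroup_profiles(group, sizes[group], rng, base):
            record, truth = generate_patient(profile, cfg)
            cohort[record.patient_id] = record
            truths[record.patient_id] = replace(truth, subgroup=group)
    return cohort, truths


_ENTITY_FIELDS = ("labs", "observations", "codes", "medications", "procedures")


def degrade(
    record: PatientRecord,
    drop_fraction: Mapping[str, float],
    seed: int = 0,
) -> PatientRecord:
    """Drop an exact fraction of entries per entity type (ground truth is
    unchanged; used to probe completeness and accuracy degradation).

    Sampling is fixed-count without replacement: dropping 50% of 1,000
    labs removes exactly 500.
    """
    rng = np.random.default_rng(seed)
    kept: dict[str, tuple] = {}
    for entity in _ENTITY_FIELDS:
        entries = getattr(record, entity)
        frac = drop_fraction.get(entity, 0.0)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"drop fraction for {entity} must lie in [0, 1]")
        n_drop = int(round(frac * len(entries)))
        if n_drop == 0:
            kept[entity] = entries
            continue
        drop_idx = set(rng.choice(len(entries), size=n_drop, replace=False).tolist())
        kept[entity] = tuple(e for i, e in enumerate(entries) if i not in drop_idx)
    return PatientRecord(demographics=record.demographics, **kept)
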