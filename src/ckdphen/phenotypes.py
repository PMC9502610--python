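"""Chronic-disease electronic phenotype classifiers.

Each classifier maps one :class:`~ckdphen.model.PatientRecord` to a
disease label using only structured data dated on or before the as-of
date, and records the evidence arms that fired (codes, labs, medications,
observations) so downstream reports can explain every positive.

The CKD classifier evaluates three rule arms in priority order:

1. **RRT** — any renal-replacement-therapy diagnosis or procedure code.
   RRT is mutually exclusive with the numeric CKD stages and suppresses
   them.  Modality is sub-phenotyped: transplant codes dominate dialysis;
   a maintenance-dialysis label additionally requires ≥ 3 dialysis-coded
   events in the 90 days before the as-of date, so a patient with a single
   historic dialysis episode is RRT-positive with modality *unspecified*.
2. **Laboratory staging** — chronically reduced eGFR (two readings < 60
   at least 90 days apart, most recent still low) stages CKD 3a–5 from the
   most recent eGFR; otherwise persistent albuminuria (two or more
   elevated uACR) with preserved eGFR stages CKD 1 (eGFR ≥ 90 or absent)
   or CKD 2 (eGFR 60–89).  A single elevated uACR with one eGFR 60–89 is
   *not* CKD (G2 A-unconfirmed is no disease under the persistence rules).
3. **Code-only** — any other CKD-related diagnosis code makes the pooled
   phenotype positive; when the code itself encodes a stage (e.g. an
   N18.3-type code) and no laboratory staging was possible, that stage is
   used, laboratory evidence always winning otherwise.

Definition variants mirror the sensitivity analysis of the validation
study: ``stage3a_plus`` drops the albuminuria-only arm (CKD defined as
eGFR < 60 or RRT); ``stringent_uacr`` requires the two elevated uACR
readings to be more than three months apart, for the stage 1–2 arm only.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .config import AppConfig, default_config
from .model import (
    Analyte,
    CodedEntry,
    CodedLike,
    MedicationRecord,
    PatientRecord,
    ProcedureRecord,
    entry_code,
    entry_system,
    match_code,
    normalise_code,
)
from .renal import (
    AStage,
    EgfrPoint,
    GStage,
    a_stage,
    egfr_series,
    g_stage,
    persistent_albuminuria,
    persistent_low_egfr,
    uacr_series,
)


class CkdStage(str, enum.Enum):
    NONE = "none"
    CKD1 = "CKD1"
    CKD2 = "CKD2"
    CKD3A = "CKD3a"
    CKD3B = "CKD3b"
    CKD4 = "CKD4"
    CKD5 = "CKD5"
    RRT = "RRT"


#: The fixed 8-level category set used for stage confusion matrices.
STAGE_LEVELS: tuple[CkdStage, ...] = (
    CkdStage.NONE, CkdStage.CKD1, CkdStage.CKD2, CkdStage.CKD3A,
    CkdStage.CKD3B, CkdStage.CKD4, CkdStage.CKD5, CkdStage.RRT,
)

#: Ordinal scale for coded-stage averaging: stage 3a and 3b share the
#: printed "stage 3" slot.
STAGE_ORDINAL = {
    CkdStage.CKD1: 1, CkdStage.CKD2: 2, CkdStage.CKD3A: 3,
    CkdStage.CKD3B: 3, CkdStage.CKD4: 4, CkdStage.CKD5: 5,
}
ORDINAL_STAGE = {1: CkdStage.CKD1, 2: CkdStage.CKD2, 3: CkdStage.CKD3A,
                 4: CkdStage.CKD4, 5: CkdStage.CKD5}


class RrtModality(str, enum.Enum):
    HAEMODIALYSIS = "haemodialysis"
    PERITONEAL_DIALYSIS = "peritoneal_dialysis"
    TRANSPLANT = "transplant"
    UNSPECIFIED = "unspecified"
    NONE = "none"


class CkdDefinition(str, enum.Enum):
    STAGE1_PLUS = "stage1_plus"
    STAGE3A_PLUS = "stage3a_plus"
    STRINGENT_UACR = "stringent_uacr"


class Disease(str, enum.Enum):
    T2DM = "t2dm"
    HYPERTENSION = "hypertension"
    CVD = "cvd"


class Evidence(str, enum.Enum):
    EGFR_CRITERIA = "egfr_criteria"
    UACR_CRITERIA = "uacr_criteria"
    RRT_CODES = "rrt_codes"
    CKD_RELATED_CODES = "ckd_related_codes"
    CODE_IMPLIED_STAGE = "code_implied_stage"
    CODES = "codes"
    LABS = "labs"
    MEDICATIONS = "medications"
    OBSERVATIONS = "observations"


@dataclass(frozen=True)
class AlgorithmConfig:
    """Everything a classification run depends on: variant, date, thresholds."""

    as_of: datetime.date
    ckd_definition: CkdDefinition = CkdDefinition.STAGE1_PLUS
    app: AppConfig = field(default_factory=default_config)

    def with_definition(self, definition: CkdDefinition) -> "AlgorithmConfig":
        return replace(self, ckd_definition=definition)


@dataclass(frozen=True)
class RrtResult:
    rrt: bool
    modality: RrtModality


@dataclass(frozen=True)
class CKDStageResult:
    pooled_positive: bool
    stage: CkdStage
    g_stage: Optional[GStage] = None
    a_stage: Optional[AStage] = None
    rrt_modality: RrtModality = RrtModality.NONE
    basis: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.stage is not CkdStage.NONE and not self.pooled_positive:
            raise ValueError("a staged result must be pooled-positive")


@dataclass(frozen=True)
class PhenotypeResult:
    disease: Disease
    positive: bool
    basis: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.positive and not self.basis:
            raise ValueError("a positive result must carry evidence")


def _dated(entries: Iterable, as_of: datetime.date):
    return [e for e in entries if e.date <= as_of]


def _code_entries(record: PatientRecord, as_of: datetime.date) -> list[CodedLike]:
    return _dated(record.codes, as_of) + _dated(record.procedures, as_of)


def classify_rrt(record: PatientRecord, config: AlgorithmConfig) -> RrtResult:
    """Renal replacement therapy and modality from diagnosis/procedure codes."""
    cs = config.app.codesets
    thr = config.app.thresholds
    entries = _code_entries(record, config.as_of)
    if any(match_code(e, cs, "rrt_transplant") for e in entries):
        return RrtResult(True, RrtModality.TRANSPLANT)
    hd = [e for e in entries if match_code(e, cs, "rrt_haemodialysis")]
    pd_ = [e for e in entries if match_code(e, cs, "rrt_peritoneal_dialysis")]
    if not hd and not pd_:
        return RrtResult(False, RrtModality.NONE)
    window_start = config.as_of - datetime.timedelta(
        days=thr.dialysis_maintenance_window_days)
    recent_hd = [e for e in hd if e.date >= window_start]
    recent_pd = [e for e in pd_ if e.date >= window_start]
    need = thr.dialysis_maintenance_count
    if len(recent_hd) >= need and len(recent_hd) >= len(recent_pd):
        return RrtResult(True, RrtModality.HAEMODIALYSIS)
    if len(recent_pd) >= need:
        return RrtResult(True, RrtModality.PERITONEAL_DIALYSIS)
    if len(recent_hd) + len(recent_pd) >= need:
        return RrtResult(True, RrtModality.UNSPECIFIED)
    # dialysis history without recent maintenance pattern (episodic dialysis)
    return RrtResult(True, RrtModality.UNSPECIFIED)


def _code_implied_stage(record: PatientRecord, config: AlgorithmConfig) -> Optional[CkdStage]:
    """Most severe stage encoded by the patient's diagnosis codes, if any."""
    stage_codes = config.app.stage_codes
    best: Optional[CkdStage] = None
    for entry in _dated(record.codes, config.as_of):
        mapping = stage_codes.get(entry.system.value, {})
        stage_name = mapping.get(normalise_code(entry.code))
        if stage_name is None:
            continue
        stage = CkdStage(stage_name)
        if best is None or STAGE_LEVELS.index(stage) > STAGE_LEVELS.index(best):
            best = stage
    return best


_G_TO_CKD = {GStage.G3A: CkdStage.CKD3A, GStage.G3B: CkdStage.CKD3B,
             GStage.G4: CkdStage.CKD4, GStage.G5: CkdStage.CKD5}


def classify_ckd(record: PatientRecord, config: AlgorithmConfig) -> CKDStageResult:
    """Pooled CKD status and stage under the configured definition variant."""
    thr = config.app.thresholds
    as_of = config.as_of

    series = egfr_series(record, config.app.ckd_epi, as_of=as_of)
    latest_egfr: Optional[EgfrPoint] = series[-1] if series else None
    uacr = uacr_series(record, as_of=as_of)
    latest_a = a_stage(uacr[-1][1], thr) if uacr else None
    latest_g = g_stage(latest_egfr.egfr, thr) if latest_egfr else None

    # 1. RRT dominates all numeric stages
    rrt = classify_rrt(record, config)
    if rrt.rrt:
        return CKDStageResult(
            pooled_positive=True, stage=CkdStage.RRT,
            g_stage=latest_g, a_stage=latest_a,
            rrt_modality=rrt.modality, basis=frozenset({Evidence.RRT_CODES}),
        )

    # 2a. chronically reduced eGFR -> stage 3a-5 from the most recent value
    chron = persistent_low_egfr(
        series,
        threshold=thr.egfr_chronic_threshold,
        min_span_days=thr.chronicity_min_span_days,
        as_of=as_of,
        require_latest_low=thr.require_latest_low_egfr,
    )
    if chron.satisfied and latest_g in _G_TO_CKD:
        return CKDStageResult(
            pooled_positive=True, stage=_G_TO_CKD[latest_g],
            g_stage=latest_g, a_stage=latest_a,
            basis=frozenset({Evidence.EGFR_CRITERIA}),
        )

    # 2b. persistent albuminuria with preserved eGFR -> stage 1 or 2
    if config.ckd_definition is not CkdDefinition.STAGE3A_PLUS:
        span = (thr.uacr_stringent_span_days
                if config.ckd_definition is CkdDefinition.STRINGENT_UACR
                else thr.uacr_min_span_days)
        alb = persistent_albuminuria(
            uacr,
            elevated_threshold=thr.uacr_elevated,
            min_count=thr.uacr_min_count,
            min_span_days=span,
            as_of=as_of,
        )
        if alb.satisfied:
            if latest_egfr is None or latest_egfr.egfr >= thr.g_stage_boundaries[0]:
                return CKDStageResult(
                    pooled_positive=True, stage=CkdStage.CKD1,
                    g_stage=latest_g, a_stage=latest_a,
                    basis=frozenset({Evidence.UACR_CRITERIA}),
                )
            if latest_egfr.egfr >= thr.egfr_chronic_threshold:
                return CKDStageResult(
                    pooled_positive=True, stage=CkdStage.CKD2,
                    g_stage=latest_g, a_stage=latest_a,
                    basis=frozenset({Evidence.UACR_CRITERIA}),
                )

    # 3. code-only CKD: pooled positive, staged only if the code implies it
    if any(match_code(e, config.app.codesets, "ckd_related")
           for e in _dated(record.codes, as_of)):
        implied = _code_implied_stage(record, config)
        basis = {Evidence.CKD_RELATED_CODES}
        stage = CkdStage.NONE
        if implied is not None:
            stage = implied
            basis.add(Evidence.CODE_IMPLIED_STAGE)
        return CKDStageResult(
            pooled_positive=True, stage=stage,
            g_stage=latest_g, a_stage=latest_a, basis=frozenset(basis),
        )

    return CKDStageResult(pooled_positive=False, stage=CkdStage.NONE,
                          g_stage=latest_g, a_stage=latest_a)


def classify_t2dm(record: PatientRecord, config: AlgorithmConfig) -> PhenotypeResult:
    """Type 2 diabetes: ≥ 2 elevated HbA1c, OR glucose-lowering medication,
    OR a diabetes diagnosis code.  A single historic elevated HbA1c among
    normal readings, with no other evidence, is *not* diabetes."""
    thr = config.app.thresholds
    cs = config.app.codesets
    basis = set()
    hba1c = [lab for lab in _dated(record.labs, config.as_of)
             if lab.analyte is Analyte.HBA1C]
    if sum(1 for lab in hba1c if lab.value >= thr.hba1c_elevated) >= thr.hba1c_min_count:
        basis.add(Evidence.LABS)
    if any(match_code(m, cs, "glucose_lowering_med")
           for m in _dated(record.medications, config.as_of)):
        basis.add(Evidence.MEDICATIONS)
    if any(match_code(c, cs, "t2dm") for c in _dated(record.codes, config.as_of)):
        basis.add(Evidence.CODES)
    return PhenotypeResult(Disease.T2DM, bool(basis), frozenset(basis))


def classify_hypertension(record: PatientRecord, config: AlgorithmConfig) -> PhenotypeResult:
    """Hypertension: diagnosis code, OR antihypertensive medication, OR ≥ 2
    clinic BP readings on distinct dates at or above 140/90."""
    thr = config.app.thresholds
    cs = config.app.codesets
    basis = set()
    if any(match_code(c, cs, "hypertension") for c in _dated(record.codes, config.as_of)):
        basis.add(Evidence.CODES)
    if any(match_code(m, cs, "antihypertensive_med")
           for m in _dated(record.medications, config.as_of)):
        basis.add(Evidence.MEDICATIONS)
    elevated_dates = set()
    for obs in _dated(record.observations, config.as_of):
        if obs.kind.value == "systolic_bp" and obs.value >= thr.bp_systolic_elevated:
            elevated_dates.add(obs.date)
        elif obs.kind.value == "diastolic_bp" and obs.value >= thr.bp_diastolic_elevated:
            elevated_dates.add(obs.date)
    if len(elevated_dates) >= thr.bp_min_count:
        basis.add(Evidence.OBSERVATIONS)
    return PhenotypeResult(Disease.HYPERTENSION, bool(basis), frozenset(basis))


def classify_cvd(record: PatientRecord, config: AlgorithmConfig) -> PhenotypeResult:
    """Cardiovascular disease: ICD/ICPC diagnosis codes only (no medication
    or laboratory arm)."""
    cs = config.app.codesets
    positive = any(match_code(c, cs, "cvd") for c in _dated(record.codes, config.as_of))
    basis = frozenset({Evidence.CODES}) if positive else frozenset()
    return PhenotypeResult(Disease.CVD, positive, basis)


def at_risk_ckd(
    record: PatientRecord,
    config: AlgorithmConfig,
    external_cvd_risk: Optional[float] = None,
) -> bool:
    """At risk of CKD: pre-existing diabetes or hypertension, any history of
    renal disease or acute kidney injury, or an externally supplied
    five-year cardiovascular risk score strictly above 15%."""
    if classify_t2dm(record, config).positive:
        return True
    if classify_hypertension(record, config).positive:
        return True
    cs = config.app.codesets
    for entry in _dated(record.codes, config.as_of):
        if match_code(entry, cs, "ckd_related") or match_code(entry, cs, "aki"):
            return True
    if external_cvd_risk is not None and external_cvd_risk > config.app.thresholds.cvd_risk_threshold:
        return True
    return False


@dataclass(frozen=True)
class PatientLabels:
    """All classifier outputs for one patient under one configuration."""

    patient_id: str
    ckd: CKDStageResult
    t2dm: PhenotypeResult
    hypertension: PhenotypeResult
    cvd: PhenotypeResult
    at_risk: bool


def classify_patient(
    record: PatientRecord,
    config: AlgorithmConfig,
    external_cvd_risk: Optional[float] = None,
) -> PatientLabels:
    return PatientLabels(
        patient_id=record.patient_id,
        ckd=classify_ckd(record, config),
        t2dm=classify_t2dm(record, config),
        hypertension=classify_hypertension(record, config),
        cvd=classify_cvd(record, config),
        at_risk=at_risk_ckd(record, config, external_cvd_risk),
    )
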