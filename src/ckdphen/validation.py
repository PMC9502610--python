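"""Diagnostic-accuracy validation machinery.

Covers the statistics a phenotype validation study needs: 2×2 confusion
counts against a gold standard, sensitivity/specificity/PPV/NPV with
asymptotic (Wald) 95% confidence intervals, Cohen's kappa for inter-rater
agreement, the Buderer sample-size formula for diagnostic accuracy
studies, the 8-level CKD stage confusion matrix, stratified validation
cohort construction (six subgroups with priority ordering), and the
administrative-code comparator that stages CKD from ICD/ICPC codes alone,
averaging the two systems' implied stages when they disagree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CodedEntry, PatientRecord, match_code, normalise_code
from .phenotypes import (
    ORDINAL_STAGE,
    STAGE_LEVELS,
    STAGE_ORDINAL,
    AlgorithmConfig,
    CkdStage,
    Disease,
    PatientLabels,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn < 1:
            raise ValueError("confusion table must contain at least one patient")


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its Wald confidence interval; ``defined`` is False
    when the denominator was zero (the value is then meaningless)."""

    value: float
    ci_low: float
    ci_high: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class AccuracyReport:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    auc: Optional[float]
    counts: ConfusionCounts


def confusion(gold: Mapping[str, bool], predicted: Mapping[str, bool]) -> ConfusionCounts:
    """Standard 2×2 counts; the two label maps must cover the same patients."""
    gkeys, pkeys = set(gold), set(predicted)
    if gkeys != pkeys:
        diff = sorted(gkeys.symmetric_difference(pkeys))
        raise ValueError(f"gold and predicted patient sets differ: {diff}")
    tp = fp = fn = tn = 0
    for pid in gold:
        g, p = bool(gold[pid]), bool(predicted[pid])
        if g and p:
            tp += 1
        elif g and not p:
            fn += 1
        elif not g and p:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _wald(numerator: int, denominator: int, z: float) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(value=float("nan"), ci_low=float("nan"),
                              ci_high=float("nan"), n=0, defined=False)
    p = numerator / denominator
    half = z * math.sqrt(p * (1.0 - p) / denominator)
    return MetricEstimate(
        value=p,
        ci_low=max(0.0, p - half),
        ci_high=min(1.0, p + half),
        n=denominator,
    )


def accuracy_report(c: ConfusionCounts, alpha: float = 0.05) -> AccuracyReport:
    """Sensitivity, specificity, PPV, NPV with asymptotic (Wald) CIs.

    The Wald interval p ± z·√(p(1−p)/n) is clipped to [0, 1] and is
    zero-width at p ∈ {0, 1}.  ``auc`` is the balanced accuracy
    (Se + Sp)/2, defined only when both Se and Sp are.
    """
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    se = _wald(c.tp, c.tp + c.fn, z)
    sp = _wald(c.tn, c.tn + c.fp, z)
    ppv = _wald(c.tp, c.tp + c.fp, z)
    npv = _wald(c.tn, c.tn + c.fn, z)
    auc = (se.value + sp.value) / 2.0 if se.defined and sp.defined else None
    return AccuracyReport(sensitivity=se, specificity=sp, ppv=ppv, npv=npv,
                          auc=auc, counts=c)


@dataclass(frozen=True)
class SampleSizeSpec:
    sensitivity: float
    specificity: float
    prevalence: float
    alpha: float = 0.05
    margin: float = 0.05
    z: Optional[float] = 1.96  # None -> exact normal quantile for 1 - alpha/2

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass(frozen=True)
class SampleSizeResult:
    n_sensitivity: int
    n_specificity: int
    n_required: int


def buderer_sample_size(spec: SampleSizeSpec) -> SampleSizeResult:
    """Buderer sample size for a diagnostic accuracy study.

    The number of diseased patients needed to estimate sensitivity to
    within ± *margin* is z²·Se(1−Se)/d²; dividing by prevalence (and the
    analogue by 1 − prevalence for specificity) gives the total cohort
    size each metric demands.  The ceiling is applied *after* the
    prevalence division, and the study size is the larger of the two.
    """
    z = spec.z if spec.z is not None else float(stats.norm.ppf(1.0 - spec.alpha / 2.0))
    d2 = spec.margin ** 2
    n_se = math.ceil(z * z * spec.sensitivity * (1.0 - spec.sensitivity) / d2
                     / spec.prevalence)
    n_sp = math.ceil(z * z * spec.specificity * (1.0 - spec.specificity) / d2
                     / (1.0 - spec.prevalence))
    return SampleSizeResult(n_sensitivity=n_se, n_specificity=n_sp,
                            n_required=max(n_se, n_sp))


def cohens_kappa(table: Sequence[Sequence[float]]) -> tuple[float, Optional[float]]:
    """Raw agreement and Cohen's kappa from a square cross-tabulation.

    Returns ``(raw_agreement, kappa)``; kappa is ``None`` when expected
    agreement is 1 (degenerate marginals).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError(f"agreement table must be square, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("agreement table counts must be non-negative")
    total = t.sum()
    if total == 0:
        raise ValueError("agreement table is empty")
    po = float(np.trace(t) / total)
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum() / total ** 2)
    if pe >= 1.0:
        return po, None
    return po, (po - pe) / (1.0 - pe)


def stage_confusion_matrix(
    gold_stages: Mapping[str, CkdStage],
    predicted_stages: Mapping[str, CkdStage],
) -> pd.DataFrame:
    """Square count matrix over the fixed 8-level stage set.

    Rows are the gold (chart-review) stages, columns the algorithm stages.
    """
    if set(gold_stages) != set(predicted_stages):
        diff = sorted(set(gold_stages).symmetric_difference(predicted_stages))
        raise ValueError(f"gold and predicted patient sets differ: {diff}")
    levels = [s.value for s in STAGE_LEVELS]
    mat = pd.DataFrame(0, index=levels, columns=levels, dtype=int)
    for pid, g in gold_stages.items():
        p = predicted_stages[pid]
        if not isinstance(g, CkdStage) or not isinstance(p, CkdStage):
            raise ValueError(f"unknown stage category for patient {pid!r}")
        mat.loc[g.value, p.value] += 1
    return mat


def one_vs_rest(matrix: pd.DataFrame, stage: CkdStage) -> ConfusionCounts:
    """Collapse the stage matrix to 2×2 counts for a single stage."""
    s = stage.value
    tp = int(matrix.loc[s, s])
    fn = int(matrix.loc[s].sum()) - tp
    fp = int(matrix[s].sum()) - tp
    tn = int(matrix.values.sum()) - tp - fn - fp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


_MILD = {CkdStage.CKD1, CkdStage.CKD2, CkdStage.CKD3A}
_MODERATE = {CkdStage.CKD3B, CkdStage.CKD4}
_SEVERE = {CkdStage.CKD5, CkdStage.RRT}


def coded_comorbidity_count(record: PatientRecord, config: AlgorithmConfig) -> int:
    """Number of the three comorbidities (diabetes, hypertension, CVD) with
    at least one ICD/ICPC diagnosis code in the record."""
    cs = config.app.codesets
    count = 0
    for concept in ("t2dm", "hypertension", "cvd"):
        if any(match_code(c, cs, concept)
               for c in record.codes if c.date <= config.as_of):
            count += 1
    return count


def chronic_medication_count(record: PatientRecord, config: AlgorithmConfig) -> int:
    """Distinct chronic-disease medications (by ATC code) in the record."""
    cs = config.app.codesets
    atc = {
        normalise_code(m.atc_code)
        for m in record.medications
        if m.date <= config.as_of and match_code(m, cs, "chronic_disease_med")
    }
    return len(atc)


def subgroup_assign(
    record: PatientRecord,
    labels: PatientLabels,
    config: AlgorithmConfig,
) -> int | str:
    """Validation-cohort subgroup (1–6) or ``"ineligible"``.

    Eligibility requires ≥ 3 laboratory-plus-observation entries.  The
    first matching subgroup wins: (1) at risk of CKD with no CKD; (2) CKD
    stages 1–3a; (3) stages 3b–4; (4) stage 5 or RRT; (5) ≥ 2 coded
    comorbidities; (6) ≥ 3 chronic-disease medications.
    """
    labs_obs = len([e for e in record.labs if e.date <= config.as_of]) + \
        len([e for e in record.observations if e.date <= config.as_of])
    if labs_obs < 3:
        return "ineligible"
    stage = labels.ckd.stage
    if labels.at_risk and not labels.ckd.pooled_positive:
        return 1
    if stage in _MILD:
        return 2
    if stage in _MODERATE:
        return 3
    if stage in _SEVERE:
        return 4
    if coded_comorbidity_count(record, config) >= 2:
        return 5
    if chronic_medication_count(record, config) >= 3:
        return 6
    return "ineligible"


def stratified_sample(
    subgroups: Mapping[int, Sequence[str]],
    n_per_group: int = 60,
    seed: int = 0,
) -> dict[int, list[str]]:
    """Uniform without-replacement sample of *n_per_group* patients per
    subgroup, reproducible under *seed*.  A subgroup smaller than the
    request is returned whole with a warning."""
    rng = np.random.default_rng(seed)
    out: dict[int, list[str]] = {}
    for group in sorted(subgroups):
        members = sorted(subgroups[group])
        if len(members) <= n_per_group:
            if len(members) < n_per_group:
                warnings.warn(
                    f"subgroup {group} has only {len(members)} members "
                    f"(requested {n_per_group}); returning all", stacklevel=2)
            out[group] = list(members)
        else:
            chosen = rng.choice(len(members), size=n_per_group, replace=False)
            out[group] = [members[i] for i in sorted(chosen)]
    return out


def coded_stage_classifier(record: PatientRecord, config: AlgorithmConfig) -> CkdStage:
    """Administrative-code comparator: CKD stage from ICD/ICPC codes only.

    Each system contributes its most severe implied stage; when the two
    systems disagree, the stage index is the ceiling of their mean on the
    ordinal 1–5 scale (stages 3a/3b share the printed "stage 3" slot,
    mapped back to 3a).  RRT codes dominate.
    """
    cs = config.app.codesets
    entries = [e for e in record.codes if e.date <= config.as_of]
    procs = [p for p in record.procedures if p.date <= config.as_of]
    for concept in ("rrt_transplant", "rrt_haemodialysis", "rrt_peritoneal_dialysis"):
        if any(match_code(e, cs, concept) for e in entries + procs):
            return CkdStage.RRT
    per_system: dict[str, int] = {}
    for entry in entries:
        mapping = config.app.stage_codes.get(entry.system.value, {})
        stage_name = mapping.get(normalise_code(entry.code))
        if stage_name is None:
            continue
        ordinal = STAGE_ORDINAL[CkdStage(stage_name)]
        key = entry.system.value
        per_system[key] = max(per_system.get(key, 0), ordinal)
    if not per_system:
        return CkdStage.NONE
    ordinals = list(per_system.values())
    combined = math.ceil(sum(ordinals) / len(ordinals))
    return ORDINAL_STAGE[combined]


def phenotype_accuracy(
    gold: Mapping[str, Mapping[str, bool]],
    predicted: Mapping[str, Mapping[str, bool]],
    diseases: Sequence[str] = ("ckd_pooled", "t2dm", "hypertension", "cvd", "rrt"),
    alpha: float = 0.05,
) -> dict[str, AccuracyReport]:
    """Per-disease accuracy reports from nested {patient: {disease: bool}} maps."""
    out = {}
    for disease in diseases:
        g = {pid: labels[disease] for pid, labels in gold.items()}
        p = {pid: labels[disease] for pid, labels in predicted.items()}
        out[disease] = accuracy_report(confusion(g, p), alpha=alpha)
    return out
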