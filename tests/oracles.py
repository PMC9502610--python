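"""Independent brute-force oracles used to cross-check the classifiers.

These restate the clinical rules as direct enumerations — all point
pairs for chronicity, an explicit if-chain for staging, the full rule
disjunction for the CKD phenotype — deliberately sharing none of the
implementation's series handling, staging maps or priority plumbing.
"""

from __future__ import annotations

import datetime
import math

import numpy as np

from ckdphen.model import (
    Analyte,
    CANONICAL_UNITS,
    Censor,
    CodeSystem,
    CodedEntry,
    LabResult,
    PatientDemographics,
    PatientRecord,
    Sex,
)
from ckdphen.phenotypes import CkdStage


def oracle_ckd_epi(sex: Sex, age: float, scr_umol: float) -> float:
    """Closed-form 2009 CKD-EPI evaluation, written out long-hand."""
    scr = scr_umol / 88.4
    if sex is Sex.FEMALE:
        kappa, alpha = 0.7, -0.329
    else:
        kappa, alpha = 0.9, -0.411
    ratio = scr / kappa
    value = 141.0
    value *= ratio ** alpha if ratio < 1 else 1.0
    value *= ratio ** -1.209 if ratio > 1 else 1.0
    value *= 0.993 ** age
    if sex is Sex.FEMALE:
        value *= 1.018
    return value


def oracle_persistent_low(points, threshold=60.0, min_span=90, as_of=None):
    """Pair enumeration: points are (date, egfr, censored_above) triples."""
    pts = sorted(p for p in points if as_of is None or p[0] <= as_of)
    if not pts:
        return False
    last_date, last_val, last_cens = pts[-1]
    if last_cens or last_val >= threshold:
        return False
    lows = [(d, v) for d, v, c in pts if not c and v < threshold]
    for i in range(len(lows)):
        for j in range(len(lows)):
            if i != j and abs((lows[j][0] - lows[i][0]).days) >= min_span:
                return True
    return False


def _egfr_points(record: PatientRecord, as_of: datetime.date):
    """Re-derive the harmonised eGFR point list by explicit date bookkeeping."""
    birth = record.demographics.birth_date
    by_date: dict[datetime.date, tuple[float, bool, bool]] = {}  # (egfr, censored, computed)
    for lab in record.labs:
        if lab.collected_date > as_of:
            continue
        if lab.analyte is Analyte.SERUM_CREATININE:
            age = (lab.collected_date - birth).days / 365.25
            if age < 18 or lab.value <= 0:
                continue
            egfr = round(oracle_ckd_epi(record.demographics.sex, age, lab.value), 1)
            by_date[lab.collected_date] = (egfr, False, True)
        elif lab.analyte is Analyte.EGFR_REPORTED:
            censored = lab.censor is Censor.ABOVE_LIMIT
            val = min(lab.value, 90.0) if censored else lab.value
            if val <= 0:
                continue
            prior = by_date.get(lab.collected_date)
            if prior is None or not prior[2]:  # computed values win the date
                by_date[lab.collected_date] = (val, censored, False)
    return [(d,) + by_date[d][:2] for d in sorted(by_date)]


def oracle_classify_ckd(record: PatientRecord, as_of: datetime.date,
                        variant: str = "stage1_plus") -> tuple[bool, CkdStage]:
    """Full rule disjunction for the CKD phenotype, enumerated directly.

    Returns (pooled_positive, stage) under the default code sets.
    """
    codes = [(c.system.value, c.code.upper().replace(".", ""), c.date)
             for c in record.codes if c.date <= as_of]
    procs = [(p.system.value, p.code.upper().replace(".", ""), p.date)
             for p in record.procedures if p.date <= as_of]

    def any_code(prefixes, systems=("ICD10AM", "ICPC2")):
        return any(s in systems and code.startswith(p)
                   for s, code, _ in codes + procs for p in prefixes)

    # arm 2 of the rule table: RRT codes
    if any_code(("Z940", "T861", "36503"),
                systems=("ICD10AM", "ICD10AM_procedure", "MBS")) or \
       any_code(("Z491", "Z492", "Z992", "13100", "13104"),
                systems=("ICD10AM", "ICD10AM_procedure", "MBS")):
        return True, CkdStage.RRT

    pts = _egfr_points(record, as_of)
    # arm 1a: chronically reduced eGFR
    if oracle_persistent_low(pts, 60.0, 90, as_of):
        latest = pts[-1][1]
        if latest < 15:
            return True, CkdStage.CKD5
        if latest < 30:
            return True, CkdStage.CKD4
        if latest < 45:
            return True, CkdStage.CKD3B
        if latest < 60:
            return True, CkdStage.CKD3A

    # arm 1b: persistent albuminuria with preserved eGFR
    if variant != "stage3a_plus":
        uacr = sorted((lab.collected_date, lab.value) for lab in record.labs
                      if lab.analyte is Analyte.UACR and lab.collected_date <= as_of)
        elevated = [(d, v) for d, v in uacr if v >= 3.0]
        persistent = len(elevated) >= 2
        if persistent and variant == "stringent_uacr":
            persistent = any(
                abs((e2[0] - e1[0]).days) >= 90
                for e1 in elevated for e2 in elevated)
        if persistent:
            latest = pts[-1][1] if pts else None
            if latest is None or latest >= 90:
                return True, CkdStage.CKD1
            if latest >= 60:
                return True, CkdStage.CKD2

    # arm 3: other CKD-related administrative codes
    ckd_prefixes = ("N18", "N19", "N03", "N04", "N05", "N08", "N11", "N14",
                    "N16", "Q61", "U99")
    implied = {"N181": CkdStage.CKD1, "N182": CkdStage.CKD2,
               "N183": CkdStage.CKD3A, "N184": CkdStage.CKD4,
               "N185": CkdStage.CKD5}
    matching = [code for s, code, _ in codes
                if any(code.startswith(p) for p in ckd_prefixes)]
    if matching:
        order = [CkdStage.CKD1, CkdStage.CKD2, CkdStage.CKD3A,
                 CkdStage.CKD4, CkdStage.CKD5]
        stages = [implied[c[:4]] for c in matching if c[:4] in implied]
        stage = max(stages, key=order.index) if stages else CkdStage.NONE
        return True, stage
    return False, CkdStage.NONE


_CODE_POOL = [
    (CodeSystem.ICD10AM, "N18.3"), (CodeSystem.ICD10AM, "N18.9"),
    (CodeSystem.ICD10AM, "N18.5"), (CodeSystem.ICD10AM, "N17.1"),
    (CodeSystem.ICD10AM, "Z49.1"), (CodeSystem.ICD10AM, "Z94.0"),
    (CodeSystem.ICD10AM, "E11.9"), (CodeSystem.ICD10AM, "I10"),
    (CodeSystem.ICD10AM, "I25.1"), (CodeSystem.ICD10AM, "A09"),
    (CodeSystem.ICPC2, "U99"), (CodeSystem.ICPC2, "T90"),
    (CodeSystem.ICPC2, "K86"), (CodeSystem.ICPC2, "A97"),
]


def random_small_record(rng: np.random.Generator, pid: str,
                        as_of: datetime.date) -> PatientRecord:
    """Random record with <= 6 labs and <= 4 codes spanning ~3 years."""
    sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
    birth = as_of - datetime.timedelta(days=int(rng.integers(20, 95) * 365.25))
    labs = []
    for _ in range(int(rng.integers(0, 7))):
        date = as_of - datetime.timedelta(days=int(rng.integers(0, 1100)))
        kind = rng.random()
        if kind < 0.5:
            labs.append(LabResult(pid, Analyte.SERUM_CREATININE,
                                  float(rng.uniform(40, 900)),
                                  CANONICAL_UNITS[Analyte.SERUM_CREATININE], date))
        elif kind < 0.75:
            censored = rng.random() < 0.2
            value = 90.0 if censored else float(rng.uniform(4, 120))
            labs.append(LabResult(pid, Analyte.EGFR_REPORTED, value,
                                  CANONICAL_UNITS[Analyte.EGFR_REPORTED], date,
                                  Censor.ABOVE_LIMIT if censored else Censor.NONE))
        else:
            labs.append(LabResult(pid, Analyte.UACR, float(rng.uniform(0, 40)),
                                  CANONICAL_UNITS[Analyte.UACR], date))
    codes = []
    for _ in range(int(rng.integers(0, 5))):
        system, code = _CODE_POOL[int(rng.integers(len(_CODE_POOL)))]
        date = as_of - datetime.timedelta(days=int(rng.integers(0, 1100)))
        codes.append(CodedEntry(pid, system, code, date))
    return PatientRecord(
        demographics=PatientDemographics(pid, sex, birth),
        labs=tuple(labs), codes=tuple(codes),
    )
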