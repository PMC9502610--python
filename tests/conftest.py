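import datetime

import pytest

from ckdphen.config import default_config
from ckdphen.model import (
    Analyte,
    CANONICAL_UNITS,
    CareSetting,
    Censor,
    CodeSystem,
    CodedEntry,
    LabResult,
    MedicationRecord,
    Observation,
    ObservationKind,
    PatientDemographics,
    PatientRecord,
    ProcedureRecord,
    ProcedureSystem,
    Sex,
)
from ckdphen.phenotypes import AlgorithmConfig
from ckdphen.simulate import DEFAULT_INDEX_DATE, generate_validation_cohort

AS_OF = DEFAULT_INDEX_DATE  # 2021-02-07
BIRTH = datetime.date(1966, 3, 15)


def day(offset: int) -> datetime.date:
    """Calendar date *offset* days before the as-of date (0 = as-of)."""
    return AS_OF - datetime.timedelta(days=offset)


def make_record(
    pid: str = "P1",
    sex: Sex = Sex.FEMALE,
    birth: datetime.date = BIRTH,
    creatinines=(),      # (days_before_as_of, umol/L)
    egfr_reported=(),    # (days_before, value) or (days_before, value, censor)
    uacrs=(),            # (days_before, mg/mmol)
    hba1cs=(),           # (days_before, mmol/mol)
    bps=(),              # (days_before, systolic, diastolic)
    icd_codes=(),        # (days_before, code)
    icpc_codes=(),
    medications=(),      # (days_before, atc)
    procedures=(),       # (days_before, system, code)
) -> PatientRecord:
    labs = []
    for d, v in creatinines:
        labs.append(LabResult(pid, Analyte.SERUM_CREATININE, v,
                              CANONICAL_UNITS[Analyte.SERUM_CREATININE], day(d)))
    for item in egfr_reported:
        d, v = item[0], item[1]
        censor = item[2] if len(item) > 2 else Censor.NONE
        labs.append(LabResult(pid, Analyte.EGFR_REPORTED, v,
                              CANONICAL_UNITS[Analyte.EGFR_REPORTED], day(d), censor))
    for d, v in uacrs:
        labs.append(LabResult(pid, Analyte.UACR, v,
                              CANONICAL_UNITS[Analyte.UACR], day(d)))
    for d, v in hba1cs:
        labs.append(LabResult(pid, Analyte.HBA1C, v,
                              CANONICAL_UNITS[Analyte.HBA1C], day(d)))
    obs = []
    for d, s, dia in bps:
        obs.append(Observation(pid, ObservationKind.SYSTOLIC_BP, s, day(d)))
        obs.append(Observation(pid, ObservationKind.DIASTOLIC_BP, dia, day(d)))
    codes = [CodedEntry(pid, CodeSystem.ICD10AM, c, day(d)) for d, c in icd_codes]
    codes += [CodedEntry(pid, CodeSystem.ICPC2, c, day(d), CareSetting.PRIMARY_CARE)
              for d, c in icpc_codes]
    meds = [MedicationRecord(pid, atc, day(d)) for d, atc in medications]
    procs = [ProcedureRecord(pid, ProcedureSystem(system), c, day(d))
             for d, system, c in procedures]
    return PatientRecord(
        demographics=PatientDemographics(pid, sex, birth),
        labs=tuple(labs), observations=tuple(obs), codes=tuple(codes),
        medications=tuple(meds), procedures=tuple(procs),
    )


@pytest.fixture(scope="session")
def app_config():
    return default_config()


@pytest.fixture(scope="session")
def algo_config(app_config):
    return AlgorithmConfig(as_of=AS_OF, app=app_config)


@pytest.fixture(scope="session")
def perfect_cohort():
    """Noise-free synthetic validation cohort with the default census."""
    return generate_validation_cohort(seed=20210207)
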