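"""Domain types for linked longitudinal EHR data.

One :class:`PatientRecord` holds everything the phenotype algorithms need
for a single patient: demographics plus date-stamped laboratory results,
observations, coded diagnoses (ICD-10-AM hospital codes, ICPC-2 primary
care codes), medications (ATC) and procedures.  All entry lists are kept
sorted non-decreasing by date, with same-day ties broken by stable input
order.

Code-based logic is driven by :class:`CodeSetLibrary`: named clinical
concepts (``"t2dm"``, ``"rrt_transplant"``, ...) mapped to per-system code
*prefixes*.  Matching is by prefix because ICD-10-AM/ICPC-2/ATC hierarchies
are prefix-structured; it is case-insensitive and ignores dots in ICD codes.
"""

from __future__ import annotations

import datetime
import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Analyte(str, enum.Enum):
    SERUM_CREATININE = "serum_creatinine"  # µmol/L
    EGFR_REPORTED = "egfr_reported"        # mL/min/1.73m²
    UACR = "uacr"                          # mg/mmol
    HBA1C = "hba1c"                        # mmol/mol
    OTHER = "other"


#: Canonical unit per analyte; conversion to these happens at ingest.
CANONICAL_UNITS: Mapping[Analyte, str] = {
    Analyte.SERUM_CREATININE: "umol/L",
    Analyte.EGFR_REPORTED: "mL/min/1.73m2",
    Analyte.UACR: "mg/mmol",
    Analyte.HBA1C: "mmol/mol",
    Analyte.OTHER: "",
}


class Censor(str, enum.Enum):
    NONE = "none"
    ABOVE_LIMIT = "above_limit"   # e.g. eGFR reported as ">90"
    BELOW_LIMIT = "below_limit"


class ObservationKind(str, enum.Enum):
    SYSTOLIC_BP = "systolic_bp"
    DIASTOLIC_BP = "diastolic_bp"
    OTHER = "other"


class CodeSystem(str, enum.Enum):
    ICD10AM = "ICD10AM"
    ICPC2 = "ICPC2"


class CareSetting(str, enum.Enum):
    HOSPITAL = "hospital"
    PRIMARY_CARE = "primary_care"


class ProcedureSystem(str, enum.Enum):
    ICD10AM_PROCEDURE = "ICD10AM_procedure"
    MBS = "MBS"


_ICD_RE = re.compile(r"^[A-Z][0-9]+(\.[0-9]+)?$", re.IGNORECASE)
_ICPC_RE = re.compile(r"^[A-Z][0-9]{2}$", re.IGNORECASE)
_ATC_RE = re.compile(r"^[A-Z][0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?$", re.IGNORECASE)


def normalise_code(code: str) -> str:
    """Uppercase and strip dots/whitespace — the comparison form for all codes."""
    return code.upper().replace(".", "").replace(" ", "")


@dataclass(frozen=True)
class PatientDemographics:
    patient_id: str
    sex: Sex
    birth_date: datetime.date

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    analyte: Analyte
    value: float
    units: str
    collected_date: datetime.date
    censor: Censor = Censor.NONE

    @property
    def date(self) -> datetime.date:
        return self.collected_date

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"lab value must be non-negative, got {self.value}")
        canonical = CANONICAL_UNITS[self.analyte]
        if canonical and self.units != canonical:
            raise ValueError(
                f"{self.analyte.value} must be stored in {canonical}, got {self.units!r}"
            )
        if self.censor is Censor.ABOVE_LIMIT and self.analyte is not Analyte.EGFR_REPORTED:
            raise ValueError("above_limit censoring only supported for reported eGFR")


@dataclass(frozen=True)
class Observation:
    patient_id: str
    kind: ObservationKind
    value: float
    date: datetime.date

    def __post_init__(self) -> None:
        if self.kind is ObservationKind.SYSTOLIC_BP and not (0 < self.value < 350):
            raise ValueError(f"systolic BP out of range: {self.value}")
        if self.kind is ObservationKind.DIASTOLIC_BP and not (0 < self.value < 250):
            raise ValueError(f"diastolic BP out of range: {self.value}")


@dataclass(frozen=True)
class CodedEntry:
    patient_id: str
    system: CodeSystem
    code: str
    date: datetime.date
    setting: CareSetting = CareSetting.HOSPITAL

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("code must be non-empty")
        if self.system is CodeSystem.ICD10AM and not _ICD_RE.match(self.code):
            raise ValueError(f"malformed ICD-10-AM code: {self.code!r}")
        if self.system is CodeSystem.ICPC2 and not _ICPC_RE.match(self.code):
            raise ValueError(f"malformed ICPC-2 code: {self.code!r}")


@dataclass(frozen=True)
class MedicationRecord:
    patient_id: str
    atc_code: str
    date: datetime.date

    def __post_init__(self) -> None:
        if not _ATC_RE.match(self.atc_code):
            raise ValueError(f"malformed ATC code: {self.atc_code!r}")


@dataclass(frozen=True)
class ProcedureRecord:
    patient_id: str
    system: ProcedureSystem
    code: str
    date: datetime.date

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("procedure code must be non-empty")


CodedLike = Union[CodedEntry, MedicationRecord, ProcedureRecord]


def _sorted_by_date(entries: Iterable) -> tuple:
    # stable sort: same-day ties keep input order
    return tuple(sorted(entries, key=lambda e: e.date))


@dataclass
class PatientRecord:
    """One patient's linked longitudinal record.

    Invariants enforced on construction: every entry carries the patient's
    id, no clinical entry predates birth, and each list is date-sorted.
    """

    demographics: PatientDemographics
    labs: tuple = field(default_factory=tuple)
    observations: tuple = field(default_factory=tuple)
    codes: tuple = field(default_factory=tuple)
    medications: tuple = field(default_factory=tuple)
    procedures: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        pid = self.demographics.patient_id
        birth = self.demographics.birth_date
        self.labs = _sorted_by_date(self.labs)
        self.observations = _sorted_by_date(self.observations)
        self.codes = _sorted_by_date(self.codes)
        self.medications = _sorted_by_date(self.medications)
        self.procedures = _sorted_by_date(self.procedures)
        for entries in (self.labs, self.observations, self.codes,
                        self.medications, self.procedures):
            for e in entries:
                if e.patient_id != pid:
                    raise ValueError(
                        f"entry patient_id {e.patient_id!r} != record {pid!r}")
                if e.date <= birth:
                    raise ValueError(
                        f"entry dated {e.date} not after birth_date {birth}")

    @property
    def patient_id(self) -> str:
        return self.demographics.patient_id

    def all_entry_dates(self) -> list[datetime.date]:
        dates: list[datetime.date] = []
        for entries in (self.labs, self.observations, self.codes,
                        self.medications, self.procedures):
            dates.extend(e.date for e in entries)
        return dates


# system keys used in code-set configuration
_SYSTEM_KEY = {
    CodedEntry: lambda e: e.system.value,
    MedicationRecord: lambda e: "ATC",
    ProcedureRecord: lambda e: e.system.value,
}


def entry_system(entry: CodedLike) -> str:
    return _SYSTEM_KEY[type(entry)](entry)


def entry_code(entry: CodedLike) -> str:
    return entry.atc_code if isinstance(entry, MedicationRecord) else entry.code


@dataclass(frozen=True)
class CodeSet:
    """One clinical concept's code prefixes, keyed by coding system."""

    concept: str
    prefixes: Mapping[str, tuple[str, ...]]  # system -> normalised prefixes

    def __post_init__(self) -> None:
        if not self.concept:
            raise ValueError("concept name must be non-empty")
        for system, prefs in self.prefixes.items():
            norm = [normalise_code(p) for p in prefs]
            if len(set(norm)) != len(norm):
                raise ValueError(
                    f"duplicate prefixes for {self.concept}/{system}")

    def matches(self, system: str, code: str) -> bool:
        norm = normalise_code(code)
        return any(norm.startswith(normalise_code(p))
                   for p in self.prefixes.get(system, ()))


class CodeSetLibrary:
    """Named concept → :class:`CodeSet` lookup used by all code-based logic."""

    def __init__(self, codesets: Mapping[str, Mapping[str, Iterable[str]]]):
        self._sets: dict[str, CodeSet] = {
            concept: CodeSet(concept, {s: tuple(p) for s, p in systems.items()})
            for concept, systems in codesets.items()
        }

    def __contains__(self, concept: str) -> bool:
        return concept in self._sets

    def __getitem__(self, concept: str) -> CodeSet:
        if concept not in self._sets:
            raise KeyError(f"unknown concept {concept!r}; "
                           f"known: {sorted(self._sets)}")
        return self._sets[concept]

    def concepts(self) -> list[str]:
        return sorted(self._sets)


def match_code(entry: CodedLike, codesets: CodeSetLibrary, concept: str) -> bool:
    """True iff *entry*'s code prefix-matches *concept* within its own system.

    An ICPC-2 entry never matches a concept configured with ICD prefixes
    only: systems are kept separate.
    """
    return codesets[concept].matches(entry_system(entry), entry_code(entry))
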