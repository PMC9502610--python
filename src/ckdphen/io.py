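"""Flat-table ingest and export for linked EHR extracts.

One CSV/TSV file per entity (``demographics``, ``labs``, ``observations``,
``codes``, ``medications``, ``procedures``), ISO-8601 dates, UTF-8.
Ingest is strict about schema (a missing mandatory column is a hard
error naming the column) but tolerant of bad rows: entries with
unparseable dates, negative values, dates before birth, or no matching
demographics are dropped and counted per reason in an
:class:`IngestReport`, so ``loaded + dropped == rows`` for every table.

Non-canonical units are converted at ingest (creatinine mg/dL × 88.4 →
µmol/L; uACR mg/g ÷ 8.84 → mg/mmol; HbA1c % (NGSP) → mmol/mol), after
which all downstream logic is unit-free.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from collections import Counter
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .config import CREATININE_UMOL_PER_MGDL, UACR_MGG_PER_MGMMOL
from .model import (
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

TABLES = ("demographics", "labs", "observations", "codes", "medications", "procedures")

_REQUIRED_COLUMNS = {
    "demographics": ("patient_id", "sex", "birth_date"),
    "labs": ("patient_id", "analyte", "value", "units", "collected_date"),
    "observations": ("patient_id", "kind", "value", "date"),
    "codes": ("patient_id", "system", "code", "date"),
    "medications": ("patient_id", "atc_code", "date"),
    "procedures": ("patient_id", "system", "code", "date"),
}


@dataclasses.dataclass
class IngestReport:
    """Row accounting per table: loaded counts plus dropped counts by reason."""

    loaded: dict = dataclasses.field(default_factory=dict)
    dropped: dict = dataclasses.field(default_factory=dict)
    warnings: dict = dataclasses.field(default_factory=dict)

    def drop(self, table: str, reason: str) -> None:
        self.dropped.setdefault(table, Counter())[reason] += 1

    def warn(self, table: str, reason: str) -> None:
        self.warnings.setdefault(table, Counter())[reason] += 1

    def total_dropped(self, table: str) -> int:
        return sum(self.dropped.get(table, Counter()).values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "loaded": self.loaded,
                "dropped": {t: dict(c) for t, c in self.dropped.items()},
                "warnings": {t: dict(c) for t, c in self.warnings.items()},
            },
            indent=2,
            sort_keys=True,
        )


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, table: str) -> None:
    for col in _REQUIRED_COLUMNS[table]:
        if col not in df.columns:
            raise ValueError(f"table {table!r} is missing mandatory column {col!r}")


def _parse_date(text: str) -> Optional[datetime.date]:
    try:
        return datetime.date.fromisoformat(text.strip())
    except (ValueError, AttributeError):
        return None


_LAB_UNIT_CONVERSIONS = {
    # (analyte, lowercase unit label) -> multiplier to canonical
    (Analyte.SERUM_CREATININE, "mg/dl"): CREATININE_UMOL_PER_MGDL,
    (Analyte.SERUM_CREATININE, "umol/l"): 1.0,
    (Analyte.SERUM_CREATININE, "µmol/l"): 1.0,
    (Analyte.UACR, "mg/g"): 1.0 / UACR_MGG_PER_MGMMOL,
    (Analyte.UACR, "mg/mmol"): 1.0,
    (Analyte.EGFR_REPORTED, "ml/min/1.73m2"): 1.0,
    (Analyte.EGFR_REPORTED, ""): 1.0,
    (Analyte.HBA1C, "mmol/mol"): 1.0,
}


def _convert_lab(analyte: Analyte, value: float, units: str) -> Optional[float]:
    unit = units.strip().lower()
    if analyte is Analyte.HBA1C and unit in {"%", "percent"}:
        # NGSP % -> IFCC mmol/mol
        return 10.93 * value - 23.5
    factor = _LAB_UNIT_CONVERSIONS.get((analyte, unit))
    if factor is None:
        if unit in {"", CANONICAL_UNITS[analyte].lower()}:
            return value
        return None
    return value * factor


def load_cohort(
    input_dir: Union[str, Path, Mapping[str, Union[str, Path]]],
) -> tuple[dict[str, PatientRecord], IngestReport]:
    """Load per-entity tables into PatientRecords keyed by patient id.

    *input_dir* is a directory containing ``demographics.csv`` (or
    ``.tsv``) and optionally the other entity tables, or an explicit
    ``{table: path}`` mapping.  Returns the cohort plus an
    :class:`IngestReport`.
    """
    if isinstance(input_dir, (str, Path)):
        base = Path(input_dir)
        paths: dict[str, Path] = {}
        for table in TABLES:
            for ext in (".csv", ".tsv"):
                p = base / f"{table}{ext}"
                if p.exists():
                    paths[table] = p
                    break
    else:
        paths = {t: Path(p) for t, p in input_dir.items()}
    if "demographics" not in paths:
        raise FileNotFoundError("no demographics table found")

    report = IngestReport()
    demo_df = _read_table(paths["demographics"])
    _require_columns(demo_df, "demographics")
    demographics: dict[str, PatientDemographics] = {}
    for _, row in demo_df.iterrows():
        pid = str(row["patient_id"]).strip()
        birth = _parse_date(row["birth_date"])
        if not pid or birth is None:
            report.drop("demographics", "bad_row")
            continue
        if pid in demographics:
            report.drop("demographics", "duplicate_patient_id")
            continue
        try:
            sex = Sex(row["sex"].strip().lower())
        except ValueError:
            report.drop("demographics", "unknown_sex")
            continue
        demographics[pid] = PatientDemographics(pid, sex, birth)
    report.loaded["demographics"] = len(demographics)

    entries: dict[str, dict[str, list]] = {
        pid: {t: [] for t in TABLES if t != "demographics"} for pid in demographics
    }

    def _common(table: str, row, date_col: str):
        """Shared row checks; returns (pid, date) or None after counting a drop."""
        pid = str(row["patient_id"]).strip()
        if pid not in demographics:
            report.drop(table, "no_demographics")
            return None
        date = _parse_date(row[date_col])
        if date is None:
            report.drop(table, "bad_date")
            return None
        if date <= demographics[pid].birth_date:
            report.drop(table, "before_birth")
            return None
        return pid, date

    if "labs" in paths:
        df = _read_table(paths["labs"])
        _require_columns(df, "labs")
        has_censor = "censor" in df.columns
        for _, row in df.iterrows():
            parsed = _common("labs", row, "collected_date")
            if parsed is None:
                continue
            pid, date = parsed
            label = str(row["analyte"]).strip().lower()
            try:
                analyte = Analyte(label)
            except ValueError:
                analyte = Analyte.OTHER
                report.warn("labs", f"unknown_analyte:{label}")
            raw = str(row["value"]).strip()
            censor = Censor.NONE
            if has_censor and str(row["censor"]).strip():
                try:
                    censor = Censor(str(row["censor"]).strip())
                except ValueError:
                    report.drop("labs", "bad_censor")
                    continue
            if raw.startswith(">"):  # ">90" reported-eGFR dialect
                raw = raw[1:]
                censor = Censor.ABOVE_LIMIT
            try:
                value = float(raw)
            except ValueError:
                report.drop("labs", "bad_value")
                continue
            if value < 0:
                report.drop("labs", "negative_value")
                continue
            if analyte is not Analyte.OTHER:
                converted = _convert_lab(analyte, value, str(row["units"]))
                if converted is None:
                    report.drop("labs", "unknown_units")
                    continue
                value = converted
                units = CANONICAL_UNITS[analyte]
            else:
                units = str(row["units"])
            if censor is Censor.ABOVE_LIMIT and analyte is not Analyte.EGFR_REPORTED:
                report.drop("labs", "bad_censor")
                continue
            entries[pid]["labs"].append(
                LabResult(pid, analyte, value, units, date, censor))
        report.loaded["labs"] = sum(len(e["labs"]) for e in entries.values())

    if "observations" in paths:
        df = _read_table(paths["observations"])
        _require_columns(df, "observations")
        for _, row in df.iterrows():
            parsed = _common("observations", row, "date")
            if parsed is None:
                continue
            pid, date = parsed
            try:
                kind = ObservationKind(str(row["kind"]).strip().lower())
            except ValueError:
                kind = ObservationKind.OTHER
                report.warn("observations", "unknown_kind")
            try:
                obs = Observation(pid, kind, float(row["value"]), date)
            except ValueError:
                report.drop("observations", "bad_value")
                continue
            entries[pid]["observations"].append(obs)
        report.loaded["observations"] = sum(
            len(e["observations"]) for e in entries.values())

    if "codes" in paths:
        df = _read_table(paths["codes"])
        _require_columns(df, "codes")
        has_setting = "setting" in df.columns
        for _, row in df.iterrows():
            parsed = _common("codes", row, "date")
            if parsed is None:
                continue
            pid, date = parsed
            setting = CareSetting.HOSPITAL
            if has_setting and str(row["setting"]).strip():
                try:
                    setting = CareSetting(str(row["setting"]).strip())
                except ValueError:
                    report.drop("codes", "bad_setting")
                    continue
            try:
                system = CodeSystem(str(row["system"]).strip())
                entry = CodedEntry(pid, system, str(row["code"]).strip(), date, setting)
            except ValueError:
                report.drop("codes", "bad_code")
                continue
            entries[pid]["codes"].append(entry)
        report.loaded["codes"] = sum(len(e["codes"]) for e in entries.values())

    if "medications" in paths:
        df = _read_table(paths["medications"])
        _require_columns(df, "medications")
        for _, row in df.iterrows():
            parsed = _common("medications", row, "date")
            if parsed is None:
                continue
            pid, date = parsed
            try:
                med = MedicationRecord(pid, str(row["atc_code"]).strip(), date)
            except ValueError:
                report.drop("medications", "bad_code")
                continue
            entries[pid]["medications"].append(med)
        report.loaded["medications"] = sum(
            len(e["medications"]) for e in entries.values())

    if "procedures" in paths:
        df = _read_table(paths["procedures"])
        _require_columns(df, "procedures")
        for _, row in df.iterrows():
            parsed = _common("procedures", row, "date")
            if parsed is None:
                continue
            pid, date = parsed
            try:
                system = ProcedureSystem(str(row["system"]).strip())
                proc = ProcedureRecord(pid, system, str(row["code"]).strip(), date)
            except ValueError:
                report.drop("procedures", "bad_code")
                continue
            entries[pid]["procedures"].append(proc)
        report.loaded["procedures"] = sum(
            len(e["procedures"]) for e in entries.values())

    cohort = {
        pid: PatientRecord(
            demographics=demo,
            labs=tuple(entries[pid]["labs"]),
            observations=tuple(entries[pid]["observations"]),
            codes=tuple(entries[pid]["codes"]),
            medications=tuple(entries[pid]["medications"]),
            procedures=tuple(entries[pid]["procedures"]),
        )
        for pid, demo in demographics.items()
    }
    return cohort, report


def write_cohort(cohort: Mapping[str, PatientRecord], out_dir: Union[str, Path]) -> None:
    """Write a cohort back to the six entity CSVs (round-trips with
    :func:`load_cohort`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo_rows, lab_rows, obs_rows, code_rows, med_rows, proc_rows = [], [], [], [], [], []
    for pid in sorted(cohort):
        rec = cohort[pid]
        d = rec.demographics
        demo_rows.append({"patient_id": pid, "sex": d.sex.value,
                          "birth_date": d.birth_date.isoformat()})
        for lab in rec.labs:
            lab_rows.append({
                "patient_id": pid, "analyte": lab.analyte.value,
                "value": repr(lab.value), "units": lab.units,
                "collected_date": lab.collected_date.isoformat(),
                "censor": lab.censor.value if lab.censor is not Censor.NONE else "",
            })
        for obs in rec.observations:
            obs_rows.append({"patient_id": pid, "kind": obs.kind.value,
                             "value": repr(obs.value), "date": obs.date.isoformat()})
        for code in rec.codes:
            code_rows.append({"patient_id": pid, "system": code.system.value,
                              "code": code.code, "date": code.date.isoformat(),
                              "setting": code.setting.value})
        for med in rec.medications:
            med_rows.append({"patient_id": pid, "atc_code": med.atc_code,
                             "date": med.date.isoformat()})
        for proc in rec.procedures:
            proc_rows.append({"patient_id": pid, "system": proc.system.value,
                              "code": proc.code, "date": proc.date.isoformat()})
    frames = {
        "demographics": pd.DataFrame(demo_rows, columns=["patient_id", "sex", "birth_date"]),
        "labs": pd.DataFrame(lab_rows, columns=["patient_id", "analyte", "value",
                                                "units", "collected_date", "censor"]),
        "observations": pd.DataFrame(obs_rows, columns=["patient_id", "kind", "value", "date"]),
        "codes": pd.DataFrame(code_rows, columns=["patient_id", "system", "code",
                                                  "date", "setting"]),
        "medications": pd.DataFrame(med_rows, columns=["patient_id", "atc_code", "date"]),
        "procedures": pd.DataFrame(proc_rows, columns=["patient_id", "system", "code", "date"]),
    }
    for table, df in frames.items():
        df.to_csv(out / f"{table}.csv", index=False)
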