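"""EHR data-completeness metrics: documentation, breadth, density, flags.

Completeness is summarised per patient over five data types — laboratory
results, observations, ICD-coded diagnoses, ICPC-coded diagnoses and
medications:

* **documentation** — cohort proportion of patients with ≥ 1 entry of
  each type;
* **breadth** — number of the five types present (0–5) per patient;
* **density** — entries per patient-year, the denominator being the span
  from first to last entry floored at one year so single-visit patients
  do not blow up the ratio;
* **metric flags 1–4** — a nested ladder of minimum-content criteria, the
  most stringent (metric 4) requiring 3 laboratory results, 3 observation
  entries, 1 coded diagnosis and 1 medication entry.

An *active* patient is one with any database entry in the two years
before the census date.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import CodeSystem, PatientRecord

DATA_TYPES = ("labs", "observations", "icd_codes", "icpc_codes", "medications")

#: Metric ladder thresholds: minimum counts of (labs, observations,
#: coded diagnoses of either system, medications) per flag.  Metrics 1-3
#: are package defaults forming a nested ladder; metric 4 is the printed
#: minimum-completeness criterion.
DEFAULT_METRIC_CRITERIA: Mapping[str, tuple[int, int, int, int]] = {
    "metric1": (0, 0, 0, 0),   # >=1 entry of any type, handled specially
    "metric2": (1, 0, 1, 0),
    "metric3": (3, 0, 1, 1),
    "metric4": (3, 3, 1, 1),
}


def _type_counts(record: PatientRecord, as_of: Optional[datetime.date]) -> dict[str, int]:
    def n(entries):
        return sum(1 for e in entries if as_of is None or e.date <= as_of)

    icd = sum(1 for c in record.codes
              if c.system is CodeSystem.ICD10AM and (as_of is None or c.date <= as_of))
    icpc = sum(1 for c in record.codes
               if c.system is CodeSystem.ICPC2 and (as_of is None or c.date <= as_of))
    return {
        "labs": n(record.labs),
        "observations": n(record.observations),
        "icd_codes": icd,
        "icpc_codes": icpc,
        "medications": n(record.medications),
    }


def activity_filter(
    cohort: Mapping[str, PatientRecord],
    as_of: datetime.date,
    window_years: float = 2.0,
) -> dict[str, PatientRecord]:
    """Patients with at least one entry of any type within the window
    ``[as_of − window_years, as_of]``."""
    start = as_of - datetime.timedelta(days=round(window_years * 365.25))
    return {
        pid: rec
        for pid, rec in cohort.items()
        if any(start <= d <= as_of for d in rec.all_entry_dates())
    }


@dataclass(frozen=True)
class CompletenessSummary:
    documentation: Mapping[str, float]        # per-type proportion with >=1 entry
    per_patient: pd.DataFrame                 # counts, breadth, density, flags
    breadth_median: float
    breadth_iqr: tuple[float, float]
    density_median: float
    density_iqr: tuple[float, float]
    metric_proportions: Mapping[str, float]


def patient_completeness(
    record: PatientRecord,
    as_of: Optional[datetime.date] = None,
    metric_criteria: Mapping[str, tuple[int, int, int, int]] = DEFAULT_METRIC_CRITERIA,
) -> dict:
    """Counts, breadth, density and metric flags for a single patient."""
    counts = _type_counts(record, as_of)
    total = sum(counts.values())
    breadth = sum(1 for v in counts.values() if v > 0)
    dates = [d for d in record.all_entry_dates() if as_of is None or d <= as_of]
    if dates:
        span_years = max(1.0, (max(dates) - min(dates)).days / 365.25)
    else:
        span_years = 1.0
    coded = counts["icd_codes"] + counts["icpc_codes"]
    row: dict = {**counts, "total_entries": total, "breadth": breadth,
                 "span_years": span_years, "density": total / span_years,
                 "lab_density": counts["labs"] / span_years}
    for name, (min_labs, min_obs, min_coded, min_meds) in metric_criteria.items():
        if name == "metric1":
            row[name] = total >= 1
        else:
            row[name] = (
                counts["labs"] >= min_labs
                and counts["observations"] >= min_obs
                and coded >= min_coded
                and counts["medications"] >= min_meds
            )
    return row


def completeness_summary(
    cohort: Mapping[str, PatientRecord],
    as_of: Optional[datetime.date] = None,
    metric_criteria: Mapping[str, tuple[int, int, int, int]] = DEFAULT_METRIC_CRITERIA,
) -> CompletenessSummary:
    """Cohort-level completeness: documentation proportions, per-patient
    breadth/density with medians and IQRs, and metric-flag proportions."""
    if not cohort:
        raise ValueError("cohort is empty")
    rows = {pid: patient_completeness(rec, as_of, metric_criteria)
            for pid, rec in cohort.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    documentation = {t: float((df[t] > 0).mean()) for t in DATA_TYPES}
    q1b, medb, q3b = np.percentile(df["breadth"], [25, 50, 75])
    q1d, medd, q3d = np.percentile(df["density"], [25, 50, 75])
    metric_props = {m: float(df[m].mean()) for m in metric_criteria}
    return CompletenessSummary(
        documentation=documentation,
        per_patient=df,
        breadth_median=float(medb),
        breadth_iqr=(float(q1b), float(q3b)),
        density_median=float(medd),
        density_iqr=(float(q1d), float(q3d)),
        metric_proportions=metric_props,
    )
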