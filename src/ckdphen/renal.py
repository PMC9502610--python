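"""Renal function primitives: CKD-EPI eGFR, KDIGO staging, chronicity.

The estimated glomerular filtration rate is computed with the 2009 CKD-EPI
creatinine equation in its single-equation form,

    eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age
           · 1.018 [female]

with Scr in mg/dL, κ = 0.7 (female) / 0.9 (male) and α = −0.329 / −0.411,
and no race coefficient (Australian laboratories report eGFR without race
adjustment).  Serum creatinine arrives in µmol/L and is divided by 88.4.

A CKD diagnosis by eGFR requires *chronicity*: two or more readings below
the threshold (default 60 mL/min/1.73m²) at least three months (90 days)
apart, with the most recent reading itself below threshold so that a
resolved episode of acute kidney injury cannot satisfy the criterion.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .config import CREATININE_UMOL_PER_MGDL, CkdEpiCoefficients, Thresholds
from .model import Analyte, Censor, PatientRecord, Sex

DAYS_PER_YEAR = 365.25


class GStage(str, enum.Enum):
    G1 = "G1"
    G2 = "G2"
    G3A = "G3a"
    G3B = "G3b"
    G4 = "G4"
    G5 = "G5"


class AStage(str, enum.Enum):
    A1 = "A1"
    A2 = "A2"
    A3 = "A3"


class EgfrSource(str, enum.Enum):
    COMPUTED_CKD_EPI = "computed_ckd_epi"
    LAB_REPORTED = "lab_reported"


@dataclass(frozen=True)
class EgfrPoint:
    date: datetime.date
    egfr: float
    source: EgfrSource
    censored_above: bool = False  # reported ">90", stored as 90

    def __post_init__(self) -> None:
        if self.egfr <= 0:
            raise ValueError(f"eGFR must be positive, got {self.egfr}")


@dataclass(frozen=True)
class ChronicityEvidence:
    """Outcome of a temporal persistence rule, with its evidence basis."""

    satisfied: bool
    first_date: Optional[datetime.date] = None
    last_date: Optional[datetime.date] = None
    qualifying_count: int = 0
    span_days: int = 0


def ckd_epi_egfr(
    sex: Sex,
    age_years: float,
    scr_umol_l: float,
    coefficients: CkdEpiCoefficients = CkdEpiCoefficients(),
) -> float:
    """2009 CKD-EPI eGFR (mL/min/1.73m²), rounded to one decimal place.

    Parameters
    ----------
    sex
        Patient sex; selects κ, α and the female multiplier.
    age_years
        Age at specimen collection; the equation is for adults (≥ 18 y).
    scr_umol_l
        Serum creatinine in µmol/L (converted internally to mg/dL).
    """
    if scr_umol_l <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr_umol_l}")
    if age_years < 18:
        raise ValueError(f"adult equation only: age {age_years} < 18")
    c = coefficients
    scr = scr_umol_l / CREATININE_UMOL_PER_MGDL
    if sex is Sex.FEMALE:
        kappa, alpha = c.kappa_female, c.alpha_female
    else:
        kappa, alpha = c.kappa_male, c.alpha_male
    ratio = scr / kappa
    egfr = (
        c.scale
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** c.beta_high
        * c.age_factor ** age_years
    )
    if sex is Sex.FEMALE:
        egfr *= c.female_multiplier
    return round(egfr, 1)


def age_at(birth_date: datetime.date, on: datetime.date) -> float:
    return (on - birth_date).days / DAYS_PER_YEAR


def egfr_series(
    record: PatientRecord,
    coefficients: CkdEpiCoefficients = CkdEpiCoefficients(),
    as_of: Optional[datetime.date] = None,
) -> list[EgfrPoint]:
    """Harmonised date-ordered eGFR series for one patient.

    One computed point per serum creatinine result; laboratory-reported
    eGFR fills dates with no creatinine (computed values take precedence
    on same-day collisions).  Reported values censored as ">90" are stored
    at 90 with the censor flag carried through.  Creatinine drawn before
    age 18 is skipped (adult equation only).
    """
    sex = record.demographics.sex
    birth = record.demographics.birth_date
    computed: dict[datetime.date, EgfrPoint] = {}
    reported: dict[datetime.date, EgfrPoint] = {}
    for lab in record.labs:
        if as_of is not None and lab.collected_date > as_of:
            continue
        if lab.analyte is Analyte.SERUM_CREATININE:
            age = age_at(birth, lab.collected_date)
            if age < 18 or lab.value <= 0:
                continue
            computed[lab.collected_date] = EgfrPoint(
                date=lab.collected_date,
                egfr=ckd_epi_egfr(sex, age, lab.value, coefficients),
                source=EgfrSource.COMPUTED_CKD_EPI,
            )
        elif lab.analyte is Analyte.EGFR_REPORTED:
            censored = lab.censor is Censor.ABOVE_LIMIT
            value = min(lab.value, 90.0) if censored else lab.value
            if value <= 0:
                continue
            reported[lab.collected_date] = EgfrPoint(
                date=lab.collected_date,
                egfr=value,
                source=EgfrSource.LAB_REPORTED,
                censored_above=censored,
            )
    merged = {**reported, **computed}  # computed wins on date collision
    return [merged[d] for d in sorted(merged)]


def g_stage(egfr: float, thresholds: Thresholds = Thresholds()) -> GStage:
    """KDIGO G-stage by half-open binning, lower bound inclusive."""
    if egfr <= 0:
        raise ValueError(f"eGFR must be positive, got {egfr}")
    b1, b2, b3a, b3b, b4 = thresholds.g_stage_boundaries
    if egfr >= b1:
        return GStage.G1
    if egfr >= b2:
        return GStage.G2
    if egfr >= b3a:
        return GStage.G3A
    if egfr >= b3b:
        return GStage.G3B
    if egfr >= b4:
        return GStage.G4
    return GStage.G5


def a_stage(uacr: float, thresholds: Thresholds = Thresholds()) -> AStage:
    """KDIGO A-stage (mg/mmol): A1 < 3, A2 [3, 30], A3 > 30."""
    if uacr < 0:
        raise ValueError(f"uACR must be non-negative, got {uacr}")
    lo, hi = thresholds.a_stage_boundaries
    if uacr < lo:
        return AStage.A1
    if uacr <= hi:
        return AStage.A2
    return AStage.A3


def _low(point: EgfrPoint, threshold: float) -> bool:
    # a ">90" censored value is never evidence of reduced eGFR
    return (not point.censored_above) and point.egfr < threshold


def persistent_low_egfr(
    series: Sequence[EgfrPoint],
    threshold: float = 60.0,
    min_span_days: int = 90,
    as_of: Optional[datetime.date] = None,
    require_latest_low: bool = True,
) -> ChronicityEvidence:
    """Chronically reduced eGFR: ≥ 2 readings < *threshold* ≥ *min_span_days* apart.

    With ``require_latest_low`` (the default) the most recent reading on or
    before *as_of* must itself be below threshold, so a resolved AKI — low
    readings followed by recovery — does not satisfy chronicity.  The
    evidence reports the earliest qualifying pair.
    """
    pts = [p for p in series if as_of is None or p.date <= as_of]
    if not pts:
        return ChronicityEvidence(satisfied=False)
    pts.sort(key=lambda p: p.date)
    lows = [p for p in pts if _low(p, threshold)]
    if require_latest_low and not _low(pts[-1], threshold):
        return ChronicityEvidence(satisfied=False, qualifying_count=len(lows))
    for i, first in enumerate(lows):
        for second in lows[i + 1:]:
            span = (second.date - first.date).days
            if span >= min_span_days:
                return ChronicityEvidence(
                    satisfied=True,
                    first_date=first.date,
                    last_date=second.date,
                    qualifying_count=len(lows),
                    span_days=span,
                )
    return ChronicityEvidence(satisfied=False, qualifying_count=len(lows))


def persistent_albuminuria(
    uacr_series: Sequence[tuple[datetime.date, float]],
    elevated_threshold: float = 3.0,
    min_count: int = 2,
    min_span_days: int = 0,
    as_of: Optional[datetime.date] = None,
) -> ChronicityEvidence:
    """Persistent albuminuria: ≥ *min_count* uACR ≥ *elevated_threshold* mg/mmol.

    With ``min_span_days`` > 0 (the stringent variant) two elevated readings
    must additionally be at least that many days apart.  A single elevated
    uACR never satisfies the default rule.
    """
    pts = sorted(
        (d, v) for d, v in uacr_series if as_of is None or d <= as_of
    )
    elevated = [(d, v) for d, v in pts if v >= elevated_threshold]
    if len(elevated) < min_count or not elevated:
        return ChronicityEvidence(satisfied=False, qualifying_count=len(elevated))
    first_date, last_date = elevated[0][0], elevated[-1][0]
    span = (last_date - first_date).days
    if min_span_days > 0 and span < min_span_days:
        return ChronicityEvidence(satisfied=False, qualifying_count=len(elevated),
                                  span_days=span)
    return ChronicityEvidence(
        satisfied=True,
        first_date=first_date,
        last_date=last_date,
        qualifying_count=len(elevated),
        span_days=span,
    )


def uacr_series(
    record: PatientRecord, as_of: Optional[datetime.date] = None
) -> list[tuple[datetime.date, float]]:
    return [
        (lab.collected_date, lab.value)
        for lab in record.labs
        if lab.analyte is Analyte.UACR
        and (as_of is None or lab.collected_date <= as_of)
    ]
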