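"""Cohort construction: inclusion rules, dedup, overall survival, staging.

A patient enters the analysis cohort when their selected report — the most
recent synoptic report — documents a primary invasive melanoma with a TIL
grade assessed and vertical growth phase present.  Overall survival runs
from diagnosis (proxied by the selected report's date) to death from any
cause, censored at the last follow-up date or the administrative censor
date.  T category follows the AJCC Breslow cut points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .features import TRISTATE_FEATURES, FeatureSet, TILGrade

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

DEFAULT_ADMIN_CENSOR = date(2019, 12, 31)

#: Exclusion reasons, checked in this order; a patient is counted once
#: under the first reason that applies.
EXCLUSION_REASONS = (
    "no_synoptic_report",
    "not_primary_invasive",
    "til_not_assessed",
    "no_vertical_growth_phase",
)


def assign_t_stage(breslow_mm: Optional[float]) -> str:
    """AJCC T category from Breslow thickness (mm)."""
    if breslow_mm is None:
        return "unknown"
    if breslow_mm < 0:
        raise ValueError("negative Breslow thickness")
    if breslow_mm <= 1.0:
        return "T1"
    if breslow_mm <= 2.0:
        return "T2"
    if breslow_mm <= 4.0:
        return "T3"
    return "T4"


def assign_age_group(dob: date, diagnosis_date: date) -> Tuple[int, str]:
    """Completed years at diagnosis and the study's age stratum."""
    if dob >= diagnosis_date:
        raise ValueError("date of birth must precede diagnosis")
    age = (
        diagnosis_date.year
        - dob.year
        - ((diagnosis_date.month, diagnosis_date.day) < (dob.month, dob.day))
    )
    if age < 50:
        group = "<50"
    elif age < 70:
        group = "50-69"
    else:
        group = ">=70"
    return age, group


def compute_overall_survival(
    diagnosis_date: date,
    death_date: Optional[date],
    last_followup_date: Optional[date],
    admin_censor_date: date = DEFAULT_ADMIN_CENSOR,
) -> Tuple[float, int]:
    """Overall survival in years and the event indicator.

    A death on record at or before the administrative censor date is an
    event; otherwise the patient is censored at the earlier of the last
    follow-up date and the censor date (or at the censor date when no
    follow-up date exists).
    """
    if death_date is not None:
        if death_date < diagnosis_date:
            raise ValueError("death before diagnosis")
        if death_date <= admin_censor_date:
            return (death_date - diagnosis_date).days / DAYS_PER_YEAR, 1
    candidates = [admin_censor_date]
    if last_followup_date is not None:
        candidates.append(last_followup_date)
    end = min(candidates)
    if end < diagnosis_date:
        raise ValueError("censoring date precedes diagnosis")
    return (end - diagnosis_date).days / DAYS_PER_YEAR, 0


@dataclass
class ReportFeatures:
    """Extractor output for one report, keyed for cohort assembly."""

    report_id: str
    patient_id: str
    report_date: date
    features: FeatureSet


def select_cohort(
    report_features: Iterable[ReportFeatures],
    patients: pd.DataFrame,
    admin_censor_date: date = DEFAULT_ADMIN_CENSOR,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply inclusion rules and emit the analysis cohort.

    ``patients`` columns: patient_id, dob, sex, death_date,
    last_followup_date and optionally primary_invasive.  Returns
    (cohort, exclusions); the exclusion ledger has one row per excluded
    patient with its (first) reason, so input patients = cohort rows +
    exclusion rows.
    """
    by_patient: Dict[str, List[ReportFeatures]] = {}
    for rf in report_features:
        by_patient.setdefault(rf.patient_id, []).append(rf)

    meta = patients.set_index("patient_id")
    rows = []
    excluded = []
    for pid in meta.index:
        reports = by_patient.get(pid, [])
        synoptic = [r for r in reports if r.features.is_synoptic]
        if not synoptic:
            excluded.append({"patient_id": pid, "reason": "no_synoptic_report"})
            continue
        selected = max(synoptic, key=lambda r: (r.report_date, r.report_id))
        ties = [
            r
            for r in synoptic
            if r.report_date == selected.report_date and r is not selected
        ]
        if ties:
            logger.info(
                "patient %s: %d same-date synoptic reports; kept %s",
                pid, len(ties) + 1, selected.report_id,
            )
        m = meta.loc[pid]
        if "primary_invasive" in meta.columns and not bool(m["primary_invasive"]):
            excluded.append({"patient_id": pid, "reason": "not_primary_invasive"})
            continue
        fs = selected.features
        if fs.til_grade == TILGrade.NOT_ASSESSED:
            excluded.append({"patient_id": pid, "reason": "til_not_assessed"})
            continue
        if not fs.vertical_growth_phase:
            excluded.append({"patient_id": pid, "reason": "no_vertical_growth_phase"})
            continue
        diagnosis = selected.report_date
        dob = _as_date(m["dob"])
        age, age_group = assign_age_group(dob, diagnosis)
        os_years, event = compute_overall_survival(
            diagnosis,
            _as_date(m.get("death_date")),
            _as_date(m.get("last_followup_date")),
            admin_censor_date,
        )
        rows.append(
            {
                "patient_id": pid,
                "report_id": selected.report_id,
                "diagnosis_date": diagnosis,
                "til_grade": fs.til_grade.value,
                "breslow_mm": fs.breslow_mm,
                "mitotic_rate": fs.mitotic_rate,
                **{f: getattr(fs, f).value for f in TRISTATE_FEATURES},
                "age_years": age,
                "age_group": age_group,
                "sex": m["sex"],
                "t_stage": assign_t_stage(fs.breslow_mm),
                "os_years": os_years,
                "event": event,
            }
        )
    cohort = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return cohort, exclusions


def _as_date(value) -> Optional[date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, str):
        return date.fromisoformat(value)
    return value
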