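"""Domain types for pathology-report features.

A melanoma pathology report carries seven histopathologic characteristics:
TIL grade (Clark three-tier system), Breslow thickness (mm), mitotic rate
(per mm^2), and four tri-state findings (ulceration, histologic regression,
microscopic satellites, vascular/lymphatic invasion).  A report additionally
documents whether the tumor has entered vertical growth phase and whether the
findings are presented synoptically (as labeled data elements).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Optional


class TILGrade(str, enum.Enum):
    """Clark grading of tumor-infiltrating lymphocytes.

    ``absent``: no lymphocytes, or lymphocytes that do not infiltrate the
    tumor. ``nonbrisk``: focal infiltration only. ``brisk``: diffuse
    infiltration of the entire invasive base. ``not_assessed``: the report
    carries no TIL evaluation.
    """

    ABSENT = "absent"
    NONBRISK = "nonbrisk"
    BRISK = "brisk"
    NOT_ASSESSED = "not_assessed"


class TriState(str, enum.Enum):
    """Presence call for a binary histologic finding."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


#: The four tri-state feature names, in report order.
TRISTATE_FEATURES = (
    "ulceration",
    "histologic_regression",
    "microsatellites",
    "vascular_lymphatic_invasion",
)

#: All scored feature field names (the seven extracted characteristics).
SEVEN_FEATURES = (
    "til_grade",
    "breslow_mm",
    "mitotic_rate",
) + TRISTATE_FEATURES


@dataclass
class FeatureSet:
    """Normalized values of the seven characteristics plus report flags.

    ``breslow_mm`` and ``mitotic_rate`` are ``None`` when unknown.
    """

    til_grade: TILGrade = TILGrade.NOT_ASSESSED
    breslow_mm: Optional[float] = None
    mitotic_rate: Optional[float] = None
    ulceration: TriState = TriState.UNKNOWN
    histologic_regression: TriState = TriState.UNKNOWN
    microsatellites: TriState = TriState.UNKNOWN
    vascular_lymphatic_invasion: TriState = TriState.UNKNOWN
    vertical_growth_phase: bool = False
    is_synoptic: bool = False

    def __post_init__(self) -> None:
        if self.breslow_mm is not None and self.breslow_mm < 0:
            raise ValueError("breslow_mm must be nonnegative")
        if self.mitotic_rate is not None and self.mitotic_rate < 0:
            raise ValueError("mitotic_rate must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["til_grade"] = self.til_grade.value
        for f in TRISTATE_FEATURES:
            d[f] = getattr(self, f).value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        kwargs = dict(d)
        kwargs["til_grade"] = TILGrade(kwargs.get("til_grade", "not_assessed"))
        for f in TRISTATE_FEATURES:
            kwargs[f] = TriState(kwargs.get(f, "unknown"))
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in kwargs.items() if k in known})


@dataclass
class RawReport:
    """One free-text pathology report plus identifying metadata."""

    report_id: str
    patient_id: str
    report_date: date
    text: str


@dataclass
class Span:
    """Half-open 0-based character interval into a source text."""

    start: int
    end: int

    def slice(self, text: str) -> str:
        return text[self.start : self.end]


@dataclass
class ReportSegment:
    """A headed section of a report.

    ``span`` covers the body only; ``header`` is the normalized header label
    (``PREAMBLE`` for text before the first recognized header).
    """

    header: str
    body: str
    span: Span


@dataclass
class GoldRecord:
    """Ground-truth labels for one synthetic patient.

    ``true_event_time_years`` is the uncensored latent survival time drawn by
    the generator; observed follow-up derives from it by censoring.
    """

    patient_id: str
    true_features: FeatureSet
    diagnosis_date: date
    death_date: Optional[date] = None
    last_followup_date: Optional[date] = None
    true_event_time_years: float = float("inf")
    dob: Optional[date] = None
    sex: str = "female"
    age_years: Optional[int] = None
    eligible: bool = True
    primary_invasive: bool = True
    report_gold: dict = field(default_factory=dict)  # report_id -> FeatureSet
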