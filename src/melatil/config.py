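"""Generator configuration.

Defaults calibrate the synthetic corpus to the published melanoma TIL study
population: the per-feature category margins and their association with TIL
grade come from the study's descriptive table, and the per-term log-hazards
from its adjusted Cox model.  Associations are encoded as odds tilts: the
probability of category ``c`` given TIL grade ``g`` is proportional to
``marginal[c] * tilt[g][c]``, so setting every tilt to 1 makes a feature
independent of TIL grade.
"""

from __future__ import annotations

import math
from datetime import date
from typing import Dict, Optional

from pydantic import BaseModel, Field, model_validator

# ---------------------------------------------------------------------------
# Calibration count tables: rows are TIL grades, columns are categories.
# Counts are the study population's cross-tabulation against TIL grade
# (absent n=434, nonbrisk n=1916, brisk n=274; N=2624).
# ---------------------------------------------------------------------------

TIL_COUNTS = {"absent": 434, "nonbrisk": 1916, "brisk": 274}

AGE_GROUP_COUNTS = {
    # <50 / 50-69 / >=70
    "absent": {"<50": 90, "50-69": 219, ">=70": 125},
    "nonbrisk": {"<50": 472, "50-69": 899, ">=70": 545},
    "brisk": {"<50": 80, "50-69": 140, ">=70": 54},
}

SEX_COUNTS = {
    "absent": {"female": 200, "male": 234},
    "nonbrisk": {"female": 829, "male": 1087},
    "brisk": {"female": 133, "male": 141},
}

# T category by TIL grade, known thickness only (86 unknown overall).
T_STAGE_COUNTS = {
    "absent": {"T1": 165, "T2": 103, "T3": 67, "T4": 83},
    "nonbrisk": {"T1": 759, "T2": 461, "T3": 325, "T4": 303},
    "brisk": {"T1": 158, "T2": 66, "T3": 31, "T4": 17},
}

TRISTATE_COUNTS = {
    "ulceration": {
        "absent": {"present": 76, "absent": 352},
        "nonbrisk": {"present": 427, "absent": 1448},
        "brisk": {"present": 33, "absent": 240},
    },
    "histologic_regression": {
        "absent": {"present": 49, "absent": 381},
        "nonbrisk": {"present": 457, "absent": 1439},
        "brisk": {"present": 122, "absent": 149},
    },
    "microsatellites": {
        "absent": {"present": 15, "absent": 225},
        "nonbrisk": {"present": 50, "absent": 1003},
        "brisk": {"present": 0, "absent": 159},
    },
    "vascular_lymphatic_invasion": {
        "absent": {"present": 250, "absent": 56},
        "nonbrisk": {"present": 1092, "absent": 112},
        "brisk": {"present": 126, "absent": 9},
    },
}


def _marginal(counts_by_til: Dict[str, Dict[str, int]]) -> Dict[str, float]:
    cats: Dict[str, float] = {}
    for row in counts_by_til.values():
        for c, n in row.items():
            cats[c] = cats.get(c, 0) + n
    total = sum(cats.values())
    return {c: n / total for c, n in cats.items()}


def _tilts(counts_by_til: Dict[str, Dict[str, int]]) -> Dict[str, Dict[str, float]]:
    """Odds multipliers turning the marginal into each TIL-conditional."""
    marg = _marginal(counts_by_til)
    out: Dict[str, Dict[str, float]] = {}
    for til, row in counts_by_til.items():
        tot = sum(row.values())
        out[til] = {
            c: (row[c] / tot) / marg[c] if marg[c] > 0 and tot > 0 else 1.0
            for c in row
        }
    return out


def _default_marginals() -> Dict[str, Dict[str, float]]:
    til_total = sum(TIL_COUNTS.values())
    return {
        "til_grade": {g: n / til_total for g, n in TIL_COUNTS.items()},
        "age_group": _marginal(AGE_GROUP_COUNTS),
        "sex": _marginal(SEX_COUNTS),
        "t_stage": _marginal(T_STAGE_COUNTS),
        **{f: _marginal(t) for f, t in TRISTATE_COUNTS.items()},
    }


def _default_tilts() -> Dict[str, Dict[str, Dict[str, float]]]:
    return {
        "age_group": _tilts(AGE_GROUP_COUNTS),
        "sex": _tilts(SEX_COUNTS),
        "t_stage": _tilts(T_STAGE_COUNTS),
        **{f: _tilts(t) for f, t in TRISTATE_COUNTS.items()},
    }


#: Adjusted log-hazards of the generating proportional-hazards model
#: (exp of each value is the corresponding adjusted hazard ratio).
DEFAULT_COEFFICIENTS: Dict[str, float] = {
    "age_50_69": math.log(1.65),
    "age_70plus": math.log(3.37),
    "sex_male": math.log(1.50),
    "til_brisk": math.log(0.63),
    "til_nonbrisk": math.log(0.87),
    "breslow_per_mm": math.log(1.05),
    "mitotic_per_unit": math.log(1.02),
    "ulceration_present": math.log(2.14),
    "ulceration_unknown": math.log(2.09),
    "histologic_regression_present": 0.0,
    "histologic_regression_unknown": 0.0,
    "microsatellites_present": math.log(1.88),
    "microsatellites_unknown": math.log(0.86),
    "vascular_lymphatic_invasion_present": math.log(1.58),
    "vascular_lymphatic_invasion_unknown": math.log(1.59),
    "breslow_unknown": 0.0,
}

#: Per-feature probability that a report omits the feature line entirely
#: (calibrated to the study's Unknown fractions).
DEFAULT_MISSINGNESS: Dict[str, float] = {
    "breslow_mm": 86 / 2624,
    "mitotic_rate": 0.0,
    "ulceration": 48 / 2624,
    "histologic_regression": 27 / 2624,
    "microsatellites": 1172 / 2624,
    "vascular_lymphatic_invasion": 979 / 2624,
}

#: Mean mitotic count (per mm^2) by TIL grade; counts are geometric so the
#: medians and quartiles land on the study's 2 (1-6) overall and 1 (0-3)
#: for brisk tumors.
DEFAULT_MITOTIC_MEAN = {"absent": 3.5, "nonbrisk": 3.5, "brisk": 1.8}

#: How ineligible patients fail the inclusion criteria.
DEFAULT_INELIGIBLE_MIX = {
    "til_not_assessed": 0.45,
    "vgp_absent": 0.35,
    "no_synoptic": 0.15,
    "not_invasive": 0.05,
}


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic corpus generator.

    The defaults are the study conditions; change them only to build
    deliberately different worlds (null effects, degenerate marginals, ...).
    """

    n_patients: int = Field(default=500, gt=0)
    seed: int = 0

    marginals: Dict[str, Dict[str, float]] = Field(default_factory=_default_marginals)
    joint_tilts: Dict[str, Dict[str, Dict[str, float]]] = Field(
        default_factory=_default_tilts
    )
    coefficients: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    #: Events per person-year for the reference profile (calibrated so the
    #: whole-cohort 5-year survival sits near the study's 74.3%).
    baseline_hazard: float = Field(default=0.0135, gt=0)
    #: Annual rate of loss to follow-up (tuned with uniform accrual so the
    #: reverse-KM median follow-up lands near 3.1 years).
    ltfu_rate: float = Field(default=0.152, ge=0)

    accrual_start: date = date(2004, 6, 1)
    accrual_end: date = date(2019, 12, 31)
    admin_censor_date: date = date(2019, 12, 31)

    missingness: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    variant_intensity: float = Field(default=0.25, ge=0, le=1)
    #: Probability a variant draw uses a phrasing outside the rule lexicon
    #: (only these can defeat the extractor).
    hard_variant_share: Dict[str, float] = Field(
        default_factory=lambda: {"til_grade": 0.05}
    )

    eligible_fraction: float = Field(default=2624 / 14436, ge=0, le=1)
    ineligible_mix: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_INELIGIBLE_MIX)
    )
    #: Probability an (eligible) patient carries an extra earlier report.
    extra_report_prob: float = Field(default=0.20, ge=0, le=1)

    mitotic_mean: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_MITOTIC_MEAN)
    )
    #: Probability a report carries an irrelevant narrative sentence.
    distractor_prob: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for feat, probs in self.marginals.items():
            bad = [p for p in probs.values() if p < 0 or p > 1]
            if bad:
                raise ValueError(f"{feat}: probabilities outside [0,1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{feat}: category probabilities must sum to 1")
        for feat, p in self.missingness.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missingness[{feat}] outside [0,1]")
        if self.accrual_start >= self.admin_censor_date:
            raise ValueError("accrual window must precede the censor date")
        if self.accrual_end > self.admin_censor_date:
            raise ValueError("accrual may not extend past the censor date")
        if abs(sum(self.ineligible_mix.values()) - 1.0) > 1e-9:
            raise ValueError("ineligible_mix must sum to 1")
        return self


def tilted_probs(
    marginal: Dict[str, float], tilt: Optional[Dict[str, float]]
) -> Dict[str, float]:
    """Apply odds multipliers to a categorical marginal and renormalize."""
    if tilt is None:
        return dict(marginal)
    raw = {c: marginal[c] * tilt.get(c, 1.0) for c in marginal}
    z = sum(raw.values())
    if z <= 0:
        raise ValueError("tilted probabilities sum to zero")
    return {c: v / z for c, v in raw.items()}
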