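"""Render gold feature sets into semistructured pathology-report text.

The dialect is a two-section institutional template ("Specimen(s)",
"Results").  Synoptic reports present one labeled feature line per finding
in the results block; narrative reports fold the same findings into prose,
one sentence per line.  Each rendering draws from a variant table: a
canonical phrasing, recoverable variants (alternative surface forms the
rule lexicon also covers, e.g. "present, at least brisk" for brisk TILs),
and — narrative prose only — hard variants that no lexicon head matches,
emulating the free-text mentions a rule system genuinely misses.  Synoptic
blocks are standardized by construction, so hard phrasings never appear
there.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .config import GeneratorConfig
from .features import FeatureSet, TILGrade, TriState

# --- variant tables: labeled (synoptic) and prose (narrative) forms -------

TIL_LINES = {
    TILGrade.BRISK: {
        "canonical": "Tumor infiltrating lymphocytes: present (brisk)",
        "variants": [
            "Tumor-infiltrating lymphocytes (TILs): present, at least brisk",
            "TILs: present [brisk]",
            "Lymphocytic host response: brisk",
        ],
        "prose": [
            "Tumor infiltrating lymphocytes are present, brisk.",
            "Tumor-infiltrating lymphocytes are present, at least brisk.",
        ],
        "prose_hard": [
            "A dense lymphoid infiltrate permeates the entire base of the lesion.",
        ],
    },
    TILGrade.NONBRISK: {
        "canonical": "Tumor infiltrating lymphocytes: present (nonbrisk)",
        "variants": [
            "Tumor infiltrating lymphocytes: present [non-brisk]",
            "TILs: present, non-brisk",
            "Lymphocytic host response: nonbrisk",
        ],
        "prose": [
            "Tumor infiltrating lymphocytes are present, non-brisk.",
        ],
        "prose_hard": [
            "Focal lymphoid aggregates are noted at the base of the lesion.",
        ],
    },
    TILGrade.ABSENT: {
        "canonical": "Tumor infiltrating lymphocytes: absent",
        "variants": [
            "TILs: not identified",
            "Tumor infiltrating lymphocytes: none identified",
        ],
        "prose": [
            "Tumor infiltrating lymphocytes are absent.",
        ],
        "prose_hard": [
            "The dermal component lacks an associated lymphoid response.",
        ],
    },
}

BRESLOW_LINES = {
    "canonical": "Breslow thickness: {v:.2f} mm",
    "variants": [
        "Breslow depth: {v:.2f} mm",
        "Depth of invasion: {v:.2f} mm",
        "Breslow thickness: at least {v:.2f} mm",
    ],
    "prose": [
        "Breslow thickness is {v:.2f} mm.",
        "The lesion measures {v:.2f} mm in depth of invasion.",
    ],
}

MITOTIC_LINES = {
    "canonical": "Mitotic rate: {v:g}/mm2",
    "variants": [
        "Mitotic figures: {v:g} per mm2",
        "Mitotic index: {v:g}/mm^2",
    ],
    "zero_variants": [
        "No mitotic figures identified",
        "Mitotic rate: <1/mm2",
    ],
    "prose": [
        "Mitotic rate is {v:g}/mm2.",
    ],
    "zero_prose": [
        "No mitotic figures identified.",
        "Mitoses number less than 1/mm2.",
    ],
}

TRISTATE_LINES = {
    "ulceration": {
        TriState.PRESENT: {
            "canonical": "Ulceration: present",
            "variants": ["Ulceration is present", "Ulceration: identified"],
            "prose": ["Ulceration is present.", "The epidermis is ulcerated and present over the tumor."],
        },
        TriState.ABSENT: {
            "canonical": "Ulceration: absent",
            "variants": ["Ulceration: not identified", "No ulceration identified"],
            "prose": ["No ulceration identified.", "Ulceration is absent."],
        },
    },
    "histologic_regression": {
        TriState.PRESENT: {
            "canonical": "Histologic regression: present",
            "variants": ["Regression: present", "Histological regression: identified"],
            "prose": ["Histologic regression is present."],
        },
        TriState.ABSENT: {
            "canonical": "Histologic regression: absent",
            "variants": ["Regression: not identified", "No histologic regression identified"],
            "prose": ["No histologic regression identified."],
        },
    },
    "microsatellites": {
        TriState.PRESENT: {
            "canonical": "Microsatellites: present",
            "variants": ["Microscopic satellites: present", "Satellitosis: identified"],
            "prose": ["Microscopic satellites are present."],
        },
        TriState.ABSENT: {
            "canonical": "Microsatellites: absent",
            "variants": [
                "Microscopic satellites: not identified",
                "No microscopic satellites identified",
            ],
            "prose": ["No microscopic satellites identified."],
        },
    },
    "vascular_lymphatic_invasion": {
        TriState.PRESENT: {
            "canonical": "Vascular/lymphatic invasion: present",
            "variants": [
                "Lymphovascular invasion: present",
                "Angiolymphatic invasion: identified",
            ],
            "prose": ["Lymphovascular invasion is present."],
        },
        TriState.ABSENT: {
            "canonical": "Vascular/lymphatic invasion: absent",
            "variants": [
                "No vascular or lymphatic invasion identified",
                "Lymphovascular invasion: not identified",
            ],
            "prose": ["No vascular or lymphatic invasion identified."],
        },
    },
}

VGP_LINES = {
    True: {
        "canonical": "Vertical growth phase: present",
        "variants": ["VGP: present", "Vertical growth phase: identified"],
        "prose": ["Vertical growth phase is present."],
    },
    False: {
        "canonical": "Vertical growth phase: not identified",
        "variants": ["VGP: not identified"],
        "prose": ["Vertical growth phase is not identified."],
    },
}

SPECIMEN_SITES = [
    "left forearm", "right shoulder", "back", "left calf", "right thigh",
    "scalp", "chest wall", "left upper arm", "abdomen", "right ear",
]
PROCEDURES = ["shave biopsy", "punch biopsy", "excisional biopsy", "wide local excision"]

# Distractor prose: must never trigger a feature lexicon head.
DISTRACTORS = [
    "Margins appear free of tumor in the planes of section examined.",
    "The lesion is asymmetrical with irregular, poorly circumscribed borders.",
    "Immunohistochemical stains were reviewed and support the interpretation.",
    "The findings were discussed with the submitting clinician.",
    "Solar elastosis of the surrounding dermis is noted.",
]

DIAGNOSIS_SENTENCES = [
    "Malignant melanoma, superficial spreading type.",
    "Malignant melanoma, nodular type.",
    "Malignant melanoma, lentigo maligna type.",
    "Malignant melanoma, not otherwise specified.",
]


def _choose(rng: np.random.Generator, items: List[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _labeled(table: dict, rng, intensity: float, value: Optional[float] = None) -> str:
    if intensity > 0 and table.get("variants") and rng.random() < intensity:
        tpl = _choose(rng, table["variants"])
    else:
        tpl = table["canonical"]
    return tpl.format(v=value) if value is not None else tpl


def _prose(
    table: dict, rng, intensity: float, hard_share: float, value: Optional[float] = None
) -> str:
    pool = list(table.get("prose") or [table["canonical"]])
    hard = table.get("prose_hard") or []
    if hard and intensity > 0 and rng.random() < intensity and rng.random() < hard_share:
        tpl = _choose(rng, hard)
    else:
        tpl = pool[0] if intensity == 0 else _choose(rng, pool)
    return tpl.format(v=value) if value is not None else tpl


def render_results_block(
    fs: FeatureSet,
    config: GeneratorConfig,
    rng: np.random.Generator,
    style: str = "synoptic",
) -> List[str]:
    """One line per known feature, in fixed report order.

    ``style="synoptic"`` emits labeled data-element lines; ``"narrative"``
    emits prose, one sentence per line (the extractor's negation scope is
    line-bound, as is institutional convention).
    """
    intensity = config.variant_intensity
    narrative = style == "narrative"
    til_hard = config.hard_variant_share.get("til_grade", 0.0)

    def pick(table, value=None, hard_share=0.0):
        if narrative:
            return _prose(table, rng, intensity, hard_share, value)
        return _labeled(table, rng, intensity, value)

    lines: List[str] = []
    if fs.til_grade != TILGrade.NOT_ASSESSED:
        lines.append(pick(TIL_LINES[fs.til_grade], hard_share=til_hard))
    if fs.breslow_mm is not None:
        lines.append(pick(BRESLOW_LINES, value=fs.breslow_mm))
    if fs.mitotic_rate is not None:
        if fs.mitotic_rate == 0:
            key = "zero_prose" if narrative else "zero_variants"
            if narrative or (intensity > 0 and rng.random() < intensity):
                lines.append(_choose(rng, MITOTIC_LINES[key]) if intensity > 0 else MITOTIC_LINES[key][0])
            else:
                lines.append(pick(MITOTIC_LINES, value=0))
        else:
            lines.append(pick(MITOTIC_LINES, value=fs.mitotic_rate))
    for feat, per_state in TRISTATE_LINES.items():
        state = getattr(fs, feat)
        if state != TriState.UNKNOWN:
            lines.append(pick(per_state[state]))
    if fs.vertical_growth_phase:
        lines.append(pick(VGP_LINES[True]))
    elif rng.random() < 0.5:
        # non-VGP tumors: half the reports state it explicitly, half omit it
        lines.append(pick(VGP_LINES[False]))
    return lines


def render_report_text(
    fs: FeatureSet,
    config: GeneratorConfig,
    rng: np.random.Generator,
    report_id: str,
    patient_id: str,
    report_date,
) -> str:
    """Full report text for one gold feature set."""
    site = _choose(rng, SPECIMEN_SITES)
    proc = _choose(rng, PROCEDURES)
    head = [
        f"Accession No. {report_id}",
        f"Patient ID {patient_id}",
        f"Report date {report_date.isoformat()}",
        "",
        f"Specimen(s): Skin, {site}, {proc}",
        "",
    ]
    body: List[str] = ["Results:"]
    body.append(_choose(rng, DIAGNOSIS_SENTENCES))
    if fs.is_synoptic:
        if rng.random() < 0.5:
            body.append("Synoptic summary of data elements:")
        body.extend(render_results_block(fs, config, rng, style="synoptic"))
    else:
        body.extend(render_results_block(fs, config, rng, style="narrative"))
    if rng.random() < config.distractor_prob:
        body.append(_choose(rng, DISTRACTORS))
    return "\n".join(head + body) + "\n"
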