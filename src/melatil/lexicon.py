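"""Lexicon loading.

Extraction rules are data, not code: each feature ships a YAML file with its
head patterns (how the feature is named on a report line), value patterns
(surface form -> normalization target), and, for the tri-state findings,
shared polarity cues.  Users can point the extractor at an edited lexicon
directory to change behavior without touching code.
"""

from __future__ import annotations

import functools
import re
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import yaml

_DEFAULT_DIR = resources.files("melatil") / "lexicons"


def _read(name: str, lexicon_dir: Optional[Path] = None) -> dict:
    if lexicon_dir is not None:
        return yaml.safe_load(Path(lexicon_dir, name).read_text())
    return yaml.safe_load((_DEFAULT_DIR / name).read_text())


@functools.lru_cache(maxsize=None)
def load_header_lexicon(lexicon_dir: Optional[str] = None) -> List[dict]:
    data = _read("headers.yaml", Path(lexicon_dir) if lexicon_dir else None)
    return data["headers"]


class FeatureLexicon:
    """Compiled rule set for one feature."""

    def __init__(self, data: dict):
        self.feature: str = data["feature"]
        flags = re.IGNORECASE
        self.heads = [re.compile(p, flags) for p in data.get("heads", [])]
        # value groups: ordered list of (target, [compiled patterns])
        self.values = [
            (grp["target"], [re.compile(p, flags) for p in grp["patterns"]])
            for grp in data.get("values", [])
        ]
        vp = data.get("value_pattern")
        self.value_pattern = re.compile(vp, flags) if vp else None
        self.zero_patterns = [
            re.compile(p, flags) for p in data.get("zero_patterns", [])
        ]

    def find_head(self, line: str) -> Optional[re.Match]:
        best: Optional[re.Match] = None
        for h in self.heads:
            m = h.search(line)
            if m and (best is None or m.start() < best.start()):
                best = m
        return best


class Polarity:
    """Shared affirmation/negation cues for tri-state findings."""

    def __init__(self, data: dict):
        flags = re.IGNORECASE
        self.window: int = int(data.get("negation_window", 5))
        self.affirm = [re.compile(p, flags) for p in data["affirm"]]
        self.negate_after = [re.compile(p, flags) for p in data["negate_after"]]
        self.negate_before = [re.compile(p, flags) for p in data["negate_before"]]


@functools.lru_cache(maxsize=None)
def load_lexicons(lexicon_dir: Optional[str] = None) -> Dict[str, FeatureLexicon]:
    d = Path(lexicon_dir) if lexicon_dir else None
    names = [
        "til_grade",
        "breslow_mm",
        "mitotic_rate",
        "ulceration",
        "histologic_regression",
        "microsatellites",
        "vascular_lymphatic_invasion",
        "vertical_growth_phase",
    ]
    return {n: FeatureLexicon(_read(f"{n}.yaml", d)) for n in names}


@functools.lru_cache(maxsize=None)
def load_polarity(lexicon_dir: Optional[str] = None) -> Polarity:
    d = Path(lexicon_dir) if lexicon_dir else None
    return Polarity(_read("polarity.yaml", d))
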