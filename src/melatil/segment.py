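"""Report segmentation by predefined section headers.

Institutional pathology reports are semistructured: named sections such as
"Specimen(s)" and "Results" introduced by a header line.  Segmentation finds
header lines (case-insensitively, at line starts, followed by a colon) and
assigns every character of the report to at most one segment body.  Text
before the first recognized header becomes a ``PREAMBLE`` segment.
"""

from __future__ import annotations

import re
from typing import List

from .features import ReportSegment, Span
from .lexicon import load_header_lexicon

_HEADER_RE_CACHE: dict = {}


def _header_regex() -> re.Pattern:
    key = "headers"
    if key not in _HEADER_RE_CACHE:
        entries = load_header_lexicon()
        alts = "|".join(f"(?P<h{i}>{e['pattern']})" for i, e in enumerate(entries))
        _HEADER_RE_CACHE[key] = (
            re.compile(rf"^[ \t]*(?:{alts})[ \t]*:", re.IGNORECASE | re.MULTILINE),
            [e["label"] for e in entries],
        )
    return _HEADER_RE_CACHE[key]


def segment_report(text: str) -> List[ReportSegment]:
    """Split report text into ordered, non-overlapping headed segments.

    Returns an empty list for empty text; a report with no recognized header
    yields a single PREAMBLE segment covering the whole text.
    """
    if not text:
        return []
    pattern, labels = _header_regex()
    segments: List[ReportSegment] = []
    matches = list(pattern.finditer(text))
    if not matches or matches[0].start() > 0:
        end = matches[0].start() if matches else len(text)
        body = text[:end]
        if body.strip():
            segments.append(ReportSegment("PREAMBLE", body, Span(0, end)))
    for i, m in enumerate(matches):
        label = next(
            labels[int(name[1:])] for name, val in m.groupdict().items() if val
        )
        start = m.end()
        end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
        segments.append(ReportSegment(label, text[start:end], Span(start, end)))
    return segments
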