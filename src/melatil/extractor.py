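"""Rule-based extraction of pathologic characteristics from report text.

The extractor composes per-feature rule passes over segmented report text:

* TIL grade: surface forms normalized into absent / nonbrisk / brisk
  (e.g. "present [brisk]" and "present, at least brisk" both mean brisk);
  a report with no TIL mention is ``not_assessed``.
* Breslow thickness: decimal millimetre values; "at least X mm" floors
  report X.
* Mitotic rate: "N/mm2"-style values; explicit-zero phrasings map to 0.
* Tri-state findings (ulceration, regression, microsatellites,
  vascular/lymphatic invasion): affirmation means present, a negation cue on
  the same line means absent, no mention means unknown.
* Vertical growth phase and synoptic-format detection.

Every non-unknown extraction records the character span it came from, so
each decision is auditable against the source text.  Mentions inside the
results/synoptic block take precedence over narrative mentions, and among
competing mentions the last (most final) wins — addenda conventionally
supersede earlier text.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .features import (
    TRISTATE_FEATURES,
    FeatureSet,
    RawReport,
    ReportSegment,
    Span,
    TILGrade,
    TriState,
)
from .lexicon import FeatureLexicon, Polarity, load_lexicons, load_polarity
from .segment import segment_report

logger = logging.getLogger(__name__)

#: Segments whose mentions outrank narrative text.
_RESULT_SEGMENTS = {"RESULTS", "SYNOPTIC", "DIAGNOSIS", "ADDENDUM"}

_SYNOPTIC_MARKER = re.compile(r"\bsynoptic\b", re.IGNORECASE)
_LABELED_LINE = re.compile(r"^\s*[A-Za-z][\w()/\[\] -]*:\s*\S")
_TOKEN = re.compile(r"\S+")


@dataclass
class Extraction:
    """A FeatureSet plus the audit trail of matched spans."""

    features: FeatureSet
    spans: Dict[str, Span] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)


def _iter_lines(segments: List[ReportSegment]):
    """Yield (segment, line_text, absolute_start) for every line."""
    for seg in segments:
        offset = seg.span.start
        pos = 0
        for line in seg.body.splitlines(keepends=True):
            yield seg, line.rstrip("\n"), offset + pos
            pos += len(line)


def _pick(candidates: List[Tuple[bool, int, object]]):
    """Precedence: results-block mentions first, then last position."""
    if not candidates:
        return None
    preferred = [c for c in candidates if c[0]] or candidates
    return max(preferred, key=lambda c: c[1])[2]


def extract_til_grade(
    segments: List[ReportSegment], lex: Optional[FeatureLexicon] = None
) -> Tuple[TILGrade, Optional[Span]]:
    lex = lex or load_lexicons()["til_grade"]
    candidates = []
    for seg, line, start in _iter_lines(segments):
        head = lex.find_head(line)
        if head is None:
            continue
        tail = line[head.end() :]
        hit = None
        for target, patterns in lex.values:
            for p in patterns:
                m = p.search(tail)
                if m is not None:
                    hit = (target, head.end() + m.start(), head.end() + m.end())
                    break
                m = p.search(line)
                if m is not None:
                    hit = (target, m.start(), m.end())
                    break
            if hit:
                break
        if hit is None:
            continue
        target, lo, hi = hit
        span = Span(start + min(head.start(), lo), start + max(head.end(), hi))
        candidates.append(
            (seg.header in _RESULT_SEGMENTS, start, (TILGrade(target), span))
        )
    picked = _pick(candidates)
    if picked is None:
        return TILGrade.NOT_ASSESSED, None
    return picked


def extract_breslow_mm(
    segments: List[ReportSegment], lex: Optional[FeatureLexicon] = None
) -> Tuple[Optional[float], Optional[Span]]:
    lex = lex or load_lexicons()["breslow_mm"]
    candidates = []
    for seg, line, start in _iter_lines(segments):
        head = lex.find_head(line)
        if head is None:
            continue
        m = lex.value_pattern.search(line)
        if m is None:
            logger.info("unparseable thickness line: %r", line.strip())
            continue
        value = round(float(m.group(1)), 2)
        span = Span(start + min(head.start(), m.start()), start + max(head.end(), m.end()))
        candidates.append((seg.header in _RESULT_SEGMENTS, start, (value, span)))
    picked = _pick(candidates)
    return (None, None) if picked is None else picked


def extract_mitotic_rate(
    segments: List[ReportSegment], lex: Optional[FeatureLexicon] = None
) -> Tuple[Optional[float], Optional[Span]]:
    lex = lex or load_lexicons()["mitotic_rate"]
    candidates = []
    for seg, line, start in _iter_lines(segments):
        zero = next((z.search(line) for z in lex.zero_patterns if z.search(line)), None)
        head = lex.find_head(line)
        if zero is not None:
            span = Span(start + zero.start(), start + zero.end())
            candidates.append((seg.header in _RESULT_SEGMENTS, start, (0.0, span)))
            continue
        if head is None:
            continue
        m = lex.value_pattern.search(line)
        if m is None:
            logger.info("unparseable mitotic-rate line: %r", line.strip())
            continue
        value = float(m.group(1))
        span = Span(start + min(head.start(), m.start()), start + max(head.end(), m.end()))
        candidates.append((seg.header in _RESULT_SEGMENTS, start, (value, span)))
    picked = _pick(candidates)
    return (None, None) if picked is None else picked


def _tristate_on_line(
    line: str, head: re.Match, polarity: Polarity
) -> Optional[Tuple[TriState, int, int]]:
    """Polarity of one feature mention; None when the line carries no cue."""
    before, after = line[: head.start()], line[head.end() :]
    # negation cue within `window` tokens before the head wins first
    best_neg = None
    for p in polarity.negate_before:
        for m in p.finditer(before):
            gap = len(_TOKEN.findall(before[m.end() :]))
            if gap < polarity.window and (best_neg is None or m.start() > best_neg.start()):
                best_neg = m
    for p in polarity.negate_after:
        m = p.search(after)
        if m:
            return TriState.ABSENT, head.start(), head.end() + m.end()
    if best_neg is not None:
        return TriState.ABSENT, best_neg.start(), head.end()
    for p in polarity.affirm:
        m = p.search(after)
        if m:
            return TriState.PRESENT, head.start(), head.end() + m.end()
    return None


def extract_tristate(
    segments: List[ReportSegment],
    feature: str,
    lex: Optional[FeatureLexicon] = None,
    polarity: Optional[Polarity] = None,
) -> Tuple[TriState, Optional[Span]]:
    if feature not in TRISTATE_FEATURES:
        raise ValueError(f"not a tri-state feature: {feature}")
    lex = lex or load_lexicons()[feature]
    polarity = polarity or load_polarity()
    candidates = []
    for seg, line, start in _iter_lines(segments):
        head = lex.find_head(line)
        if head is None:
            continue
        call = _tristate_on_line(line, head, polarity)
        if call is None:
            continue
        state, lo, hi = call
        candidates.append(
            (seg.header in _RESULT_SEGMENTS, start, (state, Span(start + lo, start + hi)))
        )
    picked = _pick(candidates)
    return (TriState.UNKNOWN, None) if picked is None else picked


def detect_vgp_and_synoptic(
    segments: List[ReportSegment],
    lex: Optional[FeatureLexicon] = None,
    polarity: Optional[Polarity] = None,
    lexicon_dir: Optional[str] = None,
) -> Tuple[bool, bool]:
    """Vertical-growth-phase documentation and synoptic-format detection.

    A report is synoptic when it carries an explicit synoptic marker or a
    results block with at least three labeled feature lines.
    """
    lex = lex or load_lexicons(lexicon_dir)["vertical_growth_phase"]
    polarity = polarity or load_polarity(lexicon_dir)
    lexicons = load_lexicons(lexicon_dir)
    vgp_candidates = []
    n_feature_lines = 0
    synoptic_marker = False
    for seg, line, start in _iter_lines(segments):
        if seg.header == "SYNOPTIC" or _SYNOPTIC_MARKER.search(line):
            synoptic_marker = True
        head = lex.find_head(line)
        if head is not None:
            call = _tristate_on_line(line, head, polarity)
            present = call is not None and call[0] == TriState.PRESENT
            vgp_candidates.append((seg.header in _RESULT_SEGMENTS, start, present))
        if seg.header in _RESULT_SEGMENTS and _LABELED_LINE.match(line):
            label = line.split(":", 1)[0]
            if any(
                lx.find_head(label) is not None
                for name, lx in lexicons.items()
            ):
                n_feature_lines += 1
    vgp = bool(_pick(vgp_candidates))
    return vgp, synoptic_marker or n_feature_lines >= 3


def extract_features(
    report: RawReport, lexicon_dir: Optional[str] = None
) -> Extraction:
    """Run every rule pass over one report; deterministic, total."""
    if not report.text or not report.text.strip():
        logger.warning("empty report text: %s", report.report_id)
        return Extraction(FeatureSet(), warnings=["empty report text"])
    lexicons = load_lexicons(lexicon_dir)
    polarity = load_polarity(lexicon_dir)
    segments = segment_report(report.text)
    spans: Dict[str, Span] = {}

    til, s = extract_til_grade(segments, lexicons["til_grade"])
    if s:
        spans["til_grade"] = s
    breslow, s = extract_breslow_mm(segments, lexicons["breslow_mm"])
    if s:
        spans["breslow_mm"] = s
    mitotic, s = extract_mitotic_rate(segments, lexicons["mitotic_rate"])
    if s:
        spans["mitotic_rate"] = s
    tri: Dict[str, TriState] = {}
    for feat in TRISTATE_FEATURES:
        tri[feat], s = extract_tristate(segments, feat, lexicons[feat], polarity)
        if s:
            spans[feat] = s
    vgp, synoptic = detect_vgp_and_synoptic(
        segments, lexicons["vertical_growth_phase"], polarity, lexicon_dir
    )
    fs = FeatureSet(
        til_grade=til,
        breslow_mm=breslow,
        mitotic_rate=mitotic,
        vertical_growth_phase=vgp,
        is_synoptic=synoptic,
        **tri,
    )
    return Extraction(fs, spans)
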