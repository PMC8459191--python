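"""Plain-text serialization: report corpus, gold labels, feature sets.

Everything on disk is inspectable: one UTF-8 ``.txt`` per report, JSON-Lines
manifests and feature files, CSV patient metadata.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd

from .extractor import Extraction
from .features import FeatureSet, RawReport
from .generator import Corpus


def _jsonify(value):
    if isinstance(value, date):
        return value.isoformat()
    return value


def write_corpus(corpus: Corpus, outdir: Path) -> None:
    outdir = Path(outdir)
    reports_dir = outdir / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for r in corpus.reports:
        (reports_dir / f"{r.report_id}.txt").write_text(r.text, encoding="utf-8")
        manifest.append(
            {
                "report_id": r.report_id,
                "patient_id": r.patient_id,
                "report_date": r.report_date.isoformat(),
            }
        )
    _write_jsonl(outdir / "manifest.jsonl", manifest)
    _write_jsonl(
        outdir / "gold_reports.jsonl",
        [
            {"report_id": rid, **fs.to_dict()}
            for rid, fs in sorted(corpus.report_gold.items())
        ],
    )
    _write_jsonl(
        outdir / "gold_patients.jsonl",
        [
            {
                "patient_id": g.patient_id,
                "diagnosis_date": g.diagnosis_date.isoformat(),
                "eligible": g.eligible,
                "primary_invasive": g.primary_invasive,
                "true_event_time_years": (
                    g.true_event_time_years
                    if g.true_event_time_years != float("inf")
                    else None
                ),
                **{f"true_{k}": _jsonify(v) for k, v in g.true_features.to_dict().items()},
            }
            for g in corpus.gold
        ],
    )
    pts = corpus.patients.copy()
    pts.to_csv(outdir / "patients.csv", index=False)


def read_corpus_reports(outdir: Path) -> List[RawReport]:
    outdir = Path(outdir)
    reports = []
    for row in _read_jsonl(outdir / "manifest.jsonl"):
        text = (outdir / "reports" / f"{row['report_id']}.txt").read_text("utf-8")
        reports.append(
            RawReport(
                row["report_id"],
                row["patient_id"],
                date.fromisoformat(row["report_date"]),
                text,
            )
        )
    return reports


def read_gold_reports(path: Path) -> Dict[str, FeatureSet]:
    out = {}
    for row in _read_jsonl(Path(path)):
        rid = row.pop("report_id")
        out[rid] = FeatureSet.from_dict(row)
    return out


def write_features_jsonl(
    path: Path, extractions: List[Tuple[RawReport, Extraction]]
) -> None:
    rows = []
    for report, ex in extractions:
        rows.append(
            {
                "report_id": report.report_id,
                "patient_id": report.patient_id,
                "report_date": report.report_date.isoformat(),
                **ex.features.to_dict(),
                "spans": {k: [s.start, s.end] for k, s in ex.spans.items()},
            }
        )
    _write_jsonl(Path(path), rows)


def read_features_jsonl(path: Path) -> List[dict]:
    return _read_jsonl(Path(path))


def _write_jsonl(path: Path, rows: List[dict]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(json.dumps(row, default=_jsonify) + "\n")


def _read_jsonl(path: Path) -> List[dict]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    return rows


def read_patients_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, parse_dates=["dob", "death_date", "last_followup_date"]
    )
    return df
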