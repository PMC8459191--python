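"""End-to-end orchestration: generate -> extract -> evaluate -> cohort ->
table one -> survival analysis, with a reproducible run manifest.

Every stage reads and writes plain CSV/JSONL artifacts so any step can be
inspected or replaced; the manifest records the configuration hash, seed
and a SHA-256 digest of every artifact, so identical inputs reproduce
identical digests (timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from datetime import date
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import __version__
from .cohort import ReportFeatures, select_cohort
from .config import GeneratorConfig
from .evaluate import evaluate_corpus
from .extractor import extract_features
from .generator import generate_corpus
from .io import write_corpus, write_features_jsonl
from .survival import (
    MULTIVARIABLE_TERMS,
    cox_fit,
    km_fit,
    km_survival_at,
    logrank_test,
    reverse_km_median_followup,
    subgroup_analysis,
    univariable_scan,
)
from .tableone import build_table_one, table_one_frame

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _digest_tree(root: Path) -> Dict[str, str]:
    return {
        str(p.relative_to(root)): _digest(p)
        for p in sorted(root.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }


def run_pipeline(config: GeneratorConfig, outdir: Path) -> dict:
    """Run every stage in order; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    logger.info("stage generate: n_patients=%d seed=%d", config.n_patients, config.seed)
    corpus = generate_corpus(config)
    write_corpus(corpus, outdir)
    logger.info("generated %d reports for %d patients", len(corpus.reports), config.n_patients)

    logger.info("stage extract")
    extractions = [(r, extract_features(r)) for r in corpus.reports]
    write_features_jsonl(outdir / "features.jsonl", extractions)

    logger.info("stage evaluate")
    predicted = {r.report_id: ex.features for r, ex in extractions}
    result = evaluate_corpus(corpus.report_gold, predicted)
    (outdir / "metrics.json").write_text(json.dumps(result.to_dict(), indent=2))
    logger.info("report-level accuracy %.4f", result.accuracy)

    logger.info("stage cohort")
    rf = [
        ReportFeatures(r.report_id, r.patient_id, r.report_date, ex.features)
        for r, ex in extractions
    ]
    cohort, exclusions = select_cohort(
        rf, corpus.patients, admin_censor_date=config.admin_censor_date
    )
    cohort.to_csv(outdir / "cohort.csv", index=False)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    logger.info(
        "cohort %d of %d patients (%s)",
        len(cohort),
        len(corpus.patients),
        exclusions["reason"].value_counts().to_dict() if len(exclusions) else {},
    )

    logger.info("stage table-one")
    t1 = build_table_one(cohort)
    table_one_frame(t1).to_csv(outdir / "table1.csv", index=False)

    logger.info("stage analyze")
    analyze_cohort(cohort, outdir)

    manifest = {
        "tool_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            config.model_dump_json().encode()
        ).hexdigest(),
        "config": json.loads(config.model_dump_json()),
        "artifacts": _digest_tree(outdir),
        "elapsed_seconds": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def analyze_cohort(cohort: pd.DataFrame, outdir: Path) -> dict:
    """Survival-analysis stage: KM curves, log-rank, follow-up, Cox models."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}

    curves = []
    overall = km_fit(cohort["os_years"], cohort["event"], label="overall")
    curves.append(overall)
    groups = {}
    for g, sub in cohort.groupby("til_grade"):
        groups[g] = (sub["os_years"].values, sub["event"].values)
        curves.append(km_fit(*groups[g], label=f"til_{g}"))
    km_rows = []
    for c in curves:
        for i in range(len(c.event_times)):
            km_rows.append(
                {
                    "group": c.label,
                    "time": c.event_times[i],
                    "at_risk": c.at_risk[i],
                    "deaths": c.deaths[i],
                    "survival": c.survival[i],
                    "ci_lower": c.ci_lower[i],
                    "ci_upper": c.ci_upper[i],
                }
            )
    pd.DataFrame(km_rows).to_csv(outdir / "km_curves.csv", index=False)

    s5, ci5 = km_survival_at(overall, 5.0)
    out["five_year_os"] = {"estimate": s5, "ci95": list(ci5)}

    if len(groups) >= 2:
        lr = logrank_test(list(groups.values()))
        out["logrank"] = {"chi2": lr.chi2, "df": lr.df, "p": lr.p}

    fu = reverse_km_median_followup(cohort["os_years"], cohort["event"])
    out["followup"] = {
        "median_years": fu.median_followup_years,
        "iqr": list(fu.iqr),
    }

    uni = univariable_scan(cohort, list(MULTIVARIABLE_TERMS))
    out["cox_univariable"] = {
        var: _cox_dict(res) for var, res in uni.items()
    }
    multi = cox_fit(cohort, [], adjustment="multivariable")
    out["cox_multivariable"] = _cox_dict(multi)

    for stratifier in ("sex", "t_stage"):
        strata = subgroup_analysis(cohort, stratifier)
        out[f"subgroup_{stratifier}"] = {
            s.stratum: {
                "chi2": s.logrank.chi2,
                "p": s.logrank.p,
                "p_bonferroni": s.p_adjusted,
            }
            for s in strata
        }

    (outdir / "analysis.json").write_text(json.dumps(out, indent=2, default=float))
    return out


def _cox_dict(res) -> dict:
    return {
        "model": res.model,
        "n_used": res.n_used,
        "n_events": res.n_events,
        "terms": {
            name: dataclasses.asdict(term) for name, term in res.terms.items()
        },
        "reference_levels": res.reference_levels,
    }
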