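#!/usr/bin/env python
"""Generate the synthetic pathology-report archive.

Creates a scaled-down single-institution archive (default 4 000 patients,
~5 200 reports) with gold labels and patient metadata, writing report text
under scratch/corpus/ and a small summary under results/.  Roughly 18% of
patients carry an eligible report (TIL grade assessed, vertical growth
phase documented, synoptic format), mirroring the funnel from archive to
study cohort.
"""

import argparse
import json
from pathlib import Path

from melatil.config import GeneratorConfig
from melatil.generator import generate_corpus
from melatil.io import write_corpus

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-patients", type=int, default=4000)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "corpus")
    args = ap.parse_args()

    config = GeneratorConfig(n_patients=args.n_patients, seed=args.seed)
    corpus = generate_corpus(config)
    write_corpus(corpus, args.out)

    n_eligible = sum(g.eligible for g in corpus.gold)
    summary = {
        "n_patients": config.n_patients,
        "n_reports": len(corpus.reports),
        "n_gold_eligible": n_eligible,
        "eligible_fraction_pct": round(100 * n_eligible / config.n_patients, 1),
        "seed": config.seed,
    }
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "corpus_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(
        f"wrote {summary['n_reports']} reports for {config.n_patients} patients "
        f"to {args.out}; {n_eligible} patients ({summary['eligible_fraction_pct']}%) "
        "carry an eligible synoptic report"
    )


if __name__ == "__main__":
    main()
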