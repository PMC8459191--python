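#!/usr/bin/env python
"""Descriptive statistics by TIL grade (the cohort characteristics table).

Summarizes age, sex, Breslow thickness, T category, mitotic rate and the
tri-state findings per TIL grade, choosing Kruskal-Wallis for continuous
variables and chi-square or Fisher exact (any observed cell < 5) for
categorical ones.  Writes results/table1.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from melatil.tableone import build_table_one, table_one_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort.csv")
    args = ap.parse_args()

    cohort = pd.read_csv(args.cohort)
    rows = build_table_one(cohort)
    frame = table_one_frame(rows)
    out = ROOT / "results" / "table1.csv"
    frame.to_csv(out, index=False)
    shown = frame[["variable", "test", "p"]].to_string(index=False)
    print(f"wrote {out}\n{shown}")


if __name__ == "__main__":
    main()
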