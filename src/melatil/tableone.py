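"""Descriptive table with the study's test-selection rule.

Continuous variables are compared across TIL grades with the
Kruskal-Wallis rank test; categorical variables with the Pearson chi-square
test, switching to the Fisher exact test when any observed cell count is
below 5 (the rule is configurable to expected-count mode).  For tables
larger than 2x2, the Fisher p value is computed by exact enumeration of all
tables with the observed margins when the grand total is small enough, and
otherwise by seeded Monte-Carlo sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

FISHER_CELL_THRESHOLD = 5


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded as printed in descriptive tables."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, decimals)
EXACT_ENUMERATION_MAX_TOTAL = 200
MC_TABLES = 100_000
MC_SEED = 20211


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p value."""
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >=2 non-empty groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def _log_table_prob(table: np.ndarray, lgamma=math.lgamma) -> float:
    """Log multivariate-hypergeometric probability of an r x c table."""
    rs = table.sum(axis=1)
    cs = table.sum(axis=0)
    n = table.sum()
    out = sum(lgamma(r + 1) for r in rs) + sum(lgamma(c + 1) for c in cs)
    out -= lgamma(n + 1)
    out -= sum(lgamma(x + 1) for x in table.ravel())
    return out


def _enumerate_fisher(table: np.ndarray) -> float:
    """Exact two-sided Fisher p by enumerating tables with fixed margins.

    Two-sided in the standard probability-ordering sense: sum the
    probabilities of all tables no more probable than the observed one.
    """
    rs = table.sum(axis=1).astype(int)
    cs = table.sum(axis=0).astype(int)
    obs_lp = _log_table_prob(table)
    tol = 1e-7
    r, c = table.shape
    total_p = 0.0

    current = np.zeros((r, c), dtype=int)

    def rec(row: int, remaining_cols: np.ndarray):
        nonlocal total_p
        if row == r - 1:
            current[row, :] = remaining_cols
            lp = _log_table_prob(current)
            if lp <= obs_lp + tol:
                total_p += math.exp(lp)
            return
        # enumerate row `row` cell by cell
        def cell(j: int, left_in_row: int, cols: np.ndarray):
            if j == c - 1:
                if left_in_row <= cols[j]:
                    current[row, j] = left_in_row
                    cols2 = cols.copy()
                    cols2[j] -= left_in_row
                    rec(row + 1, cols2)
                return
            # cell value bounded by row remainder and column remainder,
            # and must leave enough capacity in later columns
            later = int(cols[j + 1 :].sum())
            lo = max(0, left_in_row - later)
            hi = min(left_in_row, int(cols[j]))
            for v in range(lo, hi + 1):
                current[row, j] = v
                cols2 = cols.copy()
                cols2[j] -= v
                cell(j + 1, left_in_row - v, cols2)

        cell(0, int(rs[row]), remaining_cols)

    rec(0, cs.copy())
    return min(1.0, total_p)


def _montecarlo_fisher(
    table: np.ndarray, n_tables: int = MC_TABLES, seed: int = MC_SEED
) -> float:
    """Seeded Monte-Carlo Fisher p for large tables.

    Tables are sampled uniformly over the fixed margins by drawing each row
    from a multivariate hypergeometric of the remaining column totals.
    """
    rng = np.random.default_rng(seed)
    rs = table.sum(axis=1).astype(int)
    cs = table.sum(axis=0).astype(int)
    obs_lp = _log_table_prob(table)
    tol = 1e-7
    hits = 0
    r = table.shape[0]
    for _ in range(n_tables):
        cols = cs.copy()
        sample = np.zeros_like(table)
        for i in range(r - 1):
            draw = rng.multivariate_hypergeometric(cols, int(rs[i]))
            sample[i, :] = draw
            cols = cols - draw
        sample[r - 1, :] = cols
        if _log_table_prob(sample) <= obs_lp + tol:
            hits += 1
    return (hits + 1) / (n_tables + 1)


def fisher_exact_rxc(
    table: np.ndarray,
    max_exact_total: int = EXACT_ENUMERATION_MAX_TOTAL,
    seed: int = MC_SEED,
) -> float:
    """Two-sided Fisher exact p for an r x c table."""
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if table.sum() <= max_exact_total:
        return _enumerate_fisher(table)
    return _montecarlo_fisher(table, seed=seed)


def categorical_test(
    table: np.ndarray, rule: str = "observed"
) -> Tuple[str, Optional[float], float]:
    """Apply the test-selection rule to a contingency table.

    Returns (test name, statistic or None, p).  ``rule="observed"`` selects
    Fisher when any observed cell is below 5; ``"expected"`` uses the
    chi-square expected counts instead.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        table = table[keep_r][:, keep_c]
        if min(table.shape) < 2:
            raise ValueError("table degenerate after dropping zero margins")
    itable = table.astype(int)
    if rule == "observed":
        sparse = bool((itable < FISHER_CELL_THRESHOLD).any())
    elif rule == "expected":
        expected = stats.contingency.expected_freq(itable)
        sparse = bool((expected < FISHER_CELL_THRESHOLD).any())
    else:
        raise ValueError(f"unknown rule: {rule}")
    if sparse:
        return "fisher", None, fisher_exact_rxc(itable)
    chi2, p, _, _ = stats.chi2_contingency(itable, correction=False)
    return "chi2", float(chi2), float(p)


@dataclass
class TableOneRow:
    variable: str
    kind: str  # "continuous" | "categorical"
    summaries: Dict[str, str]  # group label -> rendered summary
    counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    test: Optional[str] = None
    statistic: Optional[float] = None
    p: Optional[float] = None


def _median_iqr(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return "NA"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


TIL_ORDER = ("absent", "nonbrisk", "brisk")

CATEGORY_ORDERS = {
    "age_group": ("<50", "50-69", ">=70"),
    "sex": ("female", "male"),
    "t_stage": ("T1", "T2", "T3", "T4", "unknown"),
    "ulceration": ("absent", "present", "unknown"),
    "histologic_regression": ("absent", "present", "unknown"),
    "microsatellites": ("absent", "present", "unknown"),
    "vascular_lymphatic_invasion": ("absent", "present", "unknown"),
}


def build_table_one(
    cohort: pd.DataFrame, group_col: str = "til_grade", rule: str = "observed"
) -> List[TableOneRow]:
    """Per-TIL-grade descriptive rows with the test-selection rule applied."""
    if cohort.empty:
        raise ValueError("empty cohort")
    groups = [g for g in TIL_ORDER if g in set(cohort[group_col])]
    if not groups:
        groups = sorted(set(cohort[group_col]))
    subframes = {g: cohort[cohort[group_col] == g] for g in groups}
    single = len(groups) < 2

    rows: List[TableOneRow] = []

    def continuous(variable: str, label: str) -> None:
        summaries = {g: _median_iqr(subframes[g][variable]) for g in groups}
        row = TableOneRow(label, "continuous", summaries)
        if not single:
            samples = [subframes[g][variable].dropna().values for g in groups]
            if all(len(s) for s in samples):
                row.test = "kruskal_wallis"
                row.statistic, row.p = kruskal_wallis(samples)
        rows.append(row)

    def categorical(variable: str, label: str) -> None:
        order = CATEGORY_ORDERS.get(variable) or tuple(
            sorted(cohort[variable].dropna().unique())
        )
        cats = [c for c in order if (cohort[variable] == c).any()]
        counts = {
            g: {c: int((subframes[g][variable] == c).sum()) for c in cats}
            for g in groups
        }
        summaries = {}
        for g in groups:
            total = sum(counts[g].values())
            summaries[g] = "; ".join(
                f"{c}: {counts[g][c]} ({100 * counts[g][c] / total:.1f}%)"
                for c in cats
            )
        row = TableOneRow(label, "categorical", summaries, counts=counts)
        if not single and len(cats) >= 2:
            table = np.array([[counts[g][c] for g in groups] for c in cats])
            row.test, row.statistic, row.p = categorical_test(table, rule=rule)
        rows.append(row)

    continuous("age_years", "Age, median (IQR), y")
    categorical("age_group", "Age group")
    categorical("sex", "Sex")
    continuous("breslow_mm", "Breslow thickness, median (IQR), mm")
    categorical("t_stage", "T category")
    continuous("mitotic_rate", "Mitotic rate, median (IQR)")
    for var, label in (
        ("ulceration", "Ulceration"),
        ("histologic_regression", "Histologic regression"),
        ("microsatellites", "Microscopic satellites"),
        ("vascular_lymphatic_invasion", "Vascular/lymphatic invasion"),
    ):
        categorical(var, label)
    return rows


def table_one_frame(rows: List[TableOneRow]) -> pd.DataFrame:
    """Flatten TableOneRows for CSV export."""
    records = []
    for row in rows:
        rec = {"variable": row.variable, "kind": row.kind}
        rec.update({f"group_{g}": s for g, s in row.summaries.items()})
        rec.update(test=row.test, statistic=row.statistic, p=row.p)
        records.append(rec)
    return pd.DataFrame(records)
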