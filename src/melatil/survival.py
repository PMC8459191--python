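"""Survival analysis: Kaplan-Meier, log-rank, reverse-KM follow-up, Cox.

Estimation is delegated to lifelines (product-limit with Greenwood
variance, exponential-Greenwood log(-log) confidence bands, k-sample
log-rank, Cox partial likelihood with Efron tie handling); this module owns
the study's covariate encodings and result containers.

Covariate encodings mirror the published analysis: age strata (<50
reference), sex (female reference), TIL grade (absent reference),
continuous Breslow thickness per mm, continuous mitotic rate per unit, and
tri-state findings with an explicit Unknown level (absent reference).  The
multivariable model drops patients with unknown Breslow thickness; whether
histologic regression enters it is configurable, since the published
adjusted model lists it among adjustment variables but reports no estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import qth_survival_time

logger = logging.getLogger(__name__)


# --- containers -----------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    label: str = ""


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass
class CoxTerm:
    coef: float
    se: float
    hr: float
    ci_lower: float
    ci_upper: float
    p: float


@dataclass
class CoxResult:
    model: str  # "univariable" | "multivariable"
    terms: Dict[str, CoxTerm]
    n_used: int
    n_events: int
    reference_levels: Dict[str, str] = field(default_factory=dict)


@dataclass
class FollowupSummary:
    median_followup_years: float
    iqr: Tuple[float, float]


# --- Kaplan-Meier ---------------------------------------------------------

def km_fit(os_years: Sequence[float], event: Sequence[int], label: str = "") -> KMCurve:
    """Kaplan-Meier estimate with Greenwood variance and log(-log) 95% CI."""
    t = np.asarray(os_years, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.size != e.size:
        raise ValueError("os_years and event lengths differ")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(t, e, label=label or "KM")
    table = kmf.event_table
    is_event = table["observed"] > 0
    times = table.index.values[is_event.values].astype(float)
    d = table["observed"].values[is_event.values].astype(float)
    n = table["at_risk"].values[is_event.values].astype(float)
    surv = kmf.survival_function_.values.ravel()
    surv_at = np.array([kmf.predict(x) for x in times], dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n > d, d / (n * (n - d)), np.inf)
    var = surv_at**2 * np.cumsum(inc)
    var = np.where(np.isfinite(var), var, 0.0)
    ci = kmf.confidence_interval_survival_function_
    lo = np.array([_step_lookup(ci.index.values, ci.iloc[:, 0].values, x) for x in times])
    hi = np.array([_step_lookup(ci.index.values, ci.iloc[:, 1].values, x) for x in times])
    return KMCurve(times, n, d, surv_at, var, lo, hi, label=label)


def _step_lookup(times: np.ndarray, values: np.ndarray, t: float) -> float:
    idx = np.searchsorted(times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(values[idx])


def km_survival_at(curve: KMCurve, t: float) -> Tuple[float, Tuple[float, float]]:
    """Right-continuous lookup of S(t) and its 95% CI."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if curve.event_times.size and t > curve.event_times[-1]:
        logger.warning("t=%g beyond last event time; returning last estimate", t)
    est = _step_lookup(curve.event_times, curve.survival, t)
    lo = _step_lookup(curve.event_times, curve.ci_lower, t)
    hi = _step_lookup(curve.event_times, curve.ci_upper, t)
    return est, (lo, hi)


# --- log-rank -------------------------------------------------------------

def logrank_test(
    groups: Sequence[Tuple[Sequence[float], Sequence[int]]]
) -> LogRankResult:
    """k-sample log-rank chi-square with df = k - 1."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {gi} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, gi))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return LogRankResult(
        chi2=float(res.test_statistic), df=len(groups) - 1, p=float(res.p_value)
    )


# --- reverse KM -----------------------------------------------------------

def reverse_km_median_followup(
    os_years: Sequence[float], event: Sequence[int]
) -> FollowupSummary:
    """Median potential follow-up by the reverse Kaplan-Meier method.

    The censoring indicator is inverted (deaths become the censored
    observations); the median and quartiles of the resulting curve estimate
    the follow-up distribution free of mortality.
    """
    t = np.asarray(os_years, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, 1 - e)
    sf = kmf.survival_function_[kmf.survival_function_.columns[0]]
    median = float(qth_survival_time(0.5, sf))
    q1 = float(qth_survival_time(0.75, sf))  # 25th percentile of follow-up
    q3 = float(qth_survival_time(0.25, sf))
    return FollowupSummary(median_followup_years=median, iqr=(q1, q3))


# --- Cox ------------------------------------------------------------------

#: Encodable model variables and their reference levels.
REFERENCE_LEVELS = {
    "age_group": "<50",
    "sex": "female",
    "til_grade": "absent",
    "ulceration": "absent",
    "histologic_regression": "absent",
    "microsatellites": "absent",
    "vascular_lymphatic_invasion": "absent",
}

TRISTATE_VARS = (
    "ulceration",
    "histologic_regression",
    "microsatellites",
    "vascular_lymphatic_invasion",
)

#: Design-matrix columns produced for each model variable.
_ENCODERS = {
    "age_group": lambda df: pd.DataFrame(
        {
            "age_50_69": (df["age_group"] == "50-69").astype(float),
            "age_70plus": (df["age_group"] == ">=70").astype(float),
        }
    ),
    "sex": lambda df: pd.DataFrame({"sex_male": (df["sex"] == "male").astype(float)}),
    "til_grade": lambda df: pd.DataFrame(
        {
            "til_brisk": (df["til_grade"] == "brisk").astype(float),
            "til_nonbrisk": (df["til_grade"] == "nonbrisk").astype(float),
        }
    ),
    "breslow_mm": lambda df: pd.DataFrame(
        {"breslow_per_mm": df["breslow_mm"].astype(float)}
    ),
    "mitotic_rate": lambda df: pd.DataFrame(
        {"mitotic_per_unit": df["mitotic_rate"].astype(float)}
    ),
    **{
        v: (
            lambda df, v=v: pd.DataFrame(
                {
                    f"{v}_present": (df[v] == "present").astype(float),
                    f"{v}_unknown": (df[v] == "unknown").astype(float),
                }
            )
        )
        for v in TRISTATE_VARS
    },
}

MULTIVARIABLE_TERMS = (
    "age_group",
    "sex",
    "til_grade",
    "breslow_mm",
    "mitotic_rate",
    "ulceration",
    "microsatellites",
    "vascular_lymphatic_invasion",
)


def _design(cohort: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    parts = [_ENCODERS[v](cohort) for v in terms]
    X = pd.concat(parts, axis=1)
    X.index = cohort.index
    return X


def cox_fit(
    cohort: pd.DataFrame,
    terms: Sequence[str],
    adjustment: str = "multivariable",
    include_regression: bool = False,
) -> CoxResult:
    """Cox proportional-hazards fit with the study's encodings.

    ``adjustment="univariable"`` fits the given variable(s) alone;
    ``"multivariable"`` fits the adjusted covariate set (ignoring ``terms``)
    and drops rows with unknown Breslow thickness or mitotic rate, emitting
    the row count actually used.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    if adjustment not in ("univariable", "multivariable"):
        raise ValueError(f"unknown adjustment: {adjustment}")
    df = cohort.copy()
    if adjustment == "multivariable":
        terms = list(MULTIVARIABLE_TERMS)
        if include_regression:
            terms.insert(terms.index("microsatellites"), "histologic_regression")
        df = df[df["breslow_mm"].notna() & df["mitotic_rate"].notna()]
    else:
        for v in terms:
            if v in ("breslow_mm", "mitotic_rate"):
                df = df[df[v].notna()]
    X = _design(df, terms)
    data = X.assign(os_years=df["os_years"].values, event=df["event"].values)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(data, duration_col="os_years", event_col="event")
        except Exception as err:  # lifelines raises ConvergenceError
            raise RuntimeError(f"Cox fit failed: {err}") from err
    summary = cph.summary
    result_terms = {
        name: CoxTerm(
            coef=float(row["coef"]),
            se=float(row["se(coef)"]),
            hr=float(row["exp(coef)"]),
            ci_lower=float(row["exp(coef) lower 95%"]),
            ci_upper=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
        )
        for name, row in summary.iterrows()
    }
    refs = {v: REFERENCE_LEVELS[v] for v in terms if v in REFERENCE_LEVELS}
    return CoxResult(
        model=adjustment,
        terms=result_terms,
        n_used=int(data.shape[0]),
        n_events=int(data["event"].sum()),
        reference_levels=refs,
    )


def univariable_scan(cohort: pd.DataFrame, variables: Sequence[str]) -> Dict[str, CoxResult]:
    """One univariable Cox fit per model variable."""
    return {v: cox_fit(cohort, [v], adjustment="univariable") for v in variables}


# --- subgroup analysis ----------------------------------------------------

@dataclass
class StratumResult:
    stratum: str
    curves: Dict[str, KMCurve]
    logrank: LogRankResult
    p_adjusted: float


def subgroup_analysis(
    cohort: pd.DataFrame,
    stratifier: str,
    group_col: str = "til_grade",
) -> List[StratumResult]:
    """Per-stratum KM + log-rank across TIL grades, Bonferroni-adjusted.

    The multiplicity count m is the number of strata actually tested within
    this one stratifier; strata with fewer than two TIL groups are skipped
    and logged.
    """
    if stratifier not in cohort.columns:
        raise ValueError(f"stratifier {stratifier!r} not in cohort")
    tested = []
    for stratum, sub in cohort.groupby(stratifier, sort=True):
        groups = {
            str(g): (s["os_years"].values, s["event"].values)
            for g, s in sub.groupby(group_col)
            if len(s) > 0
        }
        if len(groups) < 2:
            logger.info("stratum %s skipped: fewer than 2 %s groups", stratum, group_col)
            continue
        lr = logrank_test(list(groups.values()))
        curves = {g: km_fit(t, e, label=g) for g, (t, e) in groups.items()}
        tested.append((str(stratum), curves, lr))
    m = len(tested)
    return [
        StratumResult(s, c, lr, p_adjusted=min(1.0, m * lr.p)) for s, c, lr in tested
    ]
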