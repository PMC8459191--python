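"""Extraction-quality scoring against gold labels.

Report-level metrics follow the information-extraction convention:

* accuracy  = reports with every feature correctly extracted / reports evaluated
* precision = reports with correctly identified results / reports with results identified
* recall    = reports with correctly identified results / reports with results
* F1        = 2 * precision * recall / (precision + recall)

"Correctly extracted" at report level means all features exact-match, where
a feature omitted by the report (gold unknown) must also be called unknown.
A per-feature breakdown with the same four counts is reported alongside.
Numeric comparisons tolerate 0.005 mm (Breslow) and 0.5/mm^2 (mitotic rate)
so string-rendered decimals never fail on formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

from .features import SEVEN_FEATURES, FeatureSet, TILGrade, TriState

BRESLOW_TOL = 0.005
MITOTIC_TOL = 0.5


def _has_result(fs: FeatureSet, feature: str) -> bool:
    v = getattr(fs, feature)
    if feature == "til_grade":
        return v != TILGrade.NOT_ASSESSED
    if feature in ("breslow_mm", "mitotic_rate"):
        return v is not None
    return v != TriState.UNKNOWN


def _match(gold: FeatureSet, pred: FeatureSet, feature: str) -> bool:
    g, p = getattr(gold, feature), getattr(pred, feature)
    if feature == "breslow_mm":
        if g is None or p is None:
            return g is None and p is None
        return abs(g - p) <= BRESLOW_TOL
    if feature == "mitotic_rate":
        if g is None or p is None:
            return g is None and p is None
        return abs(g - p) <= MITOTIC_TOL
    return g == p


@dataclass
class Counts:
    """Confusion counts at one granularity (overall or per feature)."""

    n_evaluated: int = 0
    n_correct: int = 0
    n_identified: int = 0
    n_with_results: int = 0
    n_exact: int = 0  # exact matches including unknown==unknown

    def __post_init__(self) -> None:
        if self.n_correct > min(self.n_identified, self.n_with_results):
            raise ValueError("n_correct exceeds its denominators")


@dataclass
class EvalResult:
    n_evaluated: int
    n_correct: int
    n_identified: int
    n_with_results: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_feature: Dict[str, "EvalResult"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_evaluated", "n_correct", "n_identified", "n_with_results",
                "accuracy", "precision", "recall", "f1",
            )
        }
        if self.per_feature:
            d["per_feature"] = {k: v.to_dict() for k, v in self.per_feature.items()}
        return d


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def score_corpus(
    gold: Mapping[str, FeatureSet], predicted: Mapping[str, FeatureSet]
) -> Dict[str, Counts]:
    """Count confusion events per feature and at report level.

    ``gold`` and ``predicted`` map report_id -> FeatureSet and must cover
    the same reports.
    """
    if set(gold) != set(predicted):
        raise ValueError("gold and predicted report id sets differ")
    if not gold:
        raise ValueError("empty corpus")
    counts = {"__report__": Counts(), **{f: Counts() for f in SEVEN_FEATURES}}
    for rid in gold:
        g, p = gold[rid], predicted[rid]
        all_exact = True
        any_gold = any_pred = False
        for feat in SEVEN_FEATURES:
            c = counts[feat]
            c.n_evaluated += 1
            has_g, has_p = _has_result(g, feat), _has_result(p, feat)
            any_gold |= has_g
            any_pred |= has_p
            ok = _match(g, p, feat)
            all_exact &= ok
            if has_g:
                c.n_with_results += 1
            if has_p:
                c.n_identified += 1
            if ok:
                c.n_exact += 1
                if has_g and has_p:
                    c.n_correct += 1
        r = counts["__report__"]
        r.n_evaluated += 1
        if any_gold:
            r.n_with_results += 1
        if any_pred:
            r.n_identified += 1
        if all_exact:
            r.n_exact += 1
            if any_gold and any_pred:
                r.n_correct += 1
    return counts


def compute_metrics(counts: Counts) -> EvalResult:
    """The four metric ratios from one set of counts."""
    if counts.n_evaluated == 0:
        raise ValueError("no reports evaluated")
    accuracy = counts.n_exact / counts.n_evaluated
    precision = counts.n_correct / counts.n_identified if counts.n_identified else 0.0
    recall = counts.n_correct / counts.n_with_results if counts.n_with_results else 0.0
    return EvalResult(
        n_evaluated=counts.n_evaluated,
        n_correct=counts.n_correct,
        n_identified=counts.n_identified,
        n_with_results=counts.n_with_results,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
    )


def evaluate_corpus(
    gold: Mapping[str, FeatureSet], predicted: Mapping[str, FeatureSet]
) -> EvalResult:
    """Report-level metrics with the per-feature breakdown attached."""
    counts = score_corpus(gold, predicted)
    result = compute_metrics(counts["__report__"])
    result.per_feature = {f: compute_metrics(counts[f]) for f in SEVEN_FEATURES}
    return result
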