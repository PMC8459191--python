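"""Independent from-definition oracles used by the test suite.

Each oracle recomputes a statistic directly from its textbook definition
(explicit products over risk sets, exhaustive enumeration) without touching
the package's analysis code paths.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Sequence, Tuple

import numpy as np


def km_product_oracle(times: Sequence[float], events: Sequence[int]):
    """Brute-force product-limit estimate.

    Returns (distinct event times, S values) via the explicit product
    S(t) = prod_{t_i <= t} (1 - d_i / n_i).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = sorted(set(times[events == 1]))
    surv = []
    s = 1.0
    for t in event_times:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return np.asarray(event_times), np.asarray(surv)


def logrank_score_oracle(
    times1: Sequence[float],
    events1: Sequence[int],
    times2: Sequence[float],
    events2: Sequence[int],
) -> float:
    """Two-group log-rank chi-square from first principles.

    Walks the pooled distinct event times, accumulating the observed minus
    hypergeometric-expected deaths in group 1 and the hypergeometric
    variance; the statistic is U^2 / V.
    """
    t1 = np.asarray(times1, dtype=float)
    e1 = np.asarray(events1, dtype=int)
    t2 = np.asarray(times2, dtype=float)
    e2 = np.asarray(events2, dtype=int)
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(t1.size), np.ones(t2.size)])
    u = 0.0
    v = 0.0
    for t in sorted(set(all_t[all_e == 1])):
        at_risk = all_t >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (grp == 0)).sum())
        dying = (all_t == t) & (all_e == 1)
        d = int(dying.sum())
        d1 = int((dying & (grp == 0)).sum())
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0
    return u * u / v


def logrank_permutation_distribution(
    times: Sequence[float], events: Sequence[int], n_group1: int
) -> List[float]:
    """Exhaustive permutation distribution of the two-group log-rank statistic.

    Enumerates every assignment of `n_group1` of the subjects to group 1 and
    recomputes the score statistic from scratch for each.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = times.size
    stats = []
    for combo in itertools.combinations(range(n), n_group1):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        stats.append(
            logrank_score_oracle(times[mask], events[mask], times[~mask], events[~mask])
        )
    return stats


def fisher_2x2_oracle(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeometric(n, r1, c1)
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= obs + 1e-7:
            total += math.exp(lp)
    return min(1.0, total)


def kruskal_oracle(samples: Sequence[Sequence[float]]) -> float:
    """Kruskal-Wallis H from its rank definition, with tie correction."""
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    start = 0
    for s in samples:
        k = len(s)
        r_mean = ranks[start : start + k].mean()
        h += k * (r_mean - (n + 1) / 2) ** 2
        start += k
    h *= 12 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    if correction > 0:
        h /= correction
    return float(h)


def cox_binary_profile_oracle(times, events, groups) -> float:
    """Cox MLE for a single binary covariate, no ties, by direct
    maximization of the log partial likelihood on a fine grid + bisection
    of the score function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(groups, dtype=float)

    def score(beta: float) -> float:
        s = 0.0
        for i in np.where(events == 1)[0]:
            risk = times >= times[i]
            w = np.exp(beta * x[risk])
            s += x[i] - np.sum(w * x[risk]) / np.sum(w)
        return s

    lo, hi = -10.0, 10.0
    if score(lo) * score(hi) > 0:
        return math.inf if score(hi) > 0 else -math.inf
    for _ in range(200):
        mid = (lo + hi) / 2
        if score(lo) * score(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2
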