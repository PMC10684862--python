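"""Independent brute-force oracles used to validate the fast implementations.

Each function here recomputes a quantity by exhaustive enumeration or an
explicit definition-level loop, deliberately sharing no code with the
package paths it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def pam_optimal_cost(d: np.ndarray, k: int) -> float:
    """Global k-medoid optimum by enumerating every medoid subset."""
    n = d.shape[0]
    best = np.inf
    for medoids in combinations(range(n), k):
        cost = sum(min(d[i, m] for m in medoids) for i in range(n))
        best = min(best, cost)
    return float(best)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over one margin.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed that of the observed table (with the usual
    1 + 1e-7 slack for float comparisons).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def auc_pair_counting(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the fraction of (positive, negative) pairs won, ties count 1/2."""
    pos = np.asarray(scores)[np.asarray(y) == 1]
    neg = np.asarray(scores)[np.asarray(y) == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def wilcoxon_exact_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p over all group assignments of the pooled values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    from scipy.stats import rankdata

    ranks = rankdata(pooled, method="average")
    obs = ranks[:nx].sum()
    stats = [ranks[list(idx)].sum() for idx in combinations(range(n), nx)]
    stats = np.asarray(stats)
    lo = (stats <= obs + 1e-9).mean()
    hi = (stats >= obs - 1e-9).mean()
    return float(min(1.0, 2 * min(lo, hi)))


def gsea_es_bruteforce(stats_sorted: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0) -> float:
    """Enrichment score via an explicit position-by-position running sum."""
    N = len(stats_sorted)
    nh = int(hit_mask.sum())
    denom = sum(abs(stats_sorted[i]) ** weight for i in range(N) if hit_mask[i])
    if denom == 0:
        denom = float(nh)
        weights = [1.0 if hit_mask[i] else 0.0 for i in range(N)]
    else:
        weights = [abs(stats_sorted[i]) ** weight if hit_mask[i] else 0.0 for i in range(N)]
    running, best = 0.0, 0.0
    for i in range(N):
        if hit_mask[i]:
            running += weights[i] / denom
        else:
            running -= 1.0 / (N - nh)
        if abs(running) > abs(best):
            best = running
    return best


def km_by_hand(times: np.ndarray, events: np.ndarray) -> dict[float, float]:
    """Product-limit estimate computed from the definition."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    s = 1.0
    out: dict[float, float] = {}
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / at_risk
        out[float(t)] = s
    return out


def logrank_by_hand(times, events, groups) -> float:
    """Two-group log-rank chi-square via the hypergeometric tally."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    gvals = sorted(set(groups.tolist()))
    assert len(gvals) == 2
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (groups == gvals[0])).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (groups == gvals[0])).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)
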