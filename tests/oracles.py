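"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity by direct enumeration or a textbook
formula, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def brute_force_step(x: np.ndarray) -> tuple[int, float]:
    """Best (k, SSE) by trying every split position explicitly."""
    x = np.asarray(x, dtype=float)
    n = x.size
    best_k, best_sse = None, np.inf
    for k in range(1, n):
        left, right = x[:k], x[k:]
        sse = (np.sum((left - left.mean()) ** 2)
               + np.sum((right - right.mean()) ** 2))
        if sse < best_sse:  # strict: first minimum wins
            best_k, best_sse = k, sse
    return best_k, best_sse


def pair_count_auc(scores, labels) -> float:
    """AUC as the concordant-pair fraction with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def step_up_bh(p) -> np.ndarray:
    """BH adjusted p-values by direct p*m/rank with a monotone cap."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def welch_textbook(x, y) -> tuple[float, float, float]:
    """Welch t, Satterthwaite df and two-sided p from the textbook formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def km_by_hand(times, events) -> list[tuple[float, float]]:
    """Product-limit curve by explicit risk-set bookkeeping.

    Events are processed before censored subjects at tied times. Returns
    (time, S(t)) pairs at distinct event times.
    """
    order = sorted(range(len(times)), key=lambda i: (times[i], -events[i]))
    at_risk = len(times)
    s = 1.0
    curve = []
    i = 0
    while i < len(order):
        t = times[order[i]]
        deaths = sum(1 for j in order[i:] if times[j] == t and events[j] == 1)
        total_here = sum(1 for j in order[i:] if times[j] == t)
        if deaths:
            s *= 1.0 - deaths / at_risk
            curve.append((t, s))
        at_risk -= total_here
        i += total_here
    return curve


def logrank_by_hand(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square from hypergeometric increments."""
    all_times = sorted({t for t, e in zip(list(times_a) + list(times_b),
                                          list(events_a) + list(events_b)) if e == 1})
    o_minus_e, var = 0.0, 0.0
    for t in all_times:
        na = sum(1 for x in times_a if x >= t)
        nb = sum(1 for x in times_b if x >= t)
        n = na + nb
        da = sum(1 for x, e in zip(times_a, events_a) if x == t and e == 1)
        db = sum(1 for x, e in zip(times_b, events_b) if x == t and e == 1)
        d = da + db
        if n < 1 or na == 0 or nb == 0:
            # only one group at risk: no information at this time
            o_minus_e += da - d * (na / n) if n else 0.0
            continue
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def hypergeom_tail_by_enumeration(universe: set, gene_set: set, hits: set) -> float:
    """P(overlap >= observed) by enumerating every possible draw of |hits|."""
    universe = sorted(universe)
    observed = len(gene_set & hits)
    total = 0
    extreme = 0
    for draw in combinations(universe, len(hits)):
        total += 1
        if len(set(draw) & gene_set) >= observed:
            extreme += 1
    return extreme / total
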