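"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, direct definitions) and
shares no code with the package paths it validates.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def mann_whitney_enumeration(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of labelings.

    Returns (U for group a, two-sided p).  U counts pairs where a > b plus
    half-ties; the p-value is the probability, over all equally likely
    assignments of the pooled values to groups of sizes |a| and |b|, of a
    U at least as far from its mean as observed.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    mean_u = n1 * len(b) / 2.0
    dev = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    idx = list(range(len(pooled)))
    for comb in combinations(idx, n1):
        sel = set(comb)
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in idx if i not in sel]
        total += 1
        if abs(u_stat(ga, gb) - mean_u) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def pairwise_auc(cases, controls) -> float:
    """AUC as the probability a case outranks a control (half for ties)."""
    s = 0.0
    for x in cases:
        for y in controls:
            if x > y:
                s += 1.0
            elif x == y:
                s += 0.5
    return s / (len(cases) * len(controls))


def quartiles_linear(values) -> tuple[float, float]:
    """Q1/Q3 by linear interpolation between order statistics."""
    x = sorted(values)
    n = len(x)

    def q(p):
        h = (n - 1) * p
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    return q(0.25), q(0.75)


def iqr_flags(values, k=1.5):
    q1, q3 = quartiles_linear(values)
    iqr = q3 - q1
    return [v < q1 - k * iqr or v > q3 + k * iqr for v in values]


def rank_pearson(x, y) -> float:
    """Spearman correlation as the Pearson correlation of mid-ranks."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def youden_scan(scores, labels, lower_indicates_case: bool) -> float:
    """Maximum sensitivity + specificity over every possible threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best = -np.inf
    grid = np.concatenate([
        np.unique(scores) - 1e-9, np.unique(scores) + 1e-9,
        [scores.min() - 1.0, scores.max() + 1.0],
    ])
    for c in grid:
        called = scores < c if lower_indicates_case else scores > c
        sens = (called & labels).sum() / labels.sum()
        spec = (~called & ~labels).sum() / (~labels).sum()
        best = max(best, sens + spec)
    return float(best)
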