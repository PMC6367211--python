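"""Independent brute-force implementations used only as test oracles.

Deliberately naive (O(n^2) ranking, explicit summation formulas) and
written without numpy vector tricks or scipy, so they share no code
path with the package implementations they check.
"""

from __future__ import annotations

import math
from itertools import permutations


def average_ranks(x) -> list[float]:
    """Average ranks (1-based) by pairwise comparison, O(n^2)."""
    ranks = []
    for xi in x:
        less = sum(1 for xj in x if xj < xi)
        equal = sum(1 for xj in x if xj == xi)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def pearson_brute(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def spearman_brute(x, y) -> float:
    return pearson_brute(average_ranks(x), average_ranks(y))


def spearman_max_for_indicator(indicator) -> float:
    """Max Spearman attainable between any distinct-valued vector and a
    fixed 0/1 indicator, by exhaustive enumeration of rank orders.

    Only feasible for short vectors (n! permutations).
    """
    n = len(indicator)
    best = -2.0
    for perm in permutations(range(1, n + 1)):
        best = max(best, spearman_brute(list(perm), list(indicator)))
    return best


def kruskal_h_brute(groups) -> float:
    """Kruskal-Wallis H with tie correction via explicit formulas."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = average_ranks(pooled)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset : offset + len(g)]
        offset += len(g)
        h += (sum(r) ** 2) / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(t**3 - t for t in counts.values())
    denom = 1.0 - tie / (n**3 - n)
    if denom == 0.0:
        return 0.0
    return h / denom
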