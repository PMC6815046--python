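"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and self-contained: exact integer
hypergeometric tail sums, per-pair Pearson correlation from the textbook
formula, exhaustive simple-path enumeration, and set-based edge dedup.
"""

from __future__ import annotations

import math
from itertools import combinations


def pearson(x, y) -> float:
    """Textbook Pearson correlation of two equal-length sequences."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def hypergeom_weights(m: int, n: int, k: int):
    """Integer table weights C(m, a) * C(n, k-a) over the support of a."""
    lo, hi = max(0, k - n), min(k, m)
    return lo, [math.comb(m, a) * math.comb(n, k - a) for a in range(lo, hi + 1)]


def fisher_greater_exact(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p by exact integer tail summation."""
    m, n, k = a + b, c + d, a + c
    lo, ws = hypergeom_weights(m, n, k)
    denom = math.comb(m + n, k)
    return sum(ws[a - lo :]) / denom


def fisher_two_sided_exact(a: int, b: int, c: int, d: int, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher p: sum of tables no more probable than the observed.

    Tie detection uses the conventional relative tolerance on the table
    probability, evaluated in exact integer arithmetic.
    """
    m, n, k = a + b, c + d, a + c
    lo, ws = hypergeom_weights(m, n, k)
    denom = math.comb(m + n, k)
    w_obs = ws[a - lo]
    scale = 10 ** 9
    bound = w_obs * (scale + int(rel_tol * scale))
    return min(1.0, sum(w for w in ws if w * scale <= bound) / denom)


def enumerate_tables(max_total: int):
    """All non-degenerate 2x2 tables (a, b, c, d) with grand total <= max_total."""
    for total in range(1, max_total + 1):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    yield a, b, c, total - a - b - c


def all_seed_paths(graph, seed, len_min, len_max, eligible=None):
    """Exhaustive DFS over simple paths through ``seed``; returns gene-set dict.

    Maps frozenset(path) -> one ordered realisation.  Paths may have the
    seed anywhere along them, so the path is extended from both ends.
    """
    if eligible is None:
        eligible = set(graph.nodes)
    found = {}

    def extend(path):
        if len_min <= len(path) <= len_max:
            found.setdefault(frozenset(path), tuple(path))
        if len(path) >= len_max:
            return
        used = set(path)
        for nxt in graph.neighbors(path[-1]):
            if nxt in eligible and nxt not in used:
                extend(path + [nxt])
        for prv in graph.neighbors(path[0]):
            if prv in eligible and prv not in used:
                extend([prv] + path)

    if seed in graph and seed in eligible:
        extend([seed])
    return found


def dedup_edges(pairs):
    """Set-of-frozen-pairs dedup oracle for undirected edge lists."""
    return {frozenset(p) for p in pairs if p[0] != p[1]}


def one_move_neighborhood(genes, seed, frontier):
    """All gene sets reachable by one add / remove / swap move."""
    genes = set(genes)
    out = []
    for g in frontier:
        out.append(genes | {g})
    for r in genes - {seed}:
        out.append(genes - {r})
        for g in frontier:
            out.append((genes - {r}) | {g})
    return out
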