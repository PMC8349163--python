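"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy/sklearn: the hypergeometric tail is summed in
exact rational arithmetic and the AUC is enumerated over positive-negative
pairs, so agreement with the package is a genuine dual-route check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b), exact rational."""
    n_total = a + b + c + d
    k_success = a + c
    n_draw = a + b
    denom = comb(n_total, n_draw)
    upper = min(n_draw, k_success)
    return Fraction(
        sum(comb(k_success, k) * comb(n_total - k_success, n_draw - k)
            for k in range(a, upper + 1)),
        denom,
    )


def hypergeom_overlap_tail(overlap: int, universe: int, pathway: int,
                           query: int) -> Fraction:
    """P(X >= overlap) drawing ``query`` genes from a ``universe`` with
    ``pathway`` successes; exact rational."""
    denom = comb(universe, query)
    upper = min(query, pathway)
    return Fraction(
        sum(comb(pathway, k) * comb(universe - pathway, query - k)
            for k in range(overlap, upper + 1)),
        denom,
    )


def mann_whitney_auc(scores: dict[str, float], positives: set[str]) -> float:
    """AUC as the normalized Mann-Whitney statistic with half credit for ties."""
    pos = [scores[g] for g in scores if g in positives]
    neg = [scores[g] for g in scores if g not in positives]
    if not pos or not neg:
        raise ValueError("need at least one positive and one negative")
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def subgraph_edge_count(edges: set[tuple[str, str]], members: set[str]) -> int:
    """Count edges with both endpoints in ``members`` by direct scan."""
    return sum(1 for u, v in edges if u in members and v in members)
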