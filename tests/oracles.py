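"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: exhaustive enumeration and direct
tallies, kept free of any code path they are used to check.
"""

from __future__ import annotations

import itertools
from math import comb


def brute_force_chain_packing(
    points: list[tuple[int, int]], max_gap: int, min_anchors: int
) -> int:
    """Maximum total anchors coverable by disjoint collinear chains.

    A chain is a sequence of points strictly increasing in the first
    coordinate and strictly monotone (either direction) in the second,
    with consecutive deltas bounded by ``max_gap`` in both; only chains of
    at least ``min_anchors`` points count.  Exhaustive recursion over all
    chain choices.
    """
    n = len(points)

    def valid_step(p, q, sign):
        da = q[0] - p[0]
        db = sign * (q[1] - p[1])
        return 0 < da <= max_gap and 0 < db <= max_gap

    def all_chains(avail: frozenset) -> list[frozenset]:
        chains = []
        order = sorted(avail, key=lambda i: points[i])
        for sign in (1, -1):
            stack = [(i,) for i in order]
            while stack:
                chain = stack.pop()
                if len(chain) >= min_anchors:
                    chains.append(frozenset(chain))
                last = chain[-1]
                for j in order:
                    if j not in chain and valid_step(points[last], points[j], sign):
                        if points[j] > points[last]:
                            stack.append(chain + (j,))
        return chains

    memo: dict[frozenset, int] = {}

    def best(avail: frozenset) -> int:
        if avail in memo:
            return memo[avail]
        result = 0
        for chain in all_chains(avail):
            result = max(result, len(chain) + best(avail - chain))
        memo[avail] = result
        return result

    return best(frozenset(range(n)))


def permutation_rank_sum_p(x: list[float], y: list[float]) -> tuple[float, float]:
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Pools the samples, assigns midranks, and enumerates every way of
    choosing which pooled observations form sample x; the p-value is the
    fraction of assignments whose rank-sum deviates from its expectation
    at least as much as the observed one.
    """
    pooled = list(x) + list(y)
    n = len(pooled)
    nx = len(x)
    # midranks by direct definition
    ranks = []
    for v in pooled:
        less = sum(1 for u in pooled if u < v)
        equal = sum(1 for u in pooled if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    w_obs = sum(ranks[:nx])
    mean = nx * (n + 1) / 2.0
    dev = abs(w_obs - mean)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n), nx):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - mean) >= dev - 1e-9:
            hits += 1
    assert total == comb(n, nx)
    return w_obs, hits / total


def gc3_50_by_scan(cds: str) -> float:
    """Character-position count of G/C at positions 3, 6, ..., 150."""
    count = 0
    for codon_index in range(50):
        base = cds[3 * codon_index + 2].upper()
        if base in ("G", "C"):
            count += 1
    return count / 50.0


def hypergeom_upper_tail(a: int, row1: int, col1: int, total: int) -> float:
    """P(X >= a) for X hypergeometric, by direct tail summation.

    ``row1`` = size of the annotated-term group, ``col1`` = size of the
    focal class, ``total`` = universe size.
    """
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        p += (
            comb(col1, k) * comb(total - col1, row1 - k) / comb(total, row1)
        )
    return p


def weighted_level_tally(calls: list[tuple[str, int, int]], context: str) -> float | None:
    """Sum(m)/sum(total) over calls of one context; None if no coverage."""
    m = sum(c[1] for c in calls if c[0] == context and c[2] > 0)
    t = sum(c[2] for c in calls if c[0] == context and c[2] > 0)
    return m / t if t else None
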