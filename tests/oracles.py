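"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (exhaustive search, rational arithmetic,
O(n^3) loops) and shares no code with the implementation path it audits.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def least_squares_breakpoints(
    values: np.ndarray, n_breakpoints: int, min_len: int
) -> tuple[int, ...]:
    """Exhaustive least-squares change-point positions for 0..2 breakpoints.

    Returns the breakpoint index tuple (right-segment start indices)
    minimizing the within-segment sum of squared errors, subject to every
    segment having at least ``min_len`` points. Ties break leftmost.
    """
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csq = np.concatenate([[0.0], np.cumsum(values**2)])

    def sse(lo: int, hi: int) -> float:
        s = csum[hi] - csum[lo]
        q = csq[hi] - csq[lo]
        return q - s * s / (hi - lo)

    if n_breakpoints == 0:
        return ()
    best: tuple[float, tuple[int, ...]] | None = None
    if n_breakpoints == 1:
        candidates = (((k,),) for k in range(min_len, n - min_len + 1))
    elif n_breakpoints == 2:
        candidates = (
            ((k1, k2),)
            for k1 in range(min_len, n - 2 * min_len + 1)
            for k2 in range(k1 + min_len, n - min_len + 1)
        )
    else:
        raise ValueError("oracle supports at most 2 breakpoints")
    for (bps,) in candidates:
        bounds = (0, *bps, n)
        cost = sum(sse(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1))
        if best is None or cost < best[0] - 1e-12:
            best = (cost, bps)
    assert best is not None
    return best[1]


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by full enumeration with rational arithmetic."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return Fraction(1)
    denom = comb(n, col1)
    p_obs = Fraction(comb(row1, a) * comb(n - row1, col1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
        if pk <= p_obs:
            total += pk
    return total


def brute_force_overlap_clusters(
    items: list[tuple[str, int, int, str]], min_reciprocal_overlap: float
) -> list[frozenset[int]]:
    """Single-linkage clusters via an all-pairs scan + naive union-find.

    ``items`` are (chromosome, start, end, direction) tuples; indices into the
    list form the returned partition.
    """
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(items)), 2):
        ci, si, ei, di = items[i]
        cj, sj, ej, dj = items[j]
        if ci != cj or di != dj:
            continue
        ov = min(ei, ej) - max(si, sj)
        if ov <= 0:
            continue
        ro = min(ov / (ei - si), ov / (ej - sj))
        if ro >= min_reciprocal_overlap:
            parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(len(items)):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def upgma_cophenetic(points: np.ndarray) -> np.ndarray:
    """Hand-rolled UPGMA: full cophenetic distance matrix from raw points.

    Naive O(n^3) agglomeration on Euclidean distances, averaging
    inter-cluster distances weighted by cluster sizes (exact UPGMA update).
    """
    n = len(points)
    dist = {
        frozenset((i, j)): float(np.linalg.norm(points[i] - points[j]))
        for i, j in itertools.combinations(range(n), 2)
    }
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    active = list(range(n))
    cdist: dict[frozenset[int], float] = dict(dist)
    coph = np.zeros((n, n))
    while len(active) > 1:
        best_pair, best_d = None, None
        for a, b in itertools.combinations(sorted(active), 2):
            d = cdist[frozenset((a, b))]
            if best_d is None or d < best_d - 1e-12:
                best_pair, best_d = (a, b), d
        assert best_pair is not None and best_d is not None
        a, b = best_pair
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = best_d
        na, nb = len(clusters[a]), len(clusters[b])
        for other in active:
            if other in (a, b):
                continue
            da = cdist[frozenset((a, other))]
            db = cdist[frozenset((b, other))]
            cdist[frozenset((a, other))] = (na * da + nb * db) / (na + nb)
        clusters[a] |= clusters[b]
        active.remove(b)
    return coph
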