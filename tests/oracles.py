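"""Independent reference implementations used to check the package.

Each oracle is deliberately written from first principles (exhaustive
recursion / enumeration / direct accumulation) and shares no code path with
the implementation it checks.
"""

from __future__ import annotations

import sys
from functools import lru_cache
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local-alignment score by exhaustive recursion over alignments.

    Every alignment is a monotone path of {pair, gap-in-a, gap-in-b} moves
    starting and ending at an aligned pair; a gap of length k costs
    ``gap_open + k * gap_extend``. Memoization only caches subproblems, the
    recursion itself enumerates all continuations.
    """
    sys.setrecursionlimit(100_000)
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def extend(i: int, j: int, state: str) -> float:
        # best achievable continuation from a[i:], b[j:]; may stop (score 0)
        best = 0.0
        if i < n and j < m:
            best = max(best, _BLOSUM62[a[i], b[j]] + extend(i + 1, j + 1, "pair"))
        if i < n:
            cost = gap_extend if state == "gap_b" else gap_open + gap_extend
            best = max(best, -cost + extend(i + 1, j, "gap_b"))
        if j < m:
            cost = gap_extend if state == "gap_a" else gap_open + gap_extend
            best = max(best, -cost + extend(i, j + 1, "gap_a"))
        return best

    best = 0.0
    for i in range(n):
        for j in range(m):
            best = max(best, _BLOSUM62[a[i], b[j]] + extend(i + 1, j + 1, "pair"))
    extend.cache_clear()
    return int(best)


def _u_statistic(values_a, values_b) -> float:
    """U of sample a: pairs where a-value exceeds b-value (ties count half)."""
    u = 0.0
    for x in values_a:
        for y in values_b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def enumerate_u_test_p(values_a, values_b, alternative: str) -> float:
    """Exact Mann-Whitney p by enumerating every group-A labelling."""
    pooled = list(values_a) + list(values_b)
    n_a = len(values_a)
    u_obs = _u_statistic(values_a, values_b)
    total = le = ge = 0
    indices = range(len(pooled))
    for combo in combinations(indices, n_a):
        chosen = set(combo)
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in indices if i not in chosen]
        u = _u_statistic(a, b)
        total += 1
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    if alternative == "less":
        return le / total
    if alternative == "greater":
        return ge / total
    return min(1.0, 2.0 * min(le, ge) / total)


def scan_profile(length: int, hits) -> dict:
    """Per-position best-hit scan over span-based hits (no alignment detail)."""
    best_identity = [None] * length
    min_evalue = [None] * length
    covered = [False] * length
    for p in range(length):
        pos = p + 1
        spanning = [h for h in hits if h.query_start <= pos <= h.query_end]
        if not spanning:
            continue
        covered[p] = True
        min_evalue[p] = min(h.evalue for h in spanning)
        best = sorted(
            spanning,
            key=lambda h: (-h.percent_identity, h.evalue, -h.alignment_length, h.read_id),
        )[0]
        best_identity[p] = best.percent_identity
    return {"best_identity": best_identity, "min_evalue": min_evalue, "covered": covered}


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random additive (tree) metric: labels and its leaf-leaf path matrix."""
    labels = [f"T{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    clusters: list[dict[int, float]] = [{i: 0.0} for i in range(n_taxa)]
    while len(clusters) > 1:
        j = int(rng.integers(1, len(clusters)))
        i = int(rng.integers(0, j))
        b = clusters.pop(j)
        a = clusters.pop(i)
        la, lb = rng.uniform(0.5, 5.0, size=2)
        for x, dx in a.items():
            for y, dy in b.items():
                D[x, y] = D[y, x] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in a.items()}
        merged.update({y: dy + lb for y, dy in b.items()})
        clusters.append(merged)
    return labels, D
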