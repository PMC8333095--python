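"""Independent brute-force oracles used to cross-check the implementation.

Everything here is coded directly from definitions (step-up FDR, the Ward
Lance-Williams recurrence, exhaustive spanning-tree and labelling
enumeration) and deliberately shares no code path with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def bh_step_up(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values by the literal step-up definition:
    q_i = min over j with p_(j) >= p_(i) of m * p_(j) / rank(j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        q[i] = running_min
    return np.minimum(q, 1.0)


def ward_d2_heights(dist: np.ndarray) -> np.ndarray:
    """Merge heights of naive O(n^3) Ward D2 agglomeration.

    Nearest pair merged each step; cluster distances updated with the
    Lance-Williams recurrence on squared distances, heights reported as
    square roots.
    """
    n = dist.shape[0]
    members = {i: 1 for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(members) > 1:
        (i, j), w = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(w)
        ni, nj = members.pop(i), members.pop(j)
        for k in list(members):
            nk = members[k]
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            new = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * w**2)
                / (ni + nj + nk)
            )
            d[(min(next_id, k), max(next_id, k))] = new
        del d[(i, j)]
        members[next_id] = ni + nj
        next_id += 1
    return np.array(heights)


def _is_spanning_tree(n: int, edges: tuple[tuple[int, int], ...]) -> bool:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            return False
        parent[ru] = rv
    return True


def min_spanning_tree_weight(dist: np.ndarray) -> float:
    """Minimum total weight over exhaustive enumeration of all spanning trees."""
    n = dist.shape[0]
    all_edges = list(combinations(range(n), 2))
    best = np.inf
    for subset in combinations(all_edges, n - 1):
        if _is_spanning_tree(n, subset):
            w = sum(dist[u, v] for u, v in subset)
            best = min(best, w)
    return float(best)


def similarity_diff(dist: np.ndarray, in_a: np.ndarray) -> float:
    """Median reciprocal within-group distance difference, from definition."""

    def med(idx: np.ndarray) -> float:
        vals = [1.0 / dist[i, j] for i, j in combinations(idx.tolist(), 2)]
        return float(np.median(vals))

    return med(np.flatnonzero(in_a)) - med(np.flatnonzero(~in_a))


def similarity_exact_p(dist: np.ndarray, in_a: np.ndarray) -> float:
    """Two-sided exact p over every labelling with group sizes fixed."""
    n = dist.shape[0]
    n_a = int(in_a.sum())
    observed = abs(similarity_diff(dist, in_a))
    count = 0
    total = 0
    for comb in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        if abs(similarity_diff(dist, mask)) >= observed:
            count += 1
        total += 1
    return count / total
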