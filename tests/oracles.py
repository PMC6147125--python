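"""Independent brute-force reference implementations used only in tests.

Each oracle is written as directly as possible from the defining
formula, independent of the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def spearman_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: mid-rank both vectors, then textbook Pearson."""

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def bh_brute(p: np.ndarray) -> np.ndarray:
    """BH step-up: q_(i) = min_{j>=i}(p_(j) * m / j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running_min = np.inf
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running_min, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def modularity_brute(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    A = np.asarray(adjacency, dtype=float)
    k = A.sum(axis=1)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    n = len(A)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items: list):
    """All set partitions (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [[first] + block] + partition[i + 1 :]
        yield [[first]] + partition


def best_partition_brute(adjacency: np.ndarray) -> tuple[float, list]:
    """Exhaustive maximum-modularity partition (feasible to ~10 nodes)."""
    n = len(adjacency)
    best_q, best = -np.inf, None
    for partition in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(partition):
            labels[block] = c
        q = modularity_brute(adjacency, labels)
        if q > best_q:
            best_q, best = q, partition
    return best_q, best
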