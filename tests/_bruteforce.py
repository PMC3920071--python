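"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions, deliberately avoiding the
library routines the package itself uses (networkx, scipy shortest paths,
vectorized rank machinery): Floyd-Warshall by triple loop, shortest-path
counting by exhaustive simple-path enumeration, clustering by triple loop,
rank-sum p-values by explicit enumeration of label assignments.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

_TOL = 1e-9


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    d = lengths.copy()
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def length_matrix(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    lengths = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                lengths[i, j] = 1.0 / w[i, j]
        lengths[i, i] = 0.0
    return lengths


def bf_strength(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([sum(w[i, j] for j in range(n) if j != i) for i in range(n)])


def bf_global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(length_matrix(w))
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def _simple_paths(lengths: np.ndarray, s: int, t: int):
    """All simple paths s -> t with their total lengths (DFS enumeration)."""
    n = lengths.shape[0]
    out = []

    def walk(node, visited, acc):
        if node == t:
            out.append((acc, tuple(visited)))
            return
        for nxt in range(n):
            if nxt not in visited and np.isfinite(lengths[node, nxt]) and nxt != node:
                walk(nxt, visited + [nxt], acc + lengths[node, nxt])

    walk(s, [s], 0.0)
    return out


def bf_betweenness(w: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Betweenness by exhaustive enumeration of all simple paths per pair."""
    n = w.shape[0]
    lengths = length_matrix(w)
    score = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _simple_paths(lengths, s, t)
            if not paths:
                continue
            dmin = min(p[0] for p in paths)
            shortest = [p[1] for p in paths if p[0] <= dmin * (1 + _TOL) + _TOL]
            sigma = len(shortest)
            for path in shortest:
                for v in path[1:-1]:
                    score[v] += 1.0 / sigma
    if normalized and n > 2:
        score /= (n - 1) * (n - 2) / 2.0
    return score


def bf_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by direct triple-loop summation."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wh = w / wmax
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    total += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def bf_ranksum_p(case_values, control_values):
    """Exhaustive-permutation rank-sum p-values (p_two, p_le, p_ge).

    Midranks computed directly; every C(n1+n2, n1) assignment of the case
    labels is enumerated and the case rank sum compared with the observed.
    """
    pooled = list(case_values) + list(control_values)
    n1 = len(case_values)
    N = len(pooled)
    order = sorted(range(N), key=lambda i: pooled[i])
    ranks = [0.0] * N
    i = 0
    while i < N:
        j = i
        while j + 1 < N and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    obs = sum(ranks[:n1])
    total = le = ge = 0
    for combo in combinations(range(N), n1):
        w = sum(ranks[k] for k in combo)
        total += 1
        if w <= obs + 1e-12:
            le += 1
        if w >= obs - 1e-12:
            ge += 1
    p_le, p_ge = le / total, ge / total
    return min(1.0, 2 * min(p_le, p_ge)), p_le, p_ge


def random_symmetric_graph(n: int, rng: np.random.Generator, density: float = 0.6) -> np.ndarray:
    """Random nonnegative symmetric weight matrix with generic weights."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.5, 2.0)
    return w
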