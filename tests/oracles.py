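"""Independent reference computations used to validate the package.

Everything here is deliberately naive (brute force, dynamic programming,
direct formula evaluation) and shares no code path with the implementations
it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def apsp_floyd_warshall(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths via scipy's Floyd-Warshall on unit weights."""
    return floyd_warshall(adjacency.astype(float), directed=True,
                          unweighted=True)


def brute_strongly_connected(adjacency: np.ndarray) -> bool:
    """Reachability closure by repeated squaring of the boolean matrix."""
    n = adjacency.shape[0]
    reach = adjacency.astype(bool) | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach.astype(int) @ reach.astype(int) > 0)
    return bool(reach.all())


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, mx: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(1, mx + 2):
            labels[i] = lab
            yield from rec(i + 1, max(mx, lab))

    yield from rec(0, 0)


def modularity_direct(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Directed modularity evaluated term by term from its definition."""
    m = adjacency.sum()
    if m == 0:
        return 0.0
    kout = adjacency.sum(axis=1)
    kin = adjacency.sum(axis=0)
    q = 0.0
    n = adjacency.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adjacency[i, j] - kout[i] * kin[j] / m
    return q / m


def best_partition_bruteforce(adjacency: np.ndarray):
    """Exhaustive directed-modularity maximization (tiny n only)."""
    best_q, best_labels = -np.inf, None
    a = adjacency.astype(float)
    m = a.sum()
    kout = a.sum(axis=1)
    kin = a.sum(axis=0)
    B = a - np.outer(kout, kin) / m
    for labels in set_partitions(adjacency.shape[0]):
        same = labels[:, None] == labels[None, :]
        q = B[same].sum() / m
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels.copy()
    return best_q, best_labels


def match_mismatch_bruteforce(a_labels: np.ndarray, b_labels: np.ndarray):
    """Per-node mismatch set of max-overlap partition matching."""
    mismatched = []
    for b in np.unique(b_labels):
        members = np.flatnonzero(b_labels == b)
        counts = {}
        for v in members:
            counts[a_labels[v]] = counts.get(a_labels[v], 0) + 1
        best_a = min(a for a in counts
                     if counts[a] == max(counts.values()))
        mismatched.extend(v for v in members if a_labels[v] != best_a)
    return sorted(mismatched)


def enumerate_global_optimum(dist: np.ndarray, K: int, alpha: float):
    """Exhaustive search over all strongly connected K-link digraphs.

    Returns (E_min, W_min, L_min) where W_min/L_min are the single-constraint
    benchmarks over the same feasible set and E_min uses them for
    normalization.  Feasible only for tiny n (C(n(n-1), K) configurations).
    """
    n = dist.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    feasible = []
    for combo in itertools.combinations(range(len(pairs)), K):
        adj = np.zeros((n, n), dtype=bool)
        for e in combo:
            adj[pairs[e]] = True
        sp = apsp_floyd_warshall(adj)
        if np.isinf(sp).any():
            continue
        W = float(dist[adj].sum())
        L = float(sp.sum())
        feasible.append((W, L))
    W_min = min(w for w, _ in feasible)
    L_min = min(l for _, l in feasible)
    E_min = min(alpha * w / W_min + (1 - alpha) * l / L_min
                for w, l in feasible)
    return E_min, W_min, L_min
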