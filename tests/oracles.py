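"""Independent brute-force oracles used to check the fast implementations.

These deliberately avoid the algorithms used inside the package: all-pairs
distances come from Floyd-Warshall, shortest-path counts from the
distance-ordered dynamic programme (with an exhaustive simple-path
enumeration double-check for tiny graphs), sign-test p-values from
enumerating every equally likely sign pattern, and the paired t from the
textbook formula.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def floyd_warshall(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs hop distances; inf for unreachable pairs."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    dist = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k][:, None] + dist[k, :][None, :])
    return dist


def path_length_oracle(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """L_i over reachable peers (inf if none) and L_p, from Floyd-Warshall."""
    dist = floyd_warshall(adjacency)
    n = dist.shape[0]
    li = np.empty(n)
    for i in range(n):
        finite = np.isfinite(dist[i]) & (np.arange(n) != i)
        li[i] = dist[i][finite].mean() if finite.any() else np.inf
    return li, float(li.mean())


def shortest_path_counts(adjacency: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of shortest s-t paths, by distance-ordered DP."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(dist[s])
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            preds = np.flatnonzero((a[:, t] > 0) & (dist[s] == dist[s, t] - 1))
            sigma[s, t] = sigma[s, preds].sum()
    return sigma


def betweenness_oracle(adjacency: np.ndarray) -> np.ndarray:
    """Ordered-pair fractional betweenness B_i via sigma_st(i) = sigma_si sigma_it."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    dist = floyd_warshall(a)
    sigma = shortest_path_counts(a, dist)
    bc = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        if not np.isfinite(dist[s, t]):
            continue
        for i in range(n):
            if i in (s, t):
                continue
            if dist[s, i] + dist[i, t] == dist[s, t]:
                bc[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    return bc


def betweenness_by_enumeration(adjacency: np.ndarray) -> np.ndarray:
    """Exhaustive simple-path enumeration; only viable for tiny graphs."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        paths: list[tuple[int, ...]] = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in np.flatnonzero(a[u]):
                if v not in path:
                    extend(path + (int(v),))

        extend((s,))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        shortest_paths = [p for p in paths if len(p) == shortest]
        for p in shortest_paths:
            for i in p[1:-1]:
                bc[i] += 1.0 / len(shortest_paths)
    return bc


def connected(adjacency: np.ndarray) -> bool:
    dist = floyd_warshall(adjacency)
    return bool(np.isfinite(dist).all())


def all_connected_graphs(n: int):
    """Every connected labelled simple graph on n nodes (small n only)."""
    edges = list(itertools.combinations(range(n), 2))
    for bits in itertools.product((0, 1), repeat=len(edges)):
        a = np.zeros((n, n), dtype=int)
        for (u, v), b in zip(edges, bits):
            a[u, v] = a[v, u] = b
        if connected(a):
            yield a


def random_connected_graph(n: int, rng: np.random.Generator, p: float = 0.5) -> np.ndarray:
    while True:
        a = (rng.random((n, n)) < p).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        if connected(a):
            return a


def sign_test_enumeration(li_values, direction: str) -> float:
    """P(X >= k) by enumerating all 2^n sign patterns of the nonzero values."""
    signs = [1 if v > 0 else -1 for v in li_values if v != 0]
    n = len(signs)
    if n == 0:
        return 1.0
    want = 1 if direction == "leftward" else -1
    k = sum(1 for s in signs if s == want)
    hits = 0
    for pattern in itertools.product((1, -1), repeat=n):
        if sum(1 for s in pattern if s == want) >= k:
            hits += 1
    return hits / 2**n


def paired_t_formula(left, right) -> tuple[float, float]:
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), two-sided p."""
    d = np.asarray(left, dtype=float) - np.asarray(right, dtype=float)
    n = d.size
    sd = math.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return t, p
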