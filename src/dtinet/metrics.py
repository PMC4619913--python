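"""Nodal topology of the binary anatomical network.

For a binary undirected graph with N nodes:

* degree            K_i = number of connections of node i;
                    K_p = (1/N) sum_i K_i
* shortest path     L_{i,j} = smallest hop count between i and j;
                    L_i = mean of L_{i,j} over reachable j != i;
                    L_p = (1/N) sum_i L_i
* betweenness       B_i = sum over ordered pairs (s, t), s != t != i, of
                    sigma_st(i) / sigma_st (fractional counting over multiple
                    shortest paths); b_i = B_i / ((N-1)(N-2)), which maps the
                    star centre to exactly 1.

Unreachable pairs are excluded from L_i's average (the edge threshold is
chosen so the network stays fully connected; exclusion only matters for
pathological inputs).  A node with no reachable peer gets L_i = inf, i.e.
zero nodal efficiency 1/L_i.  Betweenness uses Brandes' dependency
accumulation, which over all sources yields exactly the ordered-pair sum.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NodalMetrics",
    "degree",
    "shortest_path_lengths",
    "betweenness",
    "compute_nodal_metrics",
    "identify_hubs",
]


def _validate(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return a.astype(np.int8)


@dataclass
class NodalMetrics:
    """Per-node degree, mean shortest path, betweenness; network means."""

    degree: np.ndarray  # K_i
    path_length: np.ndarray  # L_i (inf for fully isolated nodes)
    betweenness: np.ndarray  # B_i, ordered-pair fractional counts
    norm_betweenness: np.ndarray  # b_i in [0, 1]
    mean_degree: float  # K_p
    char_path_length: float  # L_p

    @property
    def n_nodes(self) -> int:
        return self.degree.shape[0]


def degree(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Node degrees K_i and the network mean K_p."""
    a = _validate(adjacency)
    k = a.sum(axis=1).astype(float)
    return k, float(k.mean())


def _bfs_hops(a: np.ndarray, source: int) -> np.ndarray:
    n = a.shape[0]
    dist = np.full(n, -1, dtype=np.int64)
    dist[source] = 0
    queue = deque([source])
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    while queue:
        u = queue.popleft()
        for v in neighbors[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def shortest_path_lengths(adjacency: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal mean shortest path L_i and characteristic path length L_p."""
    a = _validate(adjacency)
    n = a.shape[0]
    li = np.empty(n)
    for i in range(n):
        dist = _bfs_hops(a, i)
        reachable = dist > 0
        li[i] = dist[reachable].mean() if reachable.any() else np.inf
    return li, float(li.mean())


def betweenness(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Betweenness B_i (ordered-pair, fractional) and normalized b_i.

    Brandes' algorithm: one BFS per source with dependency back-propagation.
    """
    a = _validate(adjacency)
    n = a.shape[0]
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest-path DAG
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1, dtype=np.int64)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        queue = deque([s])
        while queue:
            u = queue.popleft()
            order.append(u)
            for v in neighbors[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        # dependency accumulation in reverse BFS order
        delta = np.zeros(n)
        for v in reversed(order):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    # summing over every source counts each ordered (s, t) pair once
    norm = (n - 1) * (n - 2) if n > 2 else 1
    return bc, bc / norm


def compute_nodal_metrics(adjacency: np.ndarray) -> NodalMetrics:
    """All three nodal properties plus the network-level means."""
    k, kp = degree(adjacency)
    li, lp = shortest_path_lengths(adjacency)
    bc, nbc = betweenness(adjacency)
    return NodalMetrics(
        degree=k, path_length=li, betweenness=bc, norm_betweenness=nbc,
        mean_degree=kp, char_path_length=lp,
    )


def identify_hubs(metrics: NodalMetrics, n_sd: float = 1.0) -> np.ndarray:
    """Pivotal nodes: normalized betweenness above mean + ``n_sd`` SD.

    The hub notion is "largest normalized betweenness"; the literature states
    no universal cutoff, so the rule is configurable and defaults to one
    standard deviation above the mean.  Degenerate case: an all-equal b
    vector (e.g. a complete graph) yields no hubs.
    """
    b = metrics.norm_betweenness
    cut = b.mean() + n_sd * b.std()
    return np.flatnonzero(b > cut)
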