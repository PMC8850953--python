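"""JIT-compiled inner loops for the graph metrics.

Adjacency matrices here are dense uint8/bool; graphs are small (tens to a
few hundred nodes) but the pipeline evaluates tens of thousands of them
(31 thresholds x subjects x null randomizations), so the BFS and edge-swap
loops are compiled with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["apsp", "ms_rewire", "local_efficiency_sum"]


@njit(cache=True)
def _apsp_impl(indptr, indices, n):  # pragma: no cover - exercised via apsp
    dist = np.full((n, n), -1, np.int32)
    queue = np.empty(n, np.int64)
    for s in range(n):
        dist[s, s] = 0
        head = 0
        tail = 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for idx in range(indptr[u], indptr[u + 1]):
                v = indices[idx]
                if dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


def apsp(adj: np.ndarray) -> np.ndarray:
    """All-pairs BFS hop counts; -1 marks unreachable pairs."""
    a = np.ascontiguousarray(adj, dtype=np.uint8)
    n = a.shape[0]
    indptr = np.zeros(n + 1, dtype=np.int64)
    counts = a.sum(axis=1).astype(np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.nonzero(a)[1].astype(np.int64)
    return _apsp_impl(indptr, indices, n)


@njit(cache=True)
def ms_rewire(adj, edges, n_attempts, seed):  # pragma: no cover - via wrapper
    """Sequential Maslov-Sneppen double-edge swaps, in place.

    ``adj`` is a boolean matrix, ``edges`` the (m, 2) upper-triangle edge
    list; both are updated together. Attempts producing self-loops,
    parallel edges, or degenerate node sets are skipped, so the degree
    sequence is invariant.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if np.random.random() < 0.5:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 0] = min(a, d)
        edges[e1, 1] = max(a, d)
        edges[e2, 0] = min(c, b)
        edges[e2, 1] = max(c, b)


@njit(cache=True)
def local_efficiency_sum(adj):  # pragma: no cover - exercised via wrapper
    """Sum over nodes of the efficiency of each neighbour-induced subgraph."""
    n = adj.shape[0]
    nb = np.empty(n, np.int64)
    sub = np.zeros((n, n), np.uint8)
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int64)
    total = 0.0
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        for p in range(k):
            for q in range(k):
                sub[p, q] = adj[nb[p], nb[q]]
        inv_sum = 0.0
        for s in range(k):
            for p in range(k):
                dist[p] = -1
            dist[s] = 0
            head = 0
            tail = 0
            queue[tail] = s
            tail += 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u]
                for v in range(k):
                    if sub[u, v] and dist[v] < 0:
                        dist[v] = du + 1
                        queue[tail] = v
                        tail += 1
            for p in range(k):
                if p != s and dist[p] > 0:
                    inv_sum += 1.0 / dist[p]
        total += inv_sum / (k * (k - 1))
    return total
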