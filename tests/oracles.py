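"""Independent brute-force oracles for graph metrics.

Deliberately naive: plain-Python BFS and exhaustive triple enumeration.
They share no code with the package implementations they check.
"""

from __future__ import annotations

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> list[float]:
    n = len(adj)
    dist = [float("inf")] * n
    dist[source] = 0
    queue = [source]
    while queue:
        u = queue.pop(0)
        for v in range(n):
            if adj[u][v] and dist[v] == float("inf"):
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_pairs(adj: np.ndarray) -> list[list[float]]:
    return [bfs_distances(adj, s) for s in range(len(adj))]


def clustering_oracle(adj: np.ndarray) -> float:
    n = len(adj)
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if adj[nb[a]][nb[b]]
        )
        total += 2.0 * links / (k * (k - 1))
    return total / n


def path_length_oracle(adj: np.ndarray) -> float:
    d = all_pairs(adj)
    finite = [
        d[i][j]
        for i in range(len(adj))
        for j in range(len(adj))
        if i != j and d[i][j] != float("inf")
    ]
    if not finite:
        raise ValueError("no reachable pair")
    return sum(finite) / len(finite)


def global_efficiency_oracle(adj: np.ndarray) -> float:
    n = len(adj)
    d = all_pairs(adj)
    inv = [
        1.0 / d[i][j] if d[i][j] != float("inf") else 0.0
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    return sum(inv) / (n * (n - 1)) if n > 1 else 0.0


def local_efficiency_oracle(adj: np.ndarray) -> float:
    n = len(adj)
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            continue
        sub = np.array([[adj[a][b] for b in nb] for a in nb])
        total += global_efficiency_oracle(sub)
    return total / n


def nodal_efficiency_oracle(adj: np.ndarray) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        d = bfs_distances(adj, i)
        inv = [1.0 / d[j] for j in range(n) if j != i and d[j] != float("inf")]
        out.append(sum(inv) / (n - 1))
    return out


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a + a.T
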