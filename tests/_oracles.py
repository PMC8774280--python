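"""Brute-force reference implementations used to validate graph metrics.

Everything here is deliberately naive (Floyd-Warshall triple loops, triple
enumeration for triangles, explicit shortest-path enumeration for
betweenness, recursive flood fill for clusters) and independent of the
package's vectorized implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

INF = float("inf")


def fw_distances(A: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by Floyd-Warshall."""
    n = len(A)
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if A[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_global_efficiency(A: np.ndarray) -> float:
    n = len(A)
    if n < 2:
        return 0.0
    d = fw_distances(A)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] < INF:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_nodal_efficiency(A: np.ndarray) -> np.ndarray:
    n = len(A)
    d = fw_distances(A)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] < INF:
                out[i] += 1.0 / d[i, j]
        out[i] /= n - 1
    return out


def brute_local_efficiency(A: np.ndarray) -> np.ndarray:
    n = len(A)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        if len(nbrs) < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        out[i] = brute_global_efficiency(sub)
    return out


def brute_clustering(A: np.ndarray) -> np.ndarray:
    n = len(A)
    out = np.zeros(n)
    for i in range(n):
        k = int(A[i].sum())
        if k < 2:
            continue
        tri = 0
        for j, h in itertools.combinations(range(n), 2):
            if A[i, j] and A[i, h] and A[j, h]:
                tri += 1
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def _all_shortest_paths(A: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every shortest s-t path, by BFS distances + backward enumeration."""
    n = len(A)
    dist = [INF] * n
    dist[s] = 0
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if A[u, v] and dist[v] == INF:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if dist[t] == INF:
        return []

    paths: list[tuple[int, ...]] = []

    def walk(v: int, tail: list[int]) -> None:
        if v == s:
            paths.append(tuple(reversed(tail + [s])))
            return
        for u in range(n):
            if A[u, v] and dist[u] == dist[v] - 1:
                walk(u, tail + [v])

    walk(t, [])
    return paths


def brute_betweenness(A: np.ndarray, normalized: bool = True) -> np.ndarray:
    n = len(A)
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(A, s, t)
        if not paths:
            continue
        for i in range(n):
            if i in (s, t):
                continue
            through = sum(1 for p in paths if i in p)
            out[i] += through / len(paths)
    if normalized and n > 2:
        out /= (n - 1) * (n - 2) / 2.0
    return out


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    A = rng.random((n, n)) < p
    A = np.triu(A, 1)
    return A | A.T


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components of a 3-D boolean field by explicit flood fill."""
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
        and {6: abs(dx) + abs(dy) + abs(dz) == 1,
             18: abs(dx) + abs(dy) + abs(dz) <= 2,
             26: True}[connectivity]
    ]
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(v[a] + off[a] for a in range(3))
                if all(0 <= w[a] < mask.shape[a] for a in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        comps.append(comp)
    return comps
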