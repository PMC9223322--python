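"""Compiled breadth-first-search kernels for substrate detection.

Reentry detection reduces to per-edge shortest *return* paths: for an edge
(b, n), the length of the shortest b-n path that avoids the edge itself,
plus one for the closing step.  No installed graph library exposes this as
a bulk operation, and the scan visits every edge of networks with 10^4-10^5
edges, so the BFS lives here as numba-compiled loops over CSR adjacency.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def return_lengths(
    indptr: np.ndarray,
    indices: np.ndarray,
    edge_u: np.ndarray,
    edge_v: np.ndarray,
    cap: int,
) -> np.ndarray:
    """Shortest return length for each undirected edge (u, v).

    Entry e is ``1 + d`` where ``d`` is the shortest u-v distance in the
    graph with edge (u, v) removed, searched up to depth ``cap``; ``-1`` if
    no return path exists within the cap.  The quantity is symmetric in the
    edge direction, so one evaluation covers both blocked directions.
    """
    n = len(indptr) - 1
    m = len(edge_u)
    visited = np.full(n, -1, np.int64)
    dist = np.zeros(n, np.int64)
    queue = np.empty(n, np.int64)
    out = np.empty(m, np.int64)
    for e in range(m):
        b = edge_u[e]
        t = edge_v[e]
        head = 0
        tail = 0
        visited[b] = e
        dist[b] = 0
        queue[tail] = b
        tail += 1
        found = -1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            if du >= cap:
                break
            for k in range(indptr[u], indptr[u + 1]):
                w = indices[k]
                if u == b and w == t:
                    continue  # the blocked edge itself
                if visited[w] != e:
                    visited[w] = e
                    dist[w] = du + 1
                    if w == t:
                        found = du + 1
                        head = tail
                        break
                    queue[tail] = w
                    tail += 1
        out[e] = found + 1 if found > 0 else -1
    return out


@njit(cache=True)
def alternative_path(
    indptr: np.ndarray,
    indices: np.ndarray,
    b: int,
    t: int,
    cap: int,
) -> np.ndarray:
    """Shortest b -> t path avoiding edge (b, t), as a node sequence.

    Returns an array starting at ``b`` and ending at ``t``; empty if no
    such path exists within depth ``cap``.
    """
    n = len(indptr) - 1
    dist = np.full(n, -1, np.int64)
    parent = np.full(n, -1, np.int64)
    queue = np.empty(n, np.int64)
    head = 0
    tail = 0
    dist[b] = 0
    queue[tail] = b
    tail += 1
    found = False
    while head < tail and not found:
        u = queue[head]
        head += 1
        if dist[u] >= cap:
            break
        for k in range(indptr[u], indptr[u + 1]):
            w = indices[k]
            if u == b and w == t:
                continue
            if dist[w] < 0:
                dist[w] = dist[u] + 1
                parent[w] = u
                if w == t:
                    found = True
                    break
                queue[tail] = w
                tail += 1
    if not found:
        return np.empty(0, np.int64)
    length = dist[t] + 1
    path = np.empty(length, np.int64)
    node = t
    for i in range(length - 1, -1, -1):
        path[i] = node
        node = parent[node]
    return path
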