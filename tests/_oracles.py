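"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the libraries)
they verify: betweenness/closeness by explicit shortest-path enumeration,
BH by a literal step-down loop, Fisher tails by exact integer arithmetic.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_shortest_paths(adj: dict, dist: dict, s, t) -> list[list]:
    paths: list[list] = []

    def back(u, acc):
        if u == s:
            paths.append([s, *acc])
            return
        for w in adj[u]:
            if w in dist and dist[w] == dist[u] - 1:
                back(w, [u, *acc])

    if t in dist:
        back(t, [])
    return paths


def betweenness_oracle(adj: dict) -> dict:
    """Unnormalised betweenness by enumerating every shortest path."""
    nodes = sorted(adj, key=str)
    bc = {n: 0.0 for n in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def closeness_oracle(adj: dict) -> dict:
    """(reachable − 1) / Σ distances within each node's component."""
    out = {}
    for n in adj:
        dist = bfs_distances(adj, n)
        total = sum(dist.values())
        out[n] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def clustering_oracle(adj: dict) -> dict:
    out = {}
    for n in adj:
        neigh = list(adj[n])
        k = len(neigh)
        if k < 2:
            out[n] = 0.0
            continue
        links = sum(
            1
            for i, a in enumerate(neigh)
            for b in neigh[i + 1:]
            if b in adj[a]
        )
        out[n] = 2.0 * links / (k * (k - 1))
    return out


def bh_oracle(p_values) -> np.ndarray:
    """Literal BH: sort, multiply by m/rank, cumulative min from the largest."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        out[i] = running
    return np.array(out)


def fisher_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n), exact integer arithmetic."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return float(Fraction(total, denom))
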