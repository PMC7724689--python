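"""Independent brute-force oracles used to cross-check the package.

Pure-python, no networkx/scipy: shortest-path enumeration for the
centrality metrics, iterative peeling for coreness, and exact rational
enumeration for the hypergeometric tail.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction


def _bfs_dist(adj: dict, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _all_shortest_paths(adj: dict, s, t, dist_s: dict):
    """DFS enumeration of every geodesic from s to t."""
    if t not in dist_s:
        return []
    target_len = dist_s[t]
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(list(path))
            return
        for nxt in adj[node]:
            if nxt in dist_s and dist_s[nxt] == dist_s[node] + 1 and dist_s[t] >= dist_s[nxt]:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    if target_len == 0:
        return [[s]]
    walk(s, [s])
    return [p for p in paths if len(p) - 1 == target_len]


def bf_betweenness(adj: dict) -> dict:
    """Unnormalized betweenness with equal splitting among geodesics."""
    nodes = list(adj)
    btw = {v: Fraction(0) for v in nodes}
    for i, s in enumerate(nodes):
        dist_s = _bfs_dist(adj, s)
        for t in nodes[i + 1 :]:
            paths = _all_shortest_paths(adj, s, t, dist_s)
            if not paths:
                continue
            share = Fraction(1, len(paths))
            for p in paths:
                for v in p[1:-1]:
                    btw[v] += share
    return {v: float(x) for v, x in btw.items()}


def bf_closeness_wf(adj: dict) -> dict:
    """Wasserman-Faust component-scaled closeness: (r/(n-1)) * (r/sum d)."""
    nodes = list(adj)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = _bfs_dist(adj, v)
        r = len(dist) - 1
        total = sum(dist.values())
        out[v] = (r / (n - 1)) * (r / total) if r > 0 and n > 1 else 0.0
    return out


def bf_coreness(adj: dict) -> dict:
    """k-core index by iterative peeling."""
    degrees = {v: len(adj[v]) for v in adj}
    alive = set(adj)
    core = {}
    k = 0
    while alive:
        while True:
            peel = [v for v in alive if degrees[v] <= k]
            if not peel:
                break
            for v in peel:
                core[v] = k
                alive.discard(v)
                for u in adj[v]:
                    if u in alive:
                        degrees[u] -= 1
        k += 1
    return core


def enum_hypergeom_tail_counts(N: int, K: int, n: int) -> dict[int, Fraction]:
    """P[X >= k] for every k, by exhaustive enumeration of all C(N, n) draws."""
    marked = set(range(K))
    overlap_counts: dict[int, int] = {}
    total = 0
    for draw in itertools.combinations(range(N), n):
        c = sum(1 for x in draw if x in marked)
        overlap_counts[c] = overlap_counts.get(c, 0) + 1
        total += 1
    tails: dict[int, Fraction] = {}
    for k in range(0, min(K, n) + 1):
        above = sum(cnt for c, cnt in overlap_counts.items() if c >= k)
        tails[k] = Fraction(above, total)
    return tails


def graph_to_adj(g) -> dict:
    """networkx graph -> plain adjacency dict of sets (for the oracles)."""
    return {v: set(g.neighbors(v)) for v in g.nodes}
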