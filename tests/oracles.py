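"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library code paths (and networkx/scipy/
statsmodels routines) that the package itself uses: betweenness by explicit
enumeration of every shortest path, hypergeometric tails by exact rational
arithmetic and by literal draw enumeration, Holm by its five-line textbook
definition, and term grouping by union-find.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb


def _bfs_dist(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def enumerate_shortest_paths(adj: dict, s, t) -> list[list]:
    """All shortest s-t paths, by DFS guided by BFS distances to t."""
    dist_t = _bfs_dist(adj, t)
    if s not in dist_t:
        return []
    paths: list[list] = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for nxt in adj[node]:
            if dist_t.get(nxt, -1) == dist_t[node] - 1:
                walk(nxt, path + [nxt])

    walk(s, [s])
    return paths


def betweenness_by_enumeration(edges, nodes) -> dict:
    """Normalised betweenness from explicit all-pairs path enumeration."""
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    raw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                raw[v] += 1.0 / len(paths)
    n = len(nodes)
    if n <= 2:
        return {v: 0.0 for v in nodes}
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: raw[v] * scale for v in nodes}


def hypergeom_two_sided_exact(k: int, K: int, n: int, N: int) -> tuple[str, Fraction]:
    """Exact two-sided doubled-tail p-value with rational arithmetic."""
    total = comb(N, n)
    pmf = {x: Fraction(comb(K, x) * comb(N - K, n - x), total)
           for x in range(max(0, K + n - N), min(K, n) + 1)}
    upper = sum(p for x, p in pmf.items() if x >= k)
    lower = sum(p for x, p in pmf.items() if x <= k)
    direction = "enriched" if upper <= lower else "depleted"
    return direction, min(Fraction(1), 2 * min(upper, lower))


def hypergeom_tails_by_draws(k: int, K: int, n: int, N: int) -> tuple[Fraction, Fraction]:
    """Upper/lower tails by literally enumerating every size-n draw from a
    universe whose first K elements are 'in the term'.  Tiny N only."""
    in_term = set(range(K))
    hits_ge = 0
    hits_le = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        x = len(in_term.intersection(draw))
        total += 1
        if x >= k:
            hits_ge += 1
        if x <= k:
            hits_le += 1
    return Fraction(hits_ge, total), Fraction(hits_le, total)


def holm_by_definition(p_values) -> list[float]:
    """Textbook Holm: sort, multiply by decreasing factors, cumulative max."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    out = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p_values[idx]))
        out[idx] = running
    return out


def components_by_union_find(nodes, edges) -> set[frozenset]:
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return {frozenset(g) for g in groups.values()}


def kappa_from_vectors(x: list[int], y: list[int]) -> float:
    """Cohen's kappa of two binary vectors, from the 2x2 confusion counts."""
    n = len(x)
    a = sum(1 for i in range(n) if x[i] and y[i])
    b = sum(1 for i in range(n) if x[i] and not y[i])
    c = sum(1 for i in range(n) if not x[i] and y[i])
    d = n - a - b - c
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)
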