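"""Independent brute-force oracles used to validate the library.

Everything here is deliberately naive — exhaustive enumeration, hand-written
BFS, fraction arithmetic — and shares no code path with the package.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from itertools import combinations
from math import comb


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by enumerating every C(N, n) draw from a population of N
    items whose first K are successes. Exact rational arithmetic."""
    successes = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n) if len(successes.intersection(draw)) >= k)
    return Fraction(hits, comb(N, n))


def bfs_distances(adj: dict, source) -> dict:
    """Plain queue BFS over an adjacency mapping."""
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def adjacency(nodes, edges) -> dict:
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def separation_score(nodes, edges, genes_i, genes_j):
    """Network separation s_ij by explicit BFS, mirroring the documented
    conventions: within-term = mean nearest-other-gene distance (0 for a
    singleton), cross-term = mean over genes of both sets of the nearest
    opposite-set distance (shared gene -> 0), unreachable genes excluded,
    None when no finite cross-distance exists."""
    adj = adjacency(nodes, edges)
    genes_i = [g for g in genes_i if g in adj]
    genes_j = [g for g in genes_j if g in adj]
    if not genes_i or not genes_j:
        return None
    dist = {g: bfs_distances(adj, g) for g in set(genes_i) | set(genes_j)}

    def within(genes):
        if len(genes) <= 1:
            return 0.0
        vals = []
        for g in genes:
            ds = [dist[g][h] for h in genes if h != g and h in dist[g]]
            if ds:
                vals.append(min(ds))
        return sum(vals) / len(vals) if vals else 0.0

    cross_vals = []
    for src, dst in ((genes_i, genes_j), (genes_j, genes_i)):
        for g in src:
            if g in dst:
                cross_vals.append(0)
                continue
            ds = [dist[g][h] for h in dst if h in dist[g]]
            if ds:
                cross_vals.append(min(ds))
    if not cross_vals:
        return None
    d_cross = sum(cross_vals) / len(cross_vals)
    return d_cross - (within(genes_i) + within(genes_j)) / 2.0


def betweenness_by_path_enumeration(nodes, edges) -> dict:
    """Unnormalised node betweenness by enumerating every shortest path of
    every unordered node pair (endpoints excluded, equal-length paths split
    evenly)."""
    adj = adjacency(nodes, edges)
    nodes = list(nodes)
    bet = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            if t not in dist or t == s:
                continue
            paths = []

            def extend(path):
                v = path[-1]
                if v == t:
                    paths.append(path)
                    return
                for w in adj[v]:
                    if w in dist and dist[w] == dist[v] + 1 and dist[w] <= dist[t]:
                        extend(path + [w])

            extend([s])
            for p in paths:
                for v in p[1:-1]:
                    bet[v] += 1.0 / len(paths)
    return bet


def venn_regions_by_membership(sets: dict) -> dict:
    """Exclusive Venn regions via per-item membership vectors."""
    labels = sorted(sets)
    out = {}
    for item in set().union(*map(set, sets.values())):
        key = tuple(lab for lab in labels if item in sets[lab])
        out.setdefault(key, set()).add(item)
    return out
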