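"""Independent brute-force oracles used to validate the library's algorithms.

Everything here is deliberately naive — subset enumeration, hand-rolled BFS,
exact combinatorial sums — and shares no code path with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def brute_maximal_cliques(nodes, edges, min_size):
    """All maximal cliques of size >= min_size by checking every vertex subset."""
    nodes = sorted(nodes)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(subset):
        return all(frozenset((a, b)) in edge_set for a, b in combinations(subset, 2))

    cliques = [
        frozenset(sub)
        for r in range(min_size, len(nodes) + 1)
        for sub in combinations(nodes, r)
        if is_clique(sub)
    ]
    return {
        c for c in cliques
        if not any(c < other for other in cliques)
    }


def brute_k_cliques(nodes, edges, k):
    """All complete k-vertex subgraphs, by direct subset checking."""
    edge_set = {frozenset(e) for e in edges}
    return {
        frozenset(sub)
        for sub in combinations(sorted(nodes), k)
        if all(frozenset((a, b)) in edge_set for a, b in combinations(sub, 2))
    }


def brute_k_clique_percolation(nodes, edges, k):
    """k-clique communities from first principles.

    Enumerate exact k-cliques, link the ones sharing k-1 vertices, take
    connected components of that adjacency, and union each component's
    cliques.  This is the textbook definition, independent of the
    overlap-matrix route.
    """
    kcliques = sorted(brute_k_cliques(nodes, edges, k), key=lambda c: tuple(sorted(c)))
    n = len(kcliques)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if len(kcliques[i] & kcliques[j]) == k - 1:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).update(kcliques[i])
    return {frozenset(members) for members in groups.values()}


def brute_hypergeom_tail(n_total, c_size, f_size, k_hit):
    """Exact upper-tail hypergeometric probability via comb sums."""
    denom = comb(n_total, c_size)
    total = 0
    for i in range(k_hit, min(c_size, f_size) + 1):
        if c_size - i <= n_total - f_size:
            total += comb(f_size, i) * comb(n_total - f_size, c_size - i)
    return total / denom


def brute_induced_diameter(nodes, edges, members):
    """Diameter of the induced subgraph via hand-rolled BFS; inf if disconnected."""
    members = set(members)
    adj = {v: set() for v in members}
    for a, b in edges:
        if a in members and b in members and a != b:
            adj[a].add(b)
            adj[b].add(a)
    best = 0
    for source in members:
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        if len(dist) < len(members):
            return float("inf")
        best = max(best, max(dist.values()))
    return best
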