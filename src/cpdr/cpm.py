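"""Clique Percolation Method (CPM) baseline.

A k-clique community is the union of all k-cliques reachable from one
another through adjacent k-cliques, adjacency meaning k-1 shared vertices.
The classic extraction works at the level of *maximal* cliques: build the
clique-clique overlap matrix, zero off-diagonal entries below k-1, drop
cliques smaller than k, and read communities off the connected components
of what remains.  Communities may share vertices, but each maximal clique
belongs to exactly one community; a clique adjacent to nothing forms a
community on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cliques import clique_sort_key, maximal_cliques, overlap_matrix

__all__ = ["Community", "kclique_communities"]


@dataclass(frozen=True)
class Community:
    """A k-clique community: the union of its component's maximal cliques."""

    members: frozenset[str]
    k: int
    cliques: tuple[frozenset[str], ...]  # provenance: the merged maximal cliques

    def __len__(self) -> int:
        return len(self.members)


def kclique_communities(g: nx.Graph, k: int) -> list[Community]:
    """Extract all k-clique communities of ``g`` via the overlap matrix.

    Parameters
    ----------
    g : networkx.Graph
        Undirected simple interaction graph.
    k : int
        Clique percolation parameter, at least 3.
    """
    if k < 3:
        raise ValueError("clique percolation parameter k must be >= 3")
    cliques = maximal_cliques(g, min_size=k)  # diagonal < k already dropped
    if not cliques:
        return []
    counts = overlap_matrix(cliques).counts
    adjacency = counts >= (k - 1)
    np.fill_diagonal(adjacency, False)
    comp_graph = nx.from_numpy_array(adjacency)
    communities = []
    for component in nx.connected_components(comp_graph):
        merged = tuple(sorted((cliques[i] for i in component), key=clique_sort_key))
        members = frozenset().union(*merged)
        communities.append(Community(members=members, k=k, cliques=merged))
    return sorted(communities, key=lambda c: clique_sort_key(c.members))
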