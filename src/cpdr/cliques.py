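"""Maximal-clique and k-clique enumeration, and the clique-clique overlap matrix.

Cliques are represented as frozensets of protein identifiers.  All public
functions return cliques in a canonical order — size descending, ties broken
by the lexicographically smallest sorted member tuple — so that downstream
merge loops scan a deterministic sequence and repeated runs are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Clique",
    "OverlapMatrix",
    "clique_sort_key",
    "maximal_cliques",
    "k_cliques",
    "overlap_matrix",
    "write_cliques",
]

Clique = frozenset  # alias: a clique is just its member set


def clique_sort_key(members: Iterable[str]):
    """Canonical ordering key: larger cliques first, then lexicographic members."""
    ordered = tuple(sorted(members))
    return (-len(ordered), ordered)


def maximal_cliques(g: nx.Graph, min_size: int = 3) -> list[frozenset[str]]:
    """Enumerate all maximal cliques of ``g`` with at least ``min_size`` members.

    Uses pivoting Bron–Kerbosch recursion (via networkx).  The result
    contains exactly the maximal cliques — no returned clique is a subset of
    another — in canonical order.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    found = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= min_size]
    return sorted(found, key=clique_sort_key)


def k_cliques(g: nx.Graph, k: int) -> list[frozenset[str]]:
    """Enumerate all complete subgraphs of size exactly ``k``.

    Every k-subset of every maximal clique of size >= k is complete; the
    union of those subsets, deduplicated, is exactly the set of k-cliques.
    Cost is combinatorial in the largest clique size — intended for
    moderate graphs and oracle checks, not genome-scale sweeps.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    out: set[frozenset[str]] = set()
    for mc in nx.find_cliques(g):
        if len(mc) >= k:
            out.update(frozenset(sub) for sub in combinations(sorted(mc), k))
    return sorted(out, key=clique_sort_key)


@dataclass(frozen=True)
class OverlapMatrix:
    """Clique–clique overlap matrix.

    ``counts[i, j]`` is the number of shared members between cliques i and j;
    the diagonal carries clique sizes.  Symmetric by construction.
    """

    cliques: tuple[frozenset[str], ...]
    counts: np.ndarray

    def __post_init__(self):
        n = len(self.cliques)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the clique list")


def overlap_matrix(cliques: Sequence[frozenset[str]]) -> OverlapMatrix:
    """Build the clique–clique overlap matrix from an ordered clique list."""
    cliques = tuple(frozenset(c) for c in cliques)
    vertices = sorted(set().union(*cliques)) if cliques else []
    index = {v: j for j, v in enumerate(vertices)}
    incidence = np.zeros((len(cliques), len(vertices)), dtype=np.int64)
    for i, c in enumerate(cliques):
        for v in c:
            incidence[i, index[v]] = 1
    counts = incidence @ incidence.T
    return OverlapMatrix(cliques=cliques, counts=counts)


def write_cliques(cliques: Iterable[frozenset[str]], sink) -> None:
    """Write one clique per line: tab-separated, sorted member identifiers."""
    from .io import write_vertex_sets

    write_vertex_sets(cliques, sink)
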