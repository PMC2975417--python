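"""Distance-restricted clique merging (CP-DR) — the core detection algorithm.

CPM's fixed percolation parameter k forces a trade-off: small k glues most
of a dense interaction network into one giant community, large k leaves
almost nothing but isolated cliques.  CP-DR replaces the fixed-k adjacency
rule with two per-pair conditions on basic cluster units U, V (initially the
maximal cliques of size >= 3):

* shared-vertex condition: ``|U ∩ V| >= MIN(|U|, |V|) - 1``, i.e. the
  smaller unit must share all but one of its members with the larger;
* distance restriction: the subgraph induced by ``U ∪ V`` has diameter at
  most ``d`` (default d = 2, motivated by the small-world structure of
  interaction networks and the observation that almost all curated yeast
  complexes have diameter <= 2).

Mergeable pairs produce their union as a new unit appended to the pool; a
unit that merged at least once is retired after it has been compared against
every other unit.  Scanning repeats until a pass produces no merge.  Every
emitted cluster therefore has induced diameter <= d and at least 3 members,
and clusters may overlap — a protein can sit in several complexes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .cliques import clique_sort_key, maximal_cliques

__all__ = [
    "INFINITE",
    "ClusterUnit",
    "CpdrParams",
    "induced_diameter",
    "merge_condition",
    "cpdr_clusters",
]

logger = logging.getLogger(__name__)

#: Sentinel diameter of a disconnected induced subgraph.
INFINITE = math.inf


@dataclass(frozen=True)
class CpdrParams:
    """Tunable parameters of the merge procedure.

    d : maximum induced diameter of any emitted cluster, in hops (default 2).
    min_clique_size : smallest maximal clique admitted as a basic unit
        (default 3; an edge alone is not evidence of a complex).
    """

    d: int = 2
    min_clique_size: int = 3

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.min_clique_size < 3:
            raise ValueError("min_clique_size must be >= 3")


@dataclass(frozen=True)
class ClusterUnit:
    """A (possibly merged) cluster unit with its contributing maximal cliques."""

    members: frozenset[str]
    provenance: tuple[frozenset[str], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.members)


def induced_diameter(g: nx.Graph, members) -> float:
    """Diameter of the subgraph of ``g`` induced by ``members``.

    Only edges of ``g`` between members count.  Returns :data:`INFINITE`
    when the induced subgraph is disconnected, so a distance restriction
    ``<= d`` is automatically violated by disconnected unions.
    """
    members = set(members)
    if not members:
        raise ValueError("members must be non-empty")
    missing = members - set(g)
    if missing:
        raise ValueError(f"members not in graph: {sorted(missing)[:5]}")
    if len(members) == 1:
        return 0
    sub = g.subgraph(members)
    best = 0
    # BFS from every member; cheaper than generic all-pairs machinery on
    # the small vertex sets units reach under d <= 2.
    for source in members:
        dist = nx.single_source_shortest_path_length(sub, source)
        if len(dist) < len(members):
            return INFINITE
        ecc = max(dist.values())
        if ecc > best:
            best = ecc
    return best


def merge_condition(
    g: nx.Graph, u: ClusterUnit, v: ClusterUnit, params: CpdrParams
) -> bool:
    """Decide whether units ``u`` and ``v`` merge.

    True iff they share at least ``MIN(|U|, |V|) - 1`` vertices and the
    subgraph induced by their union has diameter at most ``params.d``.
    """
    mu, mv = u.members, v.members
    if mu == mv:
        raise ValueError("merge_condition requires distinct member sets")
    needed = min(len(mu), len(mv)) - 1
    if len(mu & mv) < needed:
        return False
    return induced_diameter(g, mu | mv) <= params.d


def _merged_provenance(u: ClusterUnit, v: ClusterUnit) -> tuple[frozenset[str], ...]:
    seen = dict.fromkeys(u.provenance)
    seen.update(dict.fromkeys(v.provenance))
    return tuple(sorted(seen, key=clique_sort_key))


def cpdr_clusters(
    g: nx.Graph,
    params: CpdrParams | None = None,
    *,
    absorb_subsets: bool = False,
    max_passes: int = 1000,
) -> list[ClusterUnit]:
    """Detect overlapping clusters by distance-restricted clique merging.

    Procedure: initialise the unit pool with the maximal cliques of size
    >= ``params.min_clique_size`` in canonical order; scan units in order,
    comparing each against every other unit in the (growing) pool and
    appending each mergeable pair's union at the tail; retire a unit after
    its scan iff it merged at least once; repeat until a full pass produces
    no merge; drop exact duplicates and emit in canonical order.

    A union is only appended if its member set has never been in the pool,
    which bounds the number of units ever created and guarantees
    termination; ``max_passes`` is a hard safety cap that is never reached
    in practice.

    With ``absorb_subsets=True`` clusters that are proper subsets of
    another emitted cluster are additionally removed (at the fixpoint this
    is normally a no-op, since a subset unit always satisfies both merge
    conditions against its superset and is retired by the scan itself).
    """
    if params is None:
        params = CpdrParams()
    pool: list[ClusterUnit] = [
        ClusterUnit(members=c, provenance=(c,))
        for c in maximal_cliques(g, params.min_clique_size)
    ]
    ever_seen: set[frozenset[str]] = {u.members for u in pool}
    units_by_members: dict[frozenset[str], ClusterUnit] = {u.members: u for u in pool}

    passes = 0
    while True:
        passes += 1
        if passes > max_passes:
            raise RuntimeError(f"merge scan did not stabilise within {max_passes} passes")
        merged_in_pass = False
        i = 0
        while i < len(pool):
            u = pool[i]
            u_merged = False
            j = 0
            while j < len(pool):
                if j == i:
                    j += 1
                    continue
                v = pool[j]
                if merge_condition(g, u, v, params):
                    union = u.members | v.members
                    if union not in ever_seen:
                        ever_seen.add(union)
                        w = ClusterUnit(members=union, provenance=_merged_provenance(u, v))
                        units_by_members[union] = w
                        pool.append(w)
                    if union != u.members:
                        u_merged = True
                j += 1
            if u_merged:
                pool.pop(i)
                merged_in_pass = True
            else:
                i += 1
        logger.info("pass %d: pool size %d", passes, len(pool))
        if not merged_in_pass:
            break

    clusters = pool  # member sets are unique by construction
    if absorb_subsets:
        keep = []
        member_sets = [u.members for u in clusters]
        for u in clusters:
            if not any(u.members < other for other in member_sets):
                keep.append(u)
        clusters = keep
    return sorted(clusters, key=lambda u: clique_sort_key(u.members))
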