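"""Protein-protein interaction networks: parsing, construction, summary statistics.

Interaction data arrives as tab-delimited edge lists (one interaction per
line, two or more columns, ``#`` comments).  Parsing and graph construction
are deliberately separated: :func:`load_interactions` reports the file
verbatim, while :func:`build_graph` applies the cleaning every analysis
assumes — self-interactions removed, duplicate pairs (in either order)
collapsed — yielding an undirected simple :class:`networkx.Graph` with
proteins as vertices and interactions as edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, TextIO, Union

import networkx as nx

__all__ = [
    "Interaction",
    "NetworkStats",
    "ParseError",
    "load_interactions",
    "build_graph",
    "network_stats",
    "write_edges",
]

Source = Union[str, Path, TextIO]


class Interaction(NamedTuple):
    """A single reported interaction between two proteins (possibly a self-loop)."""

    protein_a: str
    protein_b: str


class ParseError(ValueError):
    """Raised for malformed edge-list lines; the message names the line number."""


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics of an interaction network.

    ``diameter`` and ``avg_shortest_path`` are hop counts over the largest
    connected component; ``avg_clustering_coefficient`` averages the local
    clustering coefficient over *all* vertices, with degree-0/1 vertices
    contributing 0.
    """

    n_vertices: int
    n_edges: int
    avg_clustering_coefficient: float
    diameter: int
    avg_shortest_path: float


def _open_maybe(source: Source) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def load_interactions(source: Source, delimiter: str = "\t") -> list[Interaction]:
    """Parse an edge list into raw interactions, preserving file order.

    Lines starting with ``#`` and blank lines are skipped.  Each remaining
    line must carry at least two delimited fields (extra columns, e.g.
    confidence scores, are ignored).  Self-loops are *kept* at this stage;
    :func:`build_graph` removes them.

    Raises
    ------
    ParseError
        If a data line has fewer than two fields or an empty identifier;
        the message names the 1-based line number.
    """
    handle, should_close = _open_maybe(source)
    interactions: list[Interaction] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split(delimiter)
            if len(fields) < 2:
                raise ParseError(
                    f"line {lineno}: expected >= 2 fields separated by "
                    f"{delimiter!r}, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ParseError(f"line {lineno}: empty protein identifier")
            interactions.append(Interaction(a, b))
    finally:
        if should_close:
            handle.close()
    return interactions


def build_graph(interactions: Iterable[Interaction]) -> nx.Graph:
    """Build the undirected simple interaction graph.

    Self-interactions are dropped and repeated pairs (in either order)
    collapsed to a single edge.  Proteins that appear only in self-loops do
    not enter the vertex set: they would be isolated and affect no
    downstream computation.
    """
    g = nx.Graph()
    for a, b in interactions:
        if a != b:
            g.add_edge(a, b)
    return g


def network_stats(g: nx.Graph) -> NetworkStats:
    """Compute the descriptive statistics of an interaction network.

    The average clustering coefficient is the mean of the local clustering
    coefficient over all vertices (degree < 2 contributes 0).  Because real
    interaction networks are typically disconnected, the diameter and the
    average vertex distance are computed over the largest connected
    component.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("network_stats requires a non-empty graph")
    cc = nx.average_clustering(g)
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    if giant.number_of_nodes() == 1:
        diameter, avg_path = 0, 0.0
    else:
        diameter = nx.diameter(giant)
        avg_path = nx.average_shortest_path_length(giant)
    return NetworkStats(
        n_vertices=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        avg_clustering_coefficient=cc,
        diameter=diameter,
        avg_shortest_path=avg_path,
    )


def write_edges(g: nx.Graph, sink: Source, delimiter: str = "\t") -> None:
    """Write the graph as a canonical edge list (sorted pairs, sorted lines)."""
    lines = sorted(delimiter.join(sorted((a, b))) for a, b in g.edges())
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(sink, (str, Path)):
        from .io import write_text_atomic

        write_text_atomic(sink, text)
    else:
        sink.write(text)


def _stats_lines(stats: NetworkStats) -> list[str]:
    # key<TAB>value rendering shared by the CLI
    return [
        f"n_vertices\t{stats.n_vertices}",
        f"n_edges\t{stats.n_edges}",
        f"avg_clustering_coefficient\t{stats.avg_clustering_coefficient:.6g}",
        f"diameter\t{stats.diameter}",
        f"avg_shortest_path\t{stats.avg_shortest_path:.6g}",
    ]
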