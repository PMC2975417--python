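"""Planted-complex benchmark graphs with known ground truth.

The generator emulates the regime the detection algorithms target: a
protein interaction network containing meso-scale complexes (5–25 proteins)
that may share members.  Complexes are laid out in a chain — consecutive
complexes share ``overlap_size`` vertices — so the expected behaviour of
the merge rule is analytically derivable for every adjacent pair.  Within a
complex every pair of proteins interacts with probability
``intra_density``; ``noise_edges`` spurious interactions connect proteins
that share no complex.  A single integer seed drives all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .ppi_graph import write_edges

__all__ = ["GeneratorParams", "PlantedBenchmark", "generate", "write_benchmark"]


@dataclass(frozen=True)
class GeneratorParams:
    """Benchmark settings; defaults follow the meso-scale regime (sizes 5–25)."""

    n_complexes: int = 10
    size_min: int = 5
    size_max: int = 25
    overlap_size: int = 2
    intra_density: float = 1.0
    noise_edges: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.size_min < 3:
            raise ValueError("size_min must be >= 3")
        if self.size_max < self.size_min:
            raise ValueError("size_max must be >= size_min")
        if not (0 <= self.overlap_size < self.size_min):
            raise ValueError("overlap_size must satisfy 0 <= overlap_size < size_min")
        if not (0 < self.intra_density <= 1):
            raise ValueError("intra_density must lie in (0, 1]")
        if self.n_complexes < 1 or self.noise_edges < 0:
            raise ValueError("n_complexes >= 1 and noise_edges >= 0 required")


@dataclass(frozen=True)
class PlantedBenchmark:
    """A generated graph plus its planted ground-truth complexes."""

    graph: nx.Graph
    truth: tuple[frozenset[str], ...]
    params: GeneratorParams


def generate(params: GeneratorParams) -> PlantedBenchmark:
    """Generate a planted-complex benchmark; same params -> identical output."""
    rng = np.random.default_rng(params.seed)
    sizes = rng.integers(params.size_min, params.size_max + 1, params.n_complexes)

    # Chain layout: each complex reuses the last overlap_size vertices of its
    # predecessor as its first members.
    truth: list[frozenset[str]] = []
    next_id = 0
    prev_tail: list[str] = []
    for size in sizes:
        fresh_needed = int(size) - len(prev_tail)
        fresh = [f"P{next_id + i:05d}" for i in range(fresh_needed)]
        next_id += fresh_needed
        members = prev_tail + fresh
        truth.append(frozenset(members))
        prev_tail = members[-params.overlap_size :] if params.overlap_size else []

    g = nx.Graph()
    for complex_members in truth:
        ordered = sorted(complex_members)
        g.add_nodes_from(ordered)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                if params.intra_density >= 1.0 or rng.random() < params.intra_density:
                    g.add_edge(ordered[i], ordered[j])

    vertices = sorted(g.nodes())
    co_complex = {
        frozenset((a, b))
        for c in truth
        for a in c
        for b in c
        if a < b
    }
    added = 0
    attempts = 0
    max_attempts = 200 * max(params.noise_edges, 1)
    while added < params.noise_edges and attempts < max_attempts:
        attempts += 1
        a, b = (vertices[int(k)] for k in rng.integers(0, len(vertices), 2))
        if a == b or g.has_edge(a, b) or frozenset((a, b)) in co_complex:
            continue
        g.add_edge(a, b)
        added += 1
    if added < params.noise_edges:
        raise ValueError(
            f"could not place {params.noise_edges} noise edges "
            f"(graph too small or too dense); placed {added}"
        )
    return PlantedBenchmark(graph=g, truth=tuple(truth), params=params)


def write_benchmark(bench: PlantedBenchmark, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.edges.tsv`` and ``<prefix>.truth.tsv`` (catalog format)."""
    prefix = Path(out_prefix)
    edges_path = prefix.with_name(prefix.name + ".edges.tsv")
    truth_path = prefix.with_name(prefix.name + ".truth.tsv")
    write_edges(bench.graph, edges_path)
    lines = [
        f"complex{i + 1:03d}\t" + "\t".join(sorted(members))
        for i, members in enumerate(bench.truth)
    ]
    from .io import write_text_atomic

    write_text_atomic(truth_path, "\n".join(lines) + "\n")
    return edges_path, truth_path
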