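from __future__ import annotations

import networkx as nx
import pytest


def graph_from_edges(*edges: tuple[str, str]) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


def complete_graph(labels) -> nx.Graph:
    g = nx.Graph()
    labels = list(labels)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            g.add_edge(labels[i], labels[j])
    return g


def random_graph_corpus(n_graphs: int, max_nodes: int = 12, seed0: int = 0):
    """Seeded Erdos–Renyi corpus with varied sizes and densities."""
    corpus = []
    for i in range(n_graphs):
        n = 4 + (i % (max_nodes - 3))
        p = (0.2, 0.35, 0.5, 0.65, 0.8)[i % 5]
        g = nx.gnp_random_graph(n, p, seed=seed0 + i)
        corpus.append(nx.relabel_nodes(g, {v: f"v{v}" for v in g.nodes()}))
    return corpus


@pytest.fixture
def triangle() -> nx.Graph:
    return graph_from_edges(("A", "B"), ("B", "C"), ("A", "C"))


@pytest.fixture
def path_abc() -> nx.Graph:
    return graph_from_edges(("A", "B"), ("B", "C"))


@pytest.fixture
def two_shared_edge_triangles() -> nx.Graph:
    """Triangles {A,B,C} and {B,C,D} sharing the edge {B,C}."""
    return graph_from_edges(("A", "B"), ("B", "C"), ("A", "C"), ("B", "D"), ("C", "D"))


@pytest.fixture
def two_shared_vertex_triangles() -> nx.Graph:
    """Triangles {A,B,C} and {C,D,E} sharing only vertex C."""
    return graph_from_edges(
        ("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("D", "E"), ("C", "E")
    )


@pytest.fixture
def two_four_cliques() -> nx.Graph:
    """K4 on {A,B,C,D} and K4 on {A,B,C,E}; the edge D–E is absent."""
    g = complete_graph("ABCD")
    for v in "ABC":
        g.add_edge(v, "E")
    return g
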