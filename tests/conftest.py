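import networkx as nx
import numpy as np
import pytest

from pangenet import GenePresenceAbsenceMatrix, SyntheticPangenomeConfig


def make_graph(edges):
    """Build a weighted graph from (a, b, w) triples."""
    graph = nx.Graph()
    for a, b, w in edges:
        graph.add_edge(a, b, weight=w)
    return graph


def random_weighted_graph(rng, n_nodes, edge_prob=0.5):
    graph = nx.Graph()
    names = [f"n{i:02d}" for i in range(n_nodes)]
    graph.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                graph.add_edge(names[i], names[j], weight=float(rng.integers(1, 100)) / 10.0)
    return graph


def random_matrix(rng, n_genomes, n_genes):
    """Random binary matrix with no all-zero gene column."""
    values = (rng.random((n_genomes, n_genes)) < 0.4).astype(np.int8)
    empty = values.sum(axis=0) == 0
    values[rng.integers(n_genomes, size=int(empty.sum())), np.flatnonzero(empty)] = 1
    return GenePresenceAbsenceMatrix(
        genome_ids=[f"g{i:03d}" for i in range(n_genomes)],
        gene_ids=[f"gene{j:03d}" for j in range(n_genes)],
        values=values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    # 4 genomes x 5 genes; gene4 is core (all ones)
    values = np.array(
        [
            [1, 1, 1, 0, 1],
            [0, 1, 1, 1, 1],
            [1, 0, 0, 1, 1],
            [1, 1, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenePresenceAbsenceMatrix(
        genome_ids=["gA", "gB", "gC", "gD"],
        gene_ids=["gene1", "gene2", "gene3", "gene4", "core1"],
        values=values,
    )


@pytest.fixture
def two_cliques():
    """Two 4-cliques with unit weights joined by a single unit edge."""
    graph = nx.Graph()
    left = ["a1", "a2", "a3", "a4"]
    right = ["b1", "b2", "b3", "b4"]
    for group in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                graph.add_edge(group[i], group[j], weight=1.0)
    graph.add_edge("a1", "b1", weight=1.0)
    return graph


@pytest.fixture
def sim_config():
    return SyntheticPangenomeConfig(seed=7)
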