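import math

import networkx as nx
import pytest

import pangenet as pg
from pangenet.errors import ValidationError
from pangenet.transforms import TransformLog

from .conftest import make_graph, random_weighted_graph
from .oracles import exhaustive_knn_edges


class TestFilterEdgesMinWeight:
    def test_strict_comparison(self):
        graph = make_graph([("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", 0.7)])
        out = pg.filter_edges_min_weight(graph, 0.8)
        assert set(out.edges) == {("a", "b")}
        assert out.number_of_nodes() == 4  # isolated nodes retained

    def test_zero_threshold_is_identity(self):
        graph = make_graph([("a", "b", 0.1), ("b", "c", 0.2)])
        assert nx.utils.graphs_equal(pg.filter_edges_min_weight(graph, 0), graph)

    def test_infinite_threshold_isolates_everything(self):
        graph = make_graph([("a", "b", 5.0)])
        out = pg.filter_edges_min_weight(graph, math.inf)
        assert out.number_of_edges() == 0
        assert out.number_of_nodes() == 2


class TestKnnSparsify:
    def test_triangle_k1_union(self):
        graph = make_graph([("a", "b", 3.0), ("b", "c", 2.0), ("a", "c", 1.0)])
        out = pg.knn_sparsify(graph, 1)
        assert set(map(frozenset, out.edges)) == {
            frozenset(("a", "b")),
            frozenset(("b", "c")),
        }

    def test_star_leaves_always_survive(self):
        graph = make_graph([("hub", f"leaf{i}", float(i + 1)) for i in range(5)])
        out = pg.knn_sparsify(graph, 3)
        assert out.number_of_edges() == 5  # each leaf's only edge is its top-1

    def test_k_at_least_max_degree_is_identity(self, rng):
        graph = random_weighted_graph(rng, 10, 0.5)
        k = max(dict(graph.degree).values())
        assert nx.utils.graphs_equal(pg.knn_sparsify(graph, k), graph)

    def test_edge_bound_and_idempotence(self, rng):
        for _ in range(5):
            graph = random_weighted_graph(rng, 12, 0.6)
            out = pg.knn_sparsify(graph, 3)
            assert out.number_of_edges() <= graph.number_of_nodes() * 3
            again = pg.knn_sparsify(out, 3)
            assert nx.utils.graphs_equal(out, again)

    @pytest.mark.parametrize("mutual", [False, True])
    def test_matches_exhaustive_oracle(self, rng, mutual):
        for _ in range(20):
            graph = random_weighted_graph(rng, 15, 0.5)
            for k in (1, 2, 4, 8):
                out = pg.knn_sparsify(graph, k, mutual=mutual)
                expected = exhaustive_knn_edges(graph, k, mutual=mutual)
                assert set(map(frozenset, out.edges)) == expected


class TestFrequencyFilter:
    def graph_with_freq(self, freqs):
        graph = nx.Graph()
        for name, f in freqs.items():
            graph.add_node(name, frequency=f)
        names = list(freqs)
        for a, b in zip(names, names[1:]):
            graph.add_edge(a, b, weight=1.0)
        return graph

    def test_strict_bounds_on_778(self):
        graph = self.graph_with_freq({"full": 778, "seven": 7, "eight": 8, "mid": 400})
        out = pg.filter_nodes_by_frequency(graph, 778, min_frac=0.01, max_frac=0.99)
        # 778/778 > 0.99 removed; 7/778 < 1% removed; 8/778 ~ 1.03% retained
        assert set(out.nodes) == {"eight", "mid"}

    def test_incident_edges_removed_with_node(self):
        graph = self.graph_with_freq({"a": 10, "b": 1})
        out = pg.filter_nodes_by_frequency(graph, 10, min_frac=0.5)
        assert set(out.nodes) == {"a"} and out.number_of_edges() == 0

    def test_missing_frequency_attribute(self):
        graph = make_graph([("a", "b", 1.0)])
        with pytest.raises(ValidationError, match="frequency"):
            pg.filter_nodes_by_frequency(graph, 10, 0.1, 0.9)

    def test_matrix_variant(self, small_matrix):
        out = pg.filter_nodes_by_frequency(small_matrix, 4, min_frac=0.0, max_frac=0.99)
        assert "core1" not in out.gene_ids  # frequency 4/4 > 0.99
        assert set(out.gene_ids) == {"gene1", "gene2", "gene3", "gene4"}


class TestComponents:
    def test_filter_small_components(self):
        graph = nx.Graph()
        nx.add_path(graph, [f"a{i}" for i in range(12)], weight=1.0)
        nx.add_path(graph, [f"b{i}" for i in range(9)], weight=1.0)
        graph.add_node("lonely")
        out = pg.filter_small_components(graph, 10)
        assert set(out.nodes) == {f"a{i}" for i in range(12)}
        assert nx.utils.graphs_equal(pg.filter_small_components(graph, 1), graph)
        assert "lonely" not in pg.filter_small_components(graph, 2)

    def test_keep_largest_component(self):
        graph = make_graph([("a", "b", 1.0), ("c", "d", 1.0), ("d", "e", 1.0)])
        assert set(pg.keep_largest_component(graph).nodes) == {"c", "d", "e"}

    def test_keep_largest_tie_break(self):
        graph = make_graph([("c", "d", 1.0), ("a", "b", 1.0)])
        assert set(pg.keep_largest_component(graph).nodes) == {"a", "b"}

    def test_connected_graph_unchanged(self, two_cliques):
        assert nx.utils.graphs_equal(pg.keep_largest_component(two_cliques), two_cliques)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            pg.keep_largest_component(nx.Graph())

    def test_idempotence(self, rng):
        graph = random_weighted_graph(rng, 14, 0.15)
        once = pg.keep_largest_component(graph)
        assert nx.utils.graphs_equal(once, pg.keep_largest_component(once))


class TestContractCoreEdges:
    def test_chain_collapses_transitively(self):
        graph = make_graph([("a", "b", 10.0), ("b", "c", 10.0)])
        out = pg.contract_core_edges(graph, 9)
        assert out.number_of_nodes() == 1
        (node,) = out.nodes
        assert out.nodes[node]["member_genes"] == ["a", "b", "c"]
        assert out.number_of_edges() == 0

    def test_partial_contraction_keeps_outside_edge(self):
        graph = make_graph([("a", "b", 10.0), ("b", "c", 5.0)])
        out = pg.contract_core_edges(graph, 9)
        assert set(out.nodes) == {"a", "c"}
        assert out.nodes["a"]["member_genes"] == ["a", "b"]
        assert out["a"]["c"]["weight"] == 5.0

    def test_identical_circular_orders_collapse_to_one_node(self):
        orders = {
            f"g{i}": [pg.Contig(genes=[f"f{j:02d}" for j in range(50)], circular=True)]
            for i in range(100)
        }
        graph = pg.build_synteny_graph(orders)
        out = pg.contract_core_edges(graph, 99)
        assert out.number_of_nodes() == 1
        (node,) = out.nodes
        assert len(out.nodes[node]["member_genes"]) == 50

    def test_multiplicity_conserved_and_edges_never_increase(self, rng):
        for _ in range(10):
            graph = random_weighted_graph(rng, 12, 0.4)
            out = pg.contract_core_edges(graph, 5.0)
            total = sum(len(d["member_genes"]) for _, d in out.nodes(data=True))
            assert total == graph.number_of_nodes()
            assert out.number_of_edges() <= graph.number_of_edges()

    def test_parallel_edges_merge_by_max_by_default(self):
        graph = make_graph(
            [("a", "b", 10.0), ("a", "x", 3.0), ("b", "x", 7.0)]
        )
        out = pg.contract_core_edges(graph, 9)
        assert out["a"]["x"]["weight"] == 7.0
        out_sum = pg.contract_core_edges(graph, 9, merge="sum")
        assert out_sum["a"]["x"]["weight"] == 10.0

    def test_merged_frequency_is_max(self):
        graph = nx.Graph()
        graph.add_node("a", frequency=5)
        graph.add_node("b", frequency=9)
        graph.add_edge("a", "b", weight=10.0)
        out = pg.contract_core_edges(graph, 9)
        assert out.nodes["a"]["frequency"] == 9


class TestSelectNodesByAttribute:
    def setup_graph(self):
        graph = make_graph([("a", "b", 1.0), ("b", "c", 1.0)])
        for node, cc in zip("abc", ("CC5", "CC5", "CC8")):
            graph.nodes[node]["CC"] = cc
        return graph

    def test_induced_subgraph(self):
        out = pg.select_nodes_by_attribute(self.setup_graph(), "CC", {"CC5"})
        assert set(out.nodes) == {"a", "b"}
        assert out.number_of_edges() == 1

    def test_all_values_is_identity(self):
        graph = self.setup_graph()
        out = pg.select_nodes_by_attribute(graph, "CC", {"CC5", "CC8"})
        assert nx.utils.graphs_equal(out, graph)

    def test_empty_values_empty_graph(self):
        out = pg.select_nodes_by_attribute(self.setup_graph(), "CC", set())
        assert out.number_of_nodes() == 0

    def test_unknown_attribute(self):
        with pytest.raises(ValidationError):
            pg.select_nodes_by_attribute(self.setup_graph(), "host", {"human"})


class TestTransformLog:
    def test_replay_reproduces_pipeline(self, rng):
        graph = random_weighted_graph(rng, 15, 0.5)
        log = TransformLog()
        out = pg.filter_edges_min_weight(graph, 2.0, log=log)
        out = pg.knn_sparsify(out, 3, log=log)
        out = pg.keep_largest_component(out, log=log)
        out = pg.contract_core_edges(out, 8.0, log=log)
        replayed = log.replay(graph)
        assert nx.utils.graphs_equal(replayed, out)
        assert [r.op for r in log.records] == [
            "filter_edges_min_weight",
            "knn_sparsify",
            "keep_largest_component",
            "contract_core_edges",
        ]

    def test_counts_and_tsv(self, tmp_path):
        graph = make_graph([("a", "b", 1.0), ("b", "c", 5.0)])
        log = TransformLog()
        pg.filter_edges_min_weight(graph, 2.0, log=log)
        assert log.records[0].edges_removed == 1
        assert log.records[0].nodes_removed == 0
        path = tmp_path / "log.tsv"
        log.to_tsv(path)
        assert "filter_edges_min_weight" in path.read_text()
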