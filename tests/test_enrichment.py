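import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

import pangenet as pg
from pangenet.enrichment import benjamini_hochberg, bonferroni
from pangenet.errors import UsageError, ValidationError

from .oracles import fisher_p_exact, iter_all_tables


class TestFisherExact:
    def test_diagonal_table_enumeration_value(self):
        # margins (5,5)/(5,5): 6 tables, extreme one has mass 1/252 per tail
        assert pg.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_independent_table_p_one(self):
        assert pg.fisher_exact_2x2([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_degenerate_margin_p_one(self):
        assert pg.fisher_exact_2x2([[0, 0], [0, 5]]) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            pg.fisher_exact_2x2([[1, -1], [0, 2]])

    def test_invariant_under_simultaneous_row_col_swap(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            p1 = pg.fisher_exact_2x2([[a, b], [c, d]])
            p2 = pg.fisher_exact_2x2([[d, c], [b, a]])
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_exact_enumeration_sample(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            table = ((a, b), (c, d))
            assert pg.fisher_exact_2x2(table) == pytest.approx(
                fisher_p_exact(table), rel=1e-7, abs=1e-12
            )

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            table = rng.integers(0, 25, size=(2, 2))
            ours = pg.fisher_exact_2x2(table)
            theirs = scipy_fisher(table, alternative="two-sided").pvalue
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)


class TestAdjustments:
    def test_bh_monotone_and_clipped(self, rng):
        p = rng.random(50)
        adj = benjamini_hochberg(p)
        assert (adj <= 1.0).all() and (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_bh_equal_pvalues_unchanged(self):
        p = np.full(4, 2 / 252)
        assert benjamini_hochberg(p) == pytest.approx(p)

    def test_bh_known_example(self):
        # classical worked example
        p = np.array([0.01, 0.04, 0.03, 0.005])
        adj = benjamini_hochberg(p)
        assert adj == pytest.approx([0.02, 0.04, 0.04, 0.02])

    def test_bonferroni(self):
        assert bonferroni([0.01, 0.5]) == pytest.approx([0.02, 1.0])


class TestEnrichmentAnalysis:
    def test_identical_partitions_all_significant(self):
        attr_a = {f"n{i}": ("c1" if i < 5 else "c2") for i in range(10)}
        attr_b = {f"n{i}": ("x" if i < 5 else "y") for i in range(10)}
        results, any_sig = pg.enrichment_analysis(attr_a, attr_b, alpha=0.05)
        assert len(results) == 4
        for r in results:
            assert r.p == pytest.approx(2 / 252)
            assert r.adj_p == pytest.approx(2 / 252)  # BH on equal ps
            assert r.significant
        assert any_sig == {"c1": True, "c2": True}

    def test_constant_attr_b_all_p_one(self):
        attr_a = {f"n{i}": f"c{i % 3}" for i in range(9)}
        attr_b = {f"n{i}": "only" for i in range(9)}
        results, any_sig = pg.enrichment_analysis(attr_a, attr_b)
        assert len(results) == 3
        assert all(r.p == 1.0 for r in results)
        assert not any(any_sig.values())

    def test_single_node_universe(self):
        results, _ = pg.enrichment_analysis({"n": "a"}, {"n": "b"})
        assert len(results) == 1
        assert results[0].p == 1.0

    def test_missing_values_excluded_by_default(self):
        attr_a = {"n1": "c1", "n2": "NA", "n3": "c1"}
        attr_b = {"n1": "x", "n2": "x", "n3": "y"}
        results, _ = pg.enrichment_analysis(attr_a, attr_b)
        universe = sum(results[0].table)
        assert universe == 2
        results_na, _ = pg.enrichment_analysis(attr_a, attr_b, include_missing=True)
        assert sum(results_na[0].table) == 3

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            pg.enrichment_analysis({"a": "x"}, {"b": "y"})

    def test_adj_p_never_below_p(self, rng):
        attr_a = {f"n{i}": f"c{rng.integers(3)}" for i in range(40)}
        attr_b = {f"n{i}": f"v{rng.integers(4)}" for i in range(40)}
        results, _ = pg.enrichment_analysis(attr_a, attr_b)
        for r in results:
            assert r.adj_p >= r.p - 1e-12
            assert r.adj_p <= 1.0


class TestProfiles:
    def matrix(self):
        values = np.array(
            [
                [1, 1, 0, 0, 1],
                [1, 0, 0, 0, 1],
                [0, 0, 1, 1, 1],
            ],
            dtype=np.int8,
        )
        return pg.GenePresenceAbsenceMatrix(
            genome_ids=["gA", "gB", "gC"],
            gene_ids=["x1", "x2", "x3", "x4", "core"],
            values=values,
        )

    def test_proportions(self):
        profile = pg.gene_cluster_profiles(
            self.matrix(), {"x1": 1, "x2": 1, "x3": 1, "x4": 1}
        )
        assert profile.cluster_labels == [1]
        assert profile.values[0].tolist() == [0.5, 0.25, 0.5]

    def test_core_cluster_identically_one(self):
        profile = pg.gene_cluster_profiles(self.matrix(), {"core": 2})
        assert (profile.values == 1.0).all()

    def test_absent_cluster_rejected(self):
        with pytest.raises(ValidationError):
            pg.gene_cluster_profiles(self.matrix(), {"nope": 1})

    def test_genome_ordering_by_metadata(self):
        meta = pg.MetadataTable(
            attributes=["CC"],
            records={"gA": {"CC": "z"}, "gB": {"CC": "a"}, "gC": {"CC": "m"}},
        )
        profile = pg.gene_cluster_profiles(
            self.matrix(), {"x1": 1}, metadata=meta, order_by=["CC"]
        )
        assert profile.genome_ids == ["gB", "gC", "gA"]

    def test_mean_profile_identity(self, rng):
        from .conftest import random_matrix

        matrix = random_matrix(rng, 8, 12)
        labels = {g: 1 + (j % 3) for j, g in enumerate(matrix.gene_ids)}
        profile = pg.gene_cluster_profiles(matrix, labels)
        for i, label in enumerate(profile.cluster_labels):
            genes = [g for g in matrix.gene_ids if labels[g] == label]
            freqs = [
                matrix.values[:, matrix.gene_ids.index(g)].mean() for g in genes
            ]
            assert profile.values[i].mean() == pytest.approx(np.mean(freqs))

    def test_plot_writes_figure_and_tsv(self, tmp_path):
        profile = pg.gene_cluster_profiles(
            self.matrix(), {"x1": 1, "x2": 1, "x3": 2, "x4": 2}
        )
        out = tmp_path / "profiles.png"
        tsv = pg.plot_profiles(profile, None, out)
        assert out.exists()
        lines = tsv.read_text().splitlines()
        assert lines[0] == "cluster\tgenome\tproportion"
        assert len(lines) == 1 + 2 * 3  # 2 clusters x 3 genomes

    def test_out_of_range_proportions_rejected(self):
        with pytest.raises(ValidationError):
            pg.GeneClusterProfile(
                cluster_labels=[1], genome_ids=["g"], values=np.array([[1.5]])
            )


def test_fisher_exhaustive_small_totals():
    # full agreement with exact enumeration for all tables with N <= 12
    for table in iter_all_tables(12):
        assert pg.fisher_exact_2x2(table) == pytest.approx(
            fisher_p_exact(table), rel=1e-7, abs=1e-12
        )
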