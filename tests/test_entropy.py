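import itertools

import networkx as nx
import numpy as np
import pytest

from paima import cohort as ch
from paima import entropy as en

from conftest import make_dataset, xor_dataset, parity3_dataset
from oracles import (
    betweenness_oracle,
    interaction_information_oracle,
    mutual_information_oracle,
)


class TestEntropy:
    def test_balanced_binary_vector_is_one_bit(self):
        assert en.entropy(np.repeat([0, 1], 100)) == pytest.approx(1.0)

    def test_constant_vector_is_zero(self):
        assert en.entropy(np.zeros(50)) == 0.0

    def test_quarter_three_quarter_split(self):
        x = np.repeat([0, 1], [25, 75])
        assert en.entropy(x) == pytest.approx(0.8113, abs=5e-5)

    def test_miller_madow_adds_bias_correction(self):
        x = np.repeat([0, 1, 2], [5, 3, 2])
        plug = en.entropy(x)
        mm = en.entropy(x, estimator="miller_madow")
        assert mm == pytest.approx(plug + 2 / (2 * 10 * np.log(2)))


class TestMutualInformation:
    def test_independent_by_construction_is_zero(self):
        a = np.tile([0, 1, 2], 20)
        y = np.repeat([0, 1], 30)  # every genotype equally split over y
        a = np.concatenate([np.tile([0, 1, 2], 10), np.tile([0, 1, 2], 10)])
        assert en.mutual_information(a, y) == pytest.approx(0.0, abs=1e-12)

    def test_recoded_copy_attains_phenotype_entropy(self):
        y = np.repeat([0, 1], [40, 60])
        a = np.where(y == 1, 2, 0)  # relabeled copy of y
        assert en.mutual_information(a, y) == pytest.approx(en.entropy(y))

    def test_matches_contingency_oracle_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            a = rng.integers(0, 3, 200)
            y = rng.integers(0, 2, 200)
            assert en.mutual_information(a, y) == pytest.approx(
                mutual_information_oracle(a, y), abs=1e-12
            )

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a = rng.integers(0, 3, 100)
            y = rng.integers(0, 2, 100)
            i = en.mutual_information(a, y)
            assert i <= min(en.entropy(a), en.entropy(y)) + 1e-12
            assert i >= -1e-12

    def test_missing_entries_pairwise_excluded(self):
        a = np.array([0, 1, 2, -1, 1])
        y = np.array([0, 1, 1, 0, 0])
        kept = en.mutual_information(a, y)
        assert kept == pytest.approx(en.mutual_information(a[a != -1], y[a != -1]))


class TestInteractionInformation:
    def test_xor_is_pure_synergy(self):
        # two balanced binary-ized loci, phenotype their parity
        cells = np.array(list(itertools.product((0, 1), repeat=2)))
        a = np.repeat(cells[:, 0], 25)
        b = np.repeat(cells[:, 1], 25)
        y = (a + b) % 2
        assert en.mutual_information(a, y) == pytest.approx(0.0, abs=1e-12)
        assert en.interaction_information(a, b, y) == pytest.approx(en.entropy(y))

    def test_duplicated_locus_is_pure_redundancy(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 300)
        y = (a > 0).astype(int)
        assert en.interaction_information(a, a.copy(), y) == pytest.approx(
            -en.mutual_information(a, y)
        )

    def test_matches_entropy_identity_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.integers(0, 3, 150)
            b = rng.integers(0, 3, 150)
            y = rng.integers(0, 2, 150)
            assert en.interaction_information(a, b, y) == pytest.approx(
                interaction_information_oracle(a, b, y), abs=1e-10
            )


class TestThreeWayGain:
    def test_three_way_parity_needs_all_loci(self):
        cells = np.array(list(itertools.product((0, 1), repeat=3)))
        reps = 10
        a, b, c = (np.repeat(cells[:, j], reps) for j in range(3))
        y = (a + b + c) % 2
        assert en.three_way_gain(a, b, c, y) == pytest.approx(en.entropy(y))
        assert en.interaction_information(a, b, y) == pytest.approx(0.0, abs=1e-12)
        assert en.mutual_information(a, y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_attribute_adds_nothing(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 3, 200)
        c = np.zeros(200, dtype=int)
        y = rng.integers(0, 2, 200)
        assert en.three_way_gain(a, b, c, y) == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_identity_holds_numerically(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a = rng.integers(0, 3, 120)
            b = rng.integers(0, 3, 120)
            c = rng.integers(0, 3, 120)
            y = rng.integers(0, 2, 120)
            abc = en._joint_code([a, b, c])
            total = en.mutual_information(abc, y)
            parts = (
                en.mutual_information(a, y)
                + en.mutual_information(b, y)
                + en.mutual_information(c, y)
                + en.interaction_information(a, b, y)
                + en.interaction_information(a, c, y)
                + en.interaction_information(b, c, y)
                + en.three_way_gain(a, b, c, y)
            )
            assert total == pytest.approx(parts, abs=1e-9)


class TestBuildGraph:
    def test_edge_and_triangle_counts(self):
        rng = np.random.default_rng(1)
        data = make_dataset(rng.integers(0, 3, (60, 6)), np.repeat([0, 1], 30))
        g = en.build_graph(data, include_triangles=True)
        assert g.graph.number_of_edges() == 15
        assert len(g.triangles) == 20

    def test_planted_xor_pair_is_the_strongest_edge(self):
        data = xor_dataset(n_cases=400, n_controls=400, p=6, seed=21)
        g = en.build_graph(data)
        labels = g.labels
        scores = g.edge_scores()
        best = max(scores, key=scores.get)
        assert set(best) == {labels[0], labels[1]}
        assert scores[best] > 0

    def test_duplicated_columns_give_the_most_negative_edge(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 3, 300)
        y = (base > 0).astype(int)
        extra = rng.integers(0, 3, (300, 2))
        geno = np.column_stack([base, base, extra])
        data = make_dataset(geno, y)
        g = en.build_graph(data)
        labels = g.labels
        scores = g.edge_scores()
        worst = min(scores, key=scores.get)
        assert set(worst) == {labels[0], labels[1]}
        assert scores[worst] < 0

    def test_edge_classification_bins(self):
        assert en.classify_edge(3.0) == "synergy_strong"
        assert en.classify_edge(1.0) == "synergy"
        assert en.classify_edge(-0.2) == "additivity"
        assert en.classify_edge(0.0) == "additivity"
        assert en.classify_edge(-1.0) == "redundancy"

    def test_hidden_elements_are_flagged_not_deleted(self):
        rng = np.random.default_rng(8)
        data = make_dataset(rng.integers(0, 3, (80, 4)), np.repeat([0, 1], 40))
        g = en.build_graph(data, node_threshold=1e9, edge_threshold=1e9)
        assert g.graph.number_of_nodes() == 4
        assert g.graph.number_of_edges() == 6
        assert all(d["hidden"] for _, d in g.graph.nodes(data=True))
        assert g.visible_subgraph().number_of_edges() == 0

    def test_main_effect_percent_bounded_by_100(self):
        y = np.repeat([0, 1], 50)
        geno = np.column_stack([np.where(y == 1, 2, 0), np.zeros(100, dtype=int)])
        data = make_dataset(geno, y)
        g = en.build_graph(data)
        assert max(g.node_scores().values()) == pytest.approx(100.0)

    def test_triangle_scores_match_direct_three_way_gain(self):
        data = parity3_dataset(n_cases=150, n_controls=150, p=4, seed=2)
        g = en.build_graph(data, include_triangles=True)
        labels = g.labels
        tri = g.triangles[(labels[0], labels[1], labels[2])]
        direct = 100 * en.three_way_gain(
            data.genotypes[:, 0], data.genotypes[:, 1], data.genotypes[:, 2], data.phenotype
        ) / g.h_y
        assert tri == pytest.approx(direct)


class TestDendrogram:
    def test_only_positive_pair_merges_first(self):
        data = xor_dataset(n_cases=300, n_controls=300, p=3, seed=4)
        g = en.build_graph(data)
        tree = en.dendrogram(g)
        first_left, first_right, _ = tree.merges()[0]
        merged = set(first_left | first_right)
        assert merged == {g.labels[0], g.labels[1]}

    def test_equal_edges_merge_lexicographically_first_pair(self):
        graph = nx.Graph()
        for u, v in itertools.combinations("dcba", 2):
            graph.add_edge(u, v, score=1.0, cls="synergy", hidden=False)
        for n in graph.nodes:
            graph.nodes[n].update(score=1.0, hidden=False)
        g = en.InteractionGraph(graph=graph, h_y=1.0, node_threshold=0.0, edge_bins={})
        tree = en.dendrogram(g)
        left, right, _ = tree.merges()[0]
        assert left | right == frozenset({"a", "b"})

    def test_merge_heights_nondecreasing_and_newick_has_all_leaves(self):
        data = xor_dataset(n_cases=200, n_controls=200, p=6, seed=6)
        g = en.build_graph(data)
        tree = en.dendrogram(g)
        heights = tree.heights
        assert (np.diff(heights) >= -1e-9).all()
        newick = tree.to_newick()
        for label in g.labels:
            assert label in newick


class TestGraphStats:
    @staticmethod
    def _wrap(graph):
        for n in graph.nodes:
            graph.nodes[n].setdefault("score", 1.0)
            graph.nodes[n].setdefault("hidden", False)
        for _, _, d in graph.edges(data=True):
            d.setdefault("score", 1.0)
            d.setdefault("cls", "synergy")
            d.setdefault("hidden", False)
        return en.InteractionGraph(graph=graph, h_y=1.0, node_threshold=0.0, edge_bins={})

    def test_star_centre_has_betweenness_six_and_closeness_one(self):
        g = self._wrap(nx.star_graph(4))
        stats = en.graph_stats(g, visible_only=False)
        assert stats.betweenness[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert stats.closeness[0] == pytest.approx(1.0)
        assert stats.max_betweenness == pytest.approx(6.0)

    def test_complete_graph_has_zero_betweenness(self):
        g = self._wrap(nx.complete_graph(5))
        stats = en.graph_stats(g, visible_only=False)
        assert stats.max_betweenness == 0.0

    def test_betweenness_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        base = nx.gnp_random_graph(8, 0.45, seed=3)
        g = self._wrap(base.copy())
        stats = en.graph_stats(g, visible_only=False)
        adjacency = {v: set(base.neighbors(v)) for v in base.nodes}
        expected = betweenness_oracle(adjacency)
        for v, b in expected.items():
            assert stats.betweenness[v] == pytest.approx(b, abs=1e-9)

    def test_empty_visible_graph_returns_zeros_with_warning(self, caplog):
        import logging

        rng = np.random.default_rng(3)
        data = make_dataset(rng.integers(0, 3, (40, 3)), np.repeat([0, 1], 20))
        g = en.build_graph(data, node_threshold=1e9, edge_threshold=1e9)
        with caplog.at_level(logging.WARNING):
            stats = en.graph_stats(g, visible_only=True)
        assert stats.max_betweenness == 0.0
        assert any("no visible edges" in r.message for r in caplog.records)


class TestNullCalibration:
    def test_bias_corrected_estimator_tightens_the_permutation_null(self):
        rng = np.random.default_rng(0)
        n = 200
        plug, mm = [], []
        for _ in range(60):
            mafs = rng.uniform(0.1, 0.5, 2)
            a = rng.binomial(2, mafs[0], n)
            b = rng.binomial(2, mafs[1], n)
            y = rng.permutation(np.repeat([0, 1], n // 2))
            plug.append(en.interaction_information(a, b, y))
            mm.append(en.interaction_information(a, b, y, estimator="miller_madow"))
        assert abs(np.mean(mm)) < abs(np.mean(plug))
        assert np.mean(plug) > 0  # plug-in carries its known positive bias
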