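import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurocoex.coexpression import CorrelationMatrix, correlation_matrix
from neurocoex.expression_io import ExpressionMatrix
from neurocoex.network import (
    build_threshold_graph,
    degree_preserving_null,
    edge_composition_test,
    local_clustering,
    mean_clustering,
    rewire_preserving_degrees,
    threshold_sweep,
)
from neurocoex.synthetic_data import SyntheticConfig, generate_module_matrix


def cm_from_entries(genes, entries):
    """CorrelationMatrix from a dict of pairwise correlations (rest 0)."""
    n = len(genes)
    r = np.zeros((n, n))
    np.fill_diagonal(r, 1.0)
    idx = {g: i for i, g in enumerate(genes)}
    for (a, b), v in entries.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return CorrelationMatrix(genes, r)


def brute_force_local_c(g, node):
    nbrs = list(g.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return None
    t = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
    return 2 * t / (k * (k - 1))


class TestBuildThresholdGraph:
    def test_strict_cutoff(self):
        cm = cm_from_entries(
            ["a", "b", "c"], {("a", "b"): 0.95, ("a", "c"): 0.80}
        )
        g = build_threshold_graph(cm, 0.9)
        assert set(g.edges) == {("a", "b")}

    def test_equal_to_threshold_excluded(self):
        cm = cm_from_entries(["a", "b"], {("a", "b"): 0.9})
        g = build_threshold_graph(cm, 0.9)
        assert g.number_of_edges() == 0

    def test_negative_correlation_excluded_unless_absolute(self):
        cm = cm_from_entries(["a", "b"], {("a", "b"): -0.95})
        assert build_threshold_graph(cm, 0.9).number_of_edges() == 0
        assert build_threshold_graph(cm, 0.9, absolute=True).number_of_edges() == 1

    def test_scopes_filter_by_focal_membership(self):
        cm = cm_from_entries(
            ["i1", "i2", "x1", "x2"],
            {("i1", "i2"): 0.95, ("i1", "x1"): 0.95, ("x1", "x2"): 0.95},
        )
        within = build_threshold_graph(cm, 0.9, {"i1", "i2"}, scope="within_set")
        assert set(map(frozenset, within.edges)) == {frozenset({"i1", "i2"})}
        incident = build_threshold_graph(cm, 0.9, {"i1", "i2"}, scope="incident")
        assert set(map(frozenset, incident.edges)) == {
            frozenset({"i1", "i2"}),
            frozenset({"i1", "x1"}),
        }

    def test_edge_count_non_increasing_in_threshold(self, rng):
        em = ExpressionMatrix(
            pd.DataFrame(rng.standard_normal((30, 10)), index=[f"g{i}" for i in range(30)])
        )
        cm = correlation_matrix(em)
        counts = [
            build_threshold_graph(cm, t).number_of_edges()
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestLocalClustering:
    def test_triangle_node_is_fully_clustered(self):
        g = nx.complete_graph(3)
        assert local_clustering(g, 0) == 1.0

    def test_star_hub_has_zero_clustering(self):
        g = nx.star_graph(3)
        assert local_clustering(g, 0) == 0.0
        assert local_clustering(g, 1) is None  # leaf, degree 1

    def test_four_cycle_with_chord(self):
        g = nx.cycle_graph(["A", "B", "C", "D"])
        g.add_edge("A", "C")
        assert local_clustering(g, "A") == pytest.approx(2 / 3)
        assert local_clustering(g, "B") == pytest.approx(1.0)
        assert mean_clustering(g) == pytest.approx(5 / 6)

    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(5):
            g = nx.gnp_random_graph(20, 0.25, seed=seed)
            for node in g.nodes:
                expected = brute_force_local_c(g, node)
                assert local_clustering(g, node) == pytest.approx(expected)

    def test_mean_invariant_to_relabelling(self):
        g = nx.gnp_random_graph(25, 0.2, seed=4)
        relabelled = nx.relabel_nodes(g, {n: f"node_{n}" for n in g.nodes})
        assert mean_clustering(g) == pytest.approx(mean_clustering(relabelled))

    def test_absent_node_raises(self):
        with pytest.raises(KeyError):
            local_clustering(nx.complete_graph(3), 99)


class TestRewiring:
    def test_degree_sequence_preserved_exactly(self, rng):
        g = nx.gnp_random_graph(40, 0.15, seed=2)
        for _ in range(5):
            h = rewire_preserving_degrees(g, rng)
            assert dict(h.degree()) == dict(g.degree())
            assert h.number_of_edges() == g.number_of_edges()
            assert not any(a == b for a, b in h.edges)

    def test_triangle_is_rigid(self, rng):
        g = nx.complete_graph(3)
        h = rewire_preserving_degrees(g, rng)
        assert set(map(frozenset, h.edges)) == set(map(frozenset, g.edges))

    def test_rewiring_actually_randomizes(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=1)
        h = rewire_preserving_degrees(g, rng)
        assert set(map(frozenset, h.edges)) != set(map(frozenset, g.edges))


class TestDegreePreservingNull:
    def test_triangle_null_is_degenerate(self):
        res = degree_preserving_null(nx.complete_graph(3), n_networks=20, seed=0)
        assert res.ratio == pytest.approx(1.0)
        assert res.p_empirical == 1.0

    def test_er_graphs_have_no_excess_clustering_on_average(self):
        # a single 50-node realization's mean clustering is itself noisy, so
        # the no-bias claim is about the ratio averaged over replicate graphs
        ratios = [
            degree_preserving_null(
                nx.gnp_random_graph(50, 0.1, seed=s), n_networks=100, seed=s
            ).ratio
            for s in range(10)
        ]
        assert 0.8 < np.mean(ratios) < 1.25

    def test_configuration_model_samples_give_unit_ratio_on_average(self):
        # graphs already drawn from the rewiring null should sit inside it
        base = nx.gnp_random_graph(40, 0.15, seed=3)
        rng = np.random.default_rng(77)
        ratios = []
        for s in range(10):
            sample = rewire_preserving_degrees(base, rng)
            ratios.append(degree_preserving_null(sample, n_networks=100, seed=s).ratio)
        assert 0.8 < np.mean(ratios) < 1.25

    def test_seeded_determinism(self):
        g = nx.gnp_random_graph(30, 0.15, seed=9)
        a = degree_preserving_null(g, n_networks=30, seed=4)
        b = degree_preserving_null(g, n_networks=30, seed=4)
        np.testing.assert_array_equal(a.null_means, b.null_means)


class TestThresholdSweep:
    def test_planted_modules_show_excess_clustering(self):
        cfg = SyntheticConfig(
            n_genes=400,
            n_samples=100,
            modules=[(20, 0.9), (20, 0.9), (20, 0.9)],
            set_labels={"IS": [0, 1, 2]},
            seed=21,
        )
        em, truth = generate_module_matrix(cfg)
        cm = correlation_matrix(em)
        sweep = threshold_sweep(
            cm, [0.5, 0.7, 0.9], truth["sets"]["IS"], n_networks=99, seed=13
        )
        for rec in sweep:
            assert rec["ratio"] is not None and rec["ratio"] > 1
            assert rec["p_empirical"] <= 0.01

    def test_shuffled_control_has_no_excess(self, rng):
        # destroying co-expression (permuting each gene's values across
        # samples) removes the planted clustering signal entirely
        cfg = SyntheticConfig(
            n_genes=400,
            n_samples=100,
            modules=[(20, 0.9), (20, 0.9), (20, 0.9)],
            set_labels={"IS": [0, 1, 2]},
            seed=21,
        )
        em, truth = generate_module_matrix(cfg)
        ratios = []
        for rep in range(5):
            shuffled = np.apply_along_axis(rng.permutation, 1, em.values)
            em_shuf = ExpressionMatrix(
                pd.DataFrame(shuffled, index=em.gene_ids, columns=em.sample_ids)
            )
            cm = correlation_matrix(em_shuf)
            # threshold 0.1 keeps the pure-noise graph dense enough for a
            # stable clustering estimate (~16% of pairs at 100 samples)
            rec = threshold_sweep(
                cm, [0.1], truth["sets"]["IS"], n_networks=99, seed=13 + rep
            )[0]
            if rec["ratio"] is not None:
                ratios.append(rec["ratio"])
        assert ratios, "shuffled control produced no usable graphs"
        # pure-noise correlation graphs keep a small intrinsic transitivity
        # (PSD constraint on correlation matrices), so the collapsed ratio
        # sits slightly above 1 — but far below the planted-module excess
        planted = threshold_sweep(
            correlation_matrix(em), [0.5], truth["sets"]["IS"], n_networks=99, seed=13
        )[0]["ratio"]
        assert np.mean(ratios) < 1.8
        assert np.mean(ratios) < planted / 2

    def test_single_threshold_consistent_with_direct_call(self):
        cfg = SyntheticConfig(
            n_genes=100, n_samples=50, modules=[(15, 0.9)], set_labels={"IS": [0]}, seed=2
        )
        em, truth = generate_module_matrix(cfg)
        cm = correlation_matrix(em)
        sweep = threshold_sweep(cm, [0.6], truth["sets"]["IS"], n_networks=40, seed=9)
        g = build_threshold_graph(cm, 0.6, truth["sets"]["IS"])
        direct = degree_preserving_null(g, n_networks=40, seed=np.random.default_rng(9))
        assert sweep[0]["observed_c"] == pytest.approx(direct.observed_mean_c)
        assert sweep[0]["ratio"] == pytest.approx(direct.ratio)

    def test_unsorted_thresholds_rejected(self, small_expression):
        cm = correlation_matrix(small_expression)
        with pytest.raises(ValueError, match="sorted"):
            threshold_sweep(cm, [0.9, 0.5], {"g1", "g2"}, n_networks=5, seed=0)


class TestEdgeComposition:
    def test_perfect_agreement_gives_zero_chi_square(self):
        g = nx.Graph()
        focal = [f"f{i}" for i in range(6)]
        other = [f"o{i}" for i in range(5)]
        g.add_nodes_from(focal + other)
        # 11 nodes, 6 focal -> expected fraction (6-1)/(11-1) = 0.5
        within = list(itertools.combinations(focal, 2))[:10]
        cross = list(itertools.product(focal, other))[:10]
        g.add_edges_from(within + cross)
        res = edge_composition_test(g, focal)
        assert res.expected_fraction == pytest.approx(0.5)
        assert res.n_within == 10 and res.n_incident == 20
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        g = nx.Graph()
        focal = [f"f{i}" for i in range(6)]
        other = [f"o{i}" for i in range(5)]
        g.add_nodes_from(focal + other)
        pairs_within = list(itertools.combinations(focal, 2))
        for a, b in pairs_within[:15]:
            g.add_edge(a, b)
        for i in range(5):
            g.add_edge(focal[i], other[i])
        res = edge_composition_test(g, focal)
        # 20 incident edges, expected fraction 0.5, observed 15 within
        assert res.chi_square == pytest.approx(5.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(5.0, 1))

    def test_all_nodes_focal_is_degenerate(self):
        g = nx.complete_graph(4)
        with pytest.raises(ValueError, match="degenerate"):
            edge_composition_test(g, list(g.nodes))
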