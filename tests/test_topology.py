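import math

import networkx as nx
import numpy as np
import pytest

import oracles
from conftest import graph, random_small_graph
from immunetwork import (
    GeneAnnotation,
    PROFILE_FIELDS,
    TopologyProfile,
    assortativity,
    average_clustering,
    average_neighbors,
    centralization,
    composition,
    connected_components,
    degree,
    density,
    detect_communities,
    heterogeneity,
    hub,
    local_clustering,
    modularity,
    node_report,
    read_profile_json,
    shortest_path_stats,
    topology_profile,
    write_profile_json,
)


class TestDegreeAndClustering:
    def test_star_and_triangle_degrees(self, star3):
        assert degree(star3, 0) == 3
        triangle = nx.complete_graph(3)
        assert degree(triangle, 1) == 2

    def test_degree_matches_adjacency_row_sums(self):
        g = random_small_graph(99)
        a = nx.to_numpy_array(g)
        for idx, node in enumerate(g.nodes):
            assert degree(g, node) == a[idx].sum()

    def test_unknown_node_rejected(self, star3):
        with pytest.raises(KeyError):
            degree(star3, "nope")
        with pytest.raises(KeyError):
            local_clustering(star3, "nope")

    def test_triangle_node_fully_clustered(self):
        assert local_clustering(nx.complete_graph(3), 0) == 1.0

    def test_star_center_unclustered(self, star3):
        assert local_clustering(star3, 0) == 0.0

    def test_one_of_three_neighbor_pairs_linked(self):
        g = graph([("n", "a"), ("n", "b"), ("n", "c"), ("a", "b")])
        assert local_clustering(g, "n") == pytest.approx(1 / 3)

    def test_average_clustering_complete_and_tree(self):
        assert average_clustering(nx.complete_graph(5)) == 1.0
        assert average_clustering(nx.random_labeled_tree(8, seed=1)) == 0.0

    def test_average_clustering_equals_mean_of_brute_force(self):
        g = random_small_graph(30)
        nodes, edges = list(g.nodes), list(g.edges)
        assert average_clustering(g) == pytest.approx(
            oracles.average_clustering(nodes, edges), abs=1e-12)


class TestScalarMetrics:
    def test_density_examples(self):
        assert density(nx.complete_graph(3)) == 1.0
        assert density(nx.path_graph(4)) == 0.5

    def test_density_of_random_instance(self):
        g = nx.gnp_random_graph(20, 0.3, seed=4)
        assert density(g) == pytest.approx(g.number_of_edges() / 190)

    def test_heterogeneity_zero_for_regular_graphs(self):
        for g in (nx.cycle_graph(6), nx.complete_graph(4)):
            assert heterogeneity(g) == 0.0
            assert heterogeneity(g, convention="cytoscape") == 0.0

    def test_star_heterogeneity_both_conventions(self, star3):
        # degrees 3,1,1,1: mean 1.5, population variance 0.75
        assert heterogeneity(star3) == pytest.approx(0.5)
        assert heterogeneity(star3, convention="cytoscape") == pytest.approx(
            math.sqrt(0.75) / 1.5)

    def test_heterogeneity_undefined_without_edges(self):
        with pytest.raises(ValueError):
            heterogeneity(nx.empty_graph(3))

    def test_centralization_star_cycle_path(self, path4):
        assert centralization(nx.star_graph(4)) == pytest.approx(1.0)
        assert centralization(nx.cycle_graph(6)) == 0.0
        assert centralization(path4) == pytest.approx(1 / 3)

    def test_average_neighbors_examples(self, star3):
        assert average_neighbors(nx.complete_graph(3)) == 2.0
        assert average_neighbors(nx.star_graph(4)) == pytest.approx(1.6)

    def test_handshake_identity(self):
        g = random_small_graph(12)
        assert average_neighbors(g) == pytest.approx(
            2 * g.number_of_edges() / g.number_of_nodes())


class TestPaths:
    def test_path_p5_hand_enumeration(self):
        diameter, radius, plen = shortest_path_stats(nx.path_graph(5))
        assert (diameter, radius) == (4, 2)
        assert plen == pytest.approx(2.0)  # (4*1 + 3*2 + 2*3 + 1*4)/10

    def test_complete_graph(self):
        assert shortest_path_stats(nx.complete_graph(4)) == (1, 1, 1.0)

    def test_disconnected_pairs_excluded(self, two_triangles):
        diameter, radius, plen = shortest_path_stats(two_triangles)
        assert (diameter, radius, plen) == (1, 1, 1.0)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            shortest_path_stats(nx.empty_graph(3))

    def test_component_counting(self, two_triangles):
        assert connected_components(nx.complete_graph(3)) == 1
        assert connected_components(two_triangles) == 2
        assert connected_components(
            graph([("a", "b"), ("c", "d")])) == 2

    def test_components_match_union_find_oracle(self):
        g = nx.gnp_random_graph(50, 0.03, seed=8)
        assert connected_components(g) == oracles.connected_components(
            list(g.nodes), list(g.edges))


class TestCommunitiesAndModularity:
    def test_single_community_q_is_zero(self):
        g = random_small_graph(3)
        assert modularity(g, [set(g.nodes)]) == pytest.approx(0.0)

    def test_two_triangles_natural_partition(self, two_triangles):
        q = modularity(two_triangles, [{"a", "b", "c"}, {"x", "y", "z"}])
        assert q == pytest.approx(0.5)

    def test_singleton_partition_closed_form(self):
        g = random_small_graph(17)
        two_l = 2 * g.number_of_edges()
        expected = -sum(d * d for _, d in g.degree()) / two_l**2
        q = modularity(g, [{n} for n in g.nodes])
        assert q == pytest.approx(expected, abs=1e-12)
        assert q < 0

    def test_partition_must_cover_and_be_disjoint(self, two_triangles):
        with pytest.raises(ValueError, match="misses"):
            modularity(two_triangles, [{"a", "b", "c"}])
        with pytest.raises(ValueError, match="disjoint"):
            modularity(two_triangles,
                       [{"a", "b", "c"}, {"c", "x", "y", "z"}])

    def test_two_cliques_recovered_exactly(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        partition = detect_communities(g)
        assert sorted(sorted(c) for c in partition) == [
            [0, 1, 2, 3], [4, 5, 6, 7]]

    def test_planted_two_block_recovery(self):
        g = nx.planted_partition_graph(2, 10, 0.9, 0.05, seed=13)
        partition = detect_communities(g)
        assert sorted(sorted(c) for c in partition) == [
            list(range(10)), list(range(10, 20))]

    def test_detected_partition_q_non_negative(self):
        for seed in range(5):
            g = random_small_graph(seed)
            q = modularity(g, detect_communities(g))
            assert q >= 0.0

    def test_reproducible_for_fixed_seed(self):
        g = nx.gnp_random_graph(40, 0.15, seed=2)
        assert detect_communities(g, seed=1) == detect_communities(g, seed=1)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(nx.empty_graph(3))


class TestAssortativityHubComposition:
    def test_path_p4_hand_value(self, path4):
        assert assortativity(path4) == pytest.approx(-0.5)

    def test_regular_graph_undefined(self):
        assert math.isnan(assortativity(nx.cycle_graph(5)))

    def test_matches_endpoint_pearson_and_networkx(self):
        g = random_small_graph(55)
        mine = assortativity(g)
        brute = oracles.assortativity(list(g.nodes), list(g.edges))
        assert mine == pytest.approx(brute, abs=1e-12)
        assert mine == pytest.approx(
            nx.degree_assortativity_coefficient(g), abs=1e-9)

    def test_hub_and_lexicographic_tie_break(self):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, {0: "HUB1", 1: "a", 2: "b", 3: "c", 4: "d"})
        assert hub(g) == ("HUB1", 4)
        tie = graph([("AAA", "m"), ("AAA", "n"), ("AAA", "o"),
                     ("BBB", "m"), ("BBB", "n"), ("BBB", "o")])
        assert hub(tie)[0] == "AAA"

    def test_composition_fractions(self):
        edges = [(f"c{i}", f"s{i}") for i in range(3)] + [
            ("s0", "s1"), ("s1", "s2"), ("s2", "s3")]
        g = graph(edges)
        mapping = {f"c{i}": "complement" for i in range(3)}
        mapping.update({f"s{i}": "signaling" for i in range(4)})
        fractions = composition(g, GeneAnnotation(mapping))
        assert fractions["complement"] == pytest.approx(3 / 7)
        assert fractions["signaling"] == pytest.approx(4 / 7)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_unannotated_node_named_in_error(self, two_triangles):
        ann = GeneAnnotation({n: "signaling" for n in "abcxy"})
        with pytest.raises(KeyError, match="z"):
            composition(two_triangles, ann)


class TestProfile:
    def test_two_triangles_profile_hand_values(self, two_triangles):
        profile = topology_profile(two_triangles)
        vec = profile.to_vector()
        expected = [6, 6, 2.0, 1, 1, 1.0, 1.0, 0.4, 0.0, 0.0, 2,
                    math.nan, 0.5]
        np.testing.assert_allclose(vec, expected, atol=1e-12)

    def test_complete_graph_profile(self):
        profile = topology_profile(nx.complete_graph(4))
        assert (profile.nodes, profile.edges) == (4, 6)
        assert profile.density == 1.0
        assert profile.clustering_coefficient == 1.0
        assert profile.heterogeneity == 0.0
        assert profile.connected_components == 1

    def test_json_round_trip_in_canonical_order(self, two_triangles, tmp_path):
        import json
        profile = topology_profile(two_triangles)
        path = tmp_path / "profile.json"
        write_profile_json(profile, path)
        with open(path) as handle:
            keys = list(json.load(handle))
        assert keys == list(PROFILE_FIELDS)
        again = read_profile_json(path)
        np.testing.assert_allclose(again.to_vector(), profile.to_vector(),
                                   atol=0)

    def test_radius_cannot_exceed_diameter(self):
        with pytest.raises(ValueError):
            TopologyProfile(3, 2, 1.3, 1, 2, 1.0, 0.0, 0.6, 0.1, 0.5, 1,
                            math.nan, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_profile_invariants_on_random_graphs(self, seed):
        g = random_small_graph(seed)
        p = topology_profile(g)
        assert 0 <= p.clustering_coefficient <= 1
        assert 0 <= p.density <= 1
        assert p.radius <= p.diameter <= p.nodes - 1
        assert math.isnan(p.assortativity) or -1 <= p.assortativity <= 1
        assert -0.5 <= p.modularity <= 1
        assert p.average_neighbors == pytest.approx(2 * p.edges / p.nodes)

    def test_node_report_columns_and_values(self, two_triangles):
        ann = GeneAnnotation({n: "signaling" for n in "abcxyz"})
        report = node_report(two_triangles, ann)
        assert list(report.columns) == ["gene_id", "degree", "clustering",
                                        "category"]
        assert (report.degree == 2).all()
        assert (report.clustering == 1.0).all()
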