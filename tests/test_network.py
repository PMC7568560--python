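import math

import networkx as nx
import numpy as np
import pytest

from trialnet.identity import canonicalize_authors
from trialnet.impact import cumulative_impact
from trialnet.network import (
    DegenerateGraphError,
    assortativity_by_attribute,
    betweenness,
    build_network,
    coauthorship_weight,
    concentration,
    density,
    density_from_counts,
    export_graphml,
    homophily,
    largest_component_share,
    modularity_by_attribute,
    pagerank,
    yearly_metric_series,
)

from conftest import make_network, make_record
from oracles import (
    brute_betweenness,
    definition_modularity,
    mixing_matrix_assortativity,
    power_iteration_pagerank,
)


class TestEdgeWeights:
    def test_pair_weight_is_score_product_over_team_size(self):
        assert coauthorship_weight(0.2, 0.2, 10) == pytest.approx(0.004)
        assert coauthorship_weight(0.0, 5.0, 3) == 0.0

    def test_single_author_manuscript_has_no_pairs(self):
        with pytest.raises(ValueError):
            coauthorship_weight(1.0, 1.0, 1)

    def test_neighbourhood_weight_grows_linearly_with_team_size(self):
        # n(n-1)/2 pairs x s^2/n == (n-1) s^2 / 2: enumeration matches closed form
        s = 0.7
        for n in (2, 5, 12):
            total = sum(
                coauthorship_weight(s, s, n) for i in range(n) for j in range(i + 1, n)
            )
            assert total == pytest.approx((n - 1) * s**2 / 2)


class TestBuildNetwork:
    def test_three_author_record_gives_triangle(self):
        rec = make_record()
        key_map = canonicalize_authors([a.raw_name for a in rec.authors])
        net = build_network([rec], key_map, up_to_year=1970)
        assert net.n_authors == 3
        assert net.graph.number_of_edges() == 3

    def test_disjoint_records_give_two_components(self):
        recs = [
            make_record("R1", authors=("A_Ann", "B_Bob")),
            make_record("R2", authors=("C_Cyd", "D_Dee")),
        ]
        key_map = canonicalize_authors([a.raw_name for r in recs for a in r.authors])
        net = build_network(recs, key_map, up_to_year=1970)
        assert nx.number_connected_components(net.graph) == 2
        assert largest_component_share(net) == 0.5

    def test_duplicate_pairs_stay_in_multigraph_but_collapse_in_simple_view(self):
        recs = [
            make_record("R1", authors=("A_Ann", "B_Bob"), citations=50),
            make_record("R2", authors=("A_Ann", "B_Bob"), citations=100),
        ]
        key_map = canonicalize_authors([a.raw_name for r in recs for a in r.authors])
        net = build_network(recs, key_map, up_to_year=1970)
        assert net.graph.number_of_edges() == 2
        simple = net.simple_view()
        assert simple.number_of_edges() == 1
        total = sum(d["weight"] for _, _, d in net.graph.edges(data=True))
        assert simple["A_Ann"]["B_Bob"]["weight"] == pytest.approx(total)

    def test_merged_duplicate_author_listing_creates_no_self_loop(self):
        rec = make_record(authors=("Kantarjian_HM", "Kantarjian_Hagop", "B_Bob"))
        key_map = canonicalize_authors([a.raw_name for a in rec.authors])
        net = build_network([rec], key_map, up_to_year=1970)
        assert nx.number_of_selfloops(net.graph) == 0


class TestDensity:
    def test_early_network_counts_reproduce_printed_density(self):
        assert round(100 * density_from_counts(12, 30), 1) == 45.5

    def test_final_network_counts_reproduce_printed_density(self):
        assert round(100 * density_from_counts(29197, 697084), 2) == 0.16

    def test_two_connected_nodes_are_fully_dense(self):
        net = make_network([("a", "b", 1.0)])
        assert density(net) == 1.0

    def test_density_counts_distinct_pairs_not_multiedges(self):
        net = make_network([("a", "b", 1.0), ("a", "b", 2.0), ("a", "c", 1.0)])
        assert density(net) == pytest.approx(2 / 3)

    def test_single_node_density_undefined(self):
        with pytest.raises(DegenerateGraphError):
            density(make_network([], extra_nodes=["a"]))


class TestModularity:
    def test_single_community_has_zero_modularity(self):
        net = make_network(
            [("a", "b", 1.0), ("b", "c", 2.0)],
            node_attrs={"subspecialty": {"a": "x", "b": "x", "c": "x"}},
        )
        assert modularity_by_attribute(net) == pytest.approx(0.0)

    def test_two_disconnected_cliques_match_direct_evaluation(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                 ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
        labels = {n: ("L" if n in "abc" else "R") for n in "abcxyz"}
        net = make_network(edges, node_attrs={"subspecialty": labels})
        got = modularity_by_attribute(net)
        assert got == pytest.approx(definition_modularity(net.simple_view(), labels))
        assert got == pytest.approx(0.5)

    def test_random_label_shuffles_average_to_zero(self, rng):
        # the permutation null has a small negative O(1/n) bias, hence a
        # moderately large graph and a loose tolerance
        G = nx.gnm_random_graph(100, 300, seed=4)
        edges = [(u, v, 1.0) for u, v in G.edges]
        base = [str(l) for l in rng.integers(0, 3, size=100)]
        qs = []
        for _ in range(150):
            rng.shuffle(base)
            labels = dict(zip(G.nodes, base))
            net = make_network(edges, node_attrs={"subspecialty": labels})
            qs.append(modularity_by_attribute(net))
        assert abs(float(np.mean(qs))) < 0.03


class TestAssortativity:
    def test_fully_within_category_edges_are_perfectly_assortative(self):
        net = make_network(
            [("a", "b", 1.0), ("x", "y", 3.0)],
            node_attrs={"subspecialty": {"a": "L", "b": "L", "x": "R", "y": "R"}},
        )
        assert assortativity_by_attribute(net) == pytest.approx(1.0)

    def test_complete_bipartite_is_perfectly_disassortative(self):
        edges = [(u, v, 1.0) for u in "ab" for v in "xy"]
        net = make_network(edges, node_attrs={"subspecialty": {"a": "L", "b": "L", "x": "R", "y": "R"}})
        assert assortativity_by_attribute(net) == pytest.approx(-1.0)

    def test_weighted_mixing_matches_mixing_matrix_oracle(self, rng):
        G = nx.gnm_random_graph(9, 16, seed=9)
        edges = [(u, v, float(w)) for (u, v), w in zip(G.edges, rng.uniform(0.1, 4, G.number_of_edges()))]
        labels = {n: str(l) for n, l in zip(G.nodes, rng.integers(0, 3, size=9))}
        net = make_network(edges, node_attrs={"subspecialty": labels})
        got = assortativity_by_attribute(net)
        assert got == pytest.approx(mixing_matrix_assortativity(net.simple_view(), labels))

    def test_unweighted_mode_agrees_with_networkx(self):
        G = nx.gnm_random_graph(10, 20, seed=2)
        edges = [(u, v, 1.0) for u, v in G.edges]
        labels = {n: ("L" if n % 2 else "R") for n in G.nodes}
        net = make_network(edges, node_attrs={"subspecialty": labels})
        expected = nx.attribute_assortativity_coefficient(net.simple_view(), "subspecialty")
        assert assortativity_by_attribute(net, weighted=False) == pytest.approx(expected)

    def test_single_category_is_degenerate(self):
        net = make_network([("a", "b", 1.0)], node_attrs={"subspecialty": {"a": "L", "b": "L"}})
        with pytest.raises(DegenerateGraphError):
            assortativity_by_attribute(net)


class TestBetweenness:
    def test_path_graph_middle_node_carries_the_bridge(self):
        net = make_network([("a", "b", 1.0), ("b", "c", 1.0)])
        scores = betweenness(net)
        assert scores["b"] == pytest.approx(1.0)  # the only s-t pair passes through b
        assert scores["a"] == scores["c"] == 0.0

    def test_star_centre_holds_all_paths(self):
        net = make_network([("c", l, 1.0) for l in "abde"])
        scores = betweenness(net)
        assert scores["c"] == pytest.approx(1.0)
        assert all(scores[l] == 0.0 for l in "abde")

    def test_stronger_ties_are_shorter_bridges(self):
        # a-b-c strong path vs direct weak a-c edge: b still carries the pair
        net = make_network([("a", "b", 10.0), ("b", "c", 10.0), ("a", "c", 0.1)])
        scores = betweenness(net, weighted=True)
        assert scores["b"] == pytest.approx(1.0)
        assert betweenness(net, weighted=False)["b"] == 0.0

    def test_random_graph_matches_exhaustive_path_enumeration(self, rng):
        G = nx.gnm_random_graph(8, 13, seed=5)
        edges = [(u, v, float(w)) for (u, v), w in zip(G.edges, rng.uniform(0.2, 5, G.number_of_edges()))]
        net = make_network(edges)
        got = betweenness(net)
        expected = brute_betweenness(net.simple_view(), weight="distance")
        for n in got:
            assert got[n] == pytest.approx(expected[n], abs=1e-10)

    def test_normalized_to_max_variant_tops_at_one(self):
        net = make_network([("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])
        rel = betweenness(net, relative_to_max=True)
        assert max(rel.values()) == 1.0


class TestPageRank:
    def test_single_node_holds_all_probability(self):
        net = make_network([], extra_nodes=["solo"])
        assert pagerank(net) == {"solo": 1.0}

    def test_symmetric_pair_splits_evenly(self):
        net = make_network([("a", "b", 2.5)])
        pr = pagerank(net)
        assert pr["a"] == pytest.approx(0.5)
        assert pr["b"] == pytest.approx(0.5)

    def test_scores_sum_to_one(self, rng):
        G = nx.gnm_random_graph(15, 30, seed=1)
        edges = [(u, v, float(w)) for (u, v), w in zip(G.edges, rng.uniform(0.1, 2, G.number_of_edges()))]
        net = make_network(edges)
        assert sum(pagerank(net).values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_power_iteration(self, rng):
        G = nx.gnm_random_graph(7, 10, seed=3)
        edges = [(u, v, float(w)) for (u, v), w in zip(G.edges, rng.uniform(0.1, 3, G.number_of_edges()))]
        net = make_network(edges, extra_nodes=list(G.nodes))
        got = pagerank(net)
        expected = power_iteration_pagerank(net.simple_view())
        for n in got:
            assert got[n] == pytest.approx(expected[n], abs=1e-8)


class TestHomophily:
    def test_neighbor_share_counts_distinct_coauthors(self):
        edges = [("ego", f"n{i}", 1.0) for i in range(10)]
        labels = {"ego": "L", **{f"n{i}": ("L" if i < 8 else "R") for i in range(10)}}
        net = make_network(edges, node_attrs={"subspecialty": labels})
        assert homophily(net, "subspecialty")["ego"] == pytest.approx(0.8)

    def test_all_matching_coauthors_score_one(self):
        net = make_network([("a", "b", 1.0), ("a", "c", 1.0)],
                           node_attrs={"subspecialty": {"a": "L", "b": "L", "c": "L"}})
        assert homophily(net, "subspecialty")["a"] == 1.0

    def test_outlink_mode_weighs_by_link_weight(self):
        net = make_network(
            [("ego", "m", 3.0), ("ego", "o", 1.0)],
            node_attrs={"subspecialty": {"ego": "L", "m": "L", "o": "R"}},
        )
        assert homophily(net, "subspecialty", mode="outlinks")["ego"] == pytest.approx(0.75)

    def test_unlabelled_and_isolated_authors_are_excluded(self):
        net = make_network(
            [("a", "b", 1.0)],
            node_attrs={"subspecialty": {"a": "L", "b": "None", "c": "L"}},
            extra_nodes=["c"],
        )
        out = homophily(net, "subspecialty", exclude_values=("None",))
        assert set(out) == {"a"}


class TestConcentration:
    def test_uniform_impacts_top_share_is_the_fraction(self):
        edges = [(f"a{i}", f"a{(i + 1) % 20}", 1.0) for i in range(20)]
        net = make_network(edges)
        impacts = {f"a{i}": 1.0 for i in range(20)}
        _, impact_share = concentration(net, impacts, 0.10)
        assert impact_share == pytest.approx(math.ceil(0.10 * 20) / 20)

    def test_single_dominant_author_holds_all_impact(self):
        net = make_network([("star", f"n{i}", 1.0) for i in range(9)])
        impacts = {"star": 5.0, **{f"n{i}": 0.0 for i in range(9)}}
        link_share, impact_share = concentration(net, impacts, 0.10)
        assert impact_share == 1.0
        assert link_share == pytest.approx(0.5)  # star is one endpoint of every edge

    def test_random_instance_matches_exhaustive_recount(self, rng):
        G = nx.gnm_random_graph(12, 25, seed=8)
        edges = [(u, v, 1.0) for u, v in G.edges]
        net = make_network(edges, extra_nodes=list(G.nodes))
        impacts = {n: float(v) for n, v in zip(G.nodes, rng.uniform(0, 3, 12))}
        link_share, impact_share = concentration(net, impacts, 0.25)
        top = set(sorted(G.nodes, key=lambda n: (-impacts[n], n))[: math.ceil(0.25 * 12)])
        exp_links = sum((u in top) + (v in top) for u, v in G.edges) / (2 * G.number_of_edges())
        exp_impact = sum(impacts[n] for n in top) / sum(impacts.values())
        assert link_share == pytest.approx(exp_links)
        assert impact_share == pytest.approx(exp_impact)


class TestYearlySeries:
    def test_counts_are_cumulative_and_non_decreasing(self, tiny_corpus):
        records, truth = tiny_corpus
        key_map = canonicalize_authors([a.raw_name for r in records for a in r.authors])
        tiers = {int(k): v for k, v in truth["tier_median_table"].items()}
        series = yearly_metric_series(records, key_map, tiers)
        assert (series["n_authors"].diff().dropna() >= 0).all()
        assert (series["n_links"].diff().dropna() >= 0).all()
        valid = series["density"].dropna()
        assert ((valid > 0) & (valid <= 1)).all()

    def test_graphml_export_round_trips_node_count(self, tmp_path, tiny_corpus):
        records, truth = tiny_corpus
        key_map = canonicalize_authors([a.raw_name for r in records for a in r.authors])
        tiers = {int(k): v for k, v in truth["tier_median_table"].items()}
        ledger = cumulative_impact(records, key_map, None, tiers)
        net = build_network(records, key_map, max(r.year for r in records),
                            ledger=ledger, tier_median_table=tiers)
        path = export_graphml(net, tmp_path / "net.graphml")
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == net.n_authors
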