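"""Subnetwork induction, neighborhood expansion, and annotation filtering."""

import pytest

from conftest import bfs_distances
from disnet import fixtures
from disnet.errors import AmbiguousIdentifier, ConfigurationError, LookupFailure
from disnet.graph import InteractionGraph, MolecularNode
from disnet.ppi import expand_neighborhood, filter_network, induce_subnetwork, resolve_identifier

ANG_NEIGHBORS = {"ACTC1", "ACTN2", "ATP6AP1", "PTEN", "RNH1", "TDGF1", "TNFSF8"}


def path_graph(*ids):
    g = InteractionGraph()
    for a, b in zip(ids, ids[1:]):
        g.add_edge(a, b)
    return g


class TestInduceSubnetwork:
    def test_worked_example_two_binary_associations(self, toy_graph):
        sub = induce_subnetwork(["A2M", "APP", "APOE"], toy_graph)
        assert set(sub.edges()) == {("A2M", "APOE"), ("APOE", "APP")}
        assert sub.n_nodes == 3

    def test_single_gene_no_edges(self, toy_graph):
        sub = induce_subnetwork(["APP"], toy_graph)
        assert sub.n_nodes == 1 and sub.n_edges == 0

    def test_query_all_nodes_is_identity(self):
        g = fixtures.random_interactome(20, 40, seed=2)
        sub = induce_subnetwork(sorted(g.node_ids), g)
        assert sub.equals(g)

    def test_empty_query_warns_and_returns_empty(self, toy_graph):
        with pytest.warns(UserWarning, match="empty query"):
            sub = induce_subnetwork([], toy_graph)
        assert sub.n_nodes == 0

    def test_unresolved_entries_reported_not_fatal(self, toy_graph):
        with pytest.warns(UserWarning, match="NOSUCHGENE"):
            sub = induce_subnetwork(["A2M", "APOE", "NOSUCHGENE"], toy_graph)
        assert set(sub.edges()) == {("A2M", "APOE")}

    def test_never_introduces_absent_edges(self):
        g = fixtures.random_interactome(30, 60, seed=4)
        query = sorted(g.node_ids)[:15]
        sub = induce_subnetwork(query, g)
        expected = {(a, b) for a, b in g.edges() if a in set(query) and b in set(query)}
        assert set(sub.edges()) == expected


class TestExpandNeighborhood:
    def test_ang_first_neighborhood_matches_worked_example(self, toy_graph):
        nb = expand_neighborhood("ANG", 1, toy_graph)
        assert nb.graph.node_ids - {"ANG"} == ANG_NEIGHBORS
        assert nb.levels[0].nodes_new == 7

    def test_path_graph_radius_two(self):
        nb = expand_neighborhood("a", 2, path_graph("a", "b", "c", "d"))
        assert nb.graph.node_ids == {"a", "b", "c"}
        assert set(nb.graph.edges()) == {("a", "b"), ("b", "c")}

    def test_k1_equals_seed_plus_adjacency(self):
        g = fixtures.random_interactome(40, 100, seed=9)
        for seed_node in sorted(g.node_ids)[:5]:
            nb = expand_neighborhood(seed_node, 1, g)
            assert nb.graph.node_ids == {seed_node} | g.neighbors(seed_node)

    def test_counts_match_bfs_oracle_and_are_nested(self):
        g = fixtures.random_interactome(200, 600, seed=7)
        adj = {nid: g.neighbors(nid) for nid in g.node_ids}
        seed_node = sorted(g.node_ids)[0]
        dist = bfs_distances(adj, seed_node)
        previous: set = set()
        for k in (1, 2, 3):
            nb = expand_neighborhood(seed_node, k, g)
            expected = {v for v, d in dist.items() if d <= k}
            assert nb.graph.node_ids == expected
            assert previous <= nb.graph.node_ids
            # induced-subgraph edge count, checked brute force
            n_edges = sum(1 for a, b in g.edges() if a in expected and b in expected and a != b)
            assert nb.levels[k - 1].edges_cumulative == n_edges
            previous = nb.graph.node_ids

    def test_seed_absent_raises_lookup_error(self, toy_graph):
        with pytest.raises(LookupFailure):
            expand_neighborhood("NOPE", 1, toy_graph)

    def test_degree_out_of_range(self, toy_graph):
        with pytest.raises(ConfigurationError):
            expand_neighborhood("ANG", 4, toy_graph)
        with pytest.raises(ConfigurationError):
            expand_neighborhood("ANG", 0, toy_graph)
        # cap is overridable
        assert expand_neighborhood("ANG", 4, toy_graph, degree_cap=5).k == 4

    def test_self_loop_excluded_by_default(self):
        g = path_graph("a", "b")
        g.add_edge("a", "a")
        nb = expand_neighborhood("a", 1, g)
        assert ("a", "a") not in set(nb.graph.edges())
        nb2 = expand_neighborhood("a", 1, g, include_self_loops=True)
        assert ("a", "a") in set(nb2.graph.edges())


class TestFilterNetwork:
    def test_apoptosis_group_matches_worked_example(self, toy_graph):
        nb = expand_neighborhood("ANG", 1, toy_graph)
        sub = filter_network(nb.graph, "function", "apoptosis")
        assert sub.node_ids == {"TDGF1", "PTEN", "ACTN2", "TNFSF8", "ATP6AP1"}

    def test_term_with_no_annotated_nodes(self, toy_graph):
        assert filter_network(toy_graph, "function", "photosynthesis").n_nodes == 0

    def test_grouping_partitions_singly_annotated_nodes(self):
        g = InteractionGraph()
        for i, term in enumerate(["alpha", "alpha", "beta"]):
            g.add_node(MolecularNode(f"n{i}", functions={term}))
        groups = filter_network(g, "function")
        assert groups == {"alpha": {"n0", "n1"}, "beta": {"n2"}}

    def test_refiltering_is_idempotent(self, toy_graph):
        once = filter_network(toy_graph, "function", "apoptosis")
        twice = filter_network(once, "function", "apoptosis")
        assert once.equals(twice)

    def test_unknown_category(self, toy_graph):
        with pytest.raises(ConfigurationError):
            filter_network(toy_graph, "flavour", "sweet")


class TestIdentifierResolution:
    def test_resolution_order_and_case_insensitivity(self):
        g = InteractionGraph()
        g.add_node(MolecularNode("N1", gene_id=283, symbol="Ang", protein_id="P03950"))
        assert resolve_identifier(g, "N1") == "N1"
        assert resolve_identifier(g, "283") == "N1"
        assert resolve_identifier(g, "ANG") == "N1"
        assert resolve_identifier(g, "P03950") == "N1"

    def test_ambiguous_symbol_lists_candidates(self):
        g = InteractionGraph()
        g.add_node(MolecularNode("N1", symbol="DUP"))
        g.add_node(MolecularNode("N2", symbol="dup"))
        with pytest.raises(AmbiguousIdentifier) as exc:
            resolve_identifier(g, "DUP")
        assert {"N1", "N2"} == set(exc.value.candidates)
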