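"""Median-joining network construction against spanning-tree oracles."""

import itertools

import networkx as nx
import pytest

from hapnet import (
    HaplotypeError,
    NetworkParams,
    export_network,
    hamming_distance,
    median_vector,
    minimum_spanning_network,
    mj_construct,
    world_frequency_table,
)
from hapnet.cli_pipeline import pool_populations
from .conftest import hap


def complete_graph(states_list):
    g = nx.Graph()
    for a, b in itertools.combinations(sorted(states_list), 2):
        g.add_edge(a, b, weight=hamming_distance(a, b))
    g.add_nodes_from(states_list)
    return g


def all_mst_edges(states_list):
    """Oracle: union of edges over all minimum spanning trees, enumerated
    with networkx's spanning-tree iterator in increasing weight order."""
    g = complete_graph(states_list)
    if g.number_of_nodes() == 1:
        return set()
    it = iter(nx.SpanningTreeIterator(g, weight="weight", minimum=True))
    first = next(it)
    min_w = first.size(weight="weight")
    edges = {frozenset(e) for e in first.edges}
    for tree in it:
        if tree.size(weight="weight") > min_w + 1e-9:
            break
        edges |= {frozenset(e) for e in tree.edges}
    return edges


def random_haplotype_sets(n_cases, max_haps=8, max_sites=7, seed=12345):
    import numpy as np

    rng = np.random.default_rng(seed)
    for _ in range(n_cases):
        L = int(rng.integers(2, max_sites + 1))
        k = int(rng.integers(2, max_haps + 1))
        seen = set()
        while len(seen) < min(k, 2**L):
            seen.add(tuple(int(x) for x in rng.integers(0, 2, size=L)))
        yield sorted(seen)


class TestMinimumSpanningNetwork:
    def test_three_node_path(self):
        net = minimum_spanning_network([hap("00"), hap("01"), hap("11")])
        assert sorted(net.graph.edges) == [
            ((0, 0), (0, 1)),
            ((0, 1), (1, 1)),
        ]

    def test_two_nodes_single_link(self):
        net = minimum_spanning_network([hap("00"), hap("11")])
        assert net.graph.number_of_edges() == 1
        assert net.graph.edges[(0, 0), (1, 1)]["length"] == 2

    def test_equilateral_triangle_keeps_all_links(self):
        net = minimum_spanning_network([hap("000"), hap("011"), hap("110")])
        assert net.graph.number_of_edges() == 3
        assert all(d["length"] == 2 for _, _, d in net.graph.edges(data=True))

    def test_empty_input_rejected(self):
        with pytest.raises(HaplotypeError):
            minimum_spanning_network([])

    def test_msn_equals_all_mst_union(self):
        """epsilon=0 MSN is exactly the union of all-MST edges (oracle:
        exhaustive spanning-tree enumeration on random small inputs)."""
        for haps in random_haplotype_sets(60, max_haps=6, seed=777):
            hs = [hap("".join(map(str, s))) for s in haps]
            net = minimum_spanning_network(hs)
            got = {frozenset(e) for e in net.graph.edges}
            assert got == all_mst_edges(haps), f"mismatch on {haps}"

    def test_epsilon_monotonicity(self):
        """epsilon=0 networks are subgraphs of epsilon=1 networks."""
        for haps in random_haplotype_sets(30, max_haps=6, seed=31):
            hs = [hap("".join(map(str, s))) for s in haps]
            e0 = {frozenset(e) for e in minimum_spanning_network(hs).graph.edges}
            e1 = {
                frozenset(e)
                for e in minimum_spanning_network(
                    hs, NetworkParams(epsilon=1)
                ).graph.edges
            }
            assert e0 <= e1


class TestMedianVector:
    def test_per_site_majority(self):
        assert median_vector(hap("000"), hap("011"), hap("110")).states == (0, 1, 0)

    def test_duplicate_dominates(self):
        x, y = hap("0101010"), hap("1111111")
        assert median_vector(x, x, y).states == x.states

    def test_published_patterns(self):
        m = median_vector(hap("-------"), hap("+----++"), hap("------+"))
        assert m.pattern == "------+"

    def test_length_mismatch(self):
        with pytest.raises(HaplotypeError):
            median_vector(hap("01"), hap("011"), hap("010"))


def brute_force_steiner_length(haps, L):
    """Oracle: minimal total MST length over all supersets obtained by
    adding up to two extra binary vectors (sufficient at this scale)."""
    base = [h.states for h in haps]
    universe = list(itertools.product((0, 1), repeat=L))
    extras = [v for v in universe if v not in base]

    def mst_len(nodes):
        g = nx.Graph()
        for a, b in itertools.combinations(nodes, 2):
            g.add_edge(a, b, weight=hamming_distance(a, b))
        return nx.minimum_spanning_tree(g, weight="weight").size(weight="weight")

    best = mst_len(base)
    for r in (1, 2):
        for combo in itertools.combinations(extras, r):
            best = min(best, mst_len(base + list(combo)))
    return best


def network_steiner_cost(net):
    """Exact cheapest subtree of the network spanning its sampled nodes:
    enumerate median-node subsets and take the best induced MST."""
    g = net.graph
    sampled = net.sampled_nodes
    medians = net.median_nodes
    best = float("inf")
    for r in range(len(medians) + 1):
        for extra in itertools.combinations(medians, r):
            nodes = set(sampled) | set(extra)
            sub = g.subgraph(nodes)
            if sub.number_of_nodes() and nx.is_connected(sub):
                best = min(
                    best,
                    nx.minimum_spanning_tree(sub, weight="length").size(weight="length"),
                )
    return best


class TestMJConstruct:
    def test_steiner_star_through_median(self):
        """{000, 011, 110}: the median 010 gives the unique length-3
        Steiner star (the MST alone costs 4)."""
        haps = [hap("000"), hap("011"), hap("110")]
        assert brute_force_steiner_length(haps, 3) == 3
        net = mj_construct(haps)
        assert (0, 1, 0) in net.graph.nodes
        assert not net.graph.nodes[(0, 1, 0)]["sampled"]
        assert net.total_length() == 3
        assert sorted(net.graph.edges) == [
            ((0, 0, 0), (0, 1, 0)),
            ((0, 1, 0), (0, 1, 1)),
            ((0, 1, 0), (1, 1, 0)),
        ]

    def test_single_haplotype(self):
        net = mj_construct([hap("0110111")])
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_compatible_characters_give_tree(self):
        """A perfect-phylogeny set yields a tree (|E| = |V| - 1) with no
        median vectors beyond required Steiner nodes."""
        haps = [hap("0000"), hap("1000"), hap("1100"), hap("0010"), hap("0011")]
        net = mj_construct(haps)
        g = net.graph
        assert nx.is_tree(g)
        assert g.number_of_edges() == g.number_of_nodes() - 1
        assert net.median_nodes == []

    def test_connected_and_spans_no_worse_than_mst(self):
        """Every constructed network is connected, and its cheapest
        subtree spanning the sampled haplotypes costs no more than a
        minimum spanning tree of those haplotypes (Kruskal oracle) —
        median vectors may only shorten the spanning structure."""
        for haps in random_haplotype_sets(40, max_haps=8, seed=99):
            hs = [hap("".join(map(str, s))) for s in haps]
            net = mj_construct(hs)
            assert net.is_connected()
            g = complete_graph(haps)
            mst_len = nx.minimum_spanning_tree(g, weight="weight").size(weight="weight")
            assert network_steiner_cost(net) <= mst_len + 1e-9, f"worse on {haps}"

    def test_median_degree_after_pruning(self):
        for haps in random_haplotype_sets(25, max_haps=6, seed=17):
            hs = [hap("".join(map(str, s))) for s in haps]
            net = mj_construct(hs)
            g = net.graph
            dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
            sampled = net.sampled_nodes
            for m in net.median_nodes:
                on_geo = any(
                    abs(dist[s][m] + dist[m][t] - dist[s][t]) < 1e-9
                    for s, t in itertools.combinations(sampled, 2)
                )
                assert g.degree[m] >= 3 or on_geo


@pytest.fixture(scope="module")
def pooled_net():
    return mj_construct(pool_populations(world_frequency_table()))


class TestExport:
    def test_edge_list_rows(self, tmp_path):
        net = minimum_spanning_network([hap("00"), hap("01"), hap("11")])
        p = export_network(net, tmp_path / "e.tsv", "tsv")
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "node_a\tnode_b\tlength\tsites_changed"
        assert len(lines) == 3

    def test_pooled_table_dot_export(self, pooled_net, tmp_path):
        assert len(pooled_net.sampled_nodes) == 21
        p = export_network(pooled_net, tmp_path / "n.dot", "dot")
        text = p.read_text()
        assert text.startswith("graph haplonetwork {")
        assert text.count("shape=circle") == 21

    def test_size_attributes_proportional(self, tmp_path):
        net = mj_construct({hap("000"): 0.5, hap("001"): 0.25, hap("011"): 0.25})
        p = export_network(net, tmp_path / "n.graphml", "graphml")
        h = nx.read_graphml(p)
        sizes = {n: d["size"] for n, d in h.nodes(data=True) if d["sampled"]}
        assert sizes["---"] == pytest.approx(1.0)
        assert sizes["--+"] == pytest.approx(0.5)
        assert sizes["-++"] == pytest.approx(0.5)

    def test_unknown_format_rejected(self, pooled_net, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(pooled_net, tmp_path / "x", "svg")
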