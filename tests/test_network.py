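"""Correlation networks: thresholding, density, modularity, contrasts."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from immunet.network import (
    CorrelationNetwork,
    build_network,
    compare_networks,
    group_correlations,
    layout,
    max_modularity,
    same_lineage_edge_fraction,
    summarize,
)


def matrices_from_edges(nodes, edges):
    """Build corr/p matrices where listed (i, j, r) pairs are significant."""
    corr = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    p = pd.DataFrame(np.ones((len(nodes), len(nodes))), index=nodes, columns=nodes)
    np.fill_diagonal(p.values, 0.0)
    for i, j, r in edges:
        corr.loc[i, j] = corr.loc[j, i] = r
        p.loc[i, j] = p.loc[j, i] = 1e-4
    return corr, p


# independent oracles -------------------------------------------------------

def brute_density(graph):
    n = list(graph.nodes)
    pairs = 0
    for u, v in itertools.combinations(n, 2):
        if graph.has_edge(u, v):
            pairs += 1
    return 2 * pairs / (len(n) * (len(n) - 1))


def set_partitions(items):
    if not items:
        yield []
        return
    head = items[0]
    for part in set_partitions(items[1:]):
        for k in range(len(part)):
            yield part[:k] + [[head] + part[k]] + part[k + 1 :]
        yield [[head]] + part


def brute_max_modularity(graph):
    """Exhaustive Newman-Q maximisation via full partition enumeration."""
    e = graph.number_of_edges()
    if e == 0:
        return 0.0
    best = -1.0
    for part in set_partitions(list(graph.nodes)):
        q = nx.community.modularity(graph, [set(b) for b in part])
        best = max(best, q)
    return best


class TestCorrelations:
    def test_identical_columns_r_one(self):
        freq = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5]})
        corr, p = group_correlations(freq)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        freq = pd.DataFrame(rng.random((30, 6)))
        corr, _ = group_correlations(freq)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)

    def test_planted_block_recovered(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(200)
        freq = pd.DataFrame({
            "a": 0.9 * z + 0.45 * rng.standard_normal(200),
            "b": 0.9 * z + 0.45 * rng.standard_normal(200),
            "c": rng.standard_normal(200),
        })
        corr, _ = group_correlations(freq)
        assert abs(corr.loc["a", "b"] - 0.8) < 0.1

    def test_too_few_subjects(self):
        freq = pd.DataFrame(np.random.default_rng(0).random((3, 4)))
        with pytest.raises(ValueError, match=">=4"):
            group_correlations(freq)

    def test_zero_variance_warns_and_drops(self):
        freq = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": 2.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, p = group_correlations(freq)
        net = build_network(corr, p)
        assert net.graph.number_of_edges() == 0


class TestBuildNetwork:
    def test_threshold_is_strict(self):
        corr, p = matrices_from_edges(["a", "b"], [("a", "b", 0.6)])
        net = build_network(corr, p, threshold=0.6)
        assert net.graph.number_of_edges() == 0

    def test_negative_edge_kept_with_sign(self):
        corr, p = matrices_from_edges(["a", "b"], [("a", "b", -0.7)])
        net = build_network(corr, p)
        assert net.graph["a"]["b"]["weight"] == pytest.approx(-0.7)
        assert net.edges["sign"].iloc[0] == "-"

    def test_insignificant_edges_dropped(self):
        corr, p = matrices_from_edges(["a", "b"], [])
        corr.loc["a", "b"] = corr.loc["b", "a"] = 0.9
        p.loc["a", "b"] = p.loc["b", "a"] = 0.5
        net = build_network(corr, p, alpha_edge=0.05)
        assert net.graph.number_of_edges() == 0

    def test_threshold_validated(self):
        corr, p = matrices_from_edges(["a", "b"], [])
        with pytest.raises(ValueError, match="threshold"):
            build_network(corr, p, threshold=1.5)

    def test_raising_threshold_monotone(self):
        rng = np.random.default_rng(2)
        freq = pd.DataFrame(rng.random((25, 10)))
        corr, p = group_correlations(freq)
        counts = [
            build_network(corr, p, threshold=t, alpha_edge=1.0).graph.number_of_edges()
            for t in (0.0, 0.2, 0.4, 0.6, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSummarize:
    def test_complete_graph_density_one(self):
        nodes = list("abcd")
        corr, p = matrices_from_edges(
            nodes, [(i, j, 0.9) for i, j in itertools.combinations(nodes, 2)]
        )
        s = summarize(build_network(corr, p))
        assert s.density == pytest.approx(1.0)

    def test_density_at_study_scale(self):
        # 46 nodes with 107 edges: D = 2*107/(46*45) = 0.1034
        nodes = [f"n{i}" for i in range(46)]
        pairs = list(itertools.combinations(nodes, 2))[:107]
        corr, p = matrices_from_edges(nodes, [(i, j, 0.8) for i, j in pairs])
        s = summarize(build_network(corr, p))
        assert s.density == pytest.approx(2 * 107 / (46 * 45), abs=1e-12)
        assert s.density == pytest.approx(0.1034, abs=5e-4)

    def test_two_triangles_modularity_half(self):
        edges = [("a", "b", .9), ("b", "c", .9), ("a", "c", .9),
                 ("x", "y", .9), ("y", "z", .9), ("x", "z", .9)]
        corr, p = matrices_from_edges(list("abcxyz"), edges)
        s = summarize(build_network(corr, p))
        assert s.modularity == pytest.approx(0.5)
        assert len([c for c in s.communities if len(c) > 1]) == 2

    def test_single_community_q_zero(self):
        g = nx.complete_graph(5)
        assert nx.community.modularity(g, [set(g.nodes)]) == pytest.approx(0.0)
        part, q = max_modularity(g)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_empty_graph(self):
        corr, p = matrices_from_edges(list("abc"), [])
        s = summarize(build_network(corr, p))
        assert s.e == 0 and s.density == 0
        assert s.modularity == 0.0
        assert not s.negative_fraction_defined
        assert s.isolated == 3

    def test_single_node_rejected(self):
        corr, p = matrices_from_edges(["a"], [])
        with pytest.raises(ValueError, match="density undefined"):
            summarize(build_network(corr, p))

    def test_negative_edges_counted(self):
        edges = [("a", "b", -0.7), ("b", "c", 0.8), ("a", "c", -0.9)]
        corr, p = matrices_from_edges(list("abc"), edges)
        s = summarize(build_network(corr, p))
        assert s.negative_edges == 2
        assert s.negative_fraction == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_density_and_modularity_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.8), seed=int(rng.integers(1e6)))
        nodes = [f"n{i}" for i in g.nodes]
        corr, p = matrices_from_edges(
            nodes, [(f"n{u}", f"n{v}", 0.9) for u, v in g.edges]
        )
        s = summarize(build_network(corr, p))
        gg = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        assert s.density == pytest.approx(brute_density(gg), abs=1e-12)
        assert s.modularity == pytest.approx(brute_max_modularity(gg), abs=1e-9)


class TestCompareAndLayout:
    def test_identical_networks_zero_deltas(self):
        corr, p = matrices_from_edges(list("abc"), [("a", "b", 0.8)])
        h = build_network(corr, p, group="healthy")
        s = build_network(corr, p, group="sepsis")
        rep = compare_networks(h, s)
        assert rep["delta_density"] == 0
        assert rep["delta_modularity"] == 0
        assert rep["delta_negative_edges"] == 0

    def test_node_mismatch_rejected(self):
        c1, p1 = matrices_from_edges(list("ab"), [])
        c2, p2 = matrices_from_edges(list("ax"), [])
        with pytest.raises(ValueError, match="node set"):
            compare_networks(build_network(c1, p1), build_network(c2, p2))

    def test_same_lineage_fraction(self):
        corr, p = matrices_from_edges(list("abc"), [("a", "b", .9), ("a", "c", .9)])
        net = build_network(corr, p)
        lin = {"a": "T", "b": "T", "c": "B"}
        assert same_lineage_edge_fraction(net, lin) == pytest.approx(0.5)

    def test_layout_ring_for_empty_graph(self):
        corr, p = matrices_from_edges(list("abcd"), [])
        net = build_network(corr, p)
        pos = layout(net, seed=0)
        radii = [np.hypot(*pos[n]) for n in "abcd"]
        np.testing.assert_allclose(radii, radii[0])

    def test_layout_deterministic(self):
        corr, p = matrices_from_edges(list("abcd"), [("a", "b", .9), ("c", "d", .9)])
        net = build_network(corr, p)
        a, b = layout(net, seed=5), layout(net, seed=5)
        for n in "abcd":
            np.testing.assert_array_equal(a[n], b[n])

    def test_connected_pairs_closer_on_average(self, freq_cohort):
        freq, groups, _ = freq_cohort
        res = CorrelationNetwork(freq, groups).fit()
        net = res.networks["healthy"]
        pos = layout(net, seed=1)
        con, uncon = [], []
        for u, v in itertools.combinations(net.nodes, 2):
            d = np.hypot(*(pos[u] - pos[v]))
            (con if net.graph.has_edge(u, v) else uncon).append(d)
        assert np.mean(con) < np.mean(uncon)


class TestSignsEndToEnd:
    def test_edge_signs_preserved_from_matrix_to_summary(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(100)
        freq = pd.DataFrame({
            "up1": 0.9 * z + 0.4 * rng.standard_normal(100),
            "up2": 0.9 * z + 0.4 * rng.standard_normal(100),
            "down": -0.9 * z + 0.4 * rng.standard_normal(100),
        })
        corr, p = group_correlations(freq)
        net = build_network(corr, p)
        s = summarize(net)
        signs = {
            tuple(sorted((u, v))): d["weight"] > 0
            for u, v, d in net.graph.edges(data=True)
        }
        assert signs[("up1", "up2")]
        assert not signs[("down", "up1")]
        assert s.negative_edges == sum(1 for v in signs.values() if not v)
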