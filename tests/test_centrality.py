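"""Seven centrality metrics: closed forms, oracles, hand-simulated VoteRank."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from boolhub.centrality import (
    betweenness_centrality,
    centrality_table,
    closeness_centrality,
    degree_centralities,
    eigenvector_centrality,
    voterank,
)
from boolhub.errors import ConvergenceError, DataError
from boolhub.implication_net import ImplicationNetwork
from conftest import make_net, undirected_net
from oracles import (
    bf_betweenness,
    bf_closeness,
    bf_degree,
    dominant_eigenpair,
    dominant_is_defective,
)

STAR5 = undirected_net([("c", l) for l in "defg"])  # center + 4 leaves
PATH4 = undirected_net([("a", "b"), ("b", "c"), ("c", "d")])
PATH3 = undirected_net([("a", "b"), ("b", "c")])
CYCLE4 = undirected_net([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
K4 = undirected_net([(u, v) for u in "abcd" for v in "abcd" if u < v])


class TestDegree:
    def test_complete_graph_saturates(self):
        d = degree_centralities(K4)
        assert (d["c_in"] == 1.0).all() and (d["c_out"] == 1.0).all()
        assert (d["c_degree"] == 2.0).all()

    def test_directed_chain(self):
        d = degree_centralities(make_net([("a", "b"), ("b", "c")]))
        assert d.loc["a", "c_degree"] == 0.5
        assert d.loc["b", "c_degree"] == 1.0
        assert d.loc["c", "c_degree"] == 0.5

    def test_isolated_node_scores_zero(self):
        net = make_net([("a", "b")], nodes=["a", "b", "z"])
        assert (degree_centralities(net).loc["z"] == 0).all()

    def test_small_networks_rejected(self):
        with pytest.raises(DataError):
            degree_centralities(make_net([], nodes=["a"]))


class TestEigenvector:
    def test_cycle_is_uniform(self):
        e = eigenvector_centrality(CYCLE4)
        assert np.allclose(e, 0.5, atol=1e-8)

    def test_star_closed_form(self):
        e = eigenvector_centrality(STAR5)
        assert e["c"] == pytest.approx(1 / math.sqrt(2), abs=1e-6)
        for leaf in "defg":
            assert e[leaf] == pytest.approx(1 / (2 * math.sqrt(2)), abs=1e-6)

    def test_isolated_component_gets_zero(self):
        net = make_net([("a", "b"), ("b", "a")], nodes=["a", "b", "z"])
        e = eigenvector_centrality(net)
        assert e["a"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)
        assert e["b"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)
        assert e["z"] == pytest.approx(0.0, abs=1e-8)

    def test_nilpotent_adjacency_does_not_converge(self):
        with pytest.raises(ConvergenceError):
            eigenvector_centrality(make_net([("a", "b"), ("b", "c")]), max_iter=200)


class TestBetweenness:
    def test_star_center_is_maximal(self):
        b = betweenness_centrality(STAR5)
        assert b["c"] == pytest.approx(1.0)
        assert all(b[l] == 0 for l in "defg")

    def test_path_middle_node(self):
        b = betweenness_centrality(PATH4)
        assert b["b"] == pytest.approx(2 / 3)

    def test_complete_graph_is_zero(self):
        assert (betweenness_centrality(K4) == 0).all()


class TestCloseness:
    def test_path_three_nodes(self):
        c = closeness_centrality(PATH3)
        assert c["b"] == pytest.approx(1.0)
        assert c["a"] == pytest.approx(2 / 3)
        assert c["c"] == pytest.approx(2 / 3)

    def test_complete_graph_saturates(self):
        assert np.allclose(closeness_centrality(K4), 1.0)

    def test_disjoint_edges_component_scaled(self):
        net = undirected_net([("a", "b"), ("c", "d")])
        assert np.allclose(closeness_centrality(net), 1 / 3)


class TestVoteRank:
    def test_star_hand_simulation(self):
        v = voterank(STAR5)
        assert v["c"] == 1
        assert all(v[l] == 2 for l in "defg")

    def test_double_star_centers_first(self):
        net = undirected_net(
            [("a", l) for l in ("l1", "l2", "l3")] + [("b", l) for l in ("m1", "m2", "m3")]
        )
        v = voterank(net)
        assert v["a"] == 1 and v["b"] == 2
        assert all(v[l] == 3 for l in ("l1", "l2", "l3", "m1", "m2", "m3"))

    def test_single_edge_tie_breaks_to_smaller_id(self):
        v = voterank(undirected_net([("a", "b")]))
        assert v["a"] == 1

    def test_edgeless_network_all_tied_at_one(self):
        v = voterank(make_net([], nodes=list("abc")))
        assert (v == 1).all()


class TestTable:
    def test_degree_column_is_sum_of_in_and_out(self, recovery):
        t = recovery.tables["cohort0:cnv-mrna"]
        assert np.allclose(t["c_degree"], t["c_in"] + t["c_out"])

    def test_star_table_matches_component_operations(self):
        t = centrality_table(STAR5)
        assert t.loc["c", "c_degree"] == 2.0
        assert t.loc["c", "c_between"] == pytest.approx(1.0)
        assert t.loc["c", "c_eigen"] == pytest.approx(1 / math.sqrt(2), abs=1e-6)
        assert t.loc["c", "c_voterank"] == 1
        assert t.attrs["N"] == 5 and t.attrs["E"] == 4

    def test_edgeless_network_zeros_and_voterank_tie(self):
        t = centrality_table(make_net([], nodes=list("abcd")))
        assert (t[["c_degree", "c_eigen", "c_between", "c_close"]] == 0).all().all()
        assert (t["c_voterank"] == 1).all()


class TestInvariants:
    def test_degree_sums_equal_edge_count_over_n_minus_1(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 8)
            adj = rng.random((n, n)) < 0.4
            np.fill_diagonal(adj, False)
            net = make_net(
                [(f"n{i}", f"n{j}") for i, j in np.argwhere(adj)],
                nodes=[f"n{i}" for i in range(n)],
            )
            d = degree_centralities(net)
            e = net.graph.number_of_edges()
            assert d["c_in"].sum() == pytest.approx(e / (n - 1))
            assert d["c_out"].sum() == pytest.approx(e / (n - 1))

    def test_leaf_betweenness_is_zero(self):
        b = betweenness_centrality(PATH4)
        assert b["a"] == 0 and b["d"] == 0

    def test_voterank_first_pick_has_maximal_initial_votes(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            adj = rng.random((n, n)) < 0.5
            adj |= adj.T
            np.fill_diagonal(adj, False)
            if not adj.any():
                continue
            net = make_net(
                [(f"n{i}", f"n{j}") for i, j in np.argwhere(adj)],
                nodes=[f"n{i}" for i in range(n)],
                symmetric=True,
            )
            v = voterank(net)
            first = v.idxmin()
            deg = dict(net.graph.in_degree())
            assert deg[first] == max(deg.values())


def random_digraph(rng):
    n = int(rng.integers(2, 6))
    adj = rng.random((n, n)) < rng.uniform(0.2, 0.7)
    np.fill_diagonal(adj, False)
    return adj


def oracle_check_digraph(adj):
    """Degree/betweenness/closeness vs exhaustive path enumeration;
    eigenvector against the dense left eigenproblem."""
    n = len(adj)
    nodes = [f"n{i}" for i in range(n)]
    net = make_net(
        [(nodes[i], nodes[j]) for i, j in np.argwhere(adj)], nodes=nodes, symmetric=False
    )
    d = degree_centralities(net)
    ei, eo, et = bf_degree(adj.astype(float))
    assert np.allclose(d["c_in"], ei) and np.allclose(d["c_out"], eo)
    if n >= 3:
        assert np.allclose(betweenness_centrality(net), bf_betweenness(adj, False), atol=1e-12)
    assert np.allclose(closeness_centrality(net), bf_closeness(adj), atol=1e-12)
    if adj.any():
        try:
            e = eigenvector_centrality(net).to_numpy()
        except ConvergenceError:
            assert dominant_is_defective(adj)
            return
        rho, _ = dominant_eigenpair(adj.astype(float))
        assert np.linalg.norm(e) == pytest.approx(1.0, abs=1e-9)
        assert (e >= -1e-12).all()
        resid = adj.T.astype(float) @ e - rho * e
        assert np.abs(resid).max() < 1e-6


def test_oracle_equivalence_on_random_digraphs():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        oracle_check_digraph(random_digraph(rng))
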