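import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ccinet.network import (
    build_network,
    compare_networks,
    node_measures,
    pagerank,
)


def graph_from_edges(edges, nodes=None):
    g = nx.DiGraph(total=sum(w for *_, w in edges))
    if nodes:
        g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, pairs=[])
    return g


def pagerank_dense_solve(graph, damping=0.85):
    """Independent oracle: direct linear solve of the stationary equations."""
    nodes = list(graph.nodes)
    n = len(nodes)
    W = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    out = W.sum(axis=1)
    M = np.where(out[:, None] > 0, W / np.where(out == 0, 1, out)[:, None], 1.0 / n)
    x = np.linalg.solve(np.eye(n) - damping * M.T, np.full(n, (1 - damping) / n))
    return pd.Series(x / x.sum() * 1.0, index=nodes)  # solve is already normalized


class TestBuildNetwork:
    def test_counts_significant_interactions(self):
        scores = pd.DataFrame(
            {
                "sender": ["B", "B", "B", "B"],
                "receiver": ["NK", "NK", "B", "NK"],
                "ligand": ["L1", "L2", "L3", "L4"],
                "receptor": ["R1", "R2", "R3", "R4"],
                "significant": [True, True, True, False],
            }
        )
        scores.attrs["eligible_types"] = ["B", "NK", "T"]
        g = build_network(scores)
        assert g["B"]["NK"]["weight"] == 2
        assert g["B"]["B"]["weight"] == 1
        assert g.graph["total"] == 3
        assert set(g.nodes) == {"B", "NK", "T"}  # isolated node retained
        assert g["B"]["NK"]["pairs"] == [("L1", "R1"), ("L2", "R2")]

    def test_no_significant_interactions_empty_graph(self):
        scores = pd.DataFrame(
            {"sender": ["B"], "receiver": ["NK"], "ligand": ["L"],
             "receptor": ["R"], "significant": [False]}
        )
        g = build_network(scores, nodes=["B", "NK"])
        assert g.number_of_edges() == 0 and g.graph["total"] == 0


class TestNodeMeasures:
    def test_three_cycle_symmetry(self):
        g = graph_from_edges([("a", "b", 2), ("b", "c", 2), ("c", "a", 2)])
        m = node_measures(g)
        assert m["pagerank"].tolist() == pytest.approx([1 / 3] * 3, abs=1e-9)
        assert m["mediator"].nunique() == 1
        assert m["influencer"].tolist() == pytest.approx([1 / 3] * 3)

    def test_star_graph_roles(self):
        g = graph_from_edges([("hub", "x", 1), ("hub", "y", 1), ("hub", "z", 1)])
        m = node_measures(g)
        assert m.loc["hub", "influencer"] == 1.0
        assert m.loc["hub", "listener"] == 0.0
        assert m.loc["x", "listener"] == pytest.approx(1 / 3)

    def test_two_node_closed_form(self):
        # A -> B, damping d: PR(A) = (1-d)/2 / (1 - d/2); PR(B) = 1 - PR(A)
        # (B is dangling and redistributes uniformly).
        d = 0.85
        g = graph_from_edges([("A", "B", 1)])
        pr = pagerank(g, damping=d)
        # stationary equations: x_A = (1-d)/2 + d * x_B / 2
        #                       x_B = (1-d)/2 + d * (x_A + x_B / 2)
        A = np.array([[1, -d / 2], [-d, 1 - d / 2]])
        b = np.array([(1 - d) / 2, (1 - d) / 2])
        expected = np.linalg.solve(A, b)
        assert pr["A"] == pytest.approx(expected[0], abs=1e-9)
        assert pr["B"] == pytest.approx(expected[1], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_power_iteration_matches_dense_solve(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        edges = [
            (f"n{i}", f"n{j}", int(rng.integers(1, 6)))
            for i in range(n)
            for j in range(n)
            if rng.random() < 0.4
        ]
        g = graph_from_edges(edges, nodes=[f"n{i}" for i in range(n)])
        pr = pagerank(g)
        oracle = pagerank_dense_solve(g)
        assert np.abs(pr - oracle).max() <= 1e-9
        assert pr.sum() == pytest.approx(1.0, abs=1e-9)
        # cross-check against the networkx implementation as well
        nxpr = nx.pagerank(g, alpha=0.85, weight="weight", tol=1e-12, max_iter=1000)
        assert np.abs(pr - pd.Series(nxpr)).max() <= 1e-8

    def test_empty_graph_all_zero_with_warning(self):
        g = nx.DiGraph(total=0)
        g.add_nodes_from(["a", "b"])
        with pytest.warns(UserWarning, match="no interactions"):
            m = node_measures(g)
        assert (m == 0).all().all()

    def test_mediator_uses_inverse_weight_distance(self):
        # heavy two-hop path through m beats the light direct edge, making
        # m a mediator; with a heavy direct edge m is bypassed.
        heavy = graph_from_edges([("a", "m", 10), ("m", "b", 10), ("a", "b", 1)])
        light = graph_from_edges([("a", "m", 1), ("m", "b", 1), ("a", "b", 10)])
        assert node_measures(heavy).loc["m", "mediator"] > 0
        assert node_measures(light).loc["m", "mediator"] == 0


class TestCompareNetworks:
    def test_identical_graphs_zero_deltas(self):
        g = graph_from_edges([("a", "b", 2), ("b", "a", 1)])
        rep = compare_networks(g, g)
        assert (rep.nodes.filter(like="delta_") == 0).all().all()
        assert (rep.edges["log_odds_ratio"] == 0).all()
        assert (rep.edges["direction"] == "none").all()

    def test_hand_evaluated_log_odds(self):
        # a = 3 of A = 20 vs b = 1 of B = 20
        gp = graph_from_edges([("s", "t", 3), ("t", "s", 17)])
        gm = graph_from_edges([("s", "t", 1), ("t", "s", 19)])
        rep = compare_networks(gp, gm)
        row = rep.edges.set_index(["sender", "receiver"]).loc[("s", "t")]
        expected = math.log((3.5 / 17.5) / (1.5 / 19.5))
        assert row["log_odds_ratio"] == pytest.approx(expected, abs=1e-12)
        assert row["direction"] == "up_in_plus"

    def test_one_sided_edge_finite_positive(self):
        gp = graph_from_edges([("a", "b", 4), ("b", "a", 4)])
        gm = graph_from_edges([("b", "a", 8)], nodes=["a", "b"])
        rep = compare_networks(gp, gm)
        row = rep.edges.set_index(["sender", "receiver"]).loc[("a", "b")]
        assert math.isfinite(row["log_odds_ratio"]) and row["log_odds_ratio"] > 0

    def test_percentages_sum_to_100(self):
        gp = graph_from_edges([("a", "b", 3), ("b", "c", 1), ("c", "a", 6)])
        gm = graph_from_edges([("a", "b", 2), ("c", "b", 2)])
        rep = compare_networks(gp, gm)
        assert rep.edges["percent_plus"].sum() == pytest.approx(100.0)
        assert rep.edges["percent_minus"].sum() == pytest.approx(100.0)

    def test_union_nodes_with_zero_measures(self):
        gp = graph_from_edges([("a", "b", 1)])
        gm = graph_from_edges([("c", "d", 2)])
        rep = compare_networks(gp, gm)
        assert set(rep.nodes.index) == {"a", "b", "c", "d"}
        assert rep.nodes.loc["c", "pagerank_plus"] == 0.0

    def test_both_empty_is_an_error(self):
        g = nx.DiGraph(total=0)
        g.add_nodes_from("ab")
        with pytest.raises(ValueError, match="empty"):
            compare_networks(g, g)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3), st.integers(1, 9)),
            min_size=1,
            max_size=8,
        ),
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3), st.integers(1, 9)),
            min_size=1,
            max_size=8,
        ),
    )
    def test_swap_negates_everything_exactly(self, e1, e2):
        nodes = [f"n{i}" for i in range(4)]
        gp = graph_from_edges(
            list({(f"n{a}", f"n{b}"): (f"n{a}", f"n{b}", w) for a, b, w in e1}.values()),
            nodes=nodes,
        )
        gm = graph_from_edges(
            list({(f"n{a}", f"n{b}"): (f"n{a}", f"n{b}", w) for a, b, w in e2}.values()),
            nodes=nodes,
        )
        fwd = compare_networks(gp, gm)
        rev = compare_networks(gm, gp)
        assert (fwd.edges["log_odds_ratio"].to_numpy()
                == -rev.edges["log_odds_ratio"].to_numpy()).all()
        for m in ("pagerank", "influencer", "listener", "mediator"):
            assert (fwd.nodes[f"delta_{m}"].to_numpy()
                    == -rev.nodes[f"delta_{m}"].to_numpy()).all()
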