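"""Cell-cell interaction graphs and the differential network report.

Significant interactions of one partition aggregate into a directed
weighted graph over cell types: edge weight = number of significant
ligand-receptor interactions from sender to receiver (self-loops allowed,
isolated nodes retained).  Node importance is summarised by four
topological roles:

* **pagerank** — stationary random-walk centrality with teleportation,
  the overall importance of a cell type to the network;
* **influencer** — weighted out-strength as a fraction of all
  interactions (outgoing signal);
* **listener** — weighted in-strength fraction (incoming signal);
* **mediator** — betweenness centrality with edge distance 1/weight,
  the brokerage of communication between other cell types.

Two partition graphs are compared per ordered type pair through each
network's interaction percentages and a log odds ratio with the
Haldane-Anscombe 0.5 continuity correction, and per node through exact
differences of each measure (positive delta = larger in the "plus"
network).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_network",
    "pagerank",
    "node_measures",
    "compare_networks",
    "DiffReport",
    "MEASURES",
]

MEASURES = ("pagerank", "influencer", "listener", "mediator")


def build_network(scores: pd.DataFrame, nodes=None) -> nx.DiGraph:
    """Aggregate significant interactions into a directed weighted graph.

    *nodes* defaults to the eligible cell types recorded by
    :func:`ccinet.scoring.score_interactions` (falling back to all
    sender/receiver values in *scores*), so cell types without a single
    significant interaction still appear as isolated nodes.
    """
    if nodes is None:
        nodes = scores.attrs.get("eligible_types")
    if nodes is None:
        nodes = sorted(set(scores["sender"]) | set(scores["receiver"]))
    g = nx.DiGraph(total=0)
    g.add_nodes_from(nodes)
    sig = scores[scores["significant"]]
    for (s, r), grp in sig.groupby(["sender", "receiver"], sort=True):
        g.add_edge(
            s, r,
            weight=int(len(grp)),
            pairs=list(zip(grp["ligand"], grp["receptor"])),
        )
    g.graph["total"] = int(sig.shape[0])
    return g


def pagerank(graph: nx.DiGraph, damping: float = 0.85, tol: float = 1e-12,
             max_iter: int = 100_000) -> pd.Series:
    """Weighted PageRank by power iteration.

    Uniform teleportation, dangling nodes redistribute uniformly,
    iterated to an absolute L1 tolerance of *tol*.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return pd.Series(dtype=float)
    W = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    out = W.sum(axis=1)
    dangling = out == 0
    P = np.divide(W, np.where(dangling, 1.0, out)[:, None])
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = damping * (P.T @ x + x[dangling].sum() / n) + (1 - damping) / n
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    else:  # pragma: no cover - tol is reachable on any finite graph
        warnings.warn("pagerank power iteration did not converge")
    return pd.Series(x, index=nodes, name="pagerank")


def node_measures(graph: nx.DiGraph, damping: float = 0.85) -> pd.DataFrame:
    """Per-node pagerank / influencer / listener / mediator table.

    A graph without edges gets all-zero measures (with a warning): there
    is no communication to apportion.
    """
    nodes = list(graph.nodes)
    df = pd.DataFrame(0.0, index=pd.Index(nodes, name="cell_type"),
                      columns=list(MEASURES))
    total = sum(d["weight"] for _, _, d in graph.edges(data=True))
    if total == 0:
        if nodes:
            warnings.warn("graph has no interactions; all measures are zero")
        return df
    df["pagerank"] = pagerank(graph, damping=damping)
    out_s = pd.Series(dict(graph.out_degree(weight="weight")), dtype=float)
    in_s = pd.Series(dict(graph.in_degree(weight="weight")), dtype=float)
    df["influencer"] = out_s.reindex(nodes).fillna(0.0) / total
    df["listener"] = in_s.reindex(nodes).fillna(0.0) / total
    dist = nx.DiGraph()
    dist.add_nodes_from(nodes)
    for u, v, d in graph.edges(data=True):
        dist.add_edge(u, v, dist=1.0 / d["weight"])
    bc = nx.betweenness_centrality(dist, weight="dist", normalized=True)
    df["mediator"] = pd.Series(bc).reindex(nodes).fillna(0.0)
    return df


@dataclass
class DiffReport:
    """Node- and edge-level comparison of the plus and minus networks.

    ``nodes``: per cell type, each measure in the plus network, the minus
    network, and their exact difference.  ``edges``: per ordered type
    pair, significant-interaction counts, percentages of each network's
    total, their difference, the continuity-corrected log odds ratio, and
    the enrichment direction it implies.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    total_plus: int
    total_minus: int


def _log_odds(a, A, b, B, correction):
    # computed as a difference of logits so that swapping the inputs
    # negates the value exactly in floating point
    lp = np.log(a + correction) - np.log(A - a + correction)
    lm = np.log(b + correction) - np.log(B - b + correction)
    return lp - lm


def compare_networks(graph_plus: nx.DiGraph, graph_minus: nx.DiGraph,
                     damping: float = 0.85, correction: float = 0.5) -> DiffReport:
    """Compare two partition networks built with identical parameters.

    Node sets are unioned; a type absent from one network contributes
    zero measures there so every delta is defined.  For an ordered pair
    with ``a`` of the plus network's ``A`` significant interactions and
    ``b`` of the minus network's ``B``, the log odds ratio is

        ln[ ((a + c) / (A - a + c)) / ((b + c) / (B - b + c)) ]

    with the Haldane-Anscombe correction ``c = 0.5`` by default, finite
    for every pair including those present in only one network.
    """
    total_plus = graph_plus.graph.get(
        "total", int(sum(d["weight"] for *_, d in graph_plus.edges(data=True)))
    )
    total_minus = graph_minus.graph.get(
        "total", int(sum(d["weight"] for *_, d in graph_minus.edges(data=True)))
    )
    if total_plus == 0 and total_minus == 0:
        raise ValueError("both networks are empty; nothing to compare")

    nodes = sorted(set(graph_plus.nodes) | set(graph_minus.nodes))
    mp = node_measures(graph_plus, damping=damping).reindex(nodes).fillna(0.0)
    mm = node_measures(graph_minus, damping=damping).reindex(nodes).fillna(0.0)
    node_tbl = pd.DataFrame(index=pd.Index(nodes, name="cell_type"))
    for m in MEASURES:
        node_tbl[f"{m}_plus"] = mp[m]
        node_tbl[f"{m}_minus"] = mm[m]
        node_tbl[f"delta_{m}"] = mp[m] - mm[m]

    def w(g, s, r):
        return int(g[s][r]["weight"]) if g.has_edge(s, r) else 0

    recs = []
    for s in nodes:
        for r in nodes:
            a, b = w(graph_plus, s, r), w(graph_minus, s, r)
            pct_p = 100.0 * a / total_plus if total_plus else 0.0
            pct_m = 100.0 * b / total_minus if total_minus else 0.0
            lor = float(_log_odds(a, total_plus, b, total_minus, correction))
            direction = (
                "up_in_plus" if lor > 0 else "up_in_minus" if lor < 0 else "none"
            )
            recs.append((s, r, a, b, pct_p, pct_m, pct_p - pct_m, lor, direction))
    edge_tbl = pd.DataFrame(
        recs,
        columns=[
            "sender", "receiver", "count_plus", "count_minus",
            "percent_plus", "percent_minus", "delta_percent",
            "log_odds_ratio", "direction",
        ],
    )
    return DiffReport(node_tbl, edge_tbl, total_plus, total_minus)
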