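"""Matplotlib views of the differential network and enrichment table."""

from __future__ import annotations

import matplotlib

if not matplotlib.get_backend().lower().startswith("agg"):  # headless-safe
    matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

__all__ = ["plot_comparative_network", "plot_enrichment_heatmap"]


def plot_comparative_network(report, ax=None, scale: float = 4000.0):
    """Comparative CCI network: node size proportional to |delta pagerank|
    (filled when the delta is positive), edge colour by the sign of the
    interaction-percentage difference (red = up in plus, blue = up in minus),
    edge width by |log odds ratio|."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    g = nx.DiGraph()
    g.add_nodes_from(report.nodes.index)
    drawn = report.edges[
        (report.edges["count_plus"] + report.edges["count_minus"]) > 0
    ]
    for _, row in drawn.iterrows():
        g.add_edge(row["sender"], row["receiver"],
                   lor=row["log_odds_ratio"], dpct=row["delta_percent"])
    pos = nx.circular_layout(g)
    delta = report.nodes["delta_pagerank"]
    sizes = 100 + scale * delta.abs()
    colors = np.where(delta >= 0, "#d62728", "#1f77b4")
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=sizes.to_numpy(),
                           node_color=colors, alpha=0.85)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    widths = [0.5 + 2.0 * abs(d["lor"]) for *_, d in g.edges(data=True)]
    ecolors = ["#d62728" if d["dpct"] > 0 else "#1f77b4"
               for *_, d in g.edges(data=True)]
    nx.draw_networkx_edges(g, pos, ax=ax, width=widths, edge_color=ecolors,
                           arrowsize=12, connectionstyle="arc3,rad=0.08",
                           alpha=0.7)
    ax.set_axis_off()
    ax.set_title("Differential CCI network (node size ~ |ΔPageRank|)")
    return ax


def plot_enrichment_heatmap(enrichment, ax=None, value: str = "q_value"):
    """Heatmap of -log10(q) per gene set across (measure, direction)."""
    piv = enrichment.pivot_table(
        index="set_name",
        columns=["measure", "direction"],
        values=value,
        aggfunc="first",
    )
    mat = -np.log10(piv.to_numpy(dtype=float).clip(min=1e-300))
    if ax is None:
        _, ax = plt.subplots(
            figsize=(1.2 * piv.shape[1] + 3, 0.4 * piv.shape[0] + 2)
        )
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_yticks(range(piv.shape[0]), piv.index, fontsize=7)
    ax.set_xticks(
        range(piv.shape[1]),
        [f"{m}\n{d}" for m, d in piv.columns],
        fontsize=7,
    )
    ax.figure.colorbar(im, ax=ax, label=f"-log10({value})")
    ax.set_title("Topology-indexed gene-set enrichment")
    return ax
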