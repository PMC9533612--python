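"""Gene-set over-representation over network topology measures.

Each (topological measure, enrichment direction) combination maps to a
gene hit set built from the differential report: for ``up_in_plus`` and
measure *m*, the hits are the ligand genes (influencer), receptor genes
(listener), or both (mediator, pagerank) of significant plus-partition
interactions lying on edges with positive log odds ratio that are
incident — outgoing for influencer, incoming for listener, either way
for mediator and pagerank — to nodes with positive delta of *m*.
``up_in_minus`` is the mirror image.  This hit-set rule is this
package's explicit proxy for ranking genes by topological role; it is
recorded in the run manifest as an assumption.

Hits are then tested for over-representation in each supplied gene set
with the one-sided exact hypergeometric tail P(X >= overlap), against a
background of all genes in the ligand-receptor panel (only those genes
can ever be hits), with Benjamini-Hochberg correction across the sets of
one (measure, direction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .network import DiffReport, MEASURES

__all__ = ["gene_hit_sets", "fisher_enrichment", "enrichment_report", "DIRECTIONS"]

DIRECTIONS = ("up_in_plus", "up_in_minus")


def _edge_genes(scores: pd.DataFrame) -> dict:
    """(sender, receiver) -> (ligand set, receptor set) over significant rows."""
    out = {}
    sig = scores[scores["significant"].astype(bool)]
    for (s, r), grp in sig.groupby(["sender", "receiver"]):
        out[(s, r)] = (set(grp["ligand"]), set(grp["receptor"]))
    return out


def gene_hit_sets(report: DiffReport, scores_plus: pd.DataFrame,
                  scores_minus: pd.DataFrame) -> dict:
    """Hit sets keyed by (measure, direction).

    Swapping the plus and minus inputs (which negates every delta and log
    odds ratio) exchanges the ``up_in_plus`` and ``up_in_minus`` sets
    exactly.
    """
    hits = {(m, d): set() for m in MEASURES for d in DIRECTIONS}
    if report.nodes.empty:
        return hits
    by_dir = {
        "up_in_plus": (
            report.edges[report.edges["log_odds_ratio"] > 0],
            {m: set(report.nodes.index[report.nodes[f"delta_{m}"] > 0]) for m in MEASURES},
            _edge_genes(scores_plus),
        ),
        "up_in_minus": (
            report.edges[report.edges["log_odds_ratio"] < 0],
            {m: set(report.nodes.index[report.nodes[f"delta_{m}"] < 0]) for m in MEASURES},
            _edge_genes(scores_minus),
        ),
    }
    for d, (edges, pos_nodes, genes) in by_dir.items():
        for _, row in edges.iterrows():
            s, r = row["sender"], row["receiver"]
            lig, rec = genes.get((s, r), (set(), set()))
            for m in MEASURES:
                nodes = pos_nodes[m]
                if m == "influencer":
                    if s in nodes:
                        hits[(m, d)] |= lig
                elif m == "listener":
                    if r in nodes:
                        hits[(m, d)] |= rec
                else:  # mediator, pagerank: either incidence, both gene roles
                    if s in nodes or r in nodes:
                        hits[(m, d)] |= lig | rec
    return hits


def fisher_enrichment(hits, background, collection: GeneSetCollection,
                      ) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of *hits* in each set.

    *background* is the gene universe (all LR-panel genes); sets are
    restricted to it before testing.  Returns one row per set with the
    raw p-value P(X >= overlap) and a Benjamini-Hochberg q-value across
    the collection.  Results do not depend on gene ordering.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    hits = set(hits)
    if not hits <= background:
        raise ValueError(
            f"hits outside background: {sorted(hits - background)[:5]}"
        )
    M, N = len(background), len(hits)
    recs = []
    for name, genes in collection:
        in_bg = set(genes) & background
        n = len(in_bg)
        k = len(in_bg & hits)
        # survival function at k-1 gives the inclusive upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        recs.append((name, k, n, N, M, min(p, 1.0)))
    df = pd.DataFrame(
        recs,
        columns=["set_name", "overlap", "set_size", "hits_size",
                 "background_size", "p_value"],
    )
    df["q_value"] = (
        multipletests(df["p_value"], method="fdr_bh")[1] if len(df) else np.nan
    )
    return df


def enrichment_report(report: DiffReport, scores_plus, scores_minus,
                      collection: GeneSetCollection, background) -> pd.DataFrame:
    """Full enrichment table: one row per (measure, direction, set)."""
    hit_sets = gene_hit_sets(report, scores_plus, scores_minus)
    frames = []
    for (m, d), hits in sorted(hit_sets.items()):
        df = fisher_enrichment(hits, background, collection)
        df.insert(0, "direction", d)
        df.insert(0, "measure", m)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
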