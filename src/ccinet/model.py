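"""Model/results interface over the interaction-scoring machinery.

:class:`CCIModel` is built from data (counts, per-cell annotation, an LR
panel) the way a statsmodels model is built from endog/exog; ``fit()``
runs the permutation interaction test for one cell partition and returns
a :class:`CCIResults` carrying the score table, the aggregated network
and a ``summary()``.  :class:`DifferentialCCI` takes the results of the
two partitions and produces a :class:`DifferentialCCIResults` with the
node/edge comparison, enrichment and plotting.
"""

from __future__ import annotations

import pandas as pd

from . import io as _io
from .enrich import enrichment_report
from .network import DiffReport, build_network, compare_networks, node_measures
from .qc import Partition, stratify_by_marker
from .scoring import ScoringParams, score_interactions

__all__ = ["CCIModel", "CCIResults", "DifferentialCCI", "DifferentialCCIResults"]


class CCIModel:
    """Cell-cell interaction model for one count matrix.

    Parameters
    ----------
    counts : CountMatrix
        QC-filtered counts (see :func:`ccinet.qc.apply_qc`).
    annotation : DataFrame
        Validated per-cell annotation covering the matrix barcodes.
    lr_pairs : DataFrame
        Ligand-receptor panel with columns ``ligand``/``receptor``.
    params : ScoringParams, optional
    """

    def __init__(self, counts, annotation, lr_pairs, params=None):
        self.counts = counts
        self.annotation = _io.validate_annotation(annotation, barcodes=counts.barcodes)
        self.lr_pairs = _io.validate_lr_pairs(lr_pairs)
        self.params = params or ScoringParams()

    @classmethod
    def from_files(cls, counts_path, annotation_path, lr_path, params=None,
                   counts_format=None):
        counts = _io.read_counts(counts_path, format=counts_format)
        ann = _io.read_annotation(annotation_path, barcodes=counts.barcodes)
        lr = _io.read_lr_pairs(lr_path)
        return cls(counts, ann, lr, params=params)

    def stratify(self, marker_gene: str, min_marker_count: int = 1) -> Partition:
        """Partition cells by marker positivity (>= min_marker_count)."""
        return stratify_by_marker(self.counts, marker_gene, min_marker_count)

    def fit(self, partition: Partition | None = None,
            label: str | None = None) -> "CCIResults":
        """Run the permutation interaction test; on all cells when no
        partition is given, else on one partition label."""
        scores = score_interactions(
            self.counts, self.annotation, self.lr_pairs, self.params,
            partition=partition, label=label,
        )
        return CCIResults(self, scores, label)


class CCIResults:
    """Fitted interaction scores for one partition (or all cells)."""

    def __init__(self, model: CCIModel, scores: pd.DataFrame, label):
        self.model = model
        self.scores = scores
        self.label = label
        self._graph = None

    @property
    def graph(self):
        if self._graph is None:
            self._graph = build_network(self.scores)
        return self._graph

    def node_measures(self, damping: float = 0.85) -> pd.DataFrame:
        return node_measures(self.graph, damping=damping)

    @property
    def n_tested(self) -> int:
        return int(self.scores["tested"].sum())

    @property
    def n_significant(self) -> int:
        return int(self.scores["significant"].sum())

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary with the strongest interactions."""
        p = self.model.params
        lines = [
            "Cell-cell interaction results"
            + (f" [{self.label}]" if self.label else ""),
            "=" * 46,
            f"cells:                 {self.model.counts.n_cells}",
            f"cell types (eligible): {len(self.scores.attrs.get('eligible_types', []))}",
            f"LR pairs:              {len(self.model.lr_pairs)}",
            f"permutations:          {p.n_permutations}  (seed {p.seed})",
            f"tested interactions:   {self.n_tested}",
            f"significant (alpha={p.alpha}): {self.n_significant}",
            "",
        ]
        sig = self.scores[self.scores["significant"]].nlargest(top, "mean_score")
        if len(sig):
            lines.append(f"top {len(sig)} significant interactions by mean score:")
            lines.append(
                sig[["sender", "receiver", "ligand", "receptor",
                     "mean_score", "p_value"]].to_string(index=False)
            )
        else:
            lines.append("no significant interactions")
        return "\n".join(lines)


class DifferentialCCI:
    """Comparison of the positive- and negative-partition networks."""

    def __init__(self, results_plus: CCIResults, results_minus: CCIResults,
                 damping: float = 0.85, correction: float = 0.5):
        self.results_plus = results_plus
        self.results_minus = results_minus
        self.damping = damping
        self.correction = correction

    def fit(self) -> "DifferentialCCIResults":
        report = compare_networks(
            self.results_plus.graph, self.results_minus.graph,
            damping=self.damping, correction=self.correction,
        )
        return DifferentialCCIResults(self, report)


class DifferentialCCIResults:
    """Differential report plus enrichment and plotting conveniences."""

    def __init__(self, model: DifferentialCCI, report: DiffReport):
        self.model = model
        self.report = report

    @property
    def nodes(self) -> pd.DataFrame:
        return self.report.nodes

    @property
    def edges(self) -> pd.DataFrame:
        return self.report.edges

    def enrich(self, collection, background=None) -> pd.DataFrame:
        """Topology-indexed gene-set over-representation (see
        :mod:`ccinet.enrich`); background defaults to the LR panel genes."""
        if background is None:
            lr = self.model.results_plus.model.lr_pairs
            background = set(lr["ligand"]) | set(lr["receptor"])
        return enrichment_report(
            self.report,
            self.model.results_plus.scores,
            self.model.results_minus.scores,
            collection,
            background,
        )

    def plot_network(self, ax=None):
        from .plotting import plot_comparative_network

        return plot_comparative_network(self.report, ax=ax)

    def summary(self, top: int = 8) -> str:
        r = self.report
        lines = [
            "Differential cell-cell interaction network",
            "=" * 46,
            f"significant interactions: plus={r.total_plus}  minus={r.total_minus}",
            "",
            "node measures (delta = plus - minus):",
            r.nodes.round(4).to_string(),
            "",
            f"top {top} edges by |log odds ratio|:",
        ]
        top_edges = r.edges.reindex(
            r.edges["log_odds_ratio"].abs().sort_values(ascending=False).index
        ).head(top)
        lines.append(
            top_edges[["sender", "receiver", "count_plus", "count_minus",
                       "log_odds_ratio", "direction"]].round(3).to_string(index=False)
        )
        return "\n".join(lines)
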