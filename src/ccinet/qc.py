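"""Cell-level quality control, compartment subsetting, and marker stratification.

The QC gates follow the strict-inequality reading of the standard filter
wording: cells with *less than* ``min_total`` or *more than* ``max_total``
transcripts are removed, as are cells with *more than* ``max_mito_frac``
of transcripts of mitochondrial origin.  Boundary cells (exactly 200 or
5800 transcripts, exactly 5% mitochondrial) are therefore retained; flip
the thresholds by one count / one ulp for the inclusive convention.

Mitochondrial fractions are computed on raw counts before any
normalization.  Cells, never genes, are filtered.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "Partition",
    "apply_qc",
    "subset_compartment",
    "stratify_by_marker",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention gates (defaults: 200 <= total <= 5800, mito <= 5%)."""

    min_total: int = 200
    max_total: int = 5800
    max_mito_frac: float = 0.05
    mito_prefix: str = "MT-"

    def __post_init__(self):
        if not 0 < self.min_total <= self.max_total:
            raise ValueError("need 0 < min_total <= max_total")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must be in [0, 1]")


@dataclass
class QCReport:
    """Removal tally; a cell failing two gates counts once under each gate
    and once in the total."""

    n_input: int = 0
    n_kept: int = 0
    n_removed_low_total: int = 0
    n_removed_high_total: int = 0
    n_removed_mito: int = 0
    n_removed_total: int = 0
    thresholds: QCThresholds = field(default_factory=QCThresholds)


class EmptyQCResultError(RuntimeError):
    pass


def apply_qc(matrix: CountMatrix, thresholds: QCThresholds | None = None):
    """Filter cells by total-count and mitochondrial-fraction gates.

    Returns ``(filtered CountMatrix, QCReport)``.  Idempotent: applying
    the same thresholds twice equals applying them once.  Raises
    :class:`EmptyQCResultError` when a non-empty input loses every cell.
    """
    thresholds = thresholds or QCThresholds()
    totals = matrix.cell_totals()
    mito = matrix.mito_mask(thresholds.mito_prefix)
    mito_totals = (
        np.asarray(matrix.counts[mito].sum(axis=0)).ravel()
        if mito.any()
        else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)

    low = totals < thresholds.min_total
    high = totals > thresholds.max_total
    mito_fail = frac > thresholds.max_mito_frac
    keep = ~(low | high | mito_fail)

    report = QCReport(
        n_input=matrix.n_cells,
        n_kept=int(keep.sum()),
        n_removed_low_total=int(low.sum()),
        n_removed_high_total=int(high.sum()),
        n_removed_mito=int(mito_fail.sum()),
        n_removed_total=int((~keep).sum()),
        thresholds=thresholds,
    )
    if matrix.n_cells > 0 and report.n_kept == 0:
        raise EmptyQCResultError(
            f"no cells survive QC with min_total={thresholds.min_total}, "
            f"max_total={thresholds.max_total}, "
            f"max_mito_frac={thresholds.max_mito_frac}"
        )
    return matrix.subset_cells(keep), report


def subset_compartment(matrix: CountMatrix, annotation: pd.DataFrame,
                       compartment: str):
    """Restrict matrix and annotation to one compartment, original order kept."""
    present = annotation["compartment"].unique().tolist()
    if compartment not in present:
        raise KeyError(
            f"compartment {compartment!r} not in annotation (have {present})"
        )
    ann = annotation[annotation["compartment"] == compartment].reset_index(drop=True)
    wanted = set(ann["barcode"])
    mask = np.array([b in wanted for b in matrix.barcodes])
    return matrix.subset_cells(mask), ann


@dataclass
class Partition:
    """Per-cell positive/negative labels from marker-gene counts."""

    marker_gene: str
    min_marker_count: int
    labels: pd.Series  # index: barcode, values: "positive" | "negative"

    @property
    def positive_fraction(self) -> float:
        if len(self.labels) == 0:
            return float("nan")
        return float((self.labels == "positive").mean())

    def barcodes(self, label: str) -> list:
        return self.labels.index[self.labels == label].tolist()


def stratify_by_marker(matrix: CountMatrix, marker_gene: str,
                       min_marker_count: int = 1) -> Partition:
    """Label each cell positive iff its marker count >= ``min_marker_count``.

    The partition is a function of the marker row only.  A marker absent
    from the matrix raises a KeyError listing near-matching symbols; an
    all-negative result and a ``min_marker_count`` of 0 (everything
    positive) each emit a warning.
    """
    if marker_gene not in matrix.genes:
        near = difflib.get_close_matches(marker_gene, matrix.genes, n=5)
        raise KeyError(
            f"marker gene {marker_gene!r} not found; close matches: {near}"
        )
    if min_marker_count <= 0:
        warnings.warn(
            "min_marker_count <= 0 labels every cell positive", stacklevel=2
        )
    counts = matrix.gene_counts(marker_gene)
    labels = pd.Series(
        np.where(counts >= min_marker_count, "positive", "negative"),
        index=pd.Index(matrix.barcodes, name="barcode"),
        name="partition",
    )
    part = Partition(marker_gene, min_marker_count, labels)
    if matrix.n_cells and part.positive_fraction == 0.0:
        warnings.warn(
            f"no cell reaches {min_marker_count} {marker_gene} transcript(s); "
            "the positive partition is empty",
            stacklevel=2,
        )
    return part
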