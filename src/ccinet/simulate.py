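"""Seeded synthetic single-cell count data with planted interaction effects.

The generator emulates the structure of a cross-sectional immune scRNA-seq
study: several annotated cell types sampled from two cohorts (healthy
control vs. disease) and two compartments (CSF vs. PBMC), overdispersed
negative-binomial counts with cell-type-specific on/off gene programs,
always-on mitochondrial genes for QC, a sparsely expressed homotypic
marker gene (``SLAMF7`` by default), and an optional planted effect: a
multiplicative upregulation of chosen ligand genes restricted to
marker-positive cells of one cell type.

The planted effect genes are *homotypic* ligand-receptor self-pairs
(ligand == receptor, like SLAMF7 itself) expressed in every cell type at
baseline, so that without the effect the interaction statistic is
null-centred, and with it the effect cell type both sends and receives
elevated signal — the circuit a homotypic receptor creates among
receptor-positive cells.

Everything is driven by one integer seed through a single named random
stream; two calls with equal configs produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, validate_annotation, validate_lr_pairs

__all__ = ["SimConfig", "GroundTruth", "generate_dataset", "make_qc_fixture",
           "DEFAULT_CELL_TYPES"]

#: Plausible immune subsets of a CSF/PBMC study; the first ``n_cell_types``
#: are used.  "B cell" comes first so small configurations still contain the
#: default effect cell type.
DEFAULT_CELL_TYPES = [
    "B cell", "Plasma cell", "NK cell", "Granulocyte", "CD4 T cell",
    "CD8 T cell", "Treg", "Monocyte", "mDC", "pDC", "MAIT",
]

COHORTS = ("HC", "MS")
COMPARTMENTS = ("CSF", "PBMC")
DONORS_PER_COHORT = 6  # six healthy controls and six patients


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Counts for a gene that is "on" in a cell type are negative binomial
    with mean ``nb_mean`` and size (dispersion) ``nb_dispersion``; "off"
    genes are exactly zero.  ``cells_per_type`` is per cohort per
    compartment, so the total cell count is
    ``n_cell_types * cells_per_type * 4``.
    """

    seed: int = 0
    n_cell_types: int = 6
    cells_per_type: int = 100
    n_background_genes: int = 300
    n_mito_genes: int = 10
    n_lr_pairs: int = 30
    n_homotypic_pairs: int = 5
    nb_mean: float = 8.0
    nb_dispersion: float = 2.0
    mito_mean: float = 2.0
    expression_prob: float = 0.35
    shared_programs: bool = False
    marker_gene: str = "SLAMF7"
    marker_prevalence: float = 0.0512
    marker_mean: float = 1.0
    effect_cell_type: str = "B cell"
    effect_ligands: tuple = ()
    effect_multiplier: float = 1.0
    qc_noise: float = 0.0

    def __post_init__(self):
        for name in ("expression_prob", "marker_prevalence", "qc_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_multiplier < 1.0:
            raise ValueError("effect_multiplier must be >= 1")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        if self.n_cell_types < 1 or self.n_cell_types > len(DEFAULT_CELL_TYPES):
            raise ValueError(
                f"n_cell_types must be in [1, {len(DEFAULT_CELL_TYPES)}]"
            )
        if self.n_homotypic_pairs + 1 > self.n_lr_pairs:
            raise ValueError("n_lr_pairs must exceed n_homotypic_pairs + 1")

    @property
    def cell_types(self) -> list:
        return DEFAULT_CELL_TYPES[: self.n_cell_types]

    def homotypic_genes(self) -> list:
        return [f"HOM{i + 1:03d}" for i in range(self.n_homotypic_pairs)]

    def resolved_effect_ligands(self) -> list:
        """Effect ligands; defaults to all homotypic circuit genes."""
        return list(self.effect_ligands) or self.homotypic_genes()


@dataclass
class GroundTruth:
    """What was planted, per cell and globally."""

    cells: pd.DataFrame  # barcode, marker_positive, qc_violation
    effect_cell_type: str
    effect_ligands: list
    effect_multiplier: float
    config: dict = field(default_factory=dict)


def _nb_p(mean: np.ndarray, size: float) -> np.ndarray:
    # numpy's negative_binomial(n, p) has mean n(1-p)/p; p = size/(size+mean)
    return size / (size + mean)


def _build_lr_panel(config: SimConfig) -> pd.DataFrame:
    """Marker self-pair + homotypic circuit self-pairs + heterotypic pairs."""
    rows = [(config.marker_gene, config.marker_gene)]
    rows += [(g, g) for g in config.homotypic_genes()]
    n_het = config.n_lr_pairs - len(rows)
    rows += [(f"LIG{i + 1:03d}", f"REC{i + 1:03d}") for i in range(n_het)]
    return validate_lr_pairs(pd.DataFrame(rows, columns=["ligand", "receptor"]))


def generate_dataset(config: SimConfig):
    """Generate (CountMatrix, annotation, LR panel, GroundTruth).

    Draw order from the single seeded stream: gene on/off programs, marker
    positivity, count matrix, marker magnitudes, QC violators.  With
    ``effect_multiplier == 1`` marker status is independent of every other
    gene, so the positive and negative partitions are exchangeable.
    """
    rng = np.random.default_rng(config.seed)
    types = config.cell_types
    if config.effect_multiplier > 1 and config.effect_cell_type not in types:
        raise ValueError(
            f"effect_cell_type {config.effect_cell_type!r} not among "
            f"generated cell types {types}"
        )

    lr = _build_lr_panel(config)
    effect_ligands = config.resolved_effect_ligands()
    missing = set(effect_ligands) - set(lr["ligand"])
    if missing:
        raise ValueError(f"effect_ligands not in generated LR panel: {sorted(missing)}")

    bg_genes = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    mito_genes = [f"MT-SIM{i + 1:02d}" for i in range(config.n_mito_genes)]
    lr_genes = list(dict.fromkeys(
        [g for g in lr["ligand"] if g != config.marker_gene]
        + [g for g in lr["receptor"] if g != config.marker_gene]
    ))
    genes = bg_genes + mito_genes + lr_genes + [config.marker_gene]
    n_genes, k = len(genes), len(types)

    # annotation: types x cohorts x compartments blocks, donors round-robin
    recs = []
    i = 0
    for comp in COMPARTMENTS:
        for cohort in COHORTS:
            for t in types:
                for j in range(config.cells_per_type):
                    recs.append(
                        (
                            f"CELL{i + 1:06d}",
                            t,
                            f"{cohort}{j % DONORS_PER_COHORT + 1}",
                            cohort,
                            comp,
                        )
                    )
                    i += 1
    ann = pd.DataFrame(
        recs, columns=["barcode", "cell_type", "donor", "cohort", "compartment"]
    )
    n_cells = len(ann)
    type_code = pd.Categorical(ann["cell_type"], categories=types).codes

    # on/off programs per (gene, type)
    if config.shared_programs:
        on = np.repeat(
            rng.random(n_genes)[:, None] < config.expression_prob, k, axis=1
        )
    else:
        on = rng.random((n_genes, k)) < config.expression_prob
    gene_pos = {g: idx for idx, g in enumerate(genes)}
    homotypic = config.homotypic_genes()
    for g in mito_genes + homotypic:
        on[gene_pos[g], :] = True  # mito housekeeping; homotypic circuit ubiquitous
    on[gene_pos[config.marker_gene], :] = False  # marker drawn separately

    mean_gene = np.full(n_genes, config.nb_mean)
    for g in mito_genes:
        mean_gene[gene_pos[g]] = config.mito_mean

    # marker positivity first: Bernoulli(prevalence), independent of programs
    marker_positive = rng.random(n_cells) < config.marker_prevalence

    mean = on[:, type_code] * mean_gene[:, None]  # genes x cells
    if config.effect_multiplier > 1:
        affected = marker_positive & (ann["cell_type"].to_numpy() == config.effect_cell_type)
        rows = [gene_pos[g] for g in effect_ligands]
        mean[np.ix_(rows, np.flatnonzero(affected))] *= config.effect_multiplier

    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    nz = mean > 0
    counts[nz] = rng.negative_binomial(
        config.nb_dispersion, _nb_p(mean[nz], config.nb_dispersion)
    )

    # marker: Bernoulli presence x NB magnitude truncated at 1
    mrow = gene_pos[config.marker_gene]
    mag = rng.negative_binomial(
        config.nb_dispersion,
        _nb_p(np.full(n_cells, config.marker_mean), config.nb_dispersion),
    )
    counts[mrow] = np.where(marker_positive, np.maximum(mag, 1), 0)

    # QC violators: exactly one gate each, round-robin over the three gates
    qc_flag = np.array([""] * n_cells, dtype=object)
    n_viol = int(math.floor(config.qc_noise * n_cells))
    if n_viol:
        victims = rng.choice(n_cells, size=n_viol, replace=False)
        mito_rows = [gene_pos[g] for g in mito_genes]
        for which, c in enumerate(victims):
            gate = ("low_total", "high_total", "mito")[which % 3]
            col = counts[:, c].astype(float)
            if gate == "low_total":
                tot = col.sum()
                if tot > 0:
                    counts[:, c] = rng.multinomial(199, col / tot)
            elif gate == "high_total":
                tot = col.sum()
                if tot > 0:
                    counts[:, c] = rng.multinomial(5801, col / tot)
            else:
                # push the mitochondrial fraction just above 5%
                non_mito = counts[:, c].sum() - counts[mito_rows, c].sum()
                target = int(math.ceil(0.055 / (1 - 0.055) * max(non_mito, 1)))
                share = np.full(len(mito_rows), target // len(mito_rows))
                share[: target % len(mito_rows)] += 1
                counts[mito_rows, c] = share
            qc_flag[c] = gate

    matrix = CountMatrix(genes, ann["barcode"].tolist(), sp.csr_matrix(counts))
    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "barcode": ann["barcode"],
                "marker_positive": marker_positive,
                "qc_violation": qc_flag,
            }
        ),
        effect_cell_type=config.effect_cell_type,
        effect_ligands=effect_ligands,
        effect_multiplier=config.effect_multiplier,
        config=asdict(config),
    )
    return matrix, validate_annotation(ann), lr, truth


# ---------------------------------------------------------------------------
# QC boundary fixture
# ---------------------------------------------------------------------------

def make_qc_fixture(min_total: int = 200, max_total: int = 5800,
                    max_mito_frac: float = 0.05):
    """Small deterministic matrix exercising every QC gate boundary.

    Cells cover per-cell totals exactly {199, 200, 5800, 5801} and
    mitochondrial fractions exactly {4.9%, 5.0%, 5.1%} (the fraction
    boundaries are realised at total 1000, where they are integral; a
    4.9% count is not an integer at totals 199/200/5800/5801, so the full
    cross is not representable with integer counts).  A few realisable
    crossed combinations are included.  Returns ``(CountMatrix, expected)``
    where *expected* is a boolean keep label per barcode under the strict
    reading of the gates: keep iff ``min_total <= total <= max_total`` and
    ``mito_frac <= max_mito_frac``.
    """
    specs = [
        # (total, mito_count) — mito fraction = mito_count / total
        (199, 0),
        (200, 0),
        (5800, 0),
        (5801, 0),
        (1000, 49),   # 4.9%
        (1000, 50),   # 5.0%
        (1000, 51),   # 5.1%
        (200, 10),    # 5.0% at the low total boundary
        (5800, 290),  # 5.0% at the high total boundary
        (199, 9),     # fails the low-total gate only
        (5801, 290),  # fails the high-total gate only
        (1000, 56),   # 5.6%, mito gate only
    ]
    genes = ["MT-FIX1", "GENE1", "GENE2"]
    cols, keep, barcodes = [], [], []
    for idx, (total, mito) in enumerate(specs):
        rest = total - mito
        cols.append([mito, rest // 2, rest - rest // 2])
        keep.append(
            min_total <= total <= max_total and mito / total <= max_mito_frac
        )
        barcodes.append(f"FIX{idx + 1:03d}")
    counts = sp.csr_matrix(np.array(cols, dtype=np.int64).T)
    expected = pd.Series(keep, index=barcodes, name="keep")
    return CountMatrix(genes, barcodes, counts), expected
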