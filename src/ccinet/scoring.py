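"""Permutation-test scoring of ligand-receptor interactions between cell types.

For every ordered (sender, receiver) cell-type pair — including
sender == receiver, since a homotypic receptor lets a cell type signal to
itself — and every ligand-receptor pair, the interaction statistic is the
arithmetic mean of two cluster means on library-size-normalized counts:

    score = ( mean ligand over sender cells
            + mean receptor over receiver cells ) / 2

An interaction is *tested* only when the ligand is detected in at least
``min_expressing_frac`` of sender cells and the receptor in at least that
fraction of receiver cells.  Significance comes from a cluster-label
permutation null: each permutation round shuffles the cell-type labels of
all cells once and recomputes every statistic against that same shuffle,
preserving the cross-statistic correlation of the null.  The p-value uses
the add-one estimator

    p = (1 + #{permuted score >= observed}) / (n_permutations + 1)

so it is never exactly zero (implementations that report 0 differ here by
design).  Raw permutation p-values are reported by default; an optional
Benjamini-Hochberg correction can gate significance instead.

``exact_permutation_p`` enumerates the full permutation distribution on
small two-type instances and is the independent oracle the sampled test
is verified against.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SCORE_COLUMNS
from .qc import Partition

__all__ = [
    "ScoringParams",
    "normalize_counts",
    "score_interactions",
    "exact_permutation_p",
    "partition_rng",
]


@dataclass(frozen=True)
class ScoringParams:
    """Knobs of the permutation interaction test (defaults follow the
    published scheme of the permutation CCI tools: 1000 label shuffles,
    a 10% expressing-cell gate, alpha 0.05, counts scaled to 10,000 per
    cell)."""

    n_permutations: int = 1000
    min_expressing_frac: float = 0.10
    alpha: float = 0.05
    normalization_scale: float = 10_000.0
    seed: int = 0
    min_cells_per_type: int = 10
    use_bh: bool = False

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 <= self.min_expressing_frac <= 1.0:
            raise ValueError("min_expressing_frac must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def partition_rng(seed: int, label: str | None) -> np.random.Generator:
    """Random stream tagged by partition label, so adding or removing one
    partition never perturbs the other's permutations."""
    if label is None:
        return np.random.default_rng(seed)
    tag = int.from_bytes(
        hashlib.sha256(label.encode()).digest()[:4], "big"
    ) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def normalize_counts(matrix: CountMatrix, scale: float = 10_000.0) -> sp.csr_matrix:
    """Library-size normalization: each cell's values sum to *scale*.

    No log transform.  A zero-total cell (impossible after QC) raises.
    """
    totals = matrix.cell_totals()
    if np.any(totals == 0):
        bad = [matrix.barcodes[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"zero-total cells cannot be normalized: {bad}")
    d = sp.diags(scale / totals.astype(float))
    return sp.csr_matrix(matrix.counts @ d)


def _restrict_to_partition(matrix, annotation, partition, label):
    wanted = set(partition.barcodes(label))
    mask = np.array([b in wanted for b in matrix.barcodes])
    sub = matrix.subset_cells(mask)
    ann = annotation[annotation["barcode"].isin(wanted)].reset_index(drop=True)
    return sub, ann


def score_interactions(
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    lr_pairs: pd.DataFrame,
    params: ScoringParams | None = None,
    *,
    partition: Partition | None = None,
    label: str | None = None,
) -> pd.DataFrame:
    """Score every (sender, receiver, ligand, receptor) combination.

    When *partition* and *label* are given, cells are first restricted to
    that partition label and the permutation stream is tagged by the
    label.  Cell types with fewer than ``min_cells_per_type`` cells are
    excluded from testing entirely (listed in ``result.attrs``); at least
    two eligible types are required.

    Returns a DataFrame with one row per tested universe entry and the
    columns of :data:`ccinet.io.SCORE_COLUMNS`.  Untested entries (gate
    failures or genes absent from the matrix) keep ``p_value == 1`` and a
    reported ``mean_score`` of 0.  ``result.attrs`` records the partition
    label, excluded types, and parameters.
    """
    params = params or ScoringParams()
    if partition is not None:
        if label is None:
            raise ValueError("a partition requires a label to select")
        matrix, annotation = _restrict_to_partition(
            matrix, annotation, partition, label
        )
    order = {b: i for i, b in enumerate(matrix.barcodes)}
    ann = annotation.sort_values("barcode", key=lambda s: s.map(order))
    if list(ann["barcode"]) != list(matrix.barcodes):
        raise ValueError("annotation does not cover exactly the matrix barcodes")

    types = sorted(ann["cell_type"].unique())
    codes = pd.Categorical(ann["cell_type"], categories=types).codes
    sizes = np.bincount(codes, minlength=len(types))
    eligible = sizes >= params.min_cells_per_type
    if eligible.sum() < 2:
        raise ValueError(
            f"fewer than two cell types with >= {params.min_cells_per_type} "
            f"cells (sizes: {dict(zip(types, sizes.tolist()))})"
        )
    excluded = [t for t, e in zip(types, eligible) if not e]

    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    needed = [
        g
        for g in dict.fromkeys(lr_pairs["ligand"].tolist() + lr_pairs["receptor"].tolist())
        if g in gene_pos
    ]
    need_idx = {g: i for i, g in enumerate(needed)}
    rows = [gene_pos[g] for g in needed]

    n_cells, k = matrix.n_cells, len(types)
    Xn = np.asarray(normalize_counts(matrix, params.normalization_scale)[rows].todense())
    detected = np.asarray((matrix.counts[rows] > 0).todense()).astype(float)

    # one-hot / group-size matrix: column means via a single matmul
    G = np.zeros((n_cells, k))
    G[np.arange(n_cells), codes] = 1.0
    G /= np.maximum(sizes, 1)[None, :]

    M = Xn @ G          # cluster means, genes x types
    F = detected @ G    # expressing fraction, genes x types

    pairs_ok = [
        (li, ri)
        for li, ri in zip(lr_pairs["ligand"], lr_pairs["receptor"])
    ]
    li_idx = np.array([need_idx.get(l, -1) for l, _ in pairs_ok])
    ri_idx = np.array([need_idx.get(r, -1) for _, r in pairs_ok])
    present = (li_idx >= 0) & (ri_idx >= 0)
    li_safe = np.where(present, li_idx, 0)
    ri_safe = np.where(present, ri_idx, 0)

    S_obs = 0.5 * (M[li_safe][:, :, None] + M[ri_safe][:, None, :])

    rng = partition_rng(params.seed, label)
    ge = np.zeros_like(S_obs, dtype=np.int64)
    for _ in range(params.n_permutations):
        Gp = G[rng.permutation(n_cells)]
        Mp = Xn @ Gp
        Sp = 0.5 * (Mp[li_safe][:, :, None] + Mp[ri_safe][:, None, :])
        ge += Sp >= S_obs
    p = (1.0 + ge) / (params.n_permutations + 1.0)

    frac_l = F[li_safe]  # pairs x types (sender)
    frac_r = F[ri_safe]

    el = np.flatnonzero(eligible)
    recs = []
    for pi, (lig, rec) in enumerate(pairs_ok):
        for s in el:
            for r in el:
                fl = frac_l[pi, s] if present[pi] else 0.0
                fr = frac_r[pi, r] if present[pi] else 0.0
                tested = (
                    present[pi]
                    and fl >= params.min_expressing_frac
                    and fr >= params.min_expressing_frac
                )
                recs.append(
                    (
                        types[s],
                        types[r],
                        lig,
                        rec,
                        float(S_obs[pi, s, r]) if tested else 0.0,
                        float(fl),
                        float(fr),
                        float(p[pi, s, r]) if tested else 1.0,
                        bool(tested),
                    )
                )
    out = pd.DataFrame(recs, columns=SCORE_COLUMNS[:-1])
    if params.use_bh:
        q = np.ones(len(out))
        t = out["tested"].to_numpy()
        if t.any():
            q[t] = multipletests(out.loc[t, "p_value"], method="fdr_bh")[1]
        out["q_value"] = q
        out["significant"] = out["tested"] & (out["q_value"] <= params.alpha)
    else:
        out["significant"] = out["tested"] & (out["p_value"] <= params.alpha)
    out.attrs.update(
        partition=label,
        excluded_types=excluded,
        eligible_types=[types[i] for i in el],
        params=params.__dict__.copy(),
    )
    return out


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------

def exact_permutation_p(
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    lr_pair: tuple,
    sender: str,
    receiver: str,
    scale: int = 10_000,
    max_cells: int = 12,
) -> Fraction:
    """Exact permutation tail probability for one interaction, by full
    enumeration of the two-type label assignment.

    Restricted to the cells of *sender* and *receiver* (distinct types,
    at most *max_cells* cells in total), every distinct assignment of
    cells to the observed group sizes is enumerated; the returned value
    is ``#{assignments with score >= observed} / #assignments`` in exact
    rational arithmetic, with the observed assignment included in both
    numerator and denominator.
    """
    if sender == receiver:
        raise ValueError("the enumeration oracle needs two distinct types")
    ligand, receptor = lr_pair
    mask = annotation["cell_type"].isin([sender, receiver])
    ann = annotation[mask]
    wanted = set(ann["barcode"])
    cell_idx = [i for i, b in enumerate(matrix.barcodes) if b in wanted]
    n = len(cell_idx)
    if n > max_cells:
        raise ValueError(f"{n} cells exceed the enumeration bound of {max_cells}")

    totals = matrix.cell_totals()
    by_barcode = dict(zip(ann["barcode"], ann["cell_type"]))

    def norm_values(gene):
        row = matrix.gene_counts(gene)
        vals = []
        for i in cell_idx:
            if totals[i] == 0:
                raise ValueError("zero-total cell")
            vals.append(Fraction(int(row[i]) * scale, int(totals[i])))
        return vals

    lig_vals = norm_values(ligand)
    rec_vals = norm_values(receptor)
    sender_cells = [
        j for j, i in enumerate(cell_idx)
        if by_barcode[matrix.barcodes[i]] == sender
    ]
    n_s = len(sender_cells)

    def score(sender_set):
        receiver_set = [j for j in range(n) if j not in sender_set]
        lm = sum(lig_vals[j] for j in sender_set) / n_s
        rm = sum(rec_vals[j] for j in receiver_set) / (n - n_s)
        return (lm + rm) / 2

    observed = score(set(sender_cells))
    hits = sum(
        1
        for combo in itertools.combinations(range(n), n_s)
        if score(set(combo)) >= observed
    )
    return Fraction(hits, math.comb(n, n_s))
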