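"""Readers and writers for every external format the pipeline touches.

Counts travel as a 10x-style Matrix-Market triplet (genes are rows, cells
are columns, 1-based indices as the format requires) or as a dense CSV
with gene symbols in the first column and cell barcodes in the header.
Annotations and ligand-receptor panels are plain CSV; gene sets use the
tab-separated GMT convention.  Every reader validates the structural
invariants the rest of the pipeline assumes (unique identifiers,
non-negative integer counts, consistent dimensions) so downstream code
never re-checks them.

Gene identity is by symbol string, case-sensitive, with no aliasing:
``SLAMF7`` is matched literally.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "CountMatrix",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_lr_pairs",
    "write_lr_pairs",
    "read_gmt",
    "write_gmt",
    "write_outputs",
]

ANNOTATION_COLUMNS = ("barcode", "cell_type", "donor", "cohort", "compartment")


class FormatError(ValueError):
    """A file violated the structural contract of its format."""


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique()[:5].tolist()
        raise FormatError(f"duplicate {what}: {dup}")


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene x cell matrix with identifiers.

    Parameters
    ----------
    genes
        Ordered gene symbols (rows), unique.
    barcodes
        Ordered cell identifiers (columns), unique.
    counts
        ``|genes| x |barcodes|`` sparse matrix of non-negative integers.
    """

    genes: list
    barcodes: list
    counts: sp.csr_matrix

    def __post_init__(self):
        self.genes = list(self.genes)
        self.barcodes = list(self.barcodes)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.genes, "gene symbols")
        _check_unique(self.barcodes, "barcodes")
        n_g, n_c = self.counts.shape
        if n_g != len(self.genes) or n_c != len(self.barcodes):
            raise FormatError(
                f"matrix is {n_g} x {n_c} but {len(self.genes)} genes and "
                f"{len(self.barcodes)} barcodes were supplied"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count entries")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entries")
        self.counts = self.counts.astype(np.int64)

    # -- convenience ----------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Per-cell total transcript counts."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(gene) from None

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense per-cell counts for one gene."""
        return np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()

    def subset_cells(self, index) -> "CountMatrix":
        """New matrix restricted to the given barcode positions, order kept."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            self.genes,
            [self.barcodes[i] for i in index],
            self.counts[:, index],
        )

    def mito_mask(self, prefix: str = "MT-") -> np.ndarray:
        """Boolean gene mask for mitochondrial symbols (case-insensitive prefix)."""
        p = prefix.lower()
        return np.array([g.lower().startswith(p) for g in self.genes])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.barcodes == other.barcodes
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics).

    ``sets`` maps a unique set name to an ordered, de-duplicated gene list;
    every set is non-empty.
    """

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __eq__(self, other):
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and all(
            self.descriptions.get(k, "") == other.descriptions.get(k, "")
            for k in self.sets
        )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _read_identifier_column(path: Path) -> list:
    """First field of a TSV, or the second when a 10x-style multi-column
    features file (id, symbol, ...) is supplied."""
    rows = [line.rstrip("\n").split("\t") for line in path.read_text().splitlines() if line]
    if not rows:
        return []
    if len(rows[0]) >= 2:
        return [r[1] for r in rows]
    return [r[0] for r in rows]


def read_counts(path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from an mtx triplet directory or a dense CSV.

    Parameters
    ----------
    path
        Directory containing ``matrix.mtx`` + ``features.tsv`` (or
        ``genes.tsv``) + ``barcodes.tsv``, or a dense CSV file.
    format
        ``"mtx-triplet"`` or ``"dense-csv"``; inferred from *path* when
        omitted (directory -> triplet, file -> CSV).
    """
    path = Path(path)
    if format is None:
        format = "mtx-triplet" if path.is_dir() else "dense-csv"
    if format == "mtx-triplet":
        mtx = path / "matrix.mtx"
        feats = path / "features.tsv"
        if not feats.exists():
            feats = path / "genes.tsv"
        bcs = path / "barcodes.tsv"
        for p in (mtx, feats, bcs):
            if not p.exists():
                raise FormatError(f"missing triplet member: {p}")
        counts = sp.csr_matrix(scipy.io.mmread(mtx))
        genes = _read_identifier_column(feats)
        barcodes = [line.strip() for line in bcs.read_text().splitlines() if line.strip()]
        if counts.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"matrix declares {counts.shape} but feature/barcode lists have "
                f"{len(genes)} / {len(barcodes)} entries"
            )
        return CountMatrix(genes, barcodes, counts)
    if format == "dense-csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(
            [str(g) for g in df.index],
            [str(b) for b in df.columns],
            sp.csr_matrix(df.to_numpy()),
        )
    raise ValueError(f"unknown counts format {format!r}")


def write_counts(matrix: CountMatrix, path, format: str = "mtx-triplet") -> Path:
    """Write a CountMatrix in either supported format; returns the path."""
    path = Path(path)
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", matrix.counts.tocoo(), field="integer")
        (path / "features.tsv").write_text("".join(f"{g}\n" for g in matrix.genes))
        (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in matrix.barcodes))
        return path
    if format == "dense-csv":
        df = pd.DataFrame(
            matrix.counts.toarray(), index=matrix.genes, columns=matrix.barcodes
        )
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path)
        return path
    raise ValueError(f"unknown counts format {format!r}")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def validate_annotation(df: pd.DataFrame, barcodes=None) -> pd.DataFrame:
    """Validate an annotation table; returns it with string dtypes.

    Requires the columns barcode / cell_type / donor / cohort / compartment,
    one row per barcode, no empty labels.  When *barcodes* is given, every
    annotation barcode must be present in that collection.
    """
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"annotation is missing required column {col!r}")
    df = df.loc[:, list(ANNOTATION_COLUMNS)].astype(str)
    _check_unique(df["barcode"], "annotation barcodes")
    empty = df.isin(["", "nan", "None"]).any(axis=1)
    if empty.any():
        raise FormatError(
            f"empty label in annotation rows {np.flatnonzero(empty.to_numpy())[:5].tolist()}"
        )
    if barcodes is not None:
        missing = set(df["barcode"]) - set(barcodes)
        if missing:
            raise FormatError(
                f"annotation barcodes absent from count matrix: {sorted(missing)[:5]}"
            )
    return df.reset_index(drop=True)


def read_annotation(path, barcodes=None) -> pd.DataFrame:
    """Read and validate a per-cell annotation CSV."""
    return validate_annotation(pd.read_csv(path, dtype=str), barcodes=barcodes)


def write_annotation(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# ligand-receptor pairs and gene sets
# ---------------------------------------------------------------------------

def read_lr_pairs(path) -> pd.DataFrame:
    """Ligand-receptor panel CSV with columns ``ligand`` and ``receptor``.

    Self-pairs (ligand == receptor) are valid: homotypic receptors such as
    SLAMF7 bind themselves on other cells.  Duplicate rows are an error.
    """
    df = pd.read_csv(path, dtype=str)
    return validate_lr_pairs(df)


def validate_lr_pairs(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"LR table is missing required column {col!r}")
    df = df.loc[:, ["ligand", "receptor"]].astype(str)
    if df.duplicated().any():
        dup = df[df.duplicated()].head(5).to_records(index=False).tolist()
        raise FormatError(f"duplicate ligand-receptor rows: {dup}")
    if df.isin(["", "nan"]).any().any():
        raise FormatError("empty gene symbol in LR table")
    return df.reset_index(drop=True)


def write_lr_pairs(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, ["ligand", "receptor"]].to_csv(path, index=False)
    return path


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Gene lists are de-duplicated within a set, preserving first occurrence.
    """
    sets, descriptions = {}, {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"malformed GMT line {ln}: fewer than 3 fields")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise FormatError(f"duplicate gene-set name {name!r} (line {ln})")
        if not genes:
            raise FormatError(f"gene set {name!r} has no genes (line {ln})")
        sets[name] = list(dict.fromkeys(genes))
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# pipeline outputs
# ---------------------------------------------------------------------------

SCORE_COLUMNS = [
    "sender",
    "receiver",
    "ligand",
    "receptor",
    "mean_score",
    "frac_ligand",
    "frac_receptor",
    "p_value",
    "tested",
    "significant",
]


def _graph_to_edgelist(graph: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {
            "sender": u,
            "receiver": v,
            "weight": d["weight"],
            "interactions": d.get("interactions", ""),
        }
        for u, v, d in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["sender", "receiver", "weight", "interactions"])
    return df.sort_values(["sender", "receiver"]).reset_index(drop=True)


def write_outputs(
    scores: dict,
    graphs: dict,
    report,
    out_dir,
    enrichment: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> dict:
    """Write all pipeline artifacts under *out_dir*.

    Parameters
    ----------
    scores
        Mapping of partition label -> interaction score table.
    graphs
        Mapping of partition label -> directed interaction graph.
    report
        A :class:`~ccinet.network.DiffReport` or None.
    enrichment
        Optional enrichment result table.
    manifest
        Run parameters/seeds; written as JSON so a run is reproducible from
        its manifest alone.

    Returns a mapping of artifact name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    frames = []
    for label in sorted(scores):
        df = scores[label].copy()
        df.insert(0, "partition", label)
        frames.append(df)
    combined = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["partition", *SCORE_COLUMNS])
    )
    p = out_dir / "interactions.tsv"
    combined.to_csv(p, sep="\t", index=False)
    written["interactions"] = p

    for label in sorted(graphs):
        g = nx.DiGraph()
        g.add_nodes_from(graphs[label].nodes)
        for u, v, d in graphs[label].edges(data=True):
            pairs = d.get("pairs", [])
            g.add_edge(
                u, v, weight=int(d["weight"]),
                interactions=";".join(f"{l}:{r}" for l, r in pairs),
            )
        gp = out_dir / f"network_{label}.graphml"
        nx.write_graphml(g, gp)
        written[f"graph_{label}"] = gp
        ep = out_dir / f"network_{label}.edges.tsv"
        _graph_to_edgelist(g).to_csv(ep, sep="\t", index=False)
        written[f"edges_{label}"] = ep

    if report is not None:
        np_ = out_dir / "nodes_comparison.tsv"
        report.nodes.to_csv(np_, sep="\t", index=True, index_label="cell_type")
        written["nodes_comparison"] = np_
        ep_ = out_dir / "edges_comparison.tsv"
        report.edges.to_csv(ep_, sep="\t", index=False)
        written["edges_comparison"] = ep_

    if enrichment is not None:
        en = out_dir / "enrichment.tsv"
        enrichment.to_csv(en, sep="\t", index=False)
        written["enrichment"] = en

    if manifest is not None:
        mp = out_dir / "manifest.json"
        with open(mp, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written["manifest"] = mp

    return written
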