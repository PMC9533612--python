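"""End-to-end orchestration: QC -> compartment subset -> stratify ->
score both partitions -> compare -> enrich -> write outputs + manifest.

The manifest echoes every parameter (flagging assumed defaults of the
statistical scheme that the upstream study methods do not state), per-stage
cell and interaction counts, and a SHA-256 checksum of every written file;
two runs with equal manifests produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from . import io as _io
from .enrich import enrichment_report
from .network import build_network, compare_networks
from .qc import QCThresholds, apply_qc, stratify_by_marker, subset_compartment
from .scoring import ScoringParams, score_interactions

__all__ = ["RunConfig", "run_all"]

#: Scheme constants adopted from the permutation-CCI tools' published
#: defaults rather than stated by the study whose workflow this mirrors.
ASSUMED_DEFAULTS = (
    "n_permutations",
    "min_expressing_frac",
    "alpha",
    "normalization_scale",
    "min_cells_per_type",
)


@dataclass
class RunConfig:
    """Everything one run needs; loadable from a flat YAML file."""

    counts: str
    annotation: str
    lr_pairs: str
    out_dir: str
    gmt: str | None = None
    counts_format: str | None = None
    compartment: str = "CSF"
    marker_gene: str = "SLAMF7"
    min_marker_count: int = 1
    qc: QCThresholds = field(default_factory=QCThresholds)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    damping: float = 0.85
    correction: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_keys = {f.name for f in fields(QCThresholds)}
        sc_keys = {f.name for f in fields(ScoringParams)}
        top = {}
        qc_kw, sc_kw = {}, {}
        for key, val in raw.items():
            if key in qc_keys:
                qc_kw[key] = val
            elif key in sc_keys:
                sc_kw[key] = val
            else:
                top[key] = val
        return cls(qc=QCThresholds(**qc_kw), scoring=ScoringParams(**sc_kw), **top)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the populated output directory.

    Both partitions are scored with the same global seed through
    partition-tagged random streams, so adding or removing one partition
    never perturbs the other's permutations.
    """
    stages = {}

    counts = _io.read_counts(config.counts, format=config.counts_format)
    annotation = _io.read_annotation(config.annotation, barcodes=counts.barcodes)
    lr = _io.read_lr_pairs(config.lr_pairs)
    collection = _io.read_gmt(config.gmt) if config.gmt else None
    stages["input"] = {"cells": counts.n_cells, "genes": len(counts.genes),
                       "lr_pairs": len(lr)}

    counts, qc_report = apply_qc(counts, config.qc)
    annotation = annotation[annotation["barcode"].isin(counts.barcodes)]
    stages["qc"] = {
        "kept": qc_report.n_kept,
        "removed_low_total": qc_report.n_removed_low_total,
        "removed_high_total": qc_report.n_removed_high_total,
        "removed_mito": qc_report.n_removed_mito,
        "removed_total": qc_report.n_removed_total,
    }

    counts, annotation = subset_compartment(counts, annotation, config.compartment)
    stages["compartment"] = {"label": config.compartment, "cells": counts.n_cells}

    partition = stratify_by_marker(
        counts, config.marker_gene, config.min_marker_count
    )
    stages["stratify"] = {
        "marker_gene": config.marker_gene,
        "min_marker_count": config.min_marker_count,
        "positive_fraction": partition.positive_fraction,
        "n_positive": len(partition.barcodes("positive")),
        "n_negative": len(partition.barcodes("negative")),
    }

    scores, graphs = {}, {}
    for label in ("positive", "negative"):
        df = score_interactions(
            counts, annotation, lr, config.scoring,
            partition=partition, label=label,
        )
        scores[label] = df
        graphs[label] = build_network(df)
        stages[f"score_{label}"] = {
            "tested": int(df["tested"].sum()),
            "significant": int(df["significant"].sum()),
            "excluded_types": df.attrs.get("excluded_types", []),
        }

    report = compare_networks(
        graphs["positive"], graphs["negative"],
        damping=config.damping, correction=config.correction,
    )
    stages["compare"] = {
        "total_plus": report.total_plus,
        "total_minus": report.total_minus,
    }

    enrichment = None
    if collection is not None:
        background = set(lr["ligand"]) | set(lr["receptor"])
        enrichment = enrichment_report(
            report, scores["positive"], scores["negative"], collection, background
        )
        stages["enrich"] = {"gene_sets": len(collection)}

    manifest = {
        "software": {"name": "ccinet", "version": __version__},
        "config": config.to_dict(),
        "seed": config.scoring.seed,
        "assumed_defaults": {
            name: getattr(config.scoring, name) for name in ASSUMED_DEFAULTS
        },
        "stages": stages,
    }
    written = _io.write_outputs(
        scores, graphs, report, config.out_dir,
        enrichment=enrichment, manifest=None,
    )
    manifest["checksums"] = {
        name: _sha256(Path(p)) for name, p in sorted(written.items())
    }
    manifest_path = Path(config.out_dir) / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return Path(config.out_dir)
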