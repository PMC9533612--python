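import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ccinet.io import CountMatrix
from ccinet.simulate import SimConfig, generate_dataset


def annotate(barcodes, cell_types, donor="d1", cohort="HC", compartment="CSF"):
    """Minimal valid annotation table for the given barcodes."""
    n = len(barcodes)
    as_list = lambda v: list(v) if not isinstance(v, str) else [v] * n
    return pd.DataFrame(
        {
            "barcode": list(barcodes),
            "cell_type": list(cell_types),
            "donor": as_list(donor),
            "cohort": as_list(cohort),
            "compartment": as_list(compartment),
        }
    )


@pytest.fixture
def worked_example():
    """Two types x two cells each; normalized (scale 10) ligand values are
    (2, 0, 0, 0) and receptor values (0, 0, 2, 0), so the observed A->B
    score is 1 and the exact permutation p-value is 1/3."""
    counts = np.array(
        [
            [2, 0, 0, 0],   # L
            [0, 0, 2, 0],   # R
            [8, 10, 8, 10], # filler so every cell totals 10
        ]
    )
    cm = CountMatrix(["L", "R", "F"], ["c1", "c2", "c3", "c4"], sp.csr_matrix(counts))
    ann = annotate(cm.barcodes, ["A", "A", "B", "B"])
    lr = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
    return cm, ann, lr


@pytest.fixture(scope="session")
def small_dataset():
    """A QC-clean synthetic dataset shared by read-only tests."""
    cfg = SimConfig(seed=42, n_cell_types=4, cells_per_type=40, n_lr_pairs=12,
                    n_background_genes=80, marker_prevalence=0.3)
    return generate_dataset(cfg)
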