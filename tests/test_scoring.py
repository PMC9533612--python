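import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ccinet.io import CountMatrix
from ccinet.scoring import (
    ScoringParams,
    exact_permutation_p,
    normalize_counts,
    partition_rng,
    score_interactions,
)

from conftest import annotate


class TestNormalize:
    def test_values_sum_to_scale(self):
        cm = CountMatrix(["a", "b", "c"], ["c1"], sp.csr_matrix(np.array([[2], [3], [5]])))
        n = normalize_counts(cm, 10_000).toarray().ravel()
        assert n.tolist() == [2000.0, 3000.0, 5000.0]

    def test_single_gene_cell(self):
        cm = CountMatrix(["a"], ["c1"], sp.csr_matrix(np.array([[7]])))
        assert normalize_counts(cm, 10_000).toarray().ravel().tolist() == [10_000.0]

    def test_zero_total_cell_is_an_error(self):
        cm = CountMatrix(["a"], ["c1", "c2"], sp.csr_matrix(np.array([[1, 0]])))
        with pytest.raises(ValueError, match="zero-total"):
            normalize_counts(cm)


class TestExactOracle:
    def test_worked_four_cell_example_is_one_third(self, worked_example):
        cm, ann, _ = worked_example
        assert exact_permutation_p(cm, ann, ("L", "R"), "A", "B", scale=10) == Fraction(1, 3)

    def test_all_zero_expression_gives_one(self):
        counts = np.array([[0, 0, 0, 0], [0, 0, 0, 0], [5, 5, 5, 5]])
        cm = CountMatrix(["L", "R", "F"], [f"c{i}" for i in range(4)],
                         sp.csr_matrix(counts))
        ann = annotate(cm.barcodes, ["A", "A", "B", "B"])
        assert exact_permutation_p(cm, ann, ("L", "R"), "A", "B") == 1

    @pytest.mark.parametrize("n_sender", [2, 3])
    def test_all_mass_in_one_sender_cell_combinatorial(self, n_sender):
        """Six cells, ligand expressed in exactly one sender cell, receptor
        uniform: p = (# assignments placing that cell in the sender group)
        / C(6, n_s) = C(5, n_s - 1) / C(6, n_s) = n_s / 6."""
        n = 6
        lig = [0] * n
        lig[0] = 4
        counts = np.array([lig, [1] * n, [5] * n])
        cm = CountMatrix(["L", "R", "F"], [f"c{i}" for i in range(n)],
                         sp.csr_matrix(counts))
        types = ["A"] * n_sender + ["B"] * (n - n_sender)
        ann = annotate(cm.barcodes, types)
        p = exact_permutation_p(cm, ann, ("L", "R"), "A", "B")
        assert p == Fraction(n_sender, 6)

    def test_enumeration_bound_enforced(self):
        counts = np.ones((2, 13), dtype=int)
        cm = CountMatrix(["L", "R"], [f"c{i}" for i in range(13)],
                         sp.csr_matrix(counts))
        ann = annotate(cm.barcodes, ["A"] * 6 + ["B"] * 7)
        with pytest.raises(ValueError, match="enumeration bound"):
            exact_permutation_p(cm, ann, ("L", "R"), "A", "B")


class TestScoreInteractions:
    def params(self, **kw):
        kw.setdefault("min_cells_per_type", 2)
        kw.setdefault("normalization_scale", 10.0)
        return ScoringParams(**kw)

    def test_sampled_p_converges_to_exact(self, worked_example):
        cm, ann, lr = worked_example
        exact = float(exact_permutation_p(cm, ann, ("L", "R"), "A", "B", scale=10))
        n_perm = 10_000
        df = score_interactions(cm, ann, lr, self.params(n_permutations=n_perm, seed=3))
        row = df[(df.sender == "A") & (df.receiver == "B")].iloc[0]
        assert row.mean_score == pytest.approx(1.0)
        bound = 3 * math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(row.p_value - exact) <= bound

    def test_unexpressed_ligand_is_untested(self, worked_example):
        cm, ann, _ = worked_example
        lr = pd.DataFrame({"ligand": ["F"], "receptor": ["L"]})
        df = score_interactions(cm, ann, lr, self.params(n_permutations=50))
        # receptor L is absent from receiver B cells -> gated out
        row = df[(df.sender == "A") & (df.receiver == "B")].iloc[0]
        assert not row.tested and row.p_value == 1.0 and row.mean_score == 0.0
        assert not row.significant

    def test_identical_expression_gives_p_one(self):
        counts = np.tile([[3], [2], [5]], (1, 6))
        cm = CountMatrix(["L", "R", "F"], [f"c{i}" for i in range(6)],
                         sp.csr_matrix(counts))
        ann = annotate(cm.barcodes, ["A"] * 3 + ["B"] * 3)
        lr = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        df = score_interactions(cm, ann, lr, self.params(n_permutations=200))
        assert (df.p_value == 1.0).all()

    def test_cell_order_invariance(self, worked_example):
        cm, ann, lr = worked_example
        perm = [2, 0, 3, 1]
        cm2 = cm.subset_cells(perm)
        ann2 = ann.iloc[perm].reset_index(drop=True)
        a = score_interactions(cm, ann, lr, self.params(n_permutations=10, seed=0))
        b = score_interactions(cm2, ann2, lr, self.params(n_permutations=10, seed=0))
        key = ["sender", "receiver", "ligand", "receptor"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True)[key + ["mean_score"]],
            b.sort_values(key).reset_index(drop=True)[key + ["mean_score"]],
        )

    def test_p_values_never_zero(self, small_dataset):
        matrix, ann, lr, _ = small_dataset
        df = score_interactions(matrix, ann, lr, ScoringParams(n_permutations=20, seed=1))
        assert (df.p_value > 0).all() and (df.p_value <= 1).all()
        assert (df.loc[df.significant, "tested"]).all()
        assert (df.loc[df.significant, "p_value"] <= 0.05).all()

    def test_small_types_are_excluded_and_two_needed(self, worked_example):
        cm, ann, lr = worked_example
        with pytest.raises(ValueError, match="fewer than two"):
            score_interactions(cm, ann, lr, ScoringParams(min_cells_per_type=3))
        counts = np.array([[2, 0, 0, 0, 1], [0, 0, 2, 0, 1], [8, 10, 8, 10, 8]])
        cm5 = CountMatrix(["L", "R", "F"], [f"c{i}" for i in range(5)],
                          sp.csr_matrix(counts))
        ann5 = annotate(cm5.barcodes, ["A", "A", "B", "B", "C"])  # C below min 2
        df = score_interactions(cm5, ann5, lr, self.params(n_permutations=10))
        assert df.attrs["excluded_types"] == ["C"]
        assert set(df.sender) <= {"A", "B"}

    def test_includes_within_type_interactions(self, worked_example):
        cm, ann, lr = worked_example
        df = score_interactions(cm, ann, lr, self.params(n_permutations=10))
        assert ((df.sender == "A") & (df.receiver == "A")).any()

    def test_bh_option_adds_q_values(self, small_dataset):
        matrix, ann, lr, _ = small_dataset
        df = score_interactions(
            matrix, ann, lr, ScoringParams(n_permutations=50, seed=1, use_bh=True)
        )
        assert "q_value" in df.columns
        assert (df.loc[df.significant, "q_value"] <= 0.05).all()

    def test_partition_streams_are_tagged_and_deterministic(self):
        a = partition_rng(7, "positive").integers(0, 1000, 5)
        b = partition_rng(7, "positive").integers(0, 1000, 5)
        c = partition_rng(7, "negative").integers(0, 1000, 5)
        assert (a == b).all() and not (a == c).all()
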