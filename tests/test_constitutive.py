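"""Constitutive exon selection and gene expression indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rasa.constitutive import (
    ConstitutiveSelectionParams,
    exon_fold_changes,
    gene_expression_index,
    select_constitutive,
    trim_outliers,
)
from rasa.core import ConstitutivePartition, DabgMatrix, GenePartition
from rasa.preprocess import group_dabg
from tests.conftest import make_annotation, matrix_from
from tests.test_preprocess import reference_median_polish

SAMPLES = ["A1", "A2", "A3", "B1", "B2", "B3"]


def ten_exon_annot():
    return make_annotation(
        [(f"g:E{i:02d}", "g", "exon", i, None, None, 8) for i in range(1, 11)]
    )


def all_present(annot, design, threshold=0.01):
    dabg = DabgMatrix(
        p=pd.DataFrame(
            1e-6,
            index=annot.table["probeset_id"],
            columns=design.condition.index,
        )
    )
    return group_dabg(dabg, design, threshold)


class TestFoldChanges:
    def test_forced_and_identity_cases(self, six_sample_design):
        annot = make_annotation(
            [("g:E01", "g", "exon", 1, None, None, 8),
             ("g:E02", "g", "exon", 2, None, None, 8)]
        )
        m = matrix_from(
            {"g:E01": [10.0] * 3 + [12.0] * 3, "g:E02": [5.0] * 6}, SAMPLES
        )
        fc = exon_fold_changes(m, six_sample_design, annot)
        assert fc["g:E01"] == pytest.approx(2.0)
        assert fc["g:E02"] == pytest.approx(0.0)

    def test_arithmetic_mean_oracle(self, six_sample_design):
        annot = make_annotation([("g:E01", "g", "exon", 1, None, None, 8)])
        m = matrix_from({"g:E01": [8.1, 8.3, 8.0, 9.0, 9.4, 9.2]}, SAMPLES)
        fc = exon_fold_changes(m, six_sample_design, annot)
        expected = np.mean([9.0, 9.4, 9.2]) - np.mean([8.1, 8.3, 8.0])
        assert fc["g:E01"] == pytest.approx(expected, abs=1e-12)
        assert fc["g:E01"] == pytest.approx(1.0667, abs=5e-5)


class TestSelectConstitutive:
    def test_worked_ten_exon_example(self, six_sample_design):
        """One 3.0 outlier among nine 0.0 fold changes, d=2.

        Pass 1: m=0.3, s=0.9487, bounds [-1.597, 2.197] flag the outlier;
        pass 2 converges with m=0, s=0.
        """
        annot = ten_exon_annot()
        fcs = pd.Series([0.0] * 9 + [3.0], index=annot.table["probeset_id"])
        # hand-check the first-pass bounds
        m1, s1 = np.mean(fcs), np.std(fcs, ddof=1)
        assert (m1, s1) == (pytest.approx(0.3), pytest.approx(0.94868, abs=1e-5))
        assert m1 - 2 * s1 == pytest.approx(-1.597, abs=5e-4)
        assert m1 + 2 * s1 == pytest.approx(2.197, abs=5e-4)

        gp = select_constitutive(
            "g", fcs, all_present(annot, six_sample_design),
            ConstitutiveSelectionParams(d=2.0), annot,
        )
        assert len(gp.constitutive) == 9
        assert gp.outliers == ["g:E10"]
        assert gp.n_iterations == 2
        assert (gp.m, gp.s) == (0.0, 0.0)

    def test_identical_fold_changes_all_kept_one_pass(self, six_sample_design):
        annot = ten_exon_annot()
        fcs = pd.Series(1.3, index=annot.table["probeset_id"])
        gp = select_constitutive(
            "g", fcs, all_present(annot, six_sample_design),
            ConstitutiveSelectionParams(d=2.0), annot,
        )
        assert len(gp.constitutive) == 10
        assert gp.n_iterations == 1
        assert gp.s == pytest.approx(0.0, abs=1e-12)

    def test_undetected_exon_labeled_absent_regardless_of_fc(self, six_sample_design):
        annot = ten_exon_annot()
        presence = all_present(annot, six_sample_design)
        # group DABG 0.02 in condition B exceeds the 0.01 presence threshold
        presence.group_p.loc["g:E05", "B"] = 0.02
        fcs = pd.Series(0.0, index=annot.table["probeset_id"])
        gp = select_constitutive(
            "g", fcs, presence, ConstitutiveSelectionParams(), annot
        )
        assert gp.labels["g:E05"] == "absent"
        assert len(gp.constitutive) == 9

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=25),
           st.floats(1.0, 4.0))
    def test_termination_monotonicity_idempotence(self, fcs, d):
        arr = np.array(fcs)
        mask, m, s, n_iter = trim_outliers(arr, d)
        assert n_iter <= arr.size
        # at d >= 1 a pass can never flag every retained value (the sum of
        # squared deviations caps the number of points beyond d*s)
        assert mask.any()
        # idempotence: rerunning on the retained set flags nothing new
        mask2, _, _, n2 = trim_outliers(arr[mask], d)
        assert mask2.all()

    def test_noise_only_retention_rate(self):
        """At d=2 with pure N(0, 0.25) fold-change noise, >=90% of exons stay."""
        rng = np.random.default_rng(42)
        kept = total = 0
        for _ in range(500):
            fcs = rng.normal(0.0, 0.25, size=10)
            mask, *_ = trim_outliers(fcs, 2.0)
            kept += mask.sum()
            total += mask.size
        assert kept / total >= 0.90


class TestGeneExpressionIndex:
    def _partition(self, labels):
        gp = GenePartition(gene_id="g", labels=labels, m=0.0, s=0.0, n_iterations=1)
        return ConstitutivePartition(genes={"g": gp})

    def test_single_constitutive_exon_identity(self, six_sample_design):
        annot = make_annotation(
            [("g:E01", "g", "exon", 1, None, None, 8),
             ("g:E02", "g", "exon", 2, None, None, 8)]
        )
        m = matrix_from(
            {"g:E01": [8, 8, 8, 9, 9, 9.0], "g:E02": [1, 2, 3, 4, 5, 6.0]}, SAMPLES
        )
        part = self._partition({"g:E01": "constitutive", "g:E02": "outlier"})
        idx = gene_expression_index(m, part, annot)
        assert idx.values.loc["g"].tolist() == [8, 8, 8, 9, 9, 9.0]

    def test_equal_rows_identity(self, six_sample_design):
        annot = ten_exon_annot()
        v = [7.0, 7.5, 8.0, 9.0, 9.5, 10.0]
        m = matrix_from({p: v for p in annot.table["probeset_id"]}, SAMPLES)
        part = self._partition(dict.fromkeys(annot.table["probeset_id"], "constitutive"))
        idx = gene_expression_index(m, part, annot)
        assert np.allclose(idx.values.loc["g"], v)

    def test_matches_reference_median_polish(self):
        annot = make_annotation(
            [(f"g:E0{i}", "g", "exon", i, None, None, 8) for i in (1, 2, 3)]
        )
        rng = np.random.default_rng(9)
        block = rng.normal(8, 1, size=(3, 6))
        m = matrix_from(
            {f"g:E0{i+1}": block[i] for i in range(3)}, SAMPLES
        )
        part = self._partition(
            {f"g:E0{i}": "constitutive" for i in (1, 2, 3)}
        )
        idx = gene_expression_index(m, part, annot)
        assert np.allclose(idx.values.loc["g"], reference_median_polish(block), atol=1e-6)

    def test_no_constitutive_exons_falls_back_to_present(self, six_sample_design):
        annot = make_annotation(
            [("g:E01", "g", "exon", 1, None, None, 8),
             ("g:E02", "g", "exon", 2, None, None, 8)]
        )
        m = matrix_from(
            {"g:E01": [8.0] * 6, "g:E02": [9.0] * 6}, SAMPLES
        )
        part = self._partition({"g:E01": "outlier", "g:E02": "outlier"})
        presence = all_present(annot, six_sample_design)
        idx = gene_expression_index(m, part, annot, presence)
        assert "g" in idx.fallback_genes
        assert idx.has_gene("g")
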