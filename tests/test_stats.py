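"""Splicing indices, the ANOVA test and junction threshold adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

from rasa.core import GeneExpressionIndex, SampleDesign
from rasa import stats as rasa_stats
from rasa.stats import adjust_junction_threshold, midas_test, one_way_anova, splicing_index
from tests.conftest import make_annotation, matrix_from

SAMPLES = ["A1", "A2", "A3", "B1", "B2", "B3"]


def gene_index(values_by_gene):
    return GeneExpressionIndex(
        values=pd.DataFrame(values_by_gene, index=SAMPLES).T, source_exons={}
    )


class TestSplicingIndex:
    @pytest.mark.parametrize(
        "exon_shift,gene_shift,expected",
        [(3.0, 1.0, 2.0), (1.0, 1.0, 0.0), (-0.5, 1.2, -1.7)],
    )
    def test_si_is_probeset_fc_minus_gene_fc(
        self, six_sample_design, exon_shift, gene_shift, expected
    ):
        annot = make_annotation([("g:E01", "g", "exon", 1, None, None, 8)])
        m = matrix_from({"g:E01": [8.0] * 3 + [8.0 + exon_shift] * 3}, SAMPLES)
        gidx = gene_index({"g": [8.0] * 3 + [8.0 + gene_shift] * 3})
        si = splicing_index(m, gidx, six_sample_design, annot)
        assert si.loc["g:E01", "si"] == pytest.approx(expected)
        assert si.loc["g:E01", "direction"] == np.sign(expected)

    def test_missing_gene_index_marks_untestable(self, six_sample_design):
        annot = make_annotation([("g:E01", "g", "exon", 1, None, None, 8)])
        m = matrix_from({"g:E01": [8.0] * 6}, SAMPLES)
        si = splicing_index(m, gene_index({}), six_sample_design, annot)
        assert not si.loc["g:E01", "testable"]


class TestMidasTest:
    def test_equal_group_means_give_p_one(self, six_sample_design):
        nv = pd.Series([1.0, 2.0, 3.0, 3.0, 2.0, 1.0], index=SAMPLES)
        zero = pd.Series(0.0, index=SAMPLES)
        assert midas_test(nv, zero, six_sample_design) == pytest.approx(1.0)

    def test_matches_scipy_anova(self, six_sample_design):
        nv = pd.Series([1.0, 1.2, 1.1, 2.0, 2.1, 1.9], index=SAMPLES)
        zero = pd.Series(0.0, index=SAMPLES)
        expected = sp_stats.f_oneway([1.0, 1.2, 1.1], [2.0, 2.1, 1.9]).pvalue
        assert midas_test(nv, zero, six_sample_design) == pytest.approx(
            expected, abs=1e-10
        )

    def test_single_replicate_untestable(self):
        design = SampleDesign(condition=pd.Series(["A", "B"], index=["A1", "B1"]))
        nv = pd.Series([1.0, 2.0], index=["A1", "B1"])
        assert midas_test(nv, nv * 0, design) is None

    def test_zero_variance_degenerate_cases(self):
        assert one_way_anova([1.0, 1.0], [1.0, 1.0]) == 1.0
        assert one_way_anova([1.0, 1.0], [2.0, 2.0]) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-100, 100))
    def test_invariant_to_common_shift(self, shift):
        design = SampleDesign(
            condition=pd.Series(["A"] * 3 + ["B"] * 3, index=SAMPLES)
        )
        rng = np.random.default_rng(5)
        probeset = pd.Series(rng.normal(8, 1, 6), index=SAMPLES)
        gene = pd.Series(rng.normal(8, 1, 6), index=SAMPLES)
        p0 = midas_test(probeset, gene, design)
        p1 = midas_test(probeset + shift, gene + shift, design)
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_null_pvalues_uniform(self, six_sample_design):
        """Exchangeable conditions: the p<=0.05 rate matches 0.05."""
        rng = np.random.default_rng(11)
        n = 2000
        hits = 0
        for _ in range(n):
            nv = pd.Series(rng.normal(0, 1, 6), index=SAMPLES)
            gene = pd.Series(rng.normal(0, 1, 6), index=SAMPLES)
            if midas_test(nv, gene, six_sample_design) <= 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(hits / n - 0.05) <= 3 * se

    def test_vectorized_path_matches_scalar(self, six_sample_design):
        """test_all's batched ANOVA equals per-probeset midas_test."""
        annot = make_annotation(
            [(f"g:E{i:02d}", "g", "exon", i, None, None, 8) for i in range(1, 6)]
        )
        rng = np.random.default_rng(21)
        m = matrix_from(
            {f"g:E{i:02d}": rng.normal(8, 1, 6) for i in range(1, 6)}, SAMPLES
        )
        gidx = gene_index({"g": rng.normal(8, 1, 6)})
        stats = rasa_stats.test_all(m, gidx, six_sample_design, annot)
        for pid in m.values.index:
            expected = midas_test(
                m.values.loc[pid], gidx.values.loc["g"], six_sample_design
            )
            assert stats.loc[pid, "p_value"] == pytest.approx(expected, abs=1e-12)


class TestThresholdAdjustment:
    def test_worked_example(self):
        adj = adjust_junction_threshold(
            [0.001, 0.005, 0.02, 0.2, 0.5, 0.9],
            [0.002, 0.03, 0.04, 0.3, 0.6, 0.8],
            p=0.01,
        )
        assert adj.f == pytest.approx(2 / 6)
        assert adj.p_prime == pytest.approx(0.03)

    def test_identical_lists_pass_same_count(self):
        ps = [0.001, 0.004, 0.02, 0.3, 0.7]
        adj = adjust_junction_threshold(ps, ps, p=0.01)
        assert sum(x <= adj.p_prime for x in ps) == sum(x <= 0.01 for x in ps)

    def test_threshold_below_all_exons(self):
        adj = adjust_junction_threshold([0.1, 0.2], [0.05, 0.5], p=0.01)
        assert adj.f == 0.0
        assert adj.p_prime == 0.0
        assert sum(x <= adj.p_prime for x in [0.05, 0.5]) == 0

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40),
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40),
        st.floats(0.0, 1.0),
    )
    def test_pass_fraction_contract(self, exon_ps, junc_ps, p):
        """Junction pass-fraction is exactly ceil(f*N)/N; monotone in p."""
        adj = adjust_junction_threshold(exon_ps, junc_ps, p)
        n_pass_exon = sum(x <= p for x in exon_ps)
        f = n_pass_exon / len(exon_ps)
        k = -((-n_pass_exon * len(junc_ps)) // len(exon_ps))
        n_pass_junc = sum(x <= adj.p_prime for x in junc_ps)
        # ties can only raise the count, never lower it below k
        assert n_pass_junc >= k
        assert sorted(junc_ps)[: max(k, 1)][-1] >= adj.p_prime
        assert k / len(junc_ps) >= f - 1e-12

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        exon_ps = rng.uniform(0, 1, 200)
        junc_ps = rng.uniform(0, 1, 150)
        primes = [
            adjust_junction_threshold(exon_ps, junc_ps, p).p_prime
            for p in (0.001, 0.01, 0.05, 0.2, 0.9)
        ]
        assert primes == sorted(primes)

    def test_junction_rich_low_tail_shrinks_threshold(self):
        """When the low tail of junction p-values is denser than the exon
        tail (every skipping event touches several junctions but one
        exon), the matched-quantile junction threshold drops below p."""
        rng = np.random.default_rng(8)
        exon_ps = np.concatenate(
            [rng.uniform(0, 1e-3, 80), rng.uniform(0, 1, 1920)]
        )
        junc_ps = np.concatenate(
            [rng.uniform(0, 1e-3, 240), rng.uniform(0, 1, 1640)]
        )
        adj = adjust_junction_threshold(exon_ps, junc_ps, p=0.01)
        assert adj.p_prime < 0.01
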