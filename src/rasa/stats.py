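"""Splicing indices, MIDAS-style significance tests and the junction
threshold adjustment.

The splicing index of a probeset is its between-condition log2 fold
change minus its gene's: a nonzero value means the exon (or junction)
changed relative to the gene, i.e. candidate differential splicing.
Significance is a one-way ANOVA on the gene-normalized per-sample
values — the MIDAS construction; the test function is pluggable so a
rank-based or probe-level alternative can be substituted.

Junction probesets carry fewer, less optimized probes than exon
probesets, so their p-values are systematically larger. The exon
threshold ``p`` is therefore mapped onto the junction scale through the
empirical quantile functions of the two p-value populations:
``p' = Q_junc^{-1}(Q_exon(p))``, so the same top fraction of junctions
passes as of exons.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from rasa.core import (
    DesignAnnotation,
    ExpressionMatrix,
    GeneExpressionIndex,
    ThresholdAdjustment,
    ValidationError,
)
from rasa.constitutive import fold_changes

TestFunction = Callable[[np.ndarray, np.ndarray], float]


def splicing_index(
    probeset_idx: ExpressionMatrix,
    gene_idx: GeneExpressionIndex,
    design,
    annot: DesignAnnotation,
) -> pd.DataFrame:
    """Splicing index per probeset: probeset fold change minus gene fold change.

    Returns a frame indexed by probeset_id with columns ``si``,
    ``direction`` (sign of si) and ``testable`` (False when the gene has
    no expression index). Untestable probesets get NaN si.
    """
    probeset_fc = fold_changes(probeset_idx, design)
    gene_fc = (
        fold_changes(gene_idx.values, design)
        if len(gene_idx.values)
        else pd.Series(dtype=float)
    )
    gene_of = annot.table.set_index("probeset_id")["gene_id"]
    genes = gene_of.reindex(probeset_fc.index)
    aligned_gene_fc = gene_fc.reindex(genes).to_numpy()
    si = probeset_fc.to_numpy() - aligned_gene_fc
    out = pd.DataFrame(
        {
            "si": si,
            "direction": np.where(np.isnan(si), 0, np.sign(np.nan_to_num(si))).astype(int),
            "testable": ~np.isnan(si),
        },
        index=probeset_fc.index,
    )
    out.index.name = "probeset_id"
    return out


def one_way_anova(a: np.ndarray, b: np.ndarray) -> float:
    """F-test p-value comparing the means of two groups.

    Degenerate inputs are resolved explicitly: zero variance everywhere
    with equal means gives p = 1; zero within-group variance with
    different means gives p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    grand = np.concatenate([a, b]).mean()
    ss_between = n1 * (a.mean() - grand) ** 2 + n2 * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df_between, df_within = 1, n1 + n2 - 2
    if ss_within <= 0:
        return 1.0 if ss_between <= 0 else 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    return float(sp_stats.f.sf(f, df_between, df_within))


def midas_test(
    probeset_values: pd.Series,
    gene_values: pd.Series,
    design,
    test: TestFunction = one_way_anova,
) -> float | None:
    """MIDAS-style test: ANOVA across conditions on gene-normalized values.

    ``probeset_values`` and ``gene_values`` are per-sample log2 indices;
    the test runs on their difference, so any shift common to probeset
    and gene cancels. Returns None (untestable) with fewer than two
    replicates in either condition.
    """
    nv = probeset_values - gene_values
    cond_a, cond_b = design.conditions
    a = nv.loc[[s for s in design.samples_in(cond_a) if s in nv.index]]
    b = nv.loc[[s for s in design.samples_in(cond_b) if s in nv.index]]
    if len(a) < 2 or len(b) < 2:
        return None
    return test(a.to_numpy(), b.to_numpy())


def test_all(
    probeset_idx: ExpressionMatrix,
    gene_idx: GeneExpressionIndex,
    design,
    annot: DesignAnnotation,
    test: TestFunction = one_way_anova,
) -> pd.DataFrame:
    """Splicing index and p-value for every annotated probeset.

    Returns a frame indexed by probeset_id with columns ``gene_id``,
    ``kind``, ``si``, ``direction``, ``p_value``, ``testable``.
    """
    si = splicing_index(probeset_idx, gene_idx, design, annot)
    meta = annot.table.set_index("probeset_id")[["gene_id", "kind"]]
    out = si.join(meta, how="left")

    if test is one_way_anova:
        out["p_value"] = _anova_all(probeset_idx, gene_idx, design, out)
    else:
        p_values = {}
        for pid in probeset_idx.values.index:
            if not out.loc[pid, "testable"]:
                p_values[pid] = np.nan
                continue
            gene = out.loc[pid, "gene_id"]
            p = midas_test(
                probeset_idx.values.loc[pid],
                gene_idx.values.loc[gene],
                design,
                test=test,
            )
            p_values[pid] = np.nan if p is None else p
        out["p_value"] = pd.Series(p_values)

    out["testable"] = out["testable"] & out["p_value"].notna()
    return out[["gene_id", "kind", "si", "direction", "p_value", "testable"]]


def _anova_all(
    probeset_idx: ExpressionMatrix,
    gene_idx: GeneExpressionIndex,
    design,
    meta: pd.DataFrame,
) -> pd.Series:
    """Vectorized one-way ANOVA over every testable probeset at once.

    Numerically identical to :func:`one_way_anova` row by row.
    """
    values = probeset_idx.values
    testable = meta["testable"].to_numpy()
    genes = meta["gene_id"].where(meta["testable"], None)
    gene_rows = np.full(values.shape, np.nan)
    ok = testable & genes.notna().to_numpy()
    if ok.any():
        gene_rows[ok] = gene_idx.values.loc[genes[ok]].to_numpy()
    nv = values.to_numpy(dtype=float) - gene_rows

    cond_a, cond_b = design.conditions
    ia = [values.columns.get_loc(s) for s in design.samples_in(cond_a) if s in values.columns]
    ib = [values.columns.get_loc(s) for s in design.samples_in(cond_b) if s in values.columns]
    n1, n2 = len(ia), len(ib)
    if n1 < 2 or n2 < 2:
        return pd.Series(np.nan, index=values.index)

    a, b = nv[:, ia], nv[:, ib]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    grand = (n1 * ma + n2 * mb) / (n1 + n2)
    ss_between = n1 * (ma - grand) ** 2 + n2 * (mb - grand) ** 2
    ss_within = ((a - ma[:, None]) ** 2).sum(axis=1) + ((b - mb[:, None]) ** 2).sum(axis=1)
    df_within = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / (ss_within / df_within)
        p = sp_stats.f.sf(f, 1, df_within)
    degenerate = ss_within <= 0
    p[degenerate] = np.where(ss_between[degenerate] <= 0, 1.0, 0.0)
    p[~ok] = np.nan
    return pd.Series(p, index=values.index)


def adjust_junction_threshold(
    exon_pvalues, junction_pvalues, p: float
) -> ThresholdAdjustment:
    """Map the exon threshold ``p`` onto the junction p-value scale.

    ``f = Q_exon(p)`` is the fraction of exon p-values at or below
    ``p``; the adjusted threshold ``p'`` is the smallest junction
    p-value such that the junction pass-fraction reaches ``f``: with
    ``k = ceil(f * N_junc)``, ``p'`` is the k-th smallest junction
    p-value (0 when ``k = 0``). The junction pass-fraction is then
    exactly ``k / N_junc``, assuming no ties at ``p'``.
    """
    exon_p = np.sort(np.asarray(list(exon_pvalues), dtype=float))
    junc_p = np.sort(np.asarray(list(junction_pvalues), dtype=float))
    if exon_p.size == 0 or junc_p.size == 0:
        raise ValidationError("threshold adjustment needs nonempty p-value lists")
    n_pass = int(np.searchsorted(exon_p, p, side="right"))
    f = n_pass / exon_p.size
    # k = ceil(f * N_junc) in exact integer arithmetic (f = n_pass / N_exon)
    k = -((-n_pass * junc_p.size) // exon_p.size)
    p_prime = 0.0 if k == 0 else float(junc_p[k - 1])
    return ThresholdAdjustment(p=float(p), p_prime=p_prime, f=float(f))
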