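"""Step 1: putatively constitutive exon selection and gene expression.

A gene's expression index should reflect the shared abundance of its
isoforms, not the exons whose inclusion differs between conditions.
Rather than relying on transcript annotation (which leaves many genes
with no annotated constitutive exon), constitutive exons are selected
from the data itself:

1. exons undetected (group DABG above threshold) in either condition are
   set aside as *absent*;
2. among the rest, exons whose between-condition fold change falls
   strictly outside ``[m - d*s, m + d*s]`` — where ``m`` and ``s`` are
   the mean and sample standard deviation of the currently retained
   exons' fold changes — are flagged as *outliers*; ``m`` and ``s`` are
   recomputed over the survivors and the trimming repeats until no new
   exon is flagged. Removal is monotone: a flagged exon is never
   re-admitted, which guarantees termination within one pass per exon.

The gene index is then a median polish over the constitutive exons'
signal (pooled probes at probe level, or the exon index rows at
probeset level). Genes with no constitutive exon fall back to all
present exons and are flagged; genes with no present exon are excluded
from testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rasa.core import (
    ConstitutivePartition,
    ConstitutiveSelectionParams,
    DesignAnnotation,
    ExpressionMatrix,
    GeneExpressionIndex,
    GenePartition,
    PresenceCalls,
    ValidationError,
)
from rasa.preprocess import median_polish_summarize, probe_probeset_ids


def fold_changes(
    matrix: ExpressionMatrix | pd.DataFrame, design
) -> pd.Series:
    """Log2 fold change per row: mean(second condition) - mean(first).

    Condition order is the design's ``condition_order`` (lexicographic
    unless overridden).
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    cond_a, cond_b = design.conditions
    samples_a = [s for s in design.samples_in(cond_a) if s in values.columns]
    samples_b = [s for s in design.samples_in(cond_b) if s in values.columns]
    if not samples_a or not samples_b:
        raise ValidationError("each condition needs at least one sample")
    return values[samples_b].mean(axis=1) - values[samples_a].mean(axis=1)


def exon_fold_changes(
    exon_idx: ExpressionMatrix, design, annot: DesignAnnotation
) -> pd.Series:
    """Fold changes restricted to the annotation's exon probesets."""
    fc = fold_changes(exon_idx, design)
    exon_ids = [p for p in annot.exon_table["probeset_id"] if p in fc.index]
    return fc.loc[exon_ids]


def trim_outliers(
    fcs: np.ndarray, d: float, max_iterations: int | None = None
) -> tuple[np.ndarray, float, float, int]:
    """Iterative mean+/-d*sd trimming of a fold-change vector.

    Returns ``(retained_mask, m, s, n_iterations)``. Each pass computes
    ``m`` and ``s`` (sample sd, 0 with a single value) over the retained
    values and drops those strictly outside ``[m - d*s, m + d*s]``;
    dropped values are never re-admitted, so the loop terminates within
    one pass per value. The boundary is inclusive, so an all-equal
    vector (``s = 0``) is fully retained.
    """
    fcs = np.asarray(fcs, dtype=float)
    retained = np.ones(fcs.size, dtype=bool)
    max_iter = max_iterations or max(fcs.size, 1)
    m = float("nan")
    s = float("nan")
    n_iter = 0
    for _ in range(max_iter):
        if not retained.any():
            break
        n_iter += 1
        vals = fcs[retained]
        m = float(vals.mean())
        s = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        outside = retained & ((fcs < m - d * s) | (fcs > m + d * s))
        if not outside.any():
            break
        if outside.sum() == retained.sum():
            # only reachable when s underflows to 0 on near-identical
            # values; flagging everything is meaningless, so stop
            break
        retained &= ~outside
    return retained, m, s, n_iter


def select_constitutive(
    gene_id: str,
    fcs: pd.Series,
    presence: PresenceCalls,
    params: ConstitutiveSelectionParams,
    annot: DesignAnnotation,
) -> GenePartition:
    """Iteratively trim a gene's exons down to a putatively constitutive set.

    ``fcs`` maps the gene's exon probesets to their log2 fold changes.
    The interval boundary is inclusive: an exon exactly at ``m +/- d*s``
    is kept, so a gene whose exons all share one fold change (``s = 0``)
    keeps every exon.
    """
    exon_ids = annot.exons_of(gene_id)["probeset_id"].tolist()
    if not exon_ids:
        raise ValidationError(f"gene {gene_id!r} has no exons in the annotation")

    labels: dict[str, str] = {}
    retained: list[str] = []
    for pid in exon_ids:
        present_everywhere = all(
            presence.group_p.loc[pid, c] <= params.presence_threshold
            for c in presence.group_p.columns
        )
        if present_everywhere:
            retained.append(pid)
        else:
            labels[pid] = "absent"

    mask, m, s, n_iter = trim_outliers(
        fcs.loc[retained].to_numpy(dtype=float),
        params.d,
        params.max_iterations or len(exon_ids),
    )
    for pid, kept in zip(retained, mask):
        labels[pid] = "constitutive" if kept else "outlier"
    retained = [pid for pid, kept in zip(retained, mask) if kept]
    fallback = len(retained) < params.min_constitutive
    return GenePartition(
        gene_id=gene_id,
        labels={pid: labels[pid] for pid in exon_ids},
        m=m,
        s=s,
        n_iterations=n_iter,
        fallback=fallback,
    )


def select_all(
    exon_idx: ExpressionMatrix,
    presence: PresenceCalls,
    design,
    annot: DesignAnnotation,
    params: ConstitutiveSelectionParams | None = None,
) -> ConstitutivePartition:
    """Run constitutive selection for every gene in the annotation."""
    params = params or ConstitutiveSelectionParams()
    fcs = exon_fold_changes(exon_idx, design, annot)
    out = ConstitutivePartition()
    for gene_id in annot.genes:
        out.genes[gene_id] = select_constitutive(
            gene_id, fcs, presence, params, annot
        )
    return out


def _gene_source_exons(
    gp: GenePartition, presence: PresenceCalls, threshold: float
) -> tuple[list[str], bool]:
    """Constitutive exons, or all present exons as fallback."""
    if gp.constitutive:
        return gp.constitutive, False
    present = [
        pid
        for pid in gp.labels
        if all(presence.group_p.loc[pid, c] <= threshold for c in presence.group_p.columns)
    ]
    if present:
        return present, True
    # last resort: exons present in at least one condition
    partial = [
        pid
        for pid in gp.labels
        if any(presence.group_p.loc[pid, c] <= threshold for c in presence.group_p.columns)
    ]
    return partial, True


def gene_expression_index(
    matrix: ExpressionMatrix,
    partition: ConstitutivePartition,
    annot: DesignAnnotation,
    presence: PresenceCalls | None = None,
    params: ConstitutiveSelectionParams | None = None,
) -> GeneExpressionIndex:
    """Median-polish gene indices from each gene's constitutive exons.

    Accepts the probe-level matrix (pooled probes of the constitutive
    exons are polished together) or the probeset-level matrix (the
    constitutive exon index rows are polished). Genes without any
    detectable exon are excluded.
    """
    params = params or ConstitutiveSelectionParams()
    values = matrix.values
    if matrix.row_kind == "probe":
        row_groups = probe_probeset_ids(values.index)
    else:
        row_groups = pd.Series(values.index, index=values.index)

    gene_rows: dict[str, pd.Series] = {}
    source: dict[str, list[str]] = {}
    fallback_genes: set[str] = set()
    excluded: set[str] = set()
    for gp in partition:
        if presence is not None:
            exons, fellback = _gene_source_exons(gp, presence, params.presence_threshold)
        else:
            exons, fellback = gp.constitutive, False
        if not exons:
            excluded.add(gp.gene_id)
            continue
        rows = values.loc[row_groups.isin(exons).to_numpy()]
        if rows.empty:
            excluded.add(gp.gene_id)
            continue
        gene_rows[gp.gene_id] = median_polish_summarize(rows)
        source[gp.gene_id] = sorted(exons)
        if fellback:
            fallback_genes.add(gp.gene_id)

    idx = pd.DataFrame(gene_rows).T.reindex(columns=values.columns)
    idx = idx.sort_index()
    idx.index.name = "gene_id"
    return GeneExpressionIndex(
        values=idx,
        source_exons=source,
        fallback_genes=fallback_genes,
        excluded_genes=excluded,
    )
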