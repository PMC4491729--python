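"""Steps 2 and 3: junction-supported calling, unreliable-junction
recovery, final classification and end-to-end orchestration.

Step 2 requires a significant exon to have at least one significant
junction moving with it: an inclusion junction in the same direction, or
an exclusion junction in the opposite direction. Junction significance
uses the adjusted threshold ``p'`` (see :mod:`rasa.stats`).

Step 3 rescues significant exons whose junction probesets failed. For
each such exon the *best junction* is the one with the largest splicing
index in the exon's direction (absent any, the junction change is
truncated to 0), and the difference ``|si_exon| - |si_best|`` is
compared against an empirical null built from the junction-supported
exons of step 2 — the distribution of that difference when junctions
work. Exons whose difference exceeds the null's top-``q`` quantile are
declared to have unreliable junctions and kept as candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from rasa import io as rasa_io
from rasa.constitutive import ConstitutiveSelectionParams, gene_expression_index, select_all
from rasa.core import (
    DesignAnnotation,
    ExpressionMatrix,
    GeneExpressionIndex,
    NullThresholdParams,
    PresenceCalls,
    SplicingCallSet,
    ThresholdAdjustment,
    ValidationError,
)
from rasa.preprocess import group_dabg, median_scale_normalize, summarize_probesets
from rasa.stats import adjust_junction_threshold, test_all

logger = logging.getLogger("rasa")

MIN_NULL_SIZE = 20  # smallest empirical null accepted before step 3 activates


def exon_junction_relations(annot: DesignAnnotation) -> dict[str, dict[str, str]]:
    """Map each exon probeset to its junctions and their relation.

    Returns ``{exon probeset_id: {junction probeset_id: "inclusion" |
    "exclusion"}}``, computed once for the whole annotation.
    """
    exon_pid: dict[tuple[str, int], str] = {}
    exons_by_gene: dict[str, list[int]] = {}
    for row in annot.exon_table.itertuples():
        e = int(row.exon_index)
        exon_pid[(row.gene_id, e)] = row.probeset_id
        exons_by_gene.setdefault(row.gene_id, []).append(e)
    rel: dict[str, dict[str, str]] = {pid: {} for pid in exon_pid.values()}
    for row in annot.junction_table.itertuples():
        e5, e3 = int(row.exon5), int(row.exon3)
        for e in exons_by_gene.get(row.gene_id, ()):
            if e == e5 or e == e3:
                rel[exon_pid[(row.gene_id, e)]][row.probeset_id] = "inclusion"
            elif e5 < e < e3:
                rel[exon_pid[(row.gene_id, e)]][row.probeset_id] = "exclusion"
    return rel


def _support_for(
    exon_sign: int,
    relations: dict[str, str],
    p_value: dict[str, float],
    direction: dict[str, int],
    testable: dict[str, bool],
    p_prime: float,
) -> tuple[list[str], list[str]]:
    supporting: list[str] = []
    types: list[str] = []
    if exon_sign == 0:
        return supporting, types
    for jid in sorted(relations):
        if not testable.get(jid, False) or not (p_value[jid] <= p_prime):
            continue
        jsign = direction[jid]
        if jsign == 0:
            continue
        relation = relations[jid]
        if (relation == "inclusion" and jsign == exon_sign) or (
            relation == "exclusion" and jsign == -exon_sign
        ):
            supporting.append(jid)
            types.append(relation)
    return supporting, types


def find_supporting_junctions(
    exon_id: str,
    stats: pd.DataFrame,
    p: float,
    p_prime: float,
    annot: DesignAnnotation,
) -> tuple[list[str], list[str]]:
    """Significant junctions that move with a significant exon.

    Returns ``(junction_ids, support_types)`` where each type is
    "inclusion" (same direction as the exon) or "exclusion" (opposite
    direction). A probeset with splicing index exactly 0 has no
    direction and can neither support nor be supported.
    """
    row = stats.loc[exon_id]
    relations = annot.junctions_for_exon(row["gene_id"], _exon_index(annot, exon_id))
    return _support_for(
        int(row["direction"]),
        relations,
        stats["p_value"].to_dict(),
        {k: int(v) for k, v in stats["direction"].to_dict().items()},
        stats["testable"].to_dict(),
        p_prime,
    )


def best_junction_difference(
    exon_si: float, junction_sis: list[tuple[str, float]]
) -> tuple[str | None, float]:
    """Exon-vs-best-junction fold-change difference on the log scale.

    The best junction has the largest magnitude among those changing in
    the exon's direction; without one, its change is truncated to 0 and
    the difference equals ``|exon_si|``. A negative difference means the
    best junction moved more than the exon.
    """
    sign = np.sign(exon_si)
    same_dir = [(jid, s) for jid, s in junction_sis if np.sign(s) == sign and s != 0]
    if sign == 0 or not same_dir:
        return None, abs(float(exon_si))
    best_id, best_si = max(same_dir, key=lambda t: (abs(t[1]), t[0]))
    return best_id, abs(float(exon_si)) - abs(float(best_si))


def estimate_null_threshold(
    supported_exon_diffs, q: float = 0.05, min_null_size: int = MIN_NULL_SIZE
) -> NullThresholdParams | None:
    """Top-``q`` quantile of the supported-exon difference distribution.

    The cutoff is the k-th smallest difference with ``k = ceil((1-q)*N)``
    so exactly the top ``q`` fraction of the null lies strictly above it
    (up to ties). Returns None — step 3 disabled — when fewer than
    ``min_null_size`` supported exons are available.
    """
    diffs = np.sort(np.asarray(list(supported_exon_diffs), dtype=float))
    n = diffs.size
    if n < min_null_size:
        logger.warning(
            "unreliable-junction step disabled: null size %d < %d", n, min_null_size
        )
        return None
    k = int(np.ceil((1.0 - q) * n - 1e-12))
    k = max(k, 1)
    return NullThresholdParams(q=q, cutoff=float(diffs[k - 1]), null_diffs=tuple(diffs))


def _exon_index(annot: DesignAnnotation, exon_id: str) -> int:
    row = annot.table.loc[annot.table["probeset_id"] == exon_id].iloc[0]
    return int(row["exon_index"])


def classify_exons(
    stats: pd.DataFrame,
    presence: PresenceCalls,
    annot: DesignAnnotation,
    p: float = 0.01,
    q: float = 0.05,
    min_null_size: int = MIN_NULL_SIZE,
) -> tuple[SplicingCallSet, ThresholdAdjustment, NullThresholdParams | None]:
    """Assign every exon probeset its final category.

    Categories: ``absent`` (undetected in both conditions),
    ``not_significant``, ``junction_supported`` (step 2),
    ``unreliable_junction_candidate`` (step 3), and
    ``exon_only_not_called`` (significant but unsupported and within the
    null). Exons present in only one condition are still testable and
    carry ``presence_flag=True``.
    """
    exon_stats = stats[stats["kind"] == "exon"]
    junc_stats = stats[stats["kind"] == "junction"]

    exon_ps = exon_stats.loc[exon_stats["testable"], "p_value"]
    junc_ps = junc_stats.loc[junc_stats["testable"], "p_value"]
    if len(junc_ps):
        adj = adjust_junction_threshold(exon_ps, junc_ps, p)
    else:
        adj = ThresholdAdjustment(p=p, p_prime=0.0, f=0.0)

    present = presence.present
    present_any = present.any(axis=1).to_dict()
    present_all = present.all(axis=1).to_dict()
    rows: list[dict[str, Any]] = []
    significant_unsupported: list[dict[str, Any]] = []
    null_diffs: list[float] = []

    relations = exon_junction_relations(annot)
    exon_index_of = (
        annot.exon_table.set_index("probeset_id")["exon_index"].astype(int).to_dict()
    )
    j_p = stats["p_value"].to_dict()
    j_si = stats["si"].to_dict()
    j_dir = {k: int(v) for k, v in stats["direction"].to_dict().items()}
    j_testable = stats["testable"].to_dict()

    for pid, row in exon_stats.iterrows():
        gene = row["gene_id"]
        e_index = exon_index_of[pid]
        base = {
            "gene_id": gene,
            "probeset_id": pid,
            "exon_index": e_index,
            "p_value": row["p_value"],
            "si": row["si"],
            "supporting_junctions": [],
            "support_types": [],
            "best_junction_id": None,
            "fc_difference": float("nan"),
            "presence_flag": False,
        }
        if pid in present_any:
            if not present_any[pid]:
                rows.append({**base, "category": "absent"})
                continue
            base["presence_flag"] = not present_all[pid]
        if not row["testable"] or not (row["p_value"] <= p):
            rows.append({**base, "category": "not_significant"})
            continue

        exon_rel = relations.get(pid, {})
        support, types = _support_for(
            int(row["direction"]), exon_rel, j_p, j_dir, j_testable, adj.p_prime
        )
        junction_sis = [
            (jid, float(j_si[jid]))
            for jid in sorted(exon_rel)
            if j_testable.get(jid, False)
        ]
        best_id, diff = best_junction_difference(float(row["si"]), junction_sis)
        base["best_junction_id"] = best_id
        base["fc_difference"] = diff
        if support:
            null_diffs.append(diff)
            rows.append(
                {
                    **base,
                    "category": "junction_supported",
                    "supporting_junctions": support,
                    "support_types": types,
                }
            )
        else:
            significant_unsupported.append(base)

    null = estimate_null_threshold(null_diffs, q=q, min_null_size=min_null_size)
    for base in significant_unsupported:
        if null is not None and base["fc_difference"] > null.cutoff:
            rows.append({**base, "category": "unreliable_junction_candidate"})
        else:
            rows.append({**base, "category": "exon_only_not_called"})

    calls = SplicingCallSet(calls=pd.DataFrame(rows))
    return calls, adj, null


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunConfig:
    """Everything a reproducible run needs: file paths and parameters."""

    annotation: str
    design: str
    dabg: str
    probe_matrix: str | None = None
    probeset_matrix: str | None = None
    out: str | None = None
    p: float = 0.01
    q: float = 0.05
    d: float = 2.0
    presence_threshold: float = 0.01
    min_constitutive: int = 1
    min_null_size: int = MIN_NULL_SIZE
    normalize_target: str | float = "auto"
    normalize: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunResult:
    calls: SplicingCallSet
    gene_index: GeneExpressionIndex
    partition: Any
    stats: pd.DataFrame
    adjustment: ThresholdAdjustment
    null: NullThresholdParams | None
    report: dict[str, Any] = field(default_factory=dict)


def run_rasa(config: RunConfig) -> RunResult:
    """End-to-end run from input files to a classified call set.

    Deterministic: identical inputs and config give byte-identical
    outputs. Stage errors are re-raised with the stage name attached.
    """
    stage = "load"
    try:
        annot = rasa_io.read_annotation(config.annotation)
        design = rasa_io.read_design(config.design)
        dabg = rasa_io.read_dabg(config.dabg)
        if config.probeset_matrix:
            matrix = rasa_io.read_expression_matrix(
                config.probeset_matrix, row_kind="probeset"
            )
        elif config.probe_matrix:
            matrix = rasa_io.read_expression_matrix(config.probe_matrix, row_kind="probe")
        else:
            raise ValidationError("config needs probe_matrix or probeset_matrix")
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    result = run_pipeline(matrix, dabg, annot, design, config)
    if config.out:
        rasa_io.write_results(result.calls, config.out)
    return result


def run_pipeline(
    matrix: ExpressionMatrix,
    dabg,
    annot: DesignAnnotation,
    design,
    config: RunConfig | None = None,
) -> RunResult:
    """The computation behind :func:`run_rasa`, on in-memory objects.

    ``matrix`` may be probe-level (normalized and summarized here) or
    already-summarized probeset-level. File paths in ``config`` are
    ignored; only its parameters are used.
    """
    config = config or RunConfig(annotation="", design="", dabg="")
    stage = "preprocess"
    try:
        if matrix.row_kind == "probe":
            probes = matrix
            if config.normalize:
                probes = median_scale_normalize(probes, config.normalize_target)
            probesets = summarize_probesets(probes, annot)
        else:
            probes = None
            probesets = matrix
        design.check_samples(probesets.values.columns)

        stage = "presence"
        presence = group_dabg(dabg, design, threshold=config.presence_threshold)

        stage = "constitutive_selection"
        params = ConstitutiveSelectionParams(
            d=config.d,
            presence_threshold=config.presence_threshold,
            min_constitutive=config.min_constitutive,
        )
        exon_ids = [
            pid
            for pid in annot.exon_table["probeset_id"]
            if pid in probesets.values.index
        ]
        exon_idx = ExpressionMatrix(
            values=probesets.values.loc[exon_ids], row_kind="probeset"
        )
        partition = select_all(exon_idx, presence, design, annot, params)

        stage = "gene_index"
        source = probes if probes is not None else probesets
        gene_idx = gene_expression_index(source, partition, annot, presence, params)

        stage = "testing"
        stats = test_all(probesets, gene_idx, design, annot)

        stage = "classification"
        calls, adj, null = classify_exons(
            stats,
            presence,
            annot,
            p=config.p,
            q=config.q,
            min_null_size=config.min_null_size,
        )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    counts = calls.category_counts()
    report = {
        "n_genes": len(annot.genes),
        "n_exon_probesets": len(annot.exon_table),
        "n_junction_probesets": len(annot.junction_table),
        "n_fallback_genes": len(gene_idx.fallback_genes),
        "n_excluded_genes": len(gene_idx.excluded_genes),
        "p": config.p,
        "p_prime": adj.p_prime,
        "exon_quantile_f": adj.f,
        "q": config.q,
        "null_size": 0 if null is None else len(null.null_diffs),
        "null_cutoff": None if null is None else null.cutoff,
        "step3_enabled": null is not None,
        "category_counts": counts,
    }
    for key in ("p_prime", "null_cutoff", "null_size"):
        logger.info("%s = %s", key, report[key])

    return RunResult(
        calls=calls,
        gene_index=gene_idx,
        partition=partition,
        stats=stats,
        adjustment=adj,
        null=null,
        report=report,
    )
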