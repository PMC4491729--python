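"""Probe-level normalization, probeset summarization and presence calls.

Normalization is median scaling on the log2 scale: each sample column is
shifted so its median hits a common target. Summarization is Tukey
median polish over each probeset's probe block; the per-sample
expression index is the overall effect plus the column effect, which is
robust to outlier probes. Presence per condition is the geometric mean
of per-sample DABG p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rasa.core import (
    DabgMatrix,
    DesignAnnotation,
    ExpressionMatrix,
    PresenceCalls,
    SampleDesign,
    ValidationError,
)

# Convergence settings for median polish: stop when the largest absolute
# change of the residual matrix in a sweep drops below TOL.
MP_TOL = 1e-6
MP_MAX_SWEEPS = 30


def median_scale_normalize(
    m: ExpressionMatrix, target: float | str = "auto"
) -> ExpressionMatrix:
    """Shift each sample column so its median equals ``target``.

    ``target="auto"`` uses the mean of the original column medians, so
    the overall signal level is preserved. Idempotent: normalizing twice
    changes nothing.
    """
    values = m.values
    if values.empty:
        raise ValidationError("cannot normalize an empty matrix")
    medians = values.median(axis=0)
    t = float(medians.mean()) if target == "auto" else float(target)
    shifted = values.add(t - medians, axis=1)
    return ExpressionMatrix(values=shifted, row_kind=m.row_kind)


def _median(a: np.ndarray, axis: int):
    """Median with even-length = mean of the two central values.

    Faster than ``np.median`` on the many small blocks this module
    polishes; identical values by construction.
    """
    s = np.sort(a, axis=axis)
    n = a.shape[axis]
    mid = n // 2
    if n % 2:
        return np.take(s, mid, axis=axis)
    return 0.5 * (np.take(s, mid - 1, axis=axis) + np.take(s, mid, axis=axis))


def median_polish(block: np.ndarray, tol: float = MP_TOL, max_sweeps: int = MP_MAX_SWEEPS):
    """Tukey median polish of a 2-D array (rows first, then columns).

    Returns ``(overall, row_effects, col_effects, residuals)`` with the
    usual decomposition ``block = overall + row + col + residual``.
    Even-length medians are the mean of the two central values.
    """
    resid = np.asarray(block, dtype=float).copy()
    if resid.ndim != 2 or resid.size == 0:
        raise ValidationError("median polish needs a non-empty 2-D block")
    nrow, ncol = resid.shape
    overall = 0.0
    row_eff = np.zeros(nrow)
    col_eff = np.zeros(ncol)
    for _ in range(max_sweeps):
        # row sweep
        rmed = _median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        cmed_of_row = _median(row_eff, axis=0)
        row_eff -= cmed_of_row
        overall += cmed_of_row
        delta = np.abs(rmed).max(initial=0.0)
        # column sweep
        cmed = _median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        rmed_of_col = _median(col_eff, axis=0)
        col_eff -= rmed_of_col
        overall += rmed_of_col
        delta = max(delta, np.abs(cmed).max(initial=0.0))
        if delta < tol:
            break
    return overall, row_eff, col_eff, resid


def median_polish_summarize(block: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Summarize one probeset's probe block into a per-sample index.

    The index for sample ``s`` is ``overall + column_effect[s]``: the
    probe (row) effects absorb probe-affinity differences.
    """
    values = block.values if isinstance(block, ExpressionMatrix) else block
    overall, _, col_eff, _ = median_polish(values.to_numpy(dtype=float))
    return pd.Series(overall + col_eff, index=values.columns)


def probe_probeset_ids(probe_ids) -> pd.Series:
    """Map probe ids to probeset ids.

    Probe ids follow the convention ``<probeset_id>:<probe>``; the
    probeset id is everything before the final colon.
    """
    ids = pd.Series(list(probe_ids), index=list(probe_ids))
    bad = [i for i in ids if ":" not in i]
    if bad:
        raise ValidationError(
            f"probe ids must look like '<probeset_id>:<probe>'; got e.g. {bad[:3]}"
        )
    return ids.map(lambda s: s.rsplit(":", 1)[0])


def summarize_probesets(
    probes: ExpressionMatrix, annot: DesignAnnotation | None = None
) -> ExpressionMatrix:
    """Summarize a probe-level matrix into probeset indices via median polish.

    Probes are grouped by the ``<probeset_id>:<probe>`` id convention;
    when an annotation is given, only annotated probesets are kept and
    unknown probes are rejected.
    """
    if probes.row_kind != "probe":
        raise ValidationError("summarize_probesets expects a probe-level matrix")
    groups = probe_probeset_ids(probes.values.index)
    if annot is not None:
        known = set(annot.table["probeset_id"])
        unknown = sorted(set(groups) - known)
        if unknown:
            raise ValidationError(f"probes reference unannotated probesets: {unknown}")
    arr = probes.values.to_numpy(dtype=float)
    positions = pd.Series(range(len(arr)), index=probes.values.index)
    rows = {}
    for probeset_id, pos in positions.groupby(groups.to_numpy()):
        overall, _, col_eff, _ = median_polish(arr[pos.to_numpy()])
        rows[probeset_id] = overall + col_eff
    out = pd.DataFrame.from_dict(rows, orient="index", columns=probes.values.columns)
    out = out.sort_index()
    out.index.name = "probeset_id"
    return ExpressionMatrix(values=out, row_kind="probeset")


def group_dabg(
    dabg: DabgMatrix, design: SampleDesign, threshold: float = 0.01
) -> PresenceCalls:
    """Aggregate per-sample DABG p-values into per-condition presence calls.

    The group p-value is the geometric mean of the condition's sample
    p-values; a probeset is present where the group p-value is at or
    below ``threshold``.
    """
    design.check_samples(dabg.p.columns)
    cols = {}
    for cond in design.conditions:
        samples = [s for s in design.samples_in(cond) if s in dabg.p.columns]
        if not samples:
            raise ValidationError(f"condition {cond!r} has no samples in the DABG matrix")
        cols[cond] = np.exp(np.log(dabg.p[samples]).mean(axis=1))
    group_p = pd.DataFrame(cols)
    return PresenceCalls(group_p=group_p, threshold=threshold)
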