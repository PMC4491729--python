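"""Readers and writers for the TSV formats the pipeline touches.

All tables are tab-separated UTF-8 with a header row. Expression and
DABG matrices have row identifiers in the first column and sample ids in
the header. Results are written one row per exon in deterministic order
(gene_id, then exon_index) and round-trip losslessly.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from rasa.core import (
    DabgMatrix,
    DesignAnnotation,
    ExpressionMatrix,
    ParseError,
    SampleDesign,
    SplicingCallSet,
    ValidationError,
)


def _read_table(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{what}: file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{what}: no data rows in {path}") from None
    if df.empty:
        raise ParseError(f"{what}: no data rows in {path}")
    return df


def read_expression_matrix(path: str | Path, row_kind: str = "probeset") -> ExpressionMatrix:
    """Read a log2 expression matrix (rows x samples) from TSV."""
    df = _read_table(path, "expression matrix")
    id_col = df.columns[0]
    dup_rows = df[id_col][df[id_col].duplicated()]
    if len(dup_rows):
        raise ParseError(
            f"duplicate row identifier(s): {sorted(dup_rows.unique())}"
        )
    sample_cols = list(df.columns[1:])
    dup_cols = {c for c in sample_cols if sample_cols.count(c) > 1}
    if dup_cols:
        raise ParseError(f"duplicate sample column(s): {sorted(dup_cols)}")
    values = df.set_index(id_col)
    for col in values.columns:
        try:
            values[col] = values[col].astype(float)
        except ValueError as exc:
            raise ParseError(f"non-numeric cell in column {col!r}: {exc}") from None
    values.index.name = "probeset_id" if row_kind == "probeset" else "probe_id"
    try:
        return ExpressionMatrix(values=values, row_kind=row_kind)
    except ValidationError as exc:
        raise ParseError(str(exc)) from None


def read_dabg(path: str | Path) -> DabgMatrix:
    """Read a DABG p-value matrix (probesets x samples) from TSV."""
    m = read_expression_matrix(path, row_kind="probeset")
    p = m.values
    if ((p < 0) | (p > 1)).any().any():
        raise ParseError("DABG p-values must lie in [0, 1]")
    return DabgMatrix(p=p)


_ANNOT_COLS = ("probeset_id", "gene_id", "kind", "exon_index", "exon5", "exon3", "n_probes")


def read_annotation(path: str | Path) -> DesignAnnotation:
    """Read the gene/exon/junction design annotation from TSV."""
    df = _read_table(path, "annotation")
    missing = {"probeset_id", "gene_id", "kind", "n_probes"} - set(df.columns)
    if missing:
        raise ParseError(f"annotation missing columns: {sorted(missing)}")
    for col in ("exon_index", "exon5", "exon3"):
        if col not in df.columns:
            df[col] = ""
    out = pd.DataFrame(
        {
            "probeset_id": df["probeset_id"],
            "gene_id": df["gene_id"],
            "kind": df["kind"],
            "exon_index": pd.to_numeric(df["exon_index"].replace("", None)),
            "exon5": pd.to_numeric(df["exon5"].replace("", None)),
            "exon3": pd.to_numeric(df["exon3"].replace("", None)),
            "n_probes": pd.to_numeric(df["n_probes"]).astype(int),
        }
    )
    exon_missing = out[(out["kind"] == "exon") & out["exon_index"].isna()]
    if len(exon_missing):
        raise ParseError(
            f"exon rows missing exon_index: {exon_missing['probeset_id'].tolist()}"
        )
    return DesignAnnotation(table=out.reset_index(drop=True))


def write_annotation(annot: DesignAnnotation, path: str | Path) -> None:
    t = annot.table.copy()
    t.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> SampleDesign:
    """Read the sample-to-condition design table from TSV."""
    df = _read_table(path, "design")
    if not {"sample_id", "condition"} <= set(df.columns):
        raise ParseError("design table needs columns sample_id, condition")
    labels = sorted(df["condition"].unique())
    if len(labels) != 2:
        raise ParseError(
            f"runs are pairwise comparisons of exactly two conditions; got {labels}"
        )
    cond = pd.Series(df["condition"].values, index=df["sample_id"].values)
    return SampleDesign(condition=cond)


def write_matrix(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path, index_name: str = "probeset_id") -> None:
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    values = values.copy()
    values.index.name = values.index.name or index_name
    values.to_csv(path, sep="\t")


_NA = "NA"


def _fmt_opt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return _NA
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_results(calls: SplicingCallSet, path: str | Path) -> None:
    """Write a call set as TSV, one row per exon, deterministic order."""
    df = calls.calls.copy()
    df["supporting_junctions"] = df["supporting_junctions"].map(
        lambda js: ",".join(js) if js else _NA
    )
    df["support_types"] = df["support_types"].map(
        lambda ts: ",".join(ts) if ts else _NA
    )
    df["best_junction_id"] = df["best_junction_id"].map(_fmt_opt)
    df["fc_difference"] = df["fc_difference"].map(_fmt_opt)
    df["p_value"] = df["p_value"].map(_fmt_opt)
    df["si"] = df["si"].map(_fmt_opt)
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> SplicingCallSet:
    """Read a call set previously written by :func:`write_results`."""
    df = _read_table(path, "results")
    df["exon_index"] = df["exon_index"].astype(int)
    df["supporting_junctions"] = df["supporting_junctions"].map(
        lambda s: [] if s == _NA else s.split(",")
    )
    df["support_types"] = df["support_types"].map(
        lambda s: [] if s == _NA else s.split(",")
    )
    df["best_junction_id"] = df["best_junction_id"].map(
        lambda s: None if s == _NA else s
    )
    for col in ("p_value", "si", "fc_difference"):
        df[col] = df[col].map(lambda s: float("nan") if s == _NA else float(s))
    df["presence_flag"] = df["presence_flag"].map(
        lambda s: s in ("True", "true", "1")
    )
    return SplicingCallSet(calls=df)
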