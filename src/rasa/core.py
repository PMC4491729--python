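"""Domain types shared by all stages of the pipeline.

Conventions fixed here and used everywhere:

* all expression values are log2; "fold change" means a difference of
  log2 means between the two conditions (second condition minus first,
  conditions ordered lexicographically unless overridden);
* exons are addressed by a 1-based ordinal index along the gene (5'->3');
  a junction connects two exon ordinals ``exon5 < exon3``;
* a junction is an *inclusion* junction for exon ``e`` iff one of its
  endpoints is ``e``, and an *exclusion* junction for ``e`` iff it skips
  over ``e`` (``exon5 < e < exon3``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DABG_FLOOR = 1e-16  # p-values clamped to [DABG_FLOOR, 1] so log-means are defined

EXON_CATEGORIES = (
    "junction_supported",
    "unreliable_junction_candidate",
    "exon_only_not_called",
    "not_significant",
    "absent",
)


class ParseError(ValueError):
    """A file could not be parsed into a valid table."""


class ValidationError(ValueError):
    """A parsed table violates a structural invariant."""


# ---------------------------------------------------------------------------
# design annotation


@dataclass(frozen=True)
class DesignAnnotation:
    """Gene/exon/junction structure of the array design.

    ``table`` holds one row per probeset with columns ``probeset_id``,
    ``gene_id``, ``kind`` ("exon" or "junction"), ``exon_index`` (exon
    rows), ``exon5``/``exon3`` (junction rows) and ``n_probes``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        t = self.table
        required = {"probeset_id", "gene_id", "kind", "n_probes"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        dup = t["probeset_id"][t["probeset_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate probeset_id in annotation: {sorted(dup.unique())}"
            )
        bad_kind = set(t["kind"].unique()) - {"exon", "junction"}
        if bad_kind:
            raise ValidationError(f"unknown probeset kind(s): {sorted(bad_kind)}")
        if (t["n_probes"] <= 0).any():
            bad = t.loc[t["n_probes"] <= 0, "probeset_id"].tolist()
            raise ValidationError(f"non-positive n_probes for: {bad}")

        exons = t[t["kind"] == "exon"]
        juncs = t[t["kind"] == "junction"]
        if len(exons) and (exons["exon_index"] < 1).any():
            bad = exons.loc[exons["exon_index"] < 1, "probeset_id"].tolist()
            raise ValidationError(f"exon_index must be >= 1 for: {bad}")
        dup_idx = exons.duplicated(subset=["gene_id", "exon_index"])
        if dup_idx.any():
            bad = exons.loc[dup_idx, "probeset_id"].tolist()
            raise ValidationError(f"duplicate exon_index within gene for: {bad}")

        offenders: list[str] = []
        exon_sets = {
            g: set(sub["exon_index"].astype(int))
            for g, sub in exons.groupby("gene_id")
        }
        for _, row in juncs.iterrows():
            e5, e3 = row["exon5"], row["exon3"]
            if not (pd.notna(e5) and pd.notna(e3)) or not (e5 < e3):
                offenders.append(row["probeset_id"])
                continue
            known = exon_sets.get(row["gene_id"], set())
            if int(e5) not in known or int(e3) not in known:
                offenders.append(row["probeset_id"])
        if offenders:
            raise ValidationError(
                "junctions with invalid or cross-gene endpoints "
                f"(need exon5 < exon3, both exons of the same gene): {offenders}"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene_id"].unique())

    @property
    def exon_table(self) -> pd.DataFrame:
        return self.table[self.table["kind"] == "exon"]

    @property
    def junction_table(self) -> pd.DataFrame:
        return self.table[self.table["kind"] == "junction"]

    def exons_of(self, gene_id: str) -> pd.DataFrame:
        sub = self.exon_table[self.exon_table["gene_id"] == gene_id]
        return sub.sort_values("exon_index")

    def junctions_of(self, gene_id: str) -> pd.DataFrame:
        return self.junction_table[self.junction_table["gene_id"] == gene_id]

    def inclusion_junctions(self, gene_id: str, exon_index: int) -> list[str]:
        """Junction probesets with one endpoint at ``exon_index``."""
        j = self.junctions_of(gene_id)
        hit = (j["exon5"] == exon_index) | (j["exon3"] == exon_index)
        return j.loc[hit, "probeset_id"].tolist()

    def exclusion_junctions(self, gene_id: str, exon_index: int) -> list[str]:
        """Junction probesets that skip over ``exon_index``."""
        j = self.junctions_of(gene_id)
        hit = (j["exon5"] < exon_index) & (exon_index < j["exon3"])
        return j.loc[hit, "probeset_id"].tolist()

    def junctions_for_exon(self, gene_id: str, exon_index: int) -> dict[str, str]:
        """All junctions relevant to an exon, mapped to their relation.

        Returns ``{junction probeset_id: "inclusion" | "exclusion"}``.
        """
        rel = {j: "inclusion" for j in self.inclusion_junctions(gene_id, exon_index)}
        rel.update(
            {j: "exclusion" for j in self.exclusion_junctions(gene_id, exon_index)}
        )
        return rel


# ---------------------------------------------------------------------------
# expression data


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression indices, rows x samples.

    ``row_kind`` says whether rows are individual probes or summarized
    probesets.
    """

    values: pd.DataFrame
    row_kind: str = "probeset"

    def __post_init__(self) -> None:
        if self.row_kind not in ("probe", "probeset"):
            raise ValidationError(f"row_kind must be probe|probeset, got {self.row_kind!r}")
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate row identifiers: {dup}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dup}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SampleDesign:
    """Sample-to-condition assignment for a pairwise comparison.

    Exactly two condition labels; fold changes are second minus first in
    ``condition_order`` (lexicographic by default).
    """

    condition: pd.Series  # index: sample_id, values: condition label
    condition_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        labels = sorted(self.condition.unique())
        if len(labels) != 2:
            raise ValidationError(
                f"a run compares exactly two conditions (pairwise); got {labels}"
            )
        if self.condition.index.duplicated().any():
            dup = self.condition.index[self.condition.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample_id in design: {dup}")
        if self.condition_order is None:
            object.__setattr__(self, "condition_order", (labels[0], labels[1]))
        elif sorted(self.condition_order) != labels:
            raise ValidationError(
                f"condition_order {self.condition_order} does not match labels {labels}"
            )

    @property
    def conditions(self) -> tuple[str, str]:
        return self.condition_order  # type: ignore[return-value]

    def samples_in(self, cond: str) -> list[str]:
        return self.condition.index[self.condition == cond].tolist()

    def replicate_counts(self) -> dict[str, int]:
        return {c: len(self.samples_in(c)) for c in self.conditions}

    def check_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.condition.index]
        if missing:
            raise ValidationError(f"samples missing from design: {missing}")


@dataclass(frozen=True)
class DabgMatrix:
    """Per-sample detection-above-background p-values, probesets x samples.

    Values are clamped into ``[1e-16, 1]`` on construction so that the
    geometric mean over a condition's samples is always defined.
    """

    p: pd.DataFrame

    def __post_init__(self) -> None:
        clamped = self.p.clip(lower=DABG_FLOOR, upper=1.0)
        object.__setattr__(self, "p", clamped)


@dataclass(frozen=True)
class PresenceCalls:
    """Group-level detectability per probeset and condition.

    ``group_p[i, c]`` is the geometric mean of sample DABG p-values of
    probeset ``i`` in condition ``c``; a probeset is *present* in a
    condition when ``group_p <= threshold``.
    """

    group_p: pd.DataFrame  # probeset x condition
    threshold: float = 0.01

    @property
    def present(self) -> pd.DataFrame:
        return self.group_p <= self.threshold

    def is_present(self, probeset_id: str, condition: str) -> bool:
        return bool(self.group_p.loc[probeset_id, condition] <= self.threshold)


# ---------------------------------------------------------------------------
# constitutive exon selection


@dataclass(frozen=True)
class ConstitutiveSelectionParams:
    """Parameters of the iterative constitutive-exon trimming.

    ``d`` is the outlier sensitivity: an exon is trimmed when its fold
    change falls strictly outside ``[m - d*s, m + d*s]`` of the retained
    set. ``min_constitutive`` is the smallest constitutive set accepted
    before the all-present-exon fallback kicks in.
    """

    d: float = 2.0
    presence_threshold: float = 0.01
    min_constitutive: int = 1
    max_iterations: int | None = None  # None = number of exons in the gene

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValidationError("d must be positive")


@dataclass
class GenePartition:
    """Per-gene result of constitutive selection."""

    gene_id: str
    labels: dict[str, str]  # exon probeset_id -> constitutive|absent|outlier
    m: float  # mean of retained exon fold changes (NaN if none retained)
    s: float  # sample sd of retained exon fold changes
    n_iterations: int
    fallback: bool = False  # True when < min_constitutive exons survived

    @property
    def constitutive(self) -> list[str]:
        return [p for p, lab in self.labels.items() if lab == "constitutive"]

    @property
    def outliers(self) -> list[str]:
        return [p for p, lab in self.labels.items() if lab == "outlier"]

    @property
    def absent(self) -> list[str]:
        return [p for p, lab in self.labels.items() if lab == "absent"]


@dataclass
class ConstitutivePartition:
    """Constitutive/absent/outlier labels for every gene in a run."""

    genes: dict[str, GenePartition] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> GenePartition:
        return self.genes[gene_id]

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gp in self.genes.values():
            for probeset, label in gp.labels.items():
                rows.append(
                    {
                        "gene_id": gp.gene_id,
                        "probeset_id": probeset,
                        "label": label,
                        "m": gp.m,
                        "s": gp.s,
                        "n_iterations": gp.n_iterations,
                        "fallback": gp.fallback,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class GeneExpressionIndex:
    """Gene-level log2 expression indices, genes x samples.

    ``source_exons`` records, per gene, the exon probesets the index was
    computed from; ``fallback_genes`` had no constitutive exon and fell
    back to all present exons; ``excluded_genes`` had no present exon at
    all and are excluded from downstream testing.
    """

    values: pd.DataFrame
    source_exons: dict[str, list[str]]
    fallback_genes: set[str] = field(default_factory=set)
    excluded_genes: set[str] = field(default_factory=set)

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self.values.index


# ---------------------------------------------------------------------------
# splicing statistics and calls


@dataclass(frozen=True)
class ThresholdAdjustment:
    """Exon p-value threshold mapped onto the junction p-value scale.

    ``f`` is the quantile level the exon threshold ``p`` corresponds to
    in the exon p-value distribution; ``p_prime`` is the junction p-value
    achieving the same quantile level (smallest achievable fraction >= f).
    """

    p: float
    p_prime: float
    f: float


@dataclass(frozen=True)
class NullThresholdParams:
    """Empirical-null decision boundary for unreliable-junction calls.

    ``cutoff`` is the top-``q`` quantile of ``null_diffs`` (the
    exon-minus-best-junction fold-change differences of junction-supported
    exons); an unsupported significant exon with difference strictly above
    the cutoff is declared to have unreliable junctions.
    """

    q: float
    cutoff: float
    null_diffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (0 < self.q < 1):
            raise ValidationError("q must lie strictly between 0 and 1")


@dataclass
class SplicingCallSet:
    """Final per-exon classification.

    One row per exon probeset: gene_id, probeset_id, exon_index, category,
    p_value, si, supporting_junctions (list of ids), support_types,
    best_junction_id, fc_difference, presence_flag.
    """

    calls: pd.DataFrame

    COLUMNS = (
        "gene_id",
        "probeset_id",
        "exon_index",
        "category",
        "p_value",
        "si",
        "supporting_junctions",
        "support_types",
        "best_junction_id",
        "fc_difference",
        "presence_flag",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.calls.columns)
        if missing:
            raise ValidationError(f"call set missing columns: {sorted(missing)}")
        bad = set(self.calls["category"].unique()) - set(EXON_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown call categories: {sorted(bad)}")
        ordered = self.calls.sort_values(["gene_id", "exon_index"]).reset_index(
            drop=True
        )
        self.calls = ordered[list(self.COLUMNS)]

    def category_counts(self) -> dict[str, int]:
        counts = self.calls["category"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in EXON_CATEGORIES}

    def candidates(self) -> pd.DataFrame:
        """Exons called alternatively spliced (steps 2 and 3 combined)."""
        keep = self.calls["category"].isin(
            ["junction_supported", "unreliable_junction_candidate"]
        )
        return self.calls[keep]
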