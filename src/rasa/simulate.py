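"""Synthetic exon-junction array datasets with known ground truth.

Each simulated gene is a linear chain of exons with an adjacent
junction between every consecutive pair; every planted skipping event
on an internal exon additionally gets the skip junction joining its two
neighbours (the exclusion junction). Probe-level log2 intensities are

    gene abundance(condition) + splicing shift + probe affinity + noise

with junction probesets both fewer-probed and noisier than exon
probesets, mirroring real exon-junction array designs (junction probes
cover ~30 bp versus ~120 bp for exons). A skipped exon loses
``splicing_effect`` log2 units in the second condition, its inclusion
junctions move with it and its exclusion junction moves oppositely.
Failure modes with truth labels: absent exons (background in both
conditions) and failed junction probesets (flat background signal) —
the situations steps 1 and 3 of the pipeline exist to handle. DABG
p-values are a seeded logistic function of signal above background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from rasa.core import (
    DabgMatrix,
    DesignAnnotation,
    ExpressionMatrix,
    SampleDesign,
    SplicingCallSet,
    ValidationError,
)

BACKGROUND = 3.0  # log2 background intensity
DABG_SLOPE = 3.0  # logistic steepness of the DABG curve per log2 unit
DABG_NOISE_SD = 0.5


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for a simulated two-condition experiment.

    Defaults mirror a three-replicate two-tissue comparison on an
    exon-junction array: 200 genes of 10 exons, 8 probes per exon
    probeset and 4 per junction probeset, junction probesets twice as
    noisy as exon probesets, and planted skipping events with a splicing
    index of 2 log2 units.
    """

    n_genes: int = 200
    exons_per_gene: int = 10
    n_replicates: int = 3
    frac_spliced_exons: float = 0.05
    splicing_effect: float = 2.0
    gene_fc_sd: float = 0.5
    exon_noise_sd: float = 0.25
    junction_noise_sd: float = 0.5
    probe_affinity_sd: float = 0.3
    junction_failure_rate: float = 0.0
    spliced_junction_failure_rate: float = 0.0
    frac_absent_exons: float = 0.05
    probes_per_exon: int = 8
    probes_per_junction: int = 4
    base_abundance_range: tuple[float, float] = (8.0, 11.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_spliced_exons",
            "junction_failure_rate",
            "spliced_junction_failure_rate",
            "frac_absent_exons",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("gene_fc_sd", "exon_noise_sd", "junction_noise_sd", "probe_affinity_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_genes < 1 or self.exons_per_gene < 2 or self.n_replicates < 1:
            raise ValidationError(
                "need n_genes >= 1, exons_per_gene >= 2, n_replicates >= 1"
            )


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset."""

    exons: pd.DataFrame  # probeset_id, gene_id, exon_index, is_spliced, direction, is_absent
    junctions: pd.DataFrame  # probeset_id, gene_id, is_failed
    genes: pd.DataFrame  # gene_id, abundance per condition

    def spliced_exon_ids(self) -> set[str]:
        return set(self.exons.loc[self.exons["is_spliced"], "probeset_id"])


@dataclass
class SimulatedDataset:
    probes: ExpressionMatrix
    dabg: DabgMatrix
    annotation: DesignAnnotation
    design: SampleDesign
    truth: TruthTable


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Generate a complete dataset; fully reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n_rep = params.n_replicates
    samples = [f"A{r + 1}" for r in range(n_rep)] + [f"B{r + 1}" for r in range(n_rep)]
    conditions = ["A"] * n_rep + ["B"] * n_rep
    design = SampleDesign(condition=pd.Series(conditions, index=samples))

    genes = _gene_ids(params.n_genes)
    E = params.exons_per_gene
    lo, hi = params.base_abundance_range
    abund_a = rng.uniform(lo, hi, size=params.n_genes)
    abund_b = abund_a + rng.normal(0.0, params.gene_fc_sd, size=params.n_genes)

    # plant skipping events on internal exons, exactly round(frac * eligible)
    eligible = [
        (gi, e) for gi in range(params.n_genes) for e in range(2, E)
    ]  # exon ordinals 2..E-1
    n_events = int(round(params.frac_spliced_exons * len(eligible)))
    event_rows = rng.choice(len(eligible), size=n_events, replace=False) if n_events else []
    spliced: dict[tuple[int, int], int] = {}
    for ridx in event_rows:
        gi, e = eligible[ridx]
        spliced[(gi, e)] = int(rng.choice([-1, 1]))

    # absent exons among the remaining ones
    non_spliced = [
        (gi, e)
        for gi in range(params.n_genes)
        for e in range(1, E + 1)
        if (gi, e) not in spliced
    ]
    n_absent = int(round(params.frac_absent_exons * len(non_spliced)))
    absent = set()
    if n_absent:
        for ridx in rng.choice(len(non_spliced), size=n_absent, replace=False):
            absent.add(non_spliced[ridx])

    # assemble annotation + per-probeset true signal
    annot_rows: list[dict] = []
    exon_truth: list[dict] = []
    junc_meta: list[tuple[str, int, int, int]] = []  # (probeset_id, gi, e5, e3)
    for gi, gene in enumerate(genes):
        for e in range(1, E + 1):
            pid = f"{gene}:E{e:02d}"
            annot_rows.append(
                {
                    "probeset_id": pid,
                    "gene_id": gene,
                    "kind": "exon",
                    "exon_index": e,
                    "exon5": np.nan,
                    "exon3": np.nan,
                    "n_probes": params.probes_per_exon,
                }
            )
            exon_truth.append(
                {
                    "probeset_id": pid,
                    "gene_id": gene,
                    "exon_index": e,
                    "is_spliced": (gi, e) in spliced,
                    "direction": spliced.get((gi, e), 0),
                    "is_absent": (gi, e) in absent,
                }
            )
        pairs = [(e, e + 1) for e in range(1, E)]
        pairs += sorted((e - 1, e + 1) for (g2, e) in spliced if g2 == gi)
        for e5, e3 in pairs:
            pid = f"{gene}:J{e5:02d}-{e3:02d}"
            annot_rows.append(
                {
                    "probeset_id": pid,
                    "gene_id": gene,
                    "kind": "junction",
                    "exon_index": np.nan,
                    "exon5": e5,
                    "exon3": e3,
                    "n_probes": params.probes_per_junction,
                }
            )
            junc_meta.append((pid, gi, e5, e3))

    # failed junction probesets: a random fraction of all junctions, plus
    # every junction of a chosen fraction of spliced exons (the scenario
    # step 3 exists to recover)
    n_failed = int(round(params.junction_failure_rate * len(junc_meta)))
    failed_idx = set(
        rng.choice(len(junc_meta), size=n_failed, replace=False) if n_failed else []
    )
    if params.spliced_junction_failure_rate and spliced:
        events = sorted(spliced)
        n_target = int(round(params.spliced_junction_failure_rate * len(events)))
        if n_target:
            chosen = rng.choice(len(events), size=n_target, replace=False)
            targets = {events[i] for i in chosen}
            for j, (_, gi, e5, e3) in enumerate(junc_meta):
                for g2, e in targets:
                    if gi == g2 and (e5 == e or e3 == e or e5 < e < e3):
                        failed_idx.add(j)

    # true per-sample signal for every probeset
    cond_of = np.array([0] * n_rep + [1] * n_rep)  # 0 = A, 1 = B

    def gene_abund(gi: int) -> np.ndarray:
        return np.where(cond_of == 0, abund_a[gi], abund_b[gi])

    signal: dict[str, np.ndarray] = {}
    for row in exon_truth:
        gi = genes.index(row["gene_id"])
        e = row["exon_index"]
        if row["is_absent"]:
            signal[row["probeset_id"]] = np.full(len(samples), BACKGROUND)
            continue
        s = gene_abund(gi).astype(float).copy()
        if row["is_spliced"]:
            s += np.where(cond_of == 1, row["direction"] * params.splicing_effect, 0.0)
        signal[row["probeset_id"]] = s

    junc_truth: list[dict] = []
    for j, (pid, gi, e5, e3) in enumerate(junc_meta):
        is_failed = j in failed_idx
        junc_truth.append(
            {"probeset_id": pid, "gene_id": genes[gi], "is_failed": is_failed}
        )
        if is_failed:
            signal[pid] = np.full(len(samples), BACKGROUND)
            continue
        s = gene_abund(gi).astype(float).copy()
        for (g2, e), direction in spliced.items():
            if g2 != gi:
                continue
            if e5 == e or e3 == e:  # inclusion junction moves with the exon
                s += np.where(cond_of == 1, direction * params.splicing_effect, 0.0)
            elif e5 < e < e3:  # exclusion junction moves against it
                s -= np.where(cond_of == 1, direction * params.splicing_effect, 0.0)
        signal[pid] = s

    # probe-level matrix
    probe_rows: dict[str, np.ndarray] = {}
    annot_df = pd.DataFrame(annot_rows)
    for row in annot_rows:
        pid = row["probeset_id"]
        n_probes = row["n_probes"]
        noise_sd = (
            params.exon_noise_sd if row["kind"] == "exon" else params.junction_noise_sd
        )
        affinity = rng.normal(0.0, params.probe_affinity_sd, size=n_probes)
        noise = rng.normal(0.0, noise_sd, size=(n_probes, len(samples)))
        block = signal[pid][None, :] + affinity[:, None] + noise
        for k in range(n_probes):
            probe_rows[f"{pid}:{k + 1:02d}"] = block[k]

    probes = ExpressionMatrix(
        values=pd.DataFrame(probe_rows, index=samples).T, row_kind="probe"
    )
    probes.values.index.name = "probe_id"

    # DABG p-values: logistic in signal above background, seeded noise
    probeset_ids = annot_df["probeset_id"].tolist()
    sig = np.vstack([signal[pid] for pid in probeset_ids])
    eps = rng.normal(0.0, DABG_NOISE_SD, size=sig.shape)
    p = expit(-(DABG_SLOPE * (sig - BACKGROUND) + eps))
    dabg = DabgMatrix(p=pd.DataFrame(p, index=probeset_ids, columns=samples))

    truth = TruthTable(
        exons=pd.DataFrame(exon_truth),
        junctions=pd.DataFrame(junc_truth),
        genes=pd.DataFrame(
            {"gene_id": genes, "abundance_A": abund_a, "abundance_B": abund_b}
        ),
    )
    return SimulatedDataset(
        probes=probes,
        dabg=dabg,
        annotation=DesignAnnotation(table=annot_df),
        design=design,
        truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as the TSV files the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": outdir / "probes.tsv",
        "dabg": outdir / "dabg.tsv",
        "annotation": outdir / "annotation.tsv",
        "design": outdir / "design.tsv",
        "truth_exons": outdir / "truth_exons.tsv",
        "truth_junctions": outdir / "truth_junctions.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
    }
    probes = ds.probes.values.copy()
    probes.index.name = "probe_id"
    probes.to_csv(paths["probes"], sep="\t")
    dabg = ds.dabg.p.copy()
    dabg.index.name = "probeset_id"
    dabg.to_csv(paths["dabg"], sep="\t")
    ds.annotation.table.to_csv(paths["annotation"], sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": ds.design.condition.index, "condition": ds.design.condition.values}
    ).to_csv(paths["design"], sep="\t", index=False)
    ds.truth.exons.to_csv(paths["truth_exons"], sep="\t", index=False)
    ds.truth.junctions.to_csv(paths["truth_junctions"], sep="\t", index=False)
    ds.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    return paths


def evaluate_calls(calls: SplicingCallSet, truth: TruthTable) -> dict:
    """Precision/recall/F1 of splicing calls against the planted truth.

    An exon counts as *called* when its category is junction_supported
    or unreliable_junction_candidate; truth is the planted is_spliced
    flag. Precision with zero calls is reported as None, not 0.
    """
    truth_ids = set(truth.exons["probeset_id"])
    call_ids = set(calls.calls["probeset_id"])
    if not call_ids <= truth_ids:
        raise ValidationError("call set and truth table come from different annotations")

    spliced = truth.spliced_exon_ids()
    called = set(calls.candidates()["probeset_id"])
    tp = len(called & spliced)
    fp = len(called - spliced)
    fn = len(spliced - called)
    precision = tp / (tp + fp) if called else None
    recall = tp / (tp + fn) if spliced else None
    f1 = None
    if precision not in (None, 0) and recall not in (None, 0):
        f1 = 2 * precision * recall / (precision + recall)

    per_category = {}
    for cat in ("junction_supported", "unreliable_junction_candidate"):
        ids = set(calls.calls.loc[calls.calls["category"] == cat, "probeset_id"])
        cat_tp = len(ids & spliced)
        per_category[cat] = {
            "n_called": len(ids),
            "tp": cat_tp,
            "precision": cat_tp / len(ids) if ids else None,
        }

    # direction agreement among true positives
    tp_rows = calls.calls[calls.calls["probeset_id"].isin(called & spliced)]
    truth_dir = truth.exons.set_index("probeset_id")["direction"]
    n_dir_ok = int(
        (np.sign(tp_rows["si"].to_numpy()) == truth_dir.loc[tp_rows["probeset_id"]].to_numpy()).sum()
    )

    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "direction_agreement": n_dir_ok / tp if tp else None,
        "per_category": per_category,
    }
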