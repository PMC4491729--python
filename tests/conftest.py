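import numpy as np
import pandas as pd
import pytest

from rasa.core import DesignAnnotation, ExpressionMatrix, SampleDesign
from rasa.pipeline import run_pipeline
from rasa.simulate import SimulationParams, simulate_dataset


def make_annotation(rows):
    """Build a DesignAnnotation from (probeset, gene, kind, e_idx, e5, e3, n) tuples."""
    return DesignAnnotation(
        table=pd.DataFrame(
            rows,
            columns=[
                "probeset_id",
                "gene_id",
                "kind",
                "exon_index",
                "exon5",
                "exon3",
                "n_probes",
            ],
        )
    )


@pytest.fixture
def toy_annot():
    """One 3-exon gene with adjacent junctions and the exon-2 skip junction."""
    return make_annotation(
        [
            ("g1:E01", "g1", "exon", 1, None, None, 8),
            ("g1:E02", "g1", "exon", 2, None, None, 8),
            ("g1:E03", "g1", "exon", 3, None, None, 8),
            ("g1:J01-02", "g1", "junction", None, 1, 2, 4),
            ("g1:J02-03", "g1", "junction", None, 2, 3, 4),
            ("g1:J01-03", "g1", "junction", None, 1, 3, 4),
        ]
    )


@pytest.fixture
def six_sample_design():
    return SampleDesign(
        condition=pd.Series(
            ["A", "A", "A", "B", "B", "B"],
            index=["A1", "A2", "A3", "B1", "B2", "B3"],
        )
    )


def matrix_from(rows: dict, samples, row_kind="probeset") -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame(rows, index=samples).T, row_kind=row_kind
    )


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale simulation with junction failures, shared across tests."""
    return simulate_dataset(SimulationParams(seed=7, junction_failure_rate=0.2))


@pytest.fixture(scope="session")
def default_run(default_sim):
    ds = default_sim
    return run_pipeline(ds.probes, ds.dabg, ds.annotation, ds.design)
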