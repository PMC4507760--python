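import numpy as np
import pandas as pd
import pytest

from lagnet import AnalysisConfig, TimeCourseMatrix
from lagnet.datamodel import PROCESSES


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def strict_config() -> AnalysisConfig:
    return AnalysisConfig(phase_mode="strict")


def make_timecourse(values: dict[str, dict[float, float]], n_reps: int = 2,
                    classes: dict[str, str] | None = None) -> TimeCourseMatrix:
    """Build a TimeCourseMatrix from {entity: {time: replicate-mean value}}."""
    records = []
    for eid, series in values.items():
        for t, v in series.items():
            for rep in range(1, n_reps + 1):
                records.append((eid, float(t), rep, float(v)))
    return TimeCourseMatrix(
        pd.DataFrame(records, columns=["entity_id", "time", "replicate", "value"]),
        entity_class=classes,
    )


def make_annotations(rows: list[tuple[str, str, str, tuple[str, ...]]]) -> pd.DataFrame:
    """rows: (entity_id, entity_class, family, processes)."""
    return pd.DataFrame(
        {
            "entity_class": [r[1] for r in rows],
            "family": [r[2] for r in rows],
            "processes": [tuple(r[3]) for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="entity_id"),
    )


@pytest.fixture
def tiny_annotations() -> pd.DataFrame:
    return make_annotations(
        [
            ("TF1", "TF", "bHLH", ("lipid",)),
            ("TF2", "TR", "GNAT", ("nitrogen",)),
            ("g1", "metabolic_gene", "", ("lipid",)),
            ("g2", "metabolic_gene", "", ("nitrogen",)),
            ("m1", "metabolite", "", ("lipid", "nitrogen")),
        ]
    )
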