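"""Core data types for the time-course network pipeline.

Entities fall into three sides of a tripartite design: regulators (TF/TR
transcripts), metabolic-pathway transcripts/proteins, and metabolites.
Abundance data are replicate-resolved time courses sampled on a short,
unevenly spaced grid that always starts at the time-zero control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

#: Classes an entity may carry. TF and TR are the regulator side of the
#: tripartite network; everything else is a potential correlation target.
REGULATOR_CLASSES = frozenset({"TF", "TR"})
TARGET_CLASSES = frozenset({"metabolic_gene", "metabolite", "protein"})
ENTITY_CLASSES = REGULATOR_CLASSES | TARGET_CLASSES

#: Closed vocabulary of biological-process labels used for subnetworks.
PROCESSES = (
    "lipid",
    "calvin_cycle",
    "nitrogen",
    "photosynthesis",
    "photorespiration",
    "oppp",
    "citrate_glyoxylate",
    "sucrose_starch",
    "amino_acid",
    "chlorophyll",
)
PROCESS_SET = frozenset(PROCESSES)

#: Node shapes used by the Cytoscape-oriented exports.
CLASS_SHAPES = {
    "TF": "circle",
    "TR": "circle",
    "metabolic_gene": "square",
    "protein": "square",
    "metabolite": "triangle",
}


def is_regulator(entity_class: str) -> bool:
    return entity_class in REGULATOR_CLASSES


@dataclass
class TimeCourseMatrix:
    """Replicate-resolved abundances, long format.

    ``data`` has columns ``entity_id``, ``time`` (hours), ``replicate``
    (integer), ``value`` (non-negative abundance, arbitrary units).
    Missing replicate values are simply absent rows, never zeros.
    ``entity_class`` optionally maps each id to one of `ENTITY_CLASSES`.
    """

    data: pd.DataFrame
    entity_class: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        required = {"entity_id", "time", "replicate", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        values = self.data["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("invalid abundance: non-finite value")
        if (values < 0).any():
            raise ValueError("invalid abundance: negative value")
        if self.data.duplicated(["entity_id", "time", "replicate"]).any():
            raise ValueError("duplicate record")
        times = np.sort(self.data["time"].unique())
        if 0.0 not in times:
            raise ValueError("no time-zero baseline")
        baseline_ids = set(self.data.loc[self.data["time"] == 0.0, "entity_id"])
        missing_baseline = set(self.data["entity_id"]) - baseline_ids
        if missing_baseline:
            raise ValueError(
                "no time-zero baseline for entities: "
                + ", ".join(sorted(missing_baseline)[:5])
            )
        if self.entity_class is not None:
            bad = set(self.entity_class.values()) - ENTITY_CLASSES
            if bad:
                raise ValueError(f"unknown entity class: {sorted(bad)}")

    # -- accessors --------------------------------------------------------

    @property
    def entity_ids(self) -> list[str]:
        return list(pd.unique(self.data["entity_id"]))

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time"].unique())

    def replicate_counts(self) -> pd.Series:
        return self.data.groupby(["entity_id", "time"]).size()

    def replicate_means(self) -> pd.DataFrame:
        """Entities x times matrix of replicate means (NaN where absent)."""
        means = self.data.groupby(["entity_id", "time"])["value"].mean().unstack()
        return means.reindex(index=self.entity_ids, columns=self.times)

    def with_classes(self, annotations: pd.DataFrame) -> "TimeCourseMatrix":
        classes = annotations["entity_class"].to_dict()
        return TimeCourseMatrix(self.data, entity_class=classes)


@dataclass
class CorrelationEdge:
    """A retained TF/TR -> target association at its best lag."""

    tf_id: str
    target_id: str
    target_class: str
    r: float
    lag: int
    n_pairs: int
    p: float

    @property
    def sign(self) -> int:
        return 1 if self.r >= 0 else -1

    def key(self) -> tuple[str, str]:
        return (self.tf_id, self.target_id)


@dataclass
class ResponseCall:
    """Direction and timing of one entity's response to the perturbation."""

    entity_id: str
    direction: str  # up | down | unchanged
    timing: str  # early_BTS | late_ATS | unaltered
    onset_time: Optional[float]
    max_abs_log2fc: float

    def __post_init__(self) -> None:
        unchanged = self.direction == "unchanged"
        if unchanged != (self.timing == "unaltered") or unchanged != (
            self.onset_time is None
        ):
            raise ValueError("inconsistent response call")


@dataclass
class SIMMotif:
    """Single-input motif: one regulator, >=2 exclusive targets."""

    regulator_id: str
    target_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.target_ids) < 2:
            raise ValueError("SIM requires at least 2 targets")


@dataclass
class HubCall:
    """A TF called as a regulatory hub, with its typing evidence."""

    tf_id: str
    whole_network_degree: int
    rank_percentile: float
    subnetwork_degrees: dict[str, int] = field(default_factory=dict)
    qualifying_subnetworks: tuple[str, ...] = ()
    hub_type: str = "unclassified"
    phase_edge_counts: tuple[int, int, int] = (0, 0, 0)  # (n_BTS, n_ATS, n_mixed)


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate an annotation table (index entity_id).

    Columns: ``entity_class``, ``family`` (may be empty for non-regulators),
    ``processes`` (tuple of labels from the closed vocabulary).
    """
    bad_class = set(annotations["entity_class"]) - ENTITY_CLASSES
    if bad_class:
        raise ValueError(f"unknown entity class: {sorted(bad_class)}")
    for eid, procs in annotations["processes"].items():
        unknown = set(procs) - PROCESS_SET
        if unknown:
            raise ValueError(f"unknown process label: {sorted(unknown)} ({eid})")
    regs = annotations["entity_class"].isin(REGULATOR_CLASSES)
    fam = annotations.loc[regs, "family"]
    if fam.isna().any() or (fam == "").any():
        raise ValueError("regulator without family")
    if annotations.index.duplicated().any():
        raise ValueError("duplicate entity id in annotations")
    return annotations
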