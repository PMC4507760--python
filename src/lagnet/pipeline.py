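"""End-to-end orchestration: fold change -> correlation -> network -> hubs.

Each stage is a plain function over in-memory objects; the CLI wraps them
with file I/O so any stage can be re-run independently. ``run_pipeline``
chains all stages and returns a `PipelineResult` carrying every
intermediate, which the tests and the recovery scoring use directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import pandas as pd

from .config import AnalysisConfig
from .datamodel import (
    REGULATOR_CLASSES,
    CorrelationEdge,
    HubCall,
    ResponseCall,
    SIMMotif,
    TimeCourseMatrix,
)
from .hubs import call_hubs, hub_process_table, type_hubs
from .lagcorr import correlate_all
from .netbuild import (
    DegreeStats,
    build_network,
    degree_stats,
    find_sims,
    merge_motifs,
    process_subnetwork,
)
from .preprocess import (
    DifferentialSelection,
    FoldChangeMatrix,
    classify_all,
    fold_change,
    normality_report,
    select_differential,
)


@dataclass
class PipelineResult:
    config: AnalysisConfig
    fold_changes: FoldChangeMatrix
    response_calls: dict[str, ResponseCall]
    selection: DifferentialSelection
    edges: list[CorrelationEdge]
    audit: Optional[pd.DataFrame]
    network: nx.Graph
    subnetworks: dict[str, nx.Graph]
    sims: list[SIMMotif]
    sim_subnetwork: nx.Graph
    degree_statistics: Optional[DegreeStats]
    hub_calls: list[HubCall]
    participation: pd.DataFrame
    normality: dict[str, pd.DataFrame]
    filter_counts: dict[str, int] = field(default_factory=dict)

    @property
    def called_edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.tf_id, e.target_id) for e in self.edges}

    @property
    def called_hub_types(self) -> dict[str, str]:
        return {h.tf_id: h.hub_type for h in self.hub_calls}


def run_pipeline(
    tc: TimeCourseMatrix,
    annotations: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    keep_audit: bool = False,
) -> PipelineResult:
    """Run the full analysis on one time-course dataset."""
    config = config or AnalysisConfig()
    counts: dict[str, int] = {"entities_in": len(tc.entity_ids)}

    # fold change and response classification
    fcm = fold_change(tc)
    counts["entities_excluded_zero_baseline"] = len(fcm.excluded)
    calls = classify_all(fcm, config)
    selection = select_differential(fcm, annotations, config, calls=calls)
    counts["responders"] = len(selection.responder_ids)
    counts["responder_tfs"] = len(selection.tf_ids)

    # normality diagnostics per data type (recorded, never a gate)
    lo, hi = config.correlation_window
    window_fc = fcm.window(lo, hi)
    cls = annotations["entity_class"]
    transcript_ids = [
        e for e in window_fc.index
        if cls.get(e) in REGULATOR_CLASSES | {"metabolic_gene", "protein"}
    ]
    metabolite_ids = [e for e in window_fc.index if cls.get(e) == "metabolite"]
    normality = {
        "transcripts": normality_report(window_fc.loc[transcript_ids]),
        "metabolites": normality_report(window_fc.loc[metabolite_ids]),
    }

    # time-lagged correlation, strictly bipartite on differential entities
    target_ids = [
        e for e in selection.responder_ids
        if cls.get(e) not in REGULATOR_CLASSES and e in window_fc.index
    ]
    tf_ids = [e for e in selection.tf_ids if e in window_fc.index]
    edges, audit = correlate_all(
        window_fc.loc[tf_ids],
        window_fc.loc[target_ids],
        cls,
        config,
        keep_audit=keep_audit,
    )
    counts["pairs_tested"] = len(tf_ids) * len(target_ids)
    counts["edges_retained"] = len(edges)
    counts["pairs_rejected"] = counts["pairs_tested"] - len(edges)

    # network, subnetworks, motifs, degree diagnostics
    net = build_network(edges, annotations)
    subnets = {}
    for label in sorted({p for procs in annotations["processes"] for p in procs}):
        subnets[label] = process_subnetwork(net, label)
    sims = find_sims(net)
    sim_subnet = merge_motifs(sims, net)
    dstats = degree_stats(net) if net.number_of_nodes() else None

    # hub calling and typing
    tf_universe = int(cls.isin(REGULATOR_CLASSES).sum())
    raw_hubs = call_hubs(
        net, subnets, hub_fraction=config.hub_fraction,
        subnetwork_rule=config.hub_subnetwork_rule,
        tf_universe=tf_universe,
    )
    hubs_typed = type_hubs(raw_hubs, net, calls, annotations, config, sims=sims)
    counts["hubs_called"] = len(hubs_typed)
    participation = hub_process_table(hubs_typed, net, annotations)

    return PipelineResult(
        config=config,
        fold_changes=fcm,
        response_calls=calls,
        selection=selection,
        edges=edges,
        audit=audit,
        network=net,
        subnetworks=subnets,
        sims=sims,
        sim_subnetwork=sim_subnet,
        degree_statistics=dstats,
        hub_calls=hubs_typed,
        participation=participation,
        normality=normality,
        filter_counts=counts,
    )
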