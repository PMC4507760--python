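"""Regulatory hub calling and typing.

A hub is a TF/TR node in the top 5% of regulator degrees in *both* the whole
network and at least one process subnetwork (ranking among regulator nodes
with degree >= 1; k = ceil(fraction x n) with all ties at the k-th degree
included, so the call is invariant to node relabeling).

Hubs are then typed by the phase of their correlated partners' responses:
partners responding only before TAG-synthesis onset make a BTS-specific hub,
only after it an ATS-specific hub, and both phases a permanent hub — a
regulator whose influence persists across the perturbation. Condition-
specific hubs must additionally drive a single-input motif whose targets
span at least two biological processes; hubs failing that stay unclassified.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .config import AnalysisConfig
from .datamodel import PROCESSES, HubCall, ResponseCall, SIMMotif
from .netbuild import find_sims, regulator_nodes


def top_regulator_set(
    net: nx.Graph, fraction: float, tf_universe: Optional[int] = None
) -> dict[str, int]:
    """Top-``fraction`` regulator nodes by degree, ties at the cut included.

    Only regulators with degree >= 1 are callable. ``tf_universe`` is the
    size of the TF/TR set the ranking is taken over — the full analyzed
    regulator complement of the dataset; when None it falls back to the
    number of degree >= 1 regulators in the network. Returns {tf_id: degree}.
    """
    degs = {n: net.degree(n) for n in regulator_nodes(net) if net.degree(n) >= 1}
    if not degs:
        return {}
    base = tf_universe if tf_universe is not None else len(degs)
    k = min(math.ceil(fraction * base), len(degs))
    cutoff = sorted(degs.values(), reverse=True)[k - 1]
    return {n: d for n, d in degs.items() if d >= cutoff}


def call_hubs(
    whole_net: nx.Graph,
    subnetworks: Mapping[str, nx.Graph],
    hub_fraction: float = 0.05,
    subnetwork_rule: str = "any",
    tf_universe: Optional[int] = None,
) -> list[HubCall]:
    """Hubs: top-5% in the whole network and in >=1 ("any") or every ("all")
    process subnetwork where the TF participates."""
    whole_top = top_regulator_set(whole_net, hub_fraction, tf_universe)
    sub_top = {
        label: top_regulator_set(sub, hub_fraction, tf_universe)
        for label, sub in subnetworks.items()
    }
    all_degs = sorted(
        (whole_net.degree(n) for n in regulator_nodes(whole_net) if whole_net.degree(n) >= 1),
        reverse=True,
    )
    calls = []
    for tf in sorted(whole_top):
        qualifying = tuple(label for label, top in sub_top.items() if tf in top)
        if subnetwork_rule == "any":
            ok = len(qualifying) >= 1
        else:  # all subnetworks in which the TF has degree >= 1
            member = [
                label
                for label, sub in subnetworks.items()
                if tf in sub and sub.degree(tf) >= 1
            ]
            ok = bool(member) and all(tf in sub_top[label] for label in member)
        if not ok:
            continue
        deg = whole_top[tf]
        rank = sum(1 for d in all_degs if d > deg) + 1
        calls.append(
            HubCall(
                tf_id=tf,
                whole_network_degree=deg,
                rank_percentile=100.0 * (1.0 - (rank - 1) / len(all_degs)),
                subnetwork_degrees={
                    label: sub.degree(tf)
                    for label, sub in subnetworks.items()
                    if tf in sub and sub.degree(tf) >= 1
                },
                qualifying_subnetworks=qualifying,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# phase attribution and typing
# ---------------------------------------------------------------------------

def _window_of(onset: Optional[float], config: AnalysisConfig) -> Optional[str]:
    if onset is None:
        return None
    lo, hi = config.bts_window
    if lo < onset <= hi:
        return "BTS"
    lo, hi = config.ats_window
    if lo <= onset <= hi:
        return "ATS"
    return "outside"


def assign_edge_phase(
    edge: tuple[str, str],
    response_calls: Mapping[str, ResponseCall],
    config: AnalysisConfig,
    mode: Optional[str] = None,
) -> str:
    """Phase of a (regulator, target) edge: BTS, ATS, mixed or none.

    ``mode`` defaults to ``config.phase_mode``. In "strict" mode both
    endpoints' onsets must fall in the same window (edges split across
    windows are "mixed"); in "target" mode the phase follows the target's
    onset window, requiring only that the regulator responded at all.
    "none" whenever either endpoint is unaltered.
    """
    mode = mode or config.phase_mode
    tf_id, target_id = edge
    for eid in edge:
        if eid not in response_calls:
            raise KeyError(f"unclassified endpoint: {eid}")
    tf_call, tgt_call = response_calls[tf_id], response_calls[target_id]
    if tf_call.direction == "unchanged" or tgt_call.direction == "unchanged":
        return "none"
    tgt_win = _window_of(tgt_call.onset_time, config)
    if mode == "target":
        return tgt_win if tgt_win in ("BTS", "ATS") else "mixed"
    tf_win = _window_of(tf_call.onset_time, config)
    if tf_win == tgt_win and tf_win in ("BTS", "ATS"):
        return tf_win
    return "mixed"


def type_hubs(
    hub_calls: Sequence[HubCall],
    net: nx.Graph,
    response_calls: Mapping[str, ResponseCall],
    annotations: pd.DataFrame,
    config: AnalysisConfig,
    sims: Optional[Sequence[SIMMotif]] = None,
) -> list[HubCall]:
    """Assign each hub its type from clear-phase edges only.

    BTS-only partners -> BTS_specific, ATS-only -> ATS_specific, both ->
    permanent, neither -> unclassified. Specific hubs must be a SIM
    regulator whose motif targets span >= 2 biological processes.
    """
    if sims is None:
        sims = find_sims(net)
    sim_by_reg = {m.regulator_id: m for m in sims}
    typed = []
    for call in hub_calls:
        n_bts = n_ats = n_mixed = 0
        for nb in net.neighbors(call.tf_id):
            phase = assign_edge_phase((call.tf_id, nb), response_calls, config)
            if phase == "BTS":
                n_bts += 1
            elif phase == "ATS":
                n_ats += 1
            elif phase == "mixed":
                n_mixed += 1
        if n_bts and n_ats:
            hub_type = "permanent"
        elif n_bts or n_ats:
            hub_type = "BTS_specific" if n_bts else "ATS_specific"
            motif = sim_by_reg.get(call.tf_id)
            if motif is None:
                hub_type = "unclassified"
            else:
                procs = set()
                for tgt in motif.target_ids:
                    procs.update(annotations.loc[tgt, "processes"])
                if len(procs) < 2:
                    hub_type = "unclassified"
        else:
            hub_type = "unclassified"
        typed.append(
            HubCall(
                tf_id=call.tf_id,
                whole_network_degree=call.whole_network_degree,
                rank_percentile=call.rank_percentile,
                subnetwork_degrees=call.subnetwork_degrees,
                qualifying_subnetworks=call.qualifying_subnetworks,
                hub_type=hub_type,
                phase_edge_counts=(n_bts, n_ats, n_mixed),
            )
        )
    return typed


_TYPE_ORDER = {"BTS_specific": 0, "ATS_specific": 1, "permanent": 2, "unclassified": 3}


def hub_process_table(
    hub_calls: Sequence[HubCall],
    net: nx.Graph,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Process-participation matrix: one column per hub (grouped by type),
    one row per biological process, plus a final whole-network degree row.

    A cell is 1 when the hub has at least one correlated partner annotated
    with that process.
    """
    ordered = sorted(
        hub_calls, key=lambda c: (_TYPE_ORDER[c.hub_type], -c.whole_network_degree)
    )
    data = {}
    for call in ordered:
        procs = set()
        for nb in net.neighbors(call.tf_id):
            procs.update(annotations.loc[nb, "processes"])
        col = {proc: int(proc in procs) for proc in PROCESSES}
        col["degree"] = call.whole_network_degree
        data[call.tf_id] = col
    table = pd.DataFrame(data, index=list(PROCESSES) + ["degree"])
    table.attrs["hub_types"] = {c.tf_id: c.hub_type for c in ordered}
    return table
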