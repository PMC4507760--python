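"""Hub calling (top-5% degree rule), edge-phase attribution, and typing."""

import math

import networkx as nx
import numpy as np
import pytest

from lagnet import AnalysisConfig, CorrelationEdge, build_network, call_hubs
from lagnet.datamodel import PROCESSES, REGULATOR_CLASSES, ResponseCall
from lagnet.hubs import assign_edge_phase, hub_process_table, top_regulator_set, type_hubs
from lagnet.netbuild import process_subnetwork

from conftest import make_annotations


def edge(tf, tgt, r=0.95):
    return CorrelationEdge(tf, tgt, "metabolic_gene", r, 0, 7, 1e-4)


def star_plus_singletons(n_tf=20, hub_degree=10):
    rows = [(f"T{i}", "TF", "bHLH", (PROCESSES[0],)) for i in range(n_tf)]
    rows += [(f"g{i}", "metabolic_gene", "", (PROCESSES[0],)) for i in range(hub_degree + n_tf)]
    ann = make_annotations(rows)
    edges = [edge("T0", f"g{i}") for i in range(hub_degree)]
    edges += [edge(f"T{i}", f"g{hub_degree + i}") for i in range(1, n_tf)]
    net = build_network(edges, ann)
    return net, ann


def brute_force_hubs(whole, subnets, fraction, universe=None):
    """Sort-and-intersect oracle written independently of call_hubs."""
    def top(net):
        degs = sorted(
            ((net.degree(n), n) for n, c in net.nodes(data="entity_class")
             if c in REGULATOR_CLASSES and net.degree(n) >= 1),
            reverse=True,
        )
        if not degs:
            return set()
        base = universe if universe is not None else len(degs)
        k = min(math.ceil(fraction * base), len(degs))
        cut = degs[k - 1][0]
        return {n for d, n in degs if d >= cut}

    whole_top = top(whole)
    sub_tops = [top(s) for s in subnets.values()]
    return {n for n in whole_top if any(n in s for s in sub_tops)}


class TestCallHubs:
    def test_single_dominant_tf_is_the_only_hub(self):
        net, _ = star_plus_singletons()
        subs = {"lipid": process_subnetwork(net, "lipid")}
        hubs = call_hubs(net, subs, hub_fraction=0.05)
        assert [h.tf_id for h in hubs] == ["T0"]
        assert hubs[0].whole_network_degree == 10

    def test_all_tied_tfs_are_all_called(self):
        rows = [(f"T{i}", "TF", "bHLH", (PROCESSES[0],)) for i in range(10)]
        rows += [(f"g{i}", "metabolic_gene", "", (PROCESSES[0],)) for i in range(10)]
        ann = make_annotations(rows)
        net = build_network([edge(f"T{i}", f"g{i}") for i in range(10)], ann)
        subs = {"lipid": process_subnetwork(net, "lipid")}
        hubs = call_hubs(net, subs, hub_fraction=0.05)
        assert len(hubs) == 10  # everyone tied at the k-th degree value

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(f"T{i}", "TF", "bHLH", (PROCESSES[i % 10],)) for i in range(12)]
        rows += [(f"g{i}", "metabolic_gene", "", (PROCESSES[i % 10],)) for i in range(30)]
        ann = make_annotations(rows)
        edges = [
            edge(f"T{i}", f"g{j}")
            for i in range(12)
            for j in range(30)
            if rng.random() < 0.15
        ]
        net = build_network(edges, ann)
        subs = {p: process_subnetwork(net, p) for p in PROCESSES}
        got = {h.tf_id for h in call_hubs(net, subs, hub_fraction=0.05)}
        assert got == brute_force_hubs(net, subs, 0.05)
        got_u = {h.tf_id for h in call_hubs(net, subs, 0.05, tf_universe=40)}
        assert got_u == brute_force_hubs(net, subs, 0.05, universe=40)

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(3)
        rows = [(f"T{i}", "TF", "bHLH", (PROCESSES[i % 10],)) for i in range(8)]
        rows += [(f"g{i}", "metabolic_gene", "", (PROCESSES[i % 10],)) for i in range(20)]
        ann = make_annotations(rows)
        edges = [
            edge(f"T{i}", f"g{j}") for i in range(8) for j in range(20)
            if rng.random() < 0.2
        ]
        net = build_network(edges, ann)
        subs = {p: process_subnetwork(net, p) for p in PROCESSES}
        hubs = {h.tf_id for h in call_hubs(net, subs, 0.2)}

        mapping = {n: f"X_{n}" for n in net.nodes}
        ann2 = ann.copy()
        ann2.index = [mapping[i] if i in mapping else i for i in ann.index]
        edges2 = [
            CorrelationEdge(mapping[u], mapping[v], "metabolic_gene",
                            d["r"], d["lag"], d["n_pairs"], d["p"])
            for u, v, d in net.edges(data=True)
            for u, v in [(u, v) if net.nodes[u]["entity_class"] == "TF" else (v, u)]
        ]
        net2 = build_network(edges2, ann2)
        subs2 = {p: process_subnetwork(net2, p) for p in PROCESSES}
        hubs2 = {h.tf_id for h in call_hubs(net2, subs2, 0.2)}
        assert hubs2 == {mapping[h] for h in hubs}

    def test_raising_fraction_never_removes_a_hub(self):
        net, _ = star_plus_singletons()
        subs = {"lipid": process_subnetwork(net, "lipid")}
        prev: set = set()
        for frac in (0.05, 0.1, 0.3, 0.6, 0.95):
            cur = {h.tf_id for h in call_hubs(net, subs, frac)}
            assert prev <= cur
            prev = cur

    def test_empty_network_gives_no_hubs(self):
        assert call_hubs(nx.Graph(), {}, 0.05) == []


def _call(eid, direction, onset):
    timing = (
        "unaltered" if direction == "unchanged"
        else ("early_BTS" if onset is not None and onset <= 4 else "late_ATS")
    )
    return ResponseCall(eid, direction, timing, onset, 2.0 if onset else 0.0)


class TestEdgePhase:
    def test_both_endpoints_early_is_bts(self, strict_config):
        calls = {"tf": _call("tf", "up", 1.0), "g": _call("g", "up", 2.0)}
        assert assign_edge_phase(("tf", "g"), calls, strict_config) == "BTS"

    def test_split_onsets_are_mixed_in_strict_mode(self, strict_config):
        calls = {"tf": _call("tf", "up", 2.0), "g": _call("g", "up", 12.0)}
        assert assign_edge_phase(("tf", "g"), calls, strict_config) == "mixed"

    def test_split_onsets_follow_target_in_target_mode(self, config):
        calls = {"tf": _call("tf", "up", 2.0), "g": _call("g", "up", 12.0)}
        assert assign_edge_phase(("tf", "g"), calls, config) == "ATS"

    def test_unaltered_endpoint_is_none(self, config, strict_config):
        calls = {"tf": _call("tf", "up", 1.0), "g": _call("g", "unchanged", None)}
        assert assign_edge_phase(("tf", "g"), calls, config) == "none"
        assert assign_edge_phase(("tf", "g"), calls, strict_config) == "none"

    def test_missing_call_raises(self, config):
        calls = {"tf": _call("tf", "up", 1.0)}
        with pytest.raises(KeyError, match="unclassified endpoint"):
            assign_edge_phase(("tf", "g"), calls, config)


class TestTypeHubs:
    def _typed(self, onsets: dict[str, float | None], config=None):
        config = config or AnalysisConfig()
        rows = [("T0", "TF", "bHLH", ()), ("T1", "TF", "GNAT", ())]
        rows += [
            (g, "metabolic_gene", "", (PROCESSES[i % 3],))
            for i, g in enumerate(onsets)
        ]
        ann = make_annotations(rows)
        net = build_network([edge("T0", g) for g in onsets], ann)
        calls = {"T0": _call("T0", "up", 1.0), "T1": _call("T1", "up", 1.0)}
        calls.update(
            {g: _call(g, "up" if o else "unchanged", o) for g, o in onsets.items()}
        )
        hubs = call_hubs(net, {"lipid": process_subnetwork(net, "lipid")}, 0.5)
        return type_hubs(hubs, net, calls, ann, config)

    def test_all_early_partners_make_bts_specific(self):
        typed = self._typed({"g0": 1.0, "g1": 2.0, "g2": 4.0})
        assert typed[0].hub_type == "BTS_specific"
        assert typed[0].phase_edge_counts == (3, 0, 0)

    def test_all_late_partners_make_ats_specific(self):
        typed = self._typed({"g0": 6.0, "g1": 12.0, "g2": 24.0})
        assert typed[0].hub_type == "ATS_specific"

    def test_both_phases_make_permanent(self):
        typed = self._typed({"g0": 1.0, "g1": 2.0, "g2": 12.0})
        assert typed[0].hub_type == "permanent"
        assert typed[0].phase_edge_counts == (2, 1, 0)

    def test_no_clear_edges_stays_unclassified(self):
        typed = self._typed({"g0": None, "g1": None})
        assert typed[0].hub_type == "unclassified"

    def test_specific_hub_needs_multi_process_sim(self):
        # both targets in the same process: the SIM spans only 1 process
        config = AnalysisConfig()
        rows = [("T0", "TF", "bHLH", ())]
        rows += [(g, "metabolic_gene", "", (PROCESSES[0],)) for g in ("g0", "g1")]
        ann = make_annotations(rows)
        net = build_network([edge("T0", "g0"), edge("T0", "g1")], ann)
        calls = {
            "T0": _call("T0", "up", 1.0),
            "g0": _call("g0", "up", 1.0),
            "g1": _call("g1", "up", 2.0),
        }
        hubs = call_hubs(net, {"lipid": process_subnetwork(net, "lipid")}, 0.5)
        typed = type_hubs(hubs, net, calls, ann, config)
        assert typed[0].hub_type == "unclassified"

    def test_each_hub_gets_exactly_one_type(self):
        typed = self._typed({"g0": 1.0, "g1": 6.0, "g2": 24.0, "g3": None})
        assert sum(
            typed[0].hub_type == t
            for t in ("BTS_specific", "ATS_specific", "permanent", "unclassified")
        ) == 1


class TestParticipationTable:
    def test_marks_and_degree_row(self):
        rows = [("T0", "TF", "bHLH", ())]
        rows += [("g0", "metabolic_gene", "", (PROCESSES[0],)),
                 ("g1", "metabolic_gene", "", (PROCESSES[1],))]
        ann = make_annotations(rows)
        net = build_network([edge("T0", "g0"), edge("T0", "g1")], ann)
        hubs = call_hubs(net, {p: process_subnetwork(net, p) for p in PROCESSES}, 0.5)
        table = hub_process_table(hubs, net, ann)
        assert table.loc[PROCESSES[0], "T0"] == 1
        assert table.loc[PROCESSES[2], "T0"] == 0
        assert table.loc["degree", "T0"] == 2
        assert table.drop(index="degree")["T0"].sum() == 2
        assert list(table.index) == list(PROCESSES) + ["degree"]
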