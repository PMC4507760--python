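"""Network assembly, subnetworks, SIM mining, and degree diagnostics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from lagnet import CorrelationEdge, build_network, degree_stats, find_sims, merge_motifs
from lagnet.datamodel import PROCESSES, REGULATOR_CLASSES
from lagnet.netbuild import process_subnetwork

from conftest import make_annotations


def edge(tf, tgt, r=0.95, lag=0, cls="metabolic_gene"):
    return CorrelationEdge(tf, tgt, cls, r, lag, 7, 1e-4)


def brute_force_sims(net):
    """Exhaustive SIM enumeration: check every regulator against every
    target subset via the exclusivity definition (independent of find_sims)."""
    regs = {n for n, c in net.nodes(data="entity_class") if c in REGULATOR_CLASSES}
    motifs = {}
    for reg in regs:
        exclusive = set()
        for tgt in net.neighbors(reg):
            tf_neighbors = {n for n in net.neighbors(tgt) if n in regs}
            if tf_neighbors == {reg}:
                exclusive.add(tgt)
        if len(exclusive) >= 2:
            motifs[reg] = frozenset(exclusive)
    return motifs


def random_network(rng, n_tf=8, n_tgt=22, p=0.12):
    rows = [(f"T{i}", "TF", "bHLH", (PROCESSES[i % 10],)) for i in range(n_tf)]
    rows += [(f"g{i}", "metabolic_gene", "", (PROCESSES[i % 10],)) for i in range(n_tgt)]
    ann = make_annotations(rows)
    edges = [
        edge(f"T{i}", f"g{j}")
        for i in range(n_tf)
        for j in range(n_tgt)
        if rng.random() < p
    ]
    return build_network(edges, ann), ann


class TestBuildNetwork:
    def test_small_network_counts(self, tiny_annotations):
        net = build_network(
            [edge("TF1", "g1"), edge("TF1", "g2"), edge("TF1", "m1")],
            tiny_annotations,
        )
        assert net.number_of_nodes() == 4 and net.number_of_edges() == 3

    def test_tf_tf_edge_rejected(self, tiny_annotations):
        with pytest.raises(ValueError, match="bipartite violation"):
            build_network([edge("TF1", "TF2")], tiny_annotations)

    def test_unannotated_endpoint_rejected(self, tiny_annotations):
        with pytest.raises(ValueError, match="unannotated node"):
            build_network([edge("TF1", "ghost")], tiny_annotations)

    def test_duplicates_deduplicated_keeping_strongest(self, tiny_annotations):
        edges = [edge("TF1", "g1", r=0.91), edge("TF1", "g1", r=-0.97)]
        net = build_network(edges, tiny_annotations)
        assert net.number_of_edges() == 1
        assert net["TF1"]["g1"]["r"] == -0.97

    def test_rebuild_from_own_edges_is_idempotent(self, tiny_annotations):
        net = build_network([edge("TF1", "g1"), edge("TF2", "m1")], tiny_annotations)
        edges2 = [
            CorrelationEdge(u, v, net.nodes[v]["entity_class"], d["r"], d["lag"],
                            d["n_pairs"], d["p"])
            for u, v, d in net.edges(data=True)
        ]
        net2 = build_network(edges2, tiny_annotations)
        assert nx.utils.graphs_equal(net, net2)


class TestProcessSubnetwork:
    def test_membership_follows_annotation(self, tiny_annotations):
        net = build_network([edge("TF1", "g1"), edge("TF1", "g2")], tiny_annotations)
        sub = process_subnetwork(net, "lipid")
        assert "g1" in sub and "g2" not in sub
        assert "TF1" in sub

    def test_unknown_label_rejected(self, tiny_annotations):
        net = build_network([edge("TF1", "g1")], tiny_annotations)
        with pytest.raises(ValueError, match="unknown process label"):
            process_subnetwork(net, "glycolysis2")

    def test_empty_process_keeps_tfs_no_edges(self, tiny_annotations):
        net = build_network([edge("TF1", "g1")], tiny_annotations)
        sub = process_subnetwork(net, "oppp")
        assert set(sub.nodes) == {"TF1"} and sub.number_of_edges() == 0

    def test_union_of_subnetwork_edges_covers_whole_network(self):
        rng = np.random.default_rng(0)
        net, _ = random_network(rng)
        union = set()
        for label in PROCESSES:
            union |= set(map(frozenset, process_subnetwork(net, label).edges))
        assert union == set(map(frozenset, net.edges))

    def test_subnetworks_are_subgraphs(self):
        rng = np.random.default_rng(1)
        net, _ = random_network(rng)
        for label in PROCESSES[:4]:
            sub = process_subnetwork(net, label)
            assert set(sub.nodes) <= set(net.nodes)
            assert set(map(frozenset, sub.edges)) <= set(map(frozenset, net.edges))


class TestSIMs:
    def test_pure_star_is_one_motif(self, tiny_annotations):
        net = build_network(
            [edge("TF1", "g1"), edge("TF1", "g2"), edge("TF1", "m1")],
            tiny_annotations,
        )
        motifs = find_sims(net)
        assert len(motifs) == 1
        assert motifs[0].regulator_id == "TF1"
        assert motifs[0].target_ids == frozenset({"g1", "g2", "m1"})

    def test_shared_target_excluded_from_motif(self, tiny_annotations):
        net = build_network(
            [edge("TF1", "g1"), edge("TF1", "g2"), edge("TF1", "m1"),
             edge("TF2", "g2")],
            tiny_annotations,
        )
        (motif,) = [m for m in find_sims(net) if m.regulator_id == "TF1"]
        assert motif.target_ids == frozenset({"g1", "m1"})

    def test_single_exclusive_target_is_no_motif(self, tiny_annotations):
        net = build_network([edge("TF1", "g1")], tiny_annotations)
        assert find_sims(net) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        net, _ = random_network(rng)
        got = {m.regulator_id: m.target_ids for m in find_sims(net)}
        assert got == brute_force_sims(net)

    def test_motifs_disjoint_in_targets(self):
        rng = np.random.default_rng(99)
        net, _ = random_network(rng, n_tf=10, n_tgt=30, p=0.2)
        motifs = find_sims(net)
        seen = set()
        for m in motifs:
            assert not (m.target_ids & seen)
            seen |= m.target_ids

    def test_merge_counts_and_star_identity(self, tiny_annotations):
        net = build_network(
            [edge("TF1", "g1"), edge("TF1", "g2"), edge("TF2", "m1")],
            tiny_annotations,
        )
        motifs = find_sims(net)
        merged = merge_motifs(motifs, net)
        assert merged.number_of_edges() == sum(len(m.target_ids) for m in motifs)
        assert set(merged.nodes) == {"TF1", "g1", "g2"}

    def test_merge_of_nothing_is_empty(self, tiny_annotations):
        net = build_network([edge("TF1", "g1")], tiny_annotations)
        merged = merge_motifs([], net)
        assert merged.number_of_nodes() == 0


class TestDegreeStats:
    def _annotated(self, g):
        for n in g.nodes:
            g.nodes[n]["entity_class"] = "TF" if str(n).startswith("T") else "metabolic_gene"
        return g

    def test_star_histogram(self):
        g = nx.star_graph(50)
        g = nx.relabel_nodes(g, {0: "T0", **{i: f"g{i}" for i in range(1, 51)}})
        stats = degree_stats(self._annotated(g))
        assert max(stats.all_degree_hist) == 50
        assert stats.all_degree_hist[1] == 50
        assert sum(stats.all_degree_hist.values()) == 51

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            degree_stats(nx.Graph())

    def test_powerlaw_exponent_recovered_from_configuration_model(self):
        rng = np.random.default_rng(0)
        seq = [int(d) for d in rng.zipf(2.5, size=2000) if d <= 300]
        if sum(seq) % 2:
            seq[0] += 1
        g = nx.configuration_model(seq, seed=0)
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
        g = nx.relabel_nodes(g, {n: f"T{n}" for n in g.nodes})
        stats = degree_stats(self._annotated(g))
        assert stats.exponent == pytest.approx(2.5, abs=0.4)
        assert stats.scale_free_like is True

    def test_erdos_renyi_not_scale_free(self):
        g = nx.gnp_random_graph(2000, 4 / 2000, seed=0)
        g = nx.relabel_nodes(g, {n: f"T{n}" for n in g.nodes})
        stats = degree_stats(self._annotated(g))
        assert stats.scale_free_like in (False, None)
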