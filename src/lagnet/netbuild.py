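"""Network assembly, process/motif subnetworks, and degree diagnostics.

The regulatory network is an undirected signed graph with a bipartite
constraint: every edge joins a TF/TR node to a non-TF node (metabolic gene,
protein or metabolite). Correlation is symmetric, so edges are undirected;
"regulator/target" is presentational and the TF endpoint is stored first on
export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    PROCESS_SET,
    REGULATOR_CLASSES,
    CorrelationEdge,
    SIMMotif,
)


def build_network(
    edges: Iterable[CorrelationEdge],
    annotations: pd.DataFrame,
    keep_isolated: bool = False,
    name: str = "whole",
) -> nx.Graph:
    """Assemble the signed tripartite network from retained edges.

    Duplicate edges on a node pair are deduplicated keeping the larger |r|.
    Isolated annotated nodes are excluded unless ``keep_isolated``.
    """
    g = nx.Graph(name=name)
    if keep_isolated:
        for eid, row in annotations.iterrows():
            g.add_node(
                eid,
                entity_class=row["entity_class"],
                family=row["family"],
                processes=tuple(row["processes"]),
            )
    cls = annotations["entity_class"]
    for e in edges:
        for endpoint in (e.tf_id, e.target_id):
            if endpoint not in annotations.index:
                raise ValueError(f"unannotated node: {endpoint}")
        tf_cls, tgt_cls = cls[e.tf_id], cls[e.target_id]
        if tf_cls not in REGULATOR_CLASSES or tgt_cls in REGULATOR_CLASSES:
            raise ValueError(
                f"bipartite violation: {e.tf_id} ({tf_cls}) -- {e.target_id} ({tgt_cls})"
            )
        if g.has_edge(e.tf_id, e.target_id) and abs(g[e.tf_id][e.target_id]["r"]) >= abs(e.r):
            continue
        for endpoint in (e.tf_id, e.target_id):
            row = annotations.loc[endpoint]
            g.add_node(
                endpoint,
                entity_class=row["entity_class"],
                family=row["family"],
                processes=tuple(row["processes"]),
            )
        g.add_edge(
            e.tf_id,
            e.target_id,
            r=e.r,
            lag=e.lag,
            n_pairs=e.n_pairs,
            p=e.p,
            sign=e.sign,
        )
    return g


def regulator_nodes(net: nx.Graph) -> list[str]:
    return [n for n, c in net.nodes(data="entity_class") if c in REGULATOR_CLASSES]


def target_nodes(net: nx.Graph) -> list[str]:
    return [n for n, c in net.nodes(data="entity_class") if c not in REGULATOR_CLASSES]


def process_subnetwork(net: nx.Graph, process_label: str) -> nx.Graph:
    """Induced subnetwork: all TF/TR nodes plus the process's non-TF nodes."""
    if process_label not in PROCESS_SET:
        raise ValueError(f"unknown process label: {process_label}")
    keep = set(regulator_nodes(net))
    keep.update(
        n
        for n in target_nodes(net)
        if process_label in net.nodes[n].get("processes", ())
    )
    sub = net.subgraph(keep).copy()
    sub.graph["name"] = process_label
    return sub


def find_sims(net: nx.Graph) -> list[SIMMotif]:
    """Mine single-input motifs.

    For each regulator t, collect the targets whose *only* regulator
    neighbor is t; a motif is emitted when at least two such exclusive
    targets exist. Motifs are disjoint in targets by construction.
    """
    regs = set(regulator_nodes(net))
    exclusive: dict[str, set[str]] = {}
    for tgt in target_nodes(net):
        reg_neighbors = [n for n in net.neighbors(tgt) if n in regs]
        if len(reg_neighbors) == 1:
            exclusive.setdefault(reg_neighbors[0], set()).add(tgt)
    return [
        SIMMotif(regulator_id=reg, target_ids=frozenset(tgts))
        for reg, tgts in sorted(exclusive.items())
        if len(tgts) >= 2
    ]


def merge_motifs(motifs: Sequence[SIMMotif], net: nx.Graph) -> nx.Graph:
    """Merge SIMs into the SIM subnetwork (regulators, targets, their edges)."""
    keep: set[str] = set()
    for m in motifs:
        keep.add(m.regulator_id)
        keep.update(m.target_ids)
    sub = net.subgraph(keep).copy()
    sub.graph["name"] = "SIM"
    return sub


# ---------------------------------------------------------------------------
# degree diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DegreeStats:
    """Degree histograms and a power-law diagnostic.

    The fit is least squares on log-log binned counts (logarithmic bins) of
    the all-node degree distribution; it is a diagnostic of scale-free-like
    structure, not an inferential claim. ``scale_free_like`` is None
    (undetermined) when fewer than 4 non-empty bins exist.
    """

    tf_degree_hist: dict[int, int]
    all_degree_hist: dict[int, int]
    exponent: Optional[float]
    r_squared: Optional[float]
    n_bins: int
    scale_free_like: Optional[bool]


def _log_binned_fit(degrees: np.ndarray) -> tuple[Optional[float], Optional[float], int]:
    degrees = degrees[degrees >= 1]
    if len(degrees) == 0:
        return None, None, 0
    kmax = degrees.max()
    edges = [1]
    while edges[-1] <= kmax:
        edges.append(edges[-1] * 2)
    edges = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / widths
    mask = counts > 0
    n_bins = int(mask.sum())
    if n_bins < 4:
        return None, None, n_bins
    lx = np.log10(centers[mask])
    ly = np.log10(density[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = ((ly - pred) ** 2).sum()
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-slope), float(r2), n_bins


def degree_stats(net: nx.Graph) -> DegreeStats:
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    all_deg = np.array([d for _, d in net.degree()])
    tf_deg = np.array([net.degree(n) for n in regulator_nodes(net)], dtype=int)
    tf_hist = dict(zip(*np.unique(tf_deg, return_counts=True))) if len(tf_deg) else {}
    all_hist = dict(zip(*np.unique(all_deg, return_counts=True)))
    exponent, r2, n_bins = _log_binned_fit(all_deg)
    if exponent is None:
        flag = None
    else:
        flag = bool(1.0 <= exponent <= 4.0 and r2 >= 0.8)
    return DegreeStats(
        tf_degree_hist={int(k): int(v) for k, v in tf_hist.items()},
        all_degree_hist={int(k): int(v) for k, v in all_hist.items()},
        exponent=exponent,
        r_squared=r2,
        n_bins=n_bins,
        scale_free_like=flag,
    )


def plot_degree_distribution(stats: DegreeStats, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = sorted(stats.all_degree_hist)
    cs = [stats.all_degree_hist[k] for k in ks]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.loglog(ks, cs, "o", ms=4)
    ax.set_xlabel("degree k")
    ax.set_ylabel("node count")
    if stats.exponent is not None:
        ax.set_title(f"exponent={stats.exponent:.2f}, R²={stats.r_squared:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)
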