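"""Readers and writers for the tabular and network formats the pipeline touches.

Tabular time courses are accepted in two dialects:

* **long** — columns ``entity_id``, ``time``, ``replicate``, ``value``;
* **wide** — first column ``entity_id``, remaining columns named
  ``<time>_r<replicate>`` (e.g. ``0.5_r1``).

Networks are exported as SIF (interaction labels ``pos``/``neg``), GraphML
(lossless round-trip), and node/edge attribute CSVs with the class->shape
mapping used for Cytoscape styling (TF/TR circles, genes/proteins squares,
metabolites triangles).
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from .datamodel import CLASS_SHAPES, TimeCourseMatrix, validate_annotations

_WIDE_COL = re.compile(r"^(?P<time>\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


# ---------------------------------------------------------------------------
# time-course tables
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def detect_timecourse_format(columns) -> str:
    cols = {str(c).lower() for c in columns}
    if {"entity_id", "time", "replicate", "value"} <= cols:
        return "long"
    if any(_WIDE_COL.match(str(c)) for c in columns):
        return "wide"
    raise ValueError(f"cannot detect time-course dialect from columns {list(columns)}")


def read_timecourse_table(path, format_spec: Optional[str] = None) -> TimeCourseMatrix:
    """Read a long- or wide-format abundance table.

    ``format_spec`` is ``"long"``, ``"wide"`` or None (auto-detect by header).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    fmt = format_spec or detect_timecourse_format(df.columns)
    if fmt == "long":
        df.columns = [str(c).lower() for c in df.columns]
        data = df[["entity_id", "time", "replicate", "value"]].copy()
    elif fmt == "wide":
        id_col = df.columns[0]
        records = []
        for _, row in df.iterrows():
            for col in df.columns[1:]:
                m = _WIDE_COL.match(str(col))
                if not m:
                    raise ValueError(f"bad wide column name: {col!r}")
                if pd.isna(row[col]):
                    continue  # absent replicate, not zero
                records.append(
                    (row[id_col], float(m["time"]), int(m["rep"]), float(row[col]))
                )
        data = pd.DataFrame(records, columns=["entity_id", "time", "replicate", "value"])
    else:
        raise ValueError(f"unknown format_spec: {format_spec!r}")
    data["time"] = data["time"].astype(float)
    data["replicate"] = data["replicate"].astype(int)
    data["value"] = data["value"].astype(float)
    if data["value"].isna().any():
        data = data.dropna(subset=["value"])
    return TimeCourseMatrix(data.reset_index(drop=True))


def write_timecourse_table(tc: TimeCourseMatrix, path, format_spec: str = "long") -> None:
    path = Path(path)
    sep = _sep_for(path)
    if format_spec == "long":
        tc.data.to_csv(path, sep=sep, index=False)
    elif format_spec == "wide":
        wide = tc.data.pivot_table(
            index="entity_id",
            columns=["time", "replicate"],
            values="value",
            aggfunc="first",
            sort=True,
        )
        wide.columns = [f"{t:g}_r{r}" for t, r in wide.columns]
        wide.reset_index().to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown format_spec: {format_spec!r}")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path) -> pd.DataFrame:
    """Read an annotation table: id, class, family (optional), processes.

    Processes are ``;``-separated labels from the closed vocabulary.
    Returns a DataFrame indexed by entity_id with columns ``entity_class``,
    ``family`` and ``processes`` (tuple).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str).fillna("")
    df.columns = [str(c).lower() for c in df.columns]
    df = df.rename(columns={"id": "entity_id", "class": "entity_class"})
    if "family" not in df.columns:
        df["family"] = ""
    if "processes" not in df.columns:
        df["processes"] = ""
    out = pd.DataFrame(
        {
            "entity_class": df["entity_class"].values,
            "family": df["family"].values,
            "processes": [
                tuple(p for p in str(s).split(";") if p) for s in df["processes"]
            ],
        },
        index=pd.Index(df["entity_id"], name="entity_id"),
    )
    return validate_annotations(out)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    path = Path(path)
    out = annotations.copy()
    out["processes"] = [";".join(p) for p in out["processes"]]
    out.reset_index().to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# network exports
# ---------------------------------------------------------------------------

def _edge_rows(net: nx.Graph):
    for u, v, attrs in net.edges(data=True):
        # store TF endpoint first
        if net.nodes[v].get("entity_class") in ("TF", "TR"):
            u, v = v, u
        yield u, v, attrs


def export_network(net: nx.Graph, out_dir, basename: str = "network") -> dict[str, Path]:
    """Write SIF, GraphML and node/edge attribute CSVs for a network."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": out_dir / f"{basename}.sif",
        "graphml": out_dir / f"{basename}.graphml",
        "nodes": out_dir / f"{basename}.nodes.csv",
        "edges": out_dir / f"{basename}.edges.csv",
    }

    with open(paths["sif"], "w") as fh:
        for u, v, attrs in _edge_rows(net):
            label = "pos" if attrs.get("sign", 1) > 0 else "neg"
            fh.write(f"{u} {label} {v}\n")

    with open(paths["nodes"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "entity_class", "shape", "family", "processes"])
        for n, attrs in net.nodes(data=True):
            cls = attrs.get("entity_class", "")
            w.writerow(
                [
                    n,
                    cls,
                    CLASS_SHAPES.get(cls, ""),
                    attrs.get("family", ""),
                    ";".join(attrs.get("processes", ())),
                ]
            )

    with open(paths["edges"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tf_id", "target_id", "target_class", "r", "lag", "n_pairs", "p", "sign"])
        for u, v, attrs in _edge_rows(net):
            w.writerow(
                [
                    u,
                    v,
                    net.nodes[v].get("entity_class", ""),
                    repr(attrs["r"]),
                    attrs["lag"],
                    attrs["n_pairs"],
                    repr(attrs["p"]),
                    attrs["sign"],
                ]
            )

    write_graphml(net, paths["graphml"])
    return paths


def write_graphml(net: nx.Graph, path) -> None:
    g = net.copy()
    for _, attrs in g.nodes(data=True):
        if "processes" in attrs:
            attrs["processes"] = ";".join(attrs["processes"])
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    for _, attrs in g.nodes(data=True):
        if "processes" in attrs:
            attrs["processes"] = tuple(p for p in attrs["processes"].split(";") if p)
    for _, _, attrs in g.edges(data=True):
        for key in ("lag", "n_pairs", "sign"):
            if key in attrs:
                attrs[key] = int(attrs[key])
        for key in ("r", "p"):
            if key in attrs:
                attrs[key] = float(attrs[key])
    return g


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
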