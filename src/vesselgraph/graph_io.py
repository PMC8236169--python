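"""Graph export (CSV / JSON / OBJ), import, and the edge match ratio."""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .feature_annotation import (
    EdgeFeatures,
    PointAttributes,
    VesselGraph,
    VGEdge,
    VGNode,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

CSV_COLUMNS = [
    "edge_id",
    "node_begin",
    "node_end",
    "begin_x", "begin_y", "begin_z",
    "end_x", "end_y", "end_z",
    "length",
    "distance",
    "straightness",
    "volume",
    "avg_cross_section",
    "min_radius_mean", "min_radius_std",
    "max_radius_mean", "max_radius_std",
    "avg_radius_mean", "avg_radius_std",
    "roundness_mean", "roundness_std",
    "bulge_size",
]


def export_csv(graph: VesselGraph, path) -> None:
    """One row per edge with all features; fixed column order, missing empty."""
    rows = []
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        nb = graph.nodes[e.node_begin]
        ne = graph.nodes[e.node_end]
        f = e.features or EdgeFeatures()
        rows.append(
            {
                "edge_id": eid,
                "node_begin": e.node_begin,
                "node_end": e.node_end,
                "begin_x": nb.position[0], "begin_y": nb.position[1], "begin_z": nb.position[2],
                "end_x": ne.position[0], "end_y": ne.position[1], "end_z": ne.position[2],
                **f.as_dict(),
            }
        )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def export_json(graph: VesselGraph, path) -> None:
    """Full graph including per-point centerline attributes; ``.gz`` compresses."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "dims": list(graph.dims),
        "spacing": list(graph.spacing),
        "nodes": [
            {
                "id": nid,
                "position": [float(v) for v in graph.nodes[nid].position],
                "degree": graph.nodes[nid].degree,
                "voxel_count": int(len(graph.nodes[nid].voxels)),
                "voxels": [int(v) for v in graph.nodes[nid].voxels],
            }
            for nid in sorted(graph.nodes)
        ],
        "edges": [],
    }
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        f = e.features or EdgeFeatures()
        attrs = e.attrs
        points = []
        for i, pos in enumerate(e.centerline):
            p = {"position": [float(v) for v in pos]}
            if attrs is not None:
                p.update(
                    volume=float(attrs.volume[i]),
                    n_surface=int(attrs.n_surface[i]),
                    is_inner=bool(attrs.is_inner[i]),
                )
                if attrs.n_surface[i] > 0:
                    p.update(
                        min_dist=float(attrs.min_dist[i]),
                        max_dist=float(attrs.max_dist[i]),
                        avg_dist=float(attrs.sum_dist[i] / attrs.n_surface[i]),
                    )
            points.append(p)
        doc["edges"].append(
            {
                "id": eid,
                "node_begin": e.node_begin,
                "node_end": e.node_end,
                "features": f.as_dict(),
                "centerline": points,
            }
        )
    text = json.dumps(doc)
    if str(path).endswith(".gz"):
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            fh.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def load_json(path) -> VesselGraph:
    """Read a graph written by :func:`export_json`."""
    if str(path).endswith(".gz"):
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            doc = json.load(fh)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    nodes = {}
    for n in doc["nodes"]:
        nodes[n["id"]] = VGNode(
            n["id"],
            np.asarray(n["position"], dtype=np.float64),
            np.asarray(n.get("voxels", []), dtype=np.int64),
            degree=n["degree"],
        )
    edges = {}
    for e in doc["edges"]:
        pts = np.asarray([p["position"] for p in e["centerline"]], dtype=np.float64)
        n = len(pts)
        attrs = PointAttributes.zeros(n)
        for i, p in enumerate(e["centerline"]):
            attrs.volume[i] = p.get("volume", 0.0)
            attrs.n_surface[i] = p.get("n_surface", 0)
            attrs.is_inner[i] = p.get("is_inner", False)
            if attrs.n_surface[i] > 0:
                attrs.min_dist[i] = p["min_dist"]
                attrs.max_dist[i] = p["max_dist"]
                attrs.sum_dist[i] = p["avg_dist"] * attrs.n_surface[i]
        feats = EdgeFeatures(**e["features"])
        edges[e["id"]] = VGEdge(
            e["id"], e["node_begin"], e["node_end"], pts, attrs, feats
        )
    return VesselGraph(
        nodes, edges, tuple(doc.get("dims", (1, 1, 1))), tuple(doc.get("spacing", (1.0, 1.0, 1.0)))
    )


def export_obj(graph: VesselGraph, path) -> None:
    """Centerline geometry as Wavefront OBJ (``v`` points, ``l`` polylines)."""
    with open(path, "w", encoding="utf-8") as fh:
        offset = 1  # OBJ indices are 1-based
        chunks = []
        for eid in sorted(graph.edges):
            e = graph.edges[eid]
            for p in e.centerline:
                fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            idx = range(offset, offset + len(e.centerline))
            chunks.append("l " + " ".join(str(i) for i in idx) + "\n")
            offset += len(e.centerline)
        for line in chunks:
            fh.write(line)


# ---------------------------------------------------------------------------
# Edge match ratio
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Matched edge pairs and the DICE-style ratio 2|pairs| / (|E1|+|E2|)."""

    pairs: list
    ratio: float


def _mutual_node_matching(g1: VesselGraph, g2: VesselGraph, tol: float) -> dict:
    ids1 = sorted(g1.nodes)
    ids2 = sorted(g2.nodes)
    if not ids1 or not ids2:
        return {}
    p1 = np.array([g1.nodes[i].position for i in ids1])
    p2 = np.array([g2.nodes[i].position for i in ids2])
    t1 = cKDTree(p1)
    t2 = cKDTree(p2)
    d12, n12 = t2.query(p1)
    d21, n21 = t1.query(p2)
    mapping = {}
    for i, nid in enumerate(ids1):
        j = int(n12[i])
        if d12[i] <= tol and int(n21[j]) == i:
            mapping[nid] = ids2[j]
    return mapping


def edge_match_ratio(
    g1: VesselGraph,
    g2: VesselGraph,
    node_tolerance: float | None = None,
    property_tolerance: float = 0.2,
) -> MatchResult:
    """Greedy deterministic edge matching between two graphs.

    Nodes correspond when they are mutual nearest neighbors within
    ``node_tolerance`` (default: twice the mean voxel spacing); an edge pair
    matches when both endpoint nodes correspond and the lengths agree within
    ``property_tolerance`` (relative to the larger length).
    """
    if node_tolerance is None:
        node_tolerance = 2.0 * float(np.mean(g1.spacing))
    if node_tolerance <= 0 or property_tolerance <= 0:
        raise ValueError("tolerances must be positive")
    if not g1.edges and not g2.edges:
        return MatchResult([], 1.0)
    mapping = _mutual_node_matching(g1, g2, node_tolerance)

    def edge_length(e) -> float:
        if e.features is not None and e.features.length:
            return float(e.features.length)
        return float(np.linalg.norm(np.diff(e.centerline, axis=0), axis=1).sum())

    unmatched2: dict[tuple, list] = {}
    for eid in sorted(g2.edges):
        e = g2.edges[eid]
        key = tuple(sorted((e.node_begin, e.node_end)))
        unmatched2.setdefault(key, []).append(eid)

    pairs = []
    for eid in sorted(g1.edges):
        e1 = g1.edges[eid]
        if e1.node_begin not in mapping or e1.node_end not in mapping:
            continue
        key = tuple(sorted((mapping[e1.node_begin], mapping[e1.node_end])))
        candidates = unmatched2.get(key, [])
        if not candidates:
            continue
        l1 = edge_length(e1)
        best = None
        best_diff = None
        for cid in candidates:
            l2 = edge_length(g2.edges[cid])
            if abs(l1 - l2) <= property_tolerance * max(l1, l2, 1e-300):
                diff = abs(l1 - l2)
                if best is None or diff < best_diff:
                    best, best_diff = cid, diff
        if best is not None:
            candidates.remove(best)
            pairs.append((eid, best))
    ratio = 2.0 * len(pairs) / (len(g1.edges) + len(g2.edges))
    return MatchResult(pairs, ratio)
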