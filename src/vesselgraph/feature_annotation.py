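"""Per-centerline-point attribute accumulation and per-edge features.

Every assigned foreground voxel distributes its physical volume to the
nearest centerline point(s) of its edge; surface voxels additionally
contribute their centre-to-point distance, from which the per-point minimum /
maximum / average surface distances derive.  Aggregation over points yields
the edge features, including the inputs of the dimensionless bulge-size
measure used for pruning.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.spatial import cKDTree

from .graph_build import ProtoVesselGraph, _NEIGHBOR_OFFSETS
from .volume_store import VoxelGrid, enumerate_surface, voxel_centers
from .voxel_assignment import EdgeIDVolume

logger = logging.getLogger(__name__)

_TIE_RTOL = 1e-9


@dataclass
class PointAttributes:
    """Per-centerline-point accumulators for one edge (arrays of length N)."""

    volume: np.ndarray
    min_dist: np.ndarray
    max_dist: np.ndarray
    sum_dist: np.ndarray
    n_surface: np.ndarray
    is_inner: np.ndarray
    #: per point: ids of other edges whose voxels touch this point's surface
    #: voxels (used to resolve innerness relative to a specific junction)
    adjacent_edges: list = field(default_factory=list)
    # surface voxel records used by the inner/outer classification:
    surface_voxels: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    surface_points: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @classmethod
    def zeros(cls, n: int) -> "PointAttributes":
        return cls(
            volume=np.zeros(n),
            min_dist=np.full(n, np.inf),
            max_dist=np.zeros(n),
            sum_dist=np.zeros(n),
            n_surface=np.zeros(n, dtype=np.int64),
            is_inner=np.zeros(n, dtype=bool),
            adjacent_edges=[set() for _ in range(n)],
        )

    @property
    def avg_dist(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_surface > 0, self.sum_dist / np.maximum(self.n_surface, 1), np.nan)

    def concatenated_with(self, other: "PointAttributes", merge_junction: bool = True) -> "PointAttributes":
        """Concatenate two attribute sequences, fusing the duplicated junction point."""
        a, b = self, other
        if merge_junction:
            out = PointAttributes(
                volume=np.concatenate([a.volume[:-1], [a.volume[-1] + b.volume[0]], b.volume[1:]]),
                min_dist=np.concatenate([a.min_dist[:-1], [min(a.min_dist[-1], b.min_dist[0])], b.min_dist[1:]]),
                max_dist=np.concatenate([a.max_dist[:-1], [max(a.max_dist[-1], b.max_dist[0])], b.max_dist[1:]]),
                sum_dist=np.concatenate([a.sum_dist[:-1], [a.sum_dist[-1] + b.sum_dist[0]], b.sum_dist[1:]]),
                n_surface=np.concatenate([a.n_surface[:-1], [a.n_surface[-1] + b.n_surface[0]], b.n_surface[1:]]),
                is_inner=np.concatenate([a.is_inner[:-1], [a.is_inner[-1] or b.is_inner[0]], b.is_inner[1:]]),
                adjacent_edges=a.adjacent_edges[:-1]
                + [a.adjacent_edges[-1] | b.adjacent_edges[0]]
                + b.adjacent_edges[1:],
            )
        else:
            out = PointAttributes(
                volume=np.concatenate([a.volume, b.volume]),
                min_dist=np.concatenate([a.min_dist, b.min_dist]),
                max_dist=np.concatenate([a.max_dist, b.max_dist]),
                sum_dist=np.concatenate([a.sum_dist, b.sum_dist]),
                n_surface=np.concatenate([a.n_surface, b.n_surface]),
                is_inner=np.concatenate([a.is_inner, b.is_inner]),
                adjacent_edges=list(a.adjacent_edges) + list(b.adjacent_edges),
            )
        return out

    def reversed(self) -> "PointAttributes":
        return PointAttributes(
            volume=self.volume[::-1].copy(),
            min_dist=self.min_dist[::-1].copy(),
            max_dist=self.max_dist[::-1].copy(),
            sum_dist=self.sum_dist[::-1].copy(),
            n_surface=self.n_surface[::-1].copy(),
            is_inner=self.is_inner[::-1].copy(),
            adjacent_edges=list(reversed(self.adjacent_edges)),
        )


@dataclass
class EdgeFeatures:
    length: float = 0.0
    distance: float = 0.0
    straightness: float | None = None
    volume: float = 0.0
    avg_cross_section: float | None = None
    min_radius_mean: float | None = None
    min_radius_std: float | None = None
    max_radius_mean: float | None = None
    max_radius_std: float | None = None
    avg_radius_mean: float | None = None
    avg_radius_std: float | None = None
    roundness_mean: float | None = None
    roundness_std: float | None = None
    bulge_size: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class VGNode:
    id: int
    position: np.ndarray
    voxels: np.ndarray
    degree: int = 0


@dataclass
class VGEdge:
    id: int
    node_begin: int
    node_end: int
    centerline: np.ndarray
    attrs: PointAttributes | None = None
    features: EdgeFeatures | None = None


@dataclass
class VesselGraph:
    """Refinable graph whose edges carry attributed centerlines."""

    nodes: dict
    edges: dict
    dims: tuple = (1, 1, 1)
    spacing: tuple = (1.0, 1.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def recompute_degrees(self) -> None:
        for node in self.nodes.values():
            node.degree = 0
        for edge in self.edges.values():
            self.nodes[edge.node_begin].degree += 1
            self.nodes[edge.node_end].degree += 1  # self-loops count twice

    def incident_edges(self, nid: int) -> list:
        return [
            e
            for e in self.edges.values()
            if e.node_begin == nid or e.node_end == nid
        ]


def _group_voxels_by_edge(idvol: EdgeIDVolume):
    """(edge id -> linear voxel indices) for all assigned foreground voxels."""
    nx, ny, nz = idvol.dims
    lins = []
    labs = []
    for z in range(nz):
        flat = idvol.labels[z].ravel()
        idx = np.flatnonzero(flat >= 0)
        if idx.size:
            lins.append(idx.astype(np.int64) + z * nx * ny)
            labs.append(flat[idx].astype(np.int64))
    if not lins:
        return {}
    lin = np.concatenate(lins)
    lab = np.concatenate(labs)
    order = np.argsort(lab, kind="stable")
    lin, lab = lin[order], lab[order]
    groups = {}
    edges, starts = np.unique(lab, return_index=True)
    starts = list(starts) + [lab.size]
    for i, e in enumerate(edges):
        groups[int(e)] = lin[starts[i] : starts[i + 1]]
    return groups


def accumulate_attributes(
    grid: VoxelGrid, idvol: EdgeIDVolume, proto: ProtoVesselGraph
) -> dict:
    """Accumulate per-point volume and surface distances for every edge.

    Returns ``{edge id: PointAttributes}``.  Each assigned voxel's volume is
    split equally among its nearest centerline point(s) of its edge (exact
    ties split evenly); if the voxel lies on the object surface, its
    centre-to-point distance additionally feeds the min/max/avg accumulators
    of the single nearest point (smallest point index among ties).
    UNASSIGNED voxels contribute nothing.
    """
    voxel_volume = grid.voxel_volume
    surface = set(int(v) for v in enumerate_surface(grid).positions)
    groups = _group_voxels_by_edge(idvol)
    out = {}
    for edge in proto.edges:
        pts = edge.centerline
        attrs = PointAttributes.zeros(len(pts))
        vox = groups.get(edge.id, np.empty(0, dtype=np.int64))
        if vox.size:
            tree = cKDTree(pts)
            centers = voxel_centers(grid.lin_to_xyz(vox), grid.spacing)
            k = min(8, len(pts))
            d, idx = tree.query(centers, k=k)
            d = np.atleast_2d(d.reshape(len(vox), -1))
            idx = np.atleast_2d(idx.reshape(len(vox), -1))
            tied = d <= d[:, :1] * (1.0 + _TIE_RTOL) + 1e-12
            surf_records = []
            for i, lin in enumerate(vox):
                tie_idx = idx[i][tied[i]]
                attrs.volume[tie_idx] += voxel_volume / tie_idx.size
                if int(lin) in surface:
                    p = int(tie_idx.min())
                    dist = float(d[i, 0])
                    attrs.n_surface[p] += 1
                    attrs.sum_dist[p] += dist
                    if dist < attrs.min_dist[p]:
                        attrs.min_dist[p] = dist
                    if dist > attrs.max_dist[p]:
                        attrs.max_dist[p] = dist
                    surf_records.append((int(lin), p))
            if surf_records:
                rec = np.asarray(surf_records, dtype=np.int64)
                attrs.surface_voxels = rec[:, 0]
                attrs.surface_points = rec[:, 1]
        out[edge.id] = attrs
    return out


def classify_inner_outer(attrs_by_edge: dict, idvol: EdgeIDVolume) -> None:
    """Set per-point inner flags (in place).

    A point is *inner* iff it has no associated surface voxels, or one of its
    surface voxels is a 26-neighbor of a voxel assigned to another edge.
    """
    nx, ny, nz = idvol.dims
    labels = idvol.labels
    for eid, attrs in attrs_by_edge.items():
        attrs.is_inner[:] = attrs.n_surface == 0
        for lin, p in zip(attrs.surface_voxels, attrs.surface_points):
            x, y, z = int(lin % nx), int((lin // nx) % ny), int(lin // (nx * ny))
            for dx, dy, dz in _NEIGHBOR_OFFSETS:
                xx, yy, zz = x + dx, y + dy, z + dz
                if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                    lab = int(labels[zz, yy, xx])
                    if lab >= 0 and lab != eid:
                        attrs.is_inner[p] = True
                        attrs.adjacent_edges[p].add(lab)


def _population_std(values: np.ndarray) -> float:
    return float(np.sqrt(np.mean((values - values.mean()) ** 2)))


def compute_edge_features(
    centerline: np.ndarray,
    attrs: PointAttributes,
    is_self_loop: bool = False,
) -> EdgeFeatures:
    """Aggregate point attributes into edge features."""
    pts = np.asarray(centerline, dtype=np.float64)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(seglen.sum())
    distance = float(np.linalg.norm(pts[-1] - pts[0]))
    f = EdgeFeatures(length=length, distance=distance)
    f.volume = float(attrs.volume.sum())
    if length > 0 and not is_self_loop:
        f.straightness = distance / length
    elif length == 0:
        warnings.warn("zero-length edge: straightness/avg_cross_section undefined")
    if length > 0:
        f.avg_cross_section = f.volume / length
    with_surface = attrs.n_surface > 0
    if with_surface.any():
        mn = attrs.min_dist[with_surface]
        mx = attrs.max_dist[with_surface]
        av = attrs.avg_dist[with_surface]
        roundness = np.where(mx > 0, mn / np.maximum(mx, 1e-300), 1.0)
        f.min_radius_mean = float(mn.mean())
        f.min_radius_std = _population_std(mn)
        f.max_radius_mean = float(mx.mean())
        f.max_radius_std = _population_std(mx)
        f.avg_radius_mean = float(av.mean())
        f.avg_radius_std = _population_std(av)
        f.roundness_mean = float(roundness.mean())
        f.roundness_std = _population_std(roundness)
    return f


def compute_bulge_size(edge: VGEdge, graph: VesselGraph) -> float | None:
    """Dimensionless bulge size of a bulging edge, else ``None``.

    Defined only for edges connecting a leaf node (degree 1) with a branching
    point (degree > 2):
    ``(length - inner_length(branch end) + tip_radius(leaf end)) / avg_radius_mean``.
    """
    deg_b = graph.nodes[edge.node_begin].degree
    deg_e = graph.nodes[edge.node_end].degree
    if not ((deg_b == 1 and deg_e > 2) or (deg_e == 1 and deg_b > 2)):
        return None
    leaf_at_end = deg_e == 1
    branch_node = edge.node_begin if leaf_at_end else edge.node_end
    attrs = edge.attrs
    pts = edge.centerline
    if not leaf_at_end:
        attrs = attrs.reversed()
        pts = pts[::-1]
    # now the branching node is at index 0, the leaf at index -1
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(seglen.sum())
    # inner length of the branching node: arc length of the run of points
    # inside *that node's* branching region — a point qualifies when it has
    # no surface voxels, or a surface voxel touching a sibling edge that is
    # currently incident to the branching node (adjacency to unrelated edges
    # elsewhere along the vessel does not extend the run)
    incident = {
        e.id for e in graph.incident_edges(branch_node) if e.id != edge.id
    }

    def inner_at(i: int) -> bool:
        if attrs.n_surface[i] == 0:
            return True
        return bool(attrs.adjacent_edges[i] & incident)

    run_end = 0
    while run_end < len(pts) and inner_at(run_end):
        run_end += 1
    inner_length = float(seglen[: run_end - 1].sum()) if run_end > 1 else 0.0
    tip_radius = 0.0
    for i in range(len(pts) - 1, -1, -1):
        if attrs.n_surface[i] > 0:
            tip_radius = float(attrs.min_dist[i])
            break
    with_surface = attrs.n_surface > 0
    if not with_surface.any():
        return None
    numerator = length - inner_length + tip_radius
    if numerator <= 0:
        return 0.0
    avg_radius_mean = float(attrs.avg_dist[with_surface].mean())
    if avg_radius_mean <= 0:
        warnings.warn(f"edge {edge.id}: avg radius 0, bulge size undefined")
        return None
    return numerator / avg_radius_mean


def annotate_graph(
    grid: VoxelGrid, idvol: EdgeIDVolume, proto: ProtoVesselGraph
) -> VesselGraph:
    """Build a fully attributed :class:`VesselGraph` from the proto graph."""
    attrs_by_edge = accumulate_attributes(grid, idvol, proto)
    classify_inner_outer(attrs_by_edge, idvol)
    nodes = {
        n.id: VGNode(n.id, np.asarray(n.position, dtype=np.float64), np.asarray(n.voxels, dtype=np.int64))
        for n in proto.nodes
    }
    edges = {}
    for pe in proto.edges:
        attrs = attrs_by_edge[pe.id]
        features = compute_edge_features(
            pe.centerline, attrs, is_self_loop=pe.node_begin == pe.node_end
        )
        edges[pe.id] = VGEdge(
            pe.id, pe.node_begin, pe.node_end, np.asarray(pe.centerline), attrs, features
        )
    graph = VesselGraph(nodes, edges, proto.dims, proto.spacing)
    graph.recompute_degrees()
    for edge in graph.edges.values():
        edge.features.bulge_size = compute_bulge_size(edge, graph)
    return graph
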