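"""Proto-graph extraction from a voxel skeleton.

Skeleton voxels are classified by their number of foreground 26-neighbors
(end < 2, regular = 2, branch > 2).  Connected components of end voxels and
of branch voxels become nodes (positioned at the barycenter of their voxel
centers); maximal chains of regular voxels become edges whose tips are
matched to nodes by 26-adjacency.  Closed chains with no adjacent node
produce one synthetic node and a self-loop.  The whole extraction is
slice-streamed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

from ._components import streaming_label
from .volume_store import VoxelGrid, voxel_centers

logger = logging.getLogger(__name__)


class VoxelClass(IntEnum):
    END = 1
    REGULAR = 2
    BRANCH = 3


class GraphExtractionError(RuntimeError):
    """Internal consistency failure (e.g. non-thin input skeleton)."""


def classify_voxel(neighborhood: np.ndarray) -> VoxelClass:
    """Class of a skeleton voxel from its 26-neighborhood occupancy."""
    n = int(np.count_nonzero(neighborhood))
    if n < 2:
        return VoxelClass.END
    if n == 2:
        return VoxelClass.REGULAR
    return VoxelClass.BRANCH


@dataclass
class ProtoNode:
    id: int
    voxels: np.ndarray                  # sorted linear indices
    position: np.ndarray                # barycenter, µm
    degree: int = 0
    voxel_class: VoxelClass = VoxelClass.END


@dataclass
class ProtoEdge:
    id: int
    node_begin: int
    node_end: int
    centerline: np.ndarray              # (N, 3) smoothed positions, µm
    raw_voxels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


@dataclass
class ProtoVesselGraph:
    nodes: list
    edges: list
    dims: tuple
    spacing: tuple

    def node_by_id(self, nid: int) -> ProtoNode:
        return self.nodes[nid]


def smooth_centerline(
    raw_positions: np.ndarray,
    node_begin_pos: np.ndarray,
    node_end_pos: np.ndarray,
) -> np.ndarray:
    """Smooth a raw voxel chain and pin its endpoints to the node barycenters.

    Interior raw point ``i`` is replaced by the quadratic-Bezier midpoint of
    its window, ``0.25 p[i-1] + 0.5 p[i] + 0.25 p[i+1]``; the node positions
    are prepended/appended.  The smoothed polyline is never longer than the
    raw one and never shorter than the straight endpoint distance.
    """
    begin = np.asarray(node_begin_pos, dtype=np.float64).reshape(1, 3)
    end = np.asarray(node_end_pos, dtype=np.float64).reshape(1, 3)
    raw = np.asarray(raw_positions, dtype=np.float64).reshape(-1, 3)
    if raw.shape[0] == 0:
        return np.vstack([begin, end])
    smoothed = raw.copy()
    if raw.shape[0] >= 3:
        smoothed[1:-1] = 0.25 * raw[:-2] + 0.5 * raw[1:-1] + 0.25 * raw[2:]
    return np.vstack([begin, smoothed, end])


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


def _class_slice_fn(skeleton: VoxelGrid):
    """Returns ``z -> class-value slice`` computing neighbor counts streamed."""
    nx, ny, nz = skeleton.dims
    cache: dict[int, np.ndarray] = {}

    def get(z: int) -> np.ndarray:
        if z < 0 or z >= nz:
            return np.zeros((ny, nx), dtype=bool)
        if z not in cache:
            for old in [k for k in cache if k < z - 1]:
                del cache[old]
            cache[z] = skeleton.get_slice(z)
        return cache[z]

    def class_slice(z: int) -> np.ndarray:
        window = np.stack([get(z - 1), get(z), get(z + 1)]).astype(np.int8)
        counts = ndimage.correlate(
            window, np.ones((3, 3, 3), dtype=np.int8), mode="constant", cval=0
        )[1]
        cur = window[1].astype(bool)
        nbrs = counts - 1  # exclude self
        out = np.zeros((ny, nx), dtype=np.int64)
        out[cur & (nbrs < 2)] = int(VoxelClass.END)
        out[cur & (nbrs == 2)] = int(VoxelClass.REGULAR)
        out[cur & (nbrs > 2)] = int(VoxelClass.BRANCH)
        return out

    return class_slice


def _order_chain(vox: np.ndarray, dims) -> tuple[list, bool]:
    """Order a regular-voxel component into a path; returns (chain, is_loop)."""
    nx, ny, _ = dims
    vox_set = set(int(v) for v in vox)
    coords = {
        int(v): (int(v % nx), int((v // nx) % ny), int(v // (nx * ny))) for v in vox
    }
    by_coord = {c: v for v, c in coords.items()}
    adj: dict[int, list] = {v: [] for v in vox_set}
    for v, (x, y, z) in coords.items():
        for dx, dy, dz in _NEIGHBOR_OFFSETS:
            w = by_coord.get((x + dx, y + dy, z + dz))
            if w is not None:
                adj[v].append(w)
    tips = sorted(v for v, nb in adj.items() if len(nb) <= 1)
    if len(vox_set) == 1:
        return [int(vox[0])], False
    if not tips:
        # closed loop: start at the smallest linear index
        start = min(vox_set)
        chain = [start]
        prev = None
        cur = start
        while True:
            nxts = [w for w in adj[cur] if w != prev]
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == start:
                break
            chain.append(nxt)
            prev, cur = cur, nxt
        if len(chain) != len(vox_set):
            raise GraphExtractionError("regular-voxel loop is not a simple cycle")
        return chain, True
    if len(tips) != 2:
        raise GraphExtractionError(
            f"regular-voxel chain with {len(tips)} tips (non-thin skeleton?)"
        )
    start = tips[0]  # deterministic orientation: smaller linear index first
    chain = [start]
    prev = None
    cur = start
    while len(chain) < len(vox_set):
        nxts = [w for w in adj[cur] if w != prev]
        if len(nxts) != 1:
            raise GraphExtractionError("regular-voxel component is not a path")
        chain.append(nxts[0])
        prev, cur = cur, nxts[0]
    return chain, False


def extract_proto_graph(skeleton: VoxelGrid) -> ProtoVesselGraph:
    """Build the proto-graph from a unit-wide skeleton in one streamed pass."""
    nx, ny, nz = skeleton.dims
    spacing = skeleton.spacing
    result = streaming_label(_class_slice_fn(skeleton), skeleton.dims)

    # --- nodes from END / BRANCH components -----------------------------
    nodes: list[ProtoNode] = []
    voxel_node: dict[int, int] = {}
    chain_comps = []
    for cid in range(result.n):
        value = int(result.values[cid])
        vox = result.voxels[cid]
        if value == int(VoxelClass.REGULAR):
            chain_comps.append(vox)
            continue
        nid = len(nodes)
        pos = voxel_centers(skeleton.lin_to_xyz(vox), spacing).mean(axis=0)
        nodes.append(
            ProtoNode(nid, vox, pos, voxel_class=VoxelClass(value))
        )
        for lin in vox:
            voxel_node[int(lin)] = nid

    # --- edges from REGULAR chains ---------------------------------------
    edge_records = []  # (sort_key, begin, end, chain list)

    def adjacent_nodes(lin: int) -> list:
        x, y, z = int(lin % nx), int((lin // nx) % ny), int(lin // (nx * ny))
        found = []
        for dx, dy, dz in _NEIGHBOR_OFFSETS:
            xx, yy, zz = x + dx, y + dy, z + dz
            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                nid = voxel_node.get(xx + nx * (yy + ny * zz))
                if nid is not None and nid not in found:
                    found.append(nid)
        return sorted(found)

    for vox in chain_comps:
        chain, is_loop = _order_chain(vox, skeleton.dims)
        if is_loop:
            # synthetic node at the smallest-index chain voxel + self-loop
            head = chain[0]
            nid = len(nodes)
            pos = voxel_centers(skeleton.lin_to_xyz(np.array([head])), spacing)[0]
            nodes.append(
                ProtoNode(nid, np.array([head], dtype=np.int64), pos,
                          voxel_class=VoxelClass.REGULAR)
            )
            voxel_node[head] = nid
            edge_records.append((head, nid, nid, chain[1:]))
            continue
        first_adj = adjacent_nodes(chain[0])
        last_adj = adjacent_nodes(chain[-1])
        if not first_adj or not last_adj:
            raise GraphExtractionError(
                "regular-voxel chain tip without adjacent node voxel"
            )
        if len(chain) == 1 and len(first_adj) >= 2:
            begin, end = first_adj[0], first_adj[1]
        else:
            begin = first_adj[0]
            end = last_adj[0]
            if begin == end and len(last_adj) > 1:
                end = last_adj[1]
        edge_records.append((chain[0], begin, end, chain))

    # --- zero-length edges between adjacent END and BRANCH components ----
    seen_pairs = set()
    for node in nodes:
        if node.voxel_class != VoxelClass.END:
            continue
        for lin in node.voxels:
            for other in adjacent_nodes(int(lin)):
                if other == node.id:
                    continue
                if nodes[other].voxel_class != VoxelClass.BRANCH:
                    continue
                pair = (min(node.id, other), max(node.id, other))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                edge_records.append((int(node.voxels.min()), node.id, other, []))

    edge_records.sort(key=lambda r: (r[0], r[1], r[2]))
    edges: list[ProtoEdge] = []
    for eid, (_, begin, end, chain) in enumerate(edge_records):
        raw = np.asarray(chain, dtype=np.int64)
        raw_pos = (
            voxel_centers(skeleton.lin_to_xyz(raw), spacing)
            if raw.size
            else np.empty((0, 3))
        )
        centerline = smooth_centerline(
            raw_pos, nodes[begin].position, nodes[end].position
        )
        edges.append(ProtoEdge(eid, begin, end, centerline, raw))
        nodes[begin].degree += 1
        nodes[end].degree += 1 if begin != end else 1  # self-loop counts twice

    logger.debug("proto graph: %d nodes, %d edges", len(nodes), len(edges))
    return ProtoVesselGraph(nodes, edges, skeleton.dims, spacing)
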