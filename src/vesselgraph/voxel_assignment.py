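"""Assignment of every foreground voxel to a proto-graph edge.

Four steps: (1) Voronoi mapping to the nearest centerline point, (2)
connected-component remapping that keeps, per edge, only the component
containing the edge's first centerline point, (3) identification of the
resulting cut-off regions, and (4) per-region flooding from adjacent labeled
voxels, one 6-neighbor step per wave (approximating L1-Voronoi cells of the
adjacent labeled surfaces).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._components import streaming_label
from .graph_build import ProtoVesselGraph
from .volume_store import DEFAULT_BLOCK_SIZE, VoxelGrid, voxel_centers

logger = logging.getLogger(__name__)

BACKGROUND = np.int32(-2)
UNASSIGNED = np.int32(-1)


@dataclass
class EdgeIDVolume:
    """Per-voxel edge labels; BACKGROUND (-2), UNASSIGNED (-1) or an edge id."""

    dims: tuple
    spacing: tuple
    labels: np.ndarray  # int32, shape (nz, ny, nx)

    def copy(self) -> "EdgeIDVolume":
        return EdgeIDVolume(self.dims, self.spacing, self.labels.copy())

    def label_slice(self, z: int) -> np.ndarray:
        return self.labels[z]

    def save_hdf5(self, path, dataset: str = "edge_ids") -> None:
        import h5py

        nx, ny, nz = self.dims
        bs = min(DEFAULT_BLOCK_SIZE, nx, ny, nz)
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(
                dataset, data=self.labels, chunks=(bs, bs, bs), dtype=np.int32
            )
            ds.attrs["spacing_um"] = self.spacing
            ds.attrs["background"] = int(BACKGROUND)
            ds.attrs["unassigned"] = int(UNASSIGNED)


@dataclass
class CutoffRegion:
    """A connected region of unassigned foreground voxels."""

    id: int
    bbox: tuple  # (xmin, ymin, zmin, xmax, ymax, zmax), inclusive
    voxels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def _centerline_index(proto: ProtoVesselGraph):
    """KD-tree over all centerline points, tagged with edge ids."""
    points = []
    ids = []
    for edge in proto.edges:
        points.append(edge.centerline)
        ids.append(np.full(len(edge.centerline), edge.id, dtype=np.int64))
    if not points:
        return None, None
    pts = np.vstack(points)
    return cKDTree(pts), np.concatenate(ids)


def voronoi_map(grid: VoxelGrid, proto: ProtoVesselGraph) -> EdgeIDVolume:
    """Label every foreground voxel with the edge of its nearest centerline point.

    Euclidean voxel-center to point distance in µm; exact distance ties go to
    the smaller edge id.  Voxels are processed in block-sized batches.
    """
    nx, ny, nz = grid.dims
    labels = np.full((nz, ny, nx), BACKGROUND, dtype=np.int32)
    tree, point_edge = _centerline_index(proto)
    if tree is None:
        warnings.warn("proto graph has no centerline points; all voxels unassigned")
        for z in range(nz):
            sl = grid.get_slice(z)
            labels[z][sl] = UNASSIGNED
        return EdgeIDVolume(grid.dims, grid.spacing, labels)

    k = min(4, tree.n)
    for z in range(nz):
        sl = grid.get_slice(z)
        ys, xs = np.nonzero(sl)
        if not xs.size:
            continue
        coords = np.stack([xs, ys, np.full_like(xs, z)], axis=1)
        centers = voxel_centers(coords, grid.spacing)
        for start in range(0, len(centers), DEFAULT_BLOCK_SIZE ** 2):
            batch = slice(start, start + DEFAULT_BLOCK_SIZE ** 2)
            d, idx = tree.query(centers[batch], k=k)
            if k == 1:
                best = point_edge[idx]
            else:
                tied = d <= d[:, :1] * (1.0 + 1e-12) + 1e-12
                cand = np.where(tied, point_edge[idx], np.iinfo(np.int64).max)
                best = cand.min(axis=1)
            labels[z, ys[batch], xs[batch]] = best.astype(np.int32)
    return EdgeIDVolume(grid.dims, grid.spacing, labels)


def _point_voxel(point: np.ndarray, dims, spacing) -> tuple:
    nx, ny, nz = dims
    v = np.floor(np.asarray(point) / np.asarray(spacing)).astype(np.int64)
    return (
        int(np.clip(v[0], 0, nx - 1)),
        int(np.clip(v[1], 0, ny - 1)),
        int(np.clip(v[2], 0, nz - 1)),
    )


def remap_components(idvol: EdgeIDVolume, proto: ProtoVesselGraph) -> EdgeIDVolume:
    """Keep, per edge, the label component containing its first centerline point.

    All other components of that edge id become UNASSIGNED.
    """
    nx, ny, nz = idvol.dims
    result = streaming_label(
        lambda z: idvol.labels[z].astype(np.int64) + 2, idvol.dims
    )  # shift so BACKGROUND -> 0 (ignored), UNASSIGNED -> 1, edge e -> e + 2
    comp_vol = np.full((nz, ny, nx), -1, dtype=np.int64)
    flat = comp_vol.reshape(-1)
    for cid in range(result.n):
        flat[result.voxels[cid]] = cid

    keep: set[int] = set()
    for edge in proto.edges:
        # sample at the first centerline point whose voxel carries this edge's
        # id (endpoints are node barycenters shared between edges, so the very
        # first point may legitimately sit in a sibling edge's voxel)
        found = False
        for point in edge.centerline:
            x, y, z = _point_voxel(point, idvol.dims, idvol.spacing)
            if idvol.labels[z, y, x] == edge.id:
                keep.add(int(comp_vol[z, y, x]))
                found = True
                break
        if not found:
            warnings.warn(
                f"edge {edge.id}: no centerline point voxel carries its id; "
                "edge keeps no component"
            )

    out = idvol.copy()
    for cid in range(result.n):
        value = int(result.values[cid])
        if value < 2:  # background (can't appear) or unassigned component
            continue
        if cid not in keep:
            out.labels.reshape(-1)[result.voxels[cid]] = UNASSIGNED
    return out


def find_cutoff_regions(idvol: EdgeIDVolume) -> list:
    """26-connected components of UNASSIGNED voxels with their bounding boxes."""
    result = streaming_label(
        lambda z: (idvol.labels[z] == UNASSIGNED).astype(np.int64), idvol.dims
    )
    return [
        CutoffRegion(cid, tuple(int(b) for b in result.bbox[cid]), result.voxels[cid])
        for cid in range(result.n)
    ]


_FACE_OFFSETS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def flood_cutoff_regions(idvol: EdgeIDVolume, regions: list) -> EdgeIDVolume:
    """Flood each cut-off region from adjacent labeled voxels, wave by wave.

    Labels propagate one 6-neighbor step per wave; a voxel reached in the
    same wave from several labels takes the smallest edge id.  Regions with
    no labeled neighbor anywhere remain UNASSIGNED.
    """
    nx, ny, nz = idvol.dims
    out = idvol.copy()
    labels = out.labels
    for region in regions:
        member = set(int(v) for v in region.voxels)
        # wave 0: region voxels 6-adjacent to a validly labeled voxel
        frontier: dict[int, int] = {}
        for lin in sorted(member):
            x, y, z = lin % nx, (lin // nx) % ny, lin // (nx * ny)
            best = None
            for dx, dy, dz in _FACE_OFFSETS:
                xx, yy, zz = x + dx, y + dy, z + dz
                if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                    lab = int(labels[zz, yy, xx])
                    if lab >= 0 and (best is None or lab < best):
                        best = lab
            if best is not None:
                frontier[lin] = best
        remaining = member - frontier.keys()
        while frontier:
            for lin, lab in frontier.items():
                z, rem = divmod(lin, nx * ny)
                y, x = divmod(rem, nx)
                labels[z, y, x] = lab
            nxt: dict[int, int] = {}
            for lin, lab in frontier.items():
                x, y, z = lin % nx, (lin // nx) % ny, lin // (nx * ny)
                for dx, dy, dz in _FACE_OFFSETS:
                    w = (x + dx) + nx * ((y + dy) + ny * (z + dz))
                    if (x + dx) < 0 or (x + dx) >= nx or (y + dy) < 0 or (y + dy) >= ny or (z + dz) < 0 or (z + dz) >= nz:
                        continue
                    if w in remaining:
                        prev = nxt.get(w)
                        if prev is None or lab < prev:
                            nxt[w] = lab
            remaining -= nxt.keys()
            frontier = nxt
    return out


def assign_voxels(grid: VoxelGrid, proto: ProtoVesselGraph) -> EdgeIDVolume:
    """Run the full 4-step assignment chain."""
    idvol = voronoi_map(grid, proto)
    idvol = remap_components(idvol, proto)
    regions = find_cutoff_regions(idvol)
    return flood_cutoff_regions(idvol, regions)
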