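"""Synthetic vessel phantoms with known ground-truth graphs.

Primitives (cylinders, spheres, tori, surface bumps) are rasterized
slice-by-slice (voxel centre inside any primitive → foreground), together
with the perturbations used for evaluation: topology-preserving surface
noise, volume scaling by nearest-neighbor *resampling* or alternating
*mirror* tiling, and anisotropic per-axis upsampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .volume_store import VoxelGrid, enumerate_surface

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Primitives and specs
# ---------------------------------------------------------------------------

@dataclass
class Cylinder:
    p0: tuple
    p1: tuple
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        p0 = np.asarray(self.p0, dtype=np.float64)
        p1 = np.asarray(self.p1, dtype=np.float64)
        axis = p1 - p0
        ll = float(axis @ axis)
        if ll == 0:
            return np.linalg.norm(pts - p0, axis=-1) <= self.radius
        t = np.clip(((pts - p0) @ axis) / ll, 0.0, 1.0)
        closest = p0 + t[..., None] * axis
        return np.linalg.norm(pts - closest, axis=-1) <= self.radius


@dataclass
class Sphere:
    center: tuple
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=np.float64)
        return np.linalg.norm(pts - c, axis=-1) <= self.radius


@dataclass
class Torus:
    """Torus with ring radius R and tube radius r, axis along z."""

    center: tuple
    ring_radius: float
    tube_radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=np.float64)
        d = pts - c
        rho = np.sqrt(d[..., 0] ** 2 + d[..., 1] ** 2)
        return (rho - self.ring_radius) ** 2 + d[..., 2] ** 2 <= self.tube_radius ** 2


@dataclass
class GroundTruthGraph:
    """Nominal graph of a phantom: node positions plus edge adjacency."""

    node_positions: np.ndarray            # (N, 3) µm
    edges: list                           # (begin, end) node index pairs
    edge_lengths: np.ndarray              # nominal arc lengths, µm
    edge_radii: np.ndarray                # nominal radii, µm
    n_cycles: int = 0


@dataclass
class PhantomSpec:
    primitives: list
    dims: tuple
    spacing: tuple = (1.0, 1.0, 1.0)
    ground_truth: GroundTruthGraph | None = None


@dataclass
class NoiseConfig:
    level: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("noise level must be >= 0")


def rasterize(spec: PhantomSpec):
    """Rasterize a spec; returns ``(VoxelGrid, GroundTruthGraph)``."""
    nx, ny, nz = spec.dims
    sx, sy, sz = spec.spacing
    grid = VoxelGrid(spec.dims, spec.spacing)
    xs = (np.arange(nx) + 0.5) * sx
    ys = (np.arange(ny) + 0.5) * sy
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    for z in range(nz):
        pts = np.stack([xx, yy, np.full_like(xx, (z + 0.5) * sz)], axis=-1)
        mask = np.zeros((ny, nx), dtype=bool)
        for prim in spec.primitives:
            mask |= prim.contains(pts)
        grid.set_slice(z, mask)
    if grid.count_foreground() == 0:
        raise ValueError("phantom rasterized to an empty volume")
    return grid, spec.ground_truth


# ---------------------------------------------------------------------------
# Canonical phantom factories
# ---------------------------------------------------------------------------

def cylinder_phantom(radius=4.0, length=40.0, margin=6, spacing=(1.0, 1.0, 1.0)) -> PhantomSpec:
    """Single straight cylinder along x; ground truth: 2 nodes, 1 edge."""
    sx, sy, sz = spacing
    dims = (
        int(np.ceil((length + 2 * margin) / sx)),
        int(np.ceil((2 * radius + 2 * margin) / sy)),
        int(np.ceil((2 * radius + 2 * margin) / sz)),
    )
    cy = dims[1] * sy / 2
    cz = dims[2] * sz / 2
    p0 = (margin, cy, cz)
    p1 = (margin + length, cy, cz)
    gt = GroundTruthGraph(
        node_positions=np.array([p0, p1], dtype=np.float64),
        edges=[(0, 1)],
        edge_lengths=np.array([length]),
        edge_radii=np.array([radius]),
    )
    return PhantomSpec([Cylinder(p0, p1, radius)], dims, spacing, gt)


_Y_DIRS = np.array(
    [(1.0, 0.0, 0.0), (-0.6, 0.8, 0.0), (-0.6, -0.8, 0.0)], dtype=np.float64
)


def y_phantom(radius=3.0, arm_length=16.0, margin=5, spacing=(1.0, 1.0, 1.0)) -> PhantomSpec:
    """Three cylindrical arms meeting at a junction; 4 nodes, 3 edges."""
    sx, sy, sz = spacing
    extent = arm_length + margin
    dims = (
        int(np.ceil(2 * extent / sx)),
        int(np.ceil(2 * extent / sy)),
        int(np.ceil((2 * radius + 2 * margin) / sz)),
    )
    center = np.array([extent, extent, dims[2] * sz / 2])
    tips = [center + d * arm_length for d in _Y_DIRS]
    prims = [Cylinder(tuple(center), tuple(t), radius) for t in tips]
    gt = GroundTruthGraph(
        node_positions=np.vstack([center] + tips),
        edges=[(0, 1), (0, 2), (0, 3)],
        edge_lengths=np.full(3, arm_length),
        edge_radii=np.full(3, radius),
    )
    return PhantomSpec(prims, dims, spacing, gt)


def torus_phantom(ring_radius=12.0, tube_radius=3.0, margin=5, spacing=(1.0, 1.0, 1.0)) -> PhantomSpec:
    """Solid torus; ground truth: one cyclic edge of length 2*pi*R."""
    sx, sy, sz = spacing
    ext_xy = ring_radius + tube_radius + margin
    dims = (
        int(np.ceil(2 * ext_xy / sx)),
        int(np.ceil(2 * ext_xy / sy)),
        int(np.ceil((2 * tube_radius + 2 * margin) / sz)),
    )
    center = (ext_xy, ext_xy, dims[2] * sz / 2)
    anchor = (center[0] + ring_radius, center[1], center[2])
    gt = GroundTruthGraph(
        node_positions=np.array([anchor], dtype=np.float64),
        edges=[(0, 0)],
        edge_lengths=np.array([2 * np.pi * ring_radius]),
        edge_radii=np.array([tube_radius]),
        n_cycles=1,
    )
    return PhantomSpec([Torus(center, ring_radius, tube_radius)], dims, spacing, gt)


def bump_phantom(
    protrusion_factor=1.5,
    bump_radius=3.0,
    vessel_radius=4.0,
    length=40.0,
    margin=6,
    spacing=(1.0, 1.0, 1.0),
) -> PhantomSpec:
    """Straight cylinder with a spherical side bump at its middle.

    ``protrusion_factor`` sets how far the bump protrudes beyond the vessel
    surface, in units of the bump radius, so the expected bulge size of the
    spurious branch is controllable around the pruning threshold.
    """
    sx, sy, sz = spacing
    protrusion = protrusion_factor * bump_radius
    dims = (
        int(np.ceil((length + 2 * margin) / sx)),
        int(np.ceil((2 * vessel_radius + protrusion + 2 * margin) / sy)),
        int(np.ceil((2 * vessel_radius + 2 * margin) / sz)),
    )
    cy = margin + vessel_radius
    cz = dims[2] * sz / 2
    p0 = (margin, cy, cz)
    p1 = (margin + length, cy, cz)
    gt = GroundTruthGraph(
        node_positions=np.array([p0, p1], dtype=np.float64),
        edges=[(0, 1)],
        edge_lengths=np.array([length]),
        edge_radii=np.array([vessel_radius]),
    )
    spec = PhantomSpec([Cylinder(p0, p1, vessel_radius)], dims, spacing, gt)
    cyl = spec.primitives[0]
    mid = (np.asarray(cyl.p0) + np.asarray(cyl.p1)) / 2
    # bump sphere whose tip protrudes exactly `protrusion` beyond the vessel
    # surface; beyond protrusions of 2 bump radii the sphere would detach,
    # so a stem cylinder keeps it connected
    tip_center = mid + np.array(
        [0.0, vessel_radius + protrusion - bump_radius, 0.0]
    )
    spec.primitives.append(Sphere(tuple(tip_center), bump_radius))
    if protrusion > 2 * bump_radius:
        spec.primitives.append(
            Cylinder(tuple(mid), tuple(tip_center), bump_radius)
        )
    return spec


def thick_thin_phantom(
    thick_radius=8.0, thin_radius=2.0, gap=2.0, length=40.0, margin=4,
    spacing=(1.0, 1.0, 1.0),
) -> PhantomSpec:
    """Two parallel cylinders of very different radii lying close together."""
    sx, sy, sz = spacing
    height = 2 * thick_radius + 2 * thin_radius + gap + 2 * margin
    dims = (
        int(np.ceil((length + 2 * margin) / sx)),
        int(np.ceil(height / sy)),
        int(np.ceil((2 * thick_radius + 2 * margin) / sz)),
    )
    cz = dims[2] * sz / 2
    y_thick = margin + thick_radius
    y_thin = y_thick + thick_radius + gap + thin_radius
    thick = Cylinder((margin, y_thick, cz), (margin + length, y_thick, cz), thick_radius)
    thin = Cylinder((margin, y_thin, cz), (margin + length, y_thin, cz), thin_radius)
    gt = GroundTruthGraph(
        node_positions=np.array(
            [thick.p0, thick.p1, thin.p0, thin.p1], dtype=np.float64
        ),
        edges=[(0, 1), (2, 3)],
        edge_lengths=np.full(2, length),
        edge_radii=np.array([thick_radius, thin_radius]),
    )
    return PhantomSpec([thick, thin], dims, spacing, gt)


def ground_truth_graph(gt: GroundTruthGraph):
    """Materialise a nominal ground-truth graph as a comparable VesselGraph."""
    from .feature_annotation import EdgeFeatures, VGEdge, VGNode, VesselGraph

    nodes = {
        i: VGNode(i, np.asarray(p, dtype=np.float64), np.empty(0, dtype=np.int64))
        for i, p in enumerate(gt.node_positions)
    }
    edges = {}
    for eid, (a, b) in enumerate(gt.edges):
        centerline = np.vstack([gt.node_positions[a], gt.node_positions[b]])
        feats = EdgeFeatures(
            length=float(gt.edge_lengths[eid]),
            distance=float(np.linalg.norm(gt.node_positions[b] - gt.node_positions[a])),
        )
        edges[eid] = VGEdge(eid, a, b, centerline, None, feats)
    graph = VesselGraph(nodes, edges)
    graph.recompute_degrees()
    return graph


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def add_surface_noise(grid: VoxelGrid, config: NoiseConfig) -> VoxelGrid:
    """Flip random surface voxels without changing topology.

    Surface voxels are foreground voxels with a background 26-neighbor and
    background voxels 26-adjacent to foreground.  A flip is accepted iff it
    is topology-preserving (simple-point criterion); accepted flips stop at
    ``round(level * initial foreground-surface count)``.  Deterministic for a
    fixed seed.
    """
    out = grid.copy()
    if config.level == 0:
        return out
    nx, ny, nz = out.dims
    rng = np.random.default_rng(config.seed)

    fg_surface = enumerate_surface(out).positions
    quota = int(round(config.level * fg_surface.size))
    if quota == 0:
        return out

    # candidate pool: the initial surface shell (foreground surface voxels
    # plus background voxels 26-adjacent to foreground).  Flips perturb the
    # surface at the individual-voxel level; each voxel flips at most once,
    # so the perturbation never accretes into multi-voxel tendrils.
    pool: list = []
    seen: set = set()
    for lin in fg_surface:
        x, y, z = int(lin % nx), int((lin // nx) % ny), int(lin // (nx * ny))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
                        continue
                    p = (xx, yy, zz)
                    if p in seen:
                        continue
                    if (dx, dy, dz) == (0, 0, 0) or not out.get(xx, yy, zz):
                        seen.add(p)
                        pool.append(p)
    pool.sort()

    flips = 0
    draws = 0
    flipped: set = set()
    max_draws = 200 * quota + 1000
    while flips < quota and draws < max_draws and len(flipped) < len(pool):
        draws += 1
        vox = pool[int(rng.integers(len(pool)))]
        if vox in flipped:
            continue
        x, y, z = vox
        mask = _kernels.gather_mask(out._bits, out._stride, nx, ny, nz, x, y, z)
        # a flip (either direction) preserves topology iff the voxel is a
        # simple point of the configuration with its centre set foreground
        if not _kernels.is_simple_mask(mask | (1 << _kernels.CENTER_BIT)):
            continue
        out.set(x, y, z, not out.get(x, y, z))
        flipped.add(vox)
        flips += 1
    if flips < quota:
        warnings.warn(
            f"surface noise reached only {flips}/{quota} flips "
            f"(level {flips / max(fg_surface.size, 1):.3f})"
        )
    return out


def scale_volume(grid: VoxelGrid, scale, strategy: str = "resample") -> VoxelGrid:
    """Enlarge a volume by ``scale`` per axis.

    ``resample``: nearest-neighbor upsampling, spacing divided by the scale
    (same physical extent).  ``mirror``: tile the volume ``scale`` times per
    axis with every odd tile mirrored along that axis, spacing unchanged.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if strategy == "resample":
        return anisotropize(grid, (scale, scale, scale))
    if strategy == "mirror":
        if int(scale) != scale:
            raise ValueError("mirror strategy requires an integer scale")
        s = int(scale)
        nx, ny, nz = grid.dims
        out = VoxelGrid((nx * s, ny * s, nz * s), grid.spacing)
        for z in range(nz * s):
            tz, oz = divmod(z, nz)
            src_z = nz - 1 - oz if tz % 2 else oz
            sl = grid.get_slice(src_z)
            row = np.concatenate(
                [sl[:, ::-1] if tx % 2 else sl for tx in range(s)], axis=1
            )
            big = np.concatenate(
                [row[::-1, :] if ty % 2 else row for ty in range(s)], axis=0
            )
            out.set_slice(z, big)
        return out
    raise ValueError(f"unknown scaling strategy {strategy!r}")


def anisotropize(grid: VoxelGrid, factors) -> VoxelGrid:
    """Per-axis nearest-neighbor upsampling; spacing divided per axis."""
    fx, fy, fz = factors
    if min(fx, fy, fz) < 1:
        raise ValueError("factors must be >= 1")
    nx, ny, nz = grid.dims
    sx, sy, sz = grid.spacing
    new_dims = (int(round(nx * fx)), int(round(ny * fy)), int(round(nz * fz)))
    out = VoxelGrid(new_dims, (sx / fx, sy / fy, sz / fz))
    x_src = np.minimum((np.arange(new_dims[0]) / fx).astype(np.int64), nx - 1)
    y_src = np.minimum((np.arange(new_dims[1]) / fy).astype(np.int64), ny - 1)
    cache_z = -1
    cache_slice = None
    for z in range(new_dims[2]):
        src_z = min(int(z / fz), nz - 1)
        if src_z != cache_z:
            cache_slice = grid.get_slice(src_z)
            cache_z = src_z
        out.set_slice(z, cache_slice[np.ix_(y_src, x_src)])
    return out
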