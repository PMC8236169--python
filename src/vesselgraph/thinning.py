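"""Topology-preserving iterative thinning of binary volumes.

Reduces the foreground to a unit-wide voxel skeleton by repeatedly deleting
simple border voxels in six directional subiterations.  Deletion depth is
tracked per direction in physical units so that anisotropic volumes erode at
an equal physical speed on all axes (dynamic axis selection); a static
fixed-order schedule is available for comparison.  A set of *fixed* voxels is
never deleted, and preservation of line-end voxels (exactly one foreground
neighbor) is switchable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .volume_store import ActiveSurface, VoxelGrid, enumerate_surface

logger = logging.getLogger(__name__)

#: Directional subiteration order used for tie-breaking: +x, -x, +y, -y, +z, -z.
DIRECTIONS = (
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
)

_DIR_NAMES = ("+x", "-x", "+y", "-y", "+z", "-z")


def is_simple(neighborhood: np.ndarray) -> bool:
    """Whether deleting a foreground voxel with this 26-neighborhood preserves topology.

    True iff the foreground voxels of the 26-neighborhood form exactly one
    26-connected component and the background voxels of the 18-neighborhood
    form exactly one 6-connected component touching a face neighbor.
    """
    mask = _kernels.mask_from_neighborhood26(neighborhood)
    return bool(_kernels.is_simple_mask(mask))


def is_border(neighborhood: np.ndarray, direction) -> bool:
    """True iff the face neighbor in ``direction`` (dx, dy, dz) is background."""
    dx, dy, dz = direction
    if abs(dx) + abs(dy) + abs(dz) != 1:
        raise ValueError(f"direction must be a unit axis vector, got {direction}")
    n = (dx + 1) + 3 * (dy + 1) + 9 * (dz + 1)
    if n > _kernels.CENTER_BIT:
        n -= 1
    return not bool(neighborhood[n])


def is_line_end(neighborhood: np.ndarray) -> bool:
    """True iff exactly one of the 26 neighbors is foreground."""
    return int(np.count_nonzero(neighborhood)) == 1


@dataclass
class ThinningState:
    """Bookkeeping of a thinning run."""

    grid: VoxelGrid
    active: ActiveSurface
    removed_depth: np.ndarray = field(
        default_factory=lambda: np.zeros(6, dtype=np.float64)
    )
    quiet: np.ndarray = field(default_factory=lambda: np.zeros(6, dtype=bool))
    preserve_line_ends: bool = True
    n_subiterations: int = 0


def select_direction(state: ThinningState) -> int:
    """Index into :data:`DIRECTIONS` with minimal removed depth (ties: fixed order).

    Directions whose most recent subiteration deleted nothing ("quiet") are
    skipped until another direction makes progress.
    """
    best = -1
    for d in range(6):
        if state.quiet[d]:
            continue
        if best < 0 or state.removed_depth[d] < state.removed_depth[best]:
            best = d
    return best


def _pack_fixed(grid: VoxelGrid, fixed: np.ndarray) -> np.ndarray:
    bits = np.zeros_like(grid._bits)
    nx, ny, _ = grid.dims
    for lin in fixed:
        x = int(lin % nx)
        y = int((lin // nx) % ny)
        z = int(lin // (nx * ny))
        pos = y * nx + x
        bits[z * grid._stride + (pos >> 3)] |= np.uint8(1 << (pos & 7))
    return bits


def thin(
    grid: VoxelGrid,
    fixed=None,
    preserve_line_ends: bool = True,
    direction_mode: str = "dynamic",
) -> VoxelGrid:
    """Thin ``grid`` to a unit-wide skeleton; see :func:`thin_with_state`."""
    return thin_with_state(grid, fixed, preserve_line_ends, direction_mode).grid


def thin_with_state(
    grid: VoxelGrid,
    fixed=None,
    preserve_line_ends: bool = True,
    direction_mode: str = "dynamic",
) -> ThinningState:
    """Run thinning and return the full final :class:`ThinningState`.

    Parameters
    ----------
    fixed:
        Linear voxel indices that are never deleted; must all be foreground.
    preserve_line_ends:
        Keep voxels with exactly one foreground neighbor (first pipeline
        iteration); later iterations disable this so that unconstrained line
        tips erode back to the fixed end voxels.
    direction_mode:
        ``"dynamic"`` selects the direction with the lowest accumulated
        physical deletion depth; ``"static"`` cycles the fixed order.
    """
    if direction_mode not in ("dynamic", "static"):
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    out = grid.copy()
    nx, ny, nz = out.dims
    sx, sy, sz = out.spacing
    depth_inc = (sx, sx, sy, sy, sz, sz)

    fixed = np.asarray(
        [] if fixed is None else list(fixed), dtype=np.int64
    ).ravel()
    has_fixed = fixed.size > 0
    if has_fixed:
        coords = out.lin_to_xyz(fixed)
        for (x, y, z) in coords:
            if not out.get(int(x), int(y), int(z)):
                raise ValueError(
                    f"fixed voxel ({x},{y},{z}) is not foreground"
                )
        fixed_bits = _pack_fixed(out, fixed)
    else:
        fixed_bits = np.zeros(1, dtype=np.uint8)

    state = ThinningState(
        grid=out,
        active=enumerate_surface(out),
        preserve_line_ends=preserve_line_ends,
    )
    active = state.active.positions
    static_next = 0
    while not state.quiet.all():
        if direction_mode == "dynamic":
            d = select_direction(state)
        else:
            d = static_next
            static_next = (static_next + 1) % 6
            if state.quiet[d]:
                continue
        if d < 0:  # pragma: no cover - defensive; quiet.all() guards the loop
            break
        dx, dy, dz = DIRECTIONS[d]
        keep, deleted, readd = _kernels.subiteration(
            out._bits,
            out._stride,
            nx,
            ny,
            nz,
            active,
            dx,
            dy,
            dz,
            fixed_bits,
            has_fixed,
            preserve_line_ends,
        )
        state.n_subiterations += 1
        if deleted.size:
            state.removed_depth[d] += depth_inc[d]
            state.quiet[:] = False
            parts = [active[keep.astype(bool)]]
            if readd.size:
                parts.append(readd)
            active = np.unique(np.concatenate(parts))
        else:
            state.quiet[d] = True
            active = active[keep.astype(bool)]
    state.active = ActiveSurface(active[np.isin(active, out.foreground_indices())] if active.size else active)
    logger.debug(
        "thinning finished after %d subiterations, %d skeleton voxels",
        state.n_subiterations,
        out.count_foreground(),
    )
    return state
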