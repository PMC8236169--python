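"""Numba kernels for bit-packed voxel access and local topology tests.

A 3x3x3 neighborhood is encoded as a 27-bit integer mask with bit
``n = (dx+1) + 3*(dy+1) + 9*(dz+1)`` for the offset ``(dx, dy, dz)``; the
center voxel is bit 13.  This x-fastest enumeration is the package-wide
neighborhood order (the 26-entry public order simply skips the center).
"""

from __future__ import annotations

import numpy as np
from numba import njit

CENTER_BIT = 13


@njit(cache=True, inline="always")
def _getbit(bits, stride, nx, ny, nz, x, y, z):
    if x < 0 or y < 0 or z < 0 or x >= nx or y >= ny or z >= nz:
        return False
    pos = y * nx + x
    return (bits[z * stride + (pos >> 3)] >> (pos & 7)) & 1 == 1


@njit(cache=True, inline="always")
def _setbit(bits, stride, nx, x, y, z, value):
    pos = y * nx + x
    byte = z * stride + (pos >> 3)
    if value:
        bits[byte] |= np.uint8(1 << (pos & 7))
    else:
        bits[byte] &= np.uint8(0xFF ^ (1 << (pos & 7)))


@njit(cache=True)
def gather_mask(bits, stride, nx, ny, nz, x, y, z):
    """27-bit occupancy mask of the 3x3x3 window centred on (x, y, z)."""
    mask = np.int64(0)
    n = 0
    for dz in range(-1, 2):
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                if _getbit(bits, stride, nx, ny, nz, x + dx, y + dy, z + dz):
                    mask |= np.int64(1) << n
                n += 1
    return mask


@njit(cache=True, inline="always")
def neighbor_count(mask):
    """Number of foreground voxels among the 26 neighbors."""
    m = mask & ~(np.int64(1) << CENTER_BIT)
    count = 0
    for n in range(27):
        if (m >> n) & 1:
            count += 1
    return count


@njit(cache=True)
def _fg26_components(mask):
    """26-connected components of foreground cells among the 26 neighbors."""
    visited = np.zeros(27, dtype=np.uint8)
    stack = np.empty(27, dtype=np.int64)
    comps = 0
    for start in range(27):
        if start == CENTER_BIT or visited[start] or not ((mask >> start) & 1):
            continue
        comps += 1
        top = 0
        stack[top] = start
        top += 1
        visited[start] = 1
        while top > 0:
            top -= 1
            c = stack[top]
            cx = c % 3
            cy = (c // 3) % 3
            cz = c // 9
            for n in range(27):
                if n == CENTER_BIT or visited[n] or not ((mask >> n) & 1):
                    continue
                dx = n % 3 - cx
                dy = (n // 3) % 3 - cy
                dz = n // 9 - cz
                if dx * dx <= 1 and dy * dy <= 1 and dz * dz <= 1:
                    visited[n] = 1
                    stack[top] = n
                    top += 1
    return comps


@njit(cache=True)
def _bg6_components_n18(mask):
    """6-connected background components of N18 that touch a face neighbor.

    Paths run through background cells of the 18-neighborhood only (corner
    cells and the center are excluded); a component counts when it contains
    at least one of the 6 face neighbors.
    """
    visited = np.zeros(27, dtype=np.uint8)
    stack = np.empty(27, dtype=np.int64)
    comps = 0
    for start in range(27):
        if start == CENTER_BIT or visited[start] or ((mask >> start) & 1):
            continue
        sx = start % 3 - 1
        sy = (start // 3) % 3 - 1
        sz = start // 9 - 1
        man = abs(sx) + abs(sy) + abs(sz)
        if man != 1:  # grow only from face neighbors; N18 cells get visited
            continue
        comps += 1
        top = 0
        stack[top] = start
        top += 1
        visited[start] = 1
        while top > 0:
            top -= 1
            c = stack[top]
            cx = c % 3
            cy = (c // 3) % 3
            cz = c // 9
            for n in range(27):
                if n == CENTER_BIT or visited[n] or ((mask >> n) & 1):
                    continue
                ax = n % 3 - 1
                ay = (n // 3) % 3 - 1
                az = n // 9 - 1
                if abs(ax) + abs(ay) + abs(az) > 2:  # not in N18
                    continue
                dx = n % 3 - cx
                dy = (n // 3) % 3 - cy
                dz = n // 9 - cz
                if abs(dx) + abs(dy) + abs(dz) == 1:
                    visited[n] = 1
                    stack[top] = n
                    top += 1
    return comps


@njit(cache=True)
def is_simple_mask(mask):
    """Simple-point criterion for (26, 6) connectivity on a 27-bit mask."""
    if _fg26_components(mask) != 1:
        return False
    return _bg6_components_n18(mask) == 1


@njit(cache=True)
def subiteration(
    bits,
    stride,
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
):
    """One directional thinning subiteration over the active surface.

    Candidates are selected against the pre-subiteration occupancy (border in
    direction (dx,dy,dz), simple, not fixed, not a line end when preserved),
    then deleted sequentially in ascending linear-index order with a
    simpleness re-check at deletion time.

    Returns ``(keep, deleted[:ndel], readd[:nre])`` where ``keep`` marks
    active-surface entries that were *not* considered and therefore remain.
    """
    n_active = active.shape[0]
    keep = np.ones(n_active, dtype=np.uint8)
    candidates = np.empty(n_active, dtype=np.int64)
    ncand = 0
    for i in range(n_active):
        lin = active[i]
        x = lin % nx
        y = (lin // nx) % ny
        z = lin // (nx * ny)
        if not _getbit(bits, stride, nx, ny, nz, x, y, z):
            keep[i] = 0  # stale entry
            continue
        if _getbit(bits, stride, nx, ny, nz, x + dx, y + dy, z + dz):
            continue  # not a border voxel for this direction; stays active
        keep[i] = 0  # considered: leaves the active surface either way
        if has_fixed:
            pos = y * nx + x
            if (fixed_bits[z * stride + (pos >> 3)] >> (pos & 7)) & 1:
                continue
        mask = gather_mask(bits, stride, nx, ny, nz, x, y, z)
        if preserve_line_ends and neighbor_count(mask) == 1:
            continue
        if is_simple_mask(mask):
            candidates[ncand] = lin
            ncand += 1

    deleted = np.empty(ncand, dtype=np.int64)
    ndel = 0
    readd = np.empty(26 * ncand if ncand > 0 else 1, dtype=np.int64)
    nre = 0
    for i in range(ncand):
        lin = candidates[i]
        x = lin % nx
        y = (lin // nx) % ny
        z = lin // (nx * ny)
        mask = gather_mask(bits, stride, nx, ny, nz, x, y, z)
        # re-check against current occupancy: earlier deletions in this
        # subiteration may have turned the voxel into a line end or made it
        # non-simple
        if preserve_line_ends and neighbor_count(mask) == 1:
            continue
        if not is_simple_mask(mask):
            continue
        _setbit(bits, stride, nx, x, y, z, False)
        deleted[ndel] = lin
        ndel += 1
        for ddz in range(-1, 2):
            for ddy in range(-1, 2):
                for ddx in range(-1, 2):
                    if ddx == 0 and ddy == 0 and ddz == 0:
                        continue
                    xx = x + ddx
                    yy = y + ddy
                    zz = z + ddz
                    if _getbit(bits, stride, nx, ny, nz, xx, yy, zz):
                        readd[nre] = xx + nx * (yy + ny * zz)
                        nre += 1
    return keep, deleted[:ndel], readd[:nre]


@njit(cache=True)
def gather_masks_batch(bits, stride, nx, ny, nz, lins, out):
    for i in range(lins.shape[0]):
        lin = lins[i]
        x = lin % nx
        y = (lin // nx) % ny
        z = lin // (nx * ny)
        out[i] = gather_mask(bits, stride, nx, ny, nz, x, y, z)


def mask_from_window(window: np.ndarray) -> int:
    """27-bit mask from a dense 3x3x3 ``[z, y, x]`` window (test helper)."""
    window = np.asarray(window, dtype=bool)
    if window.shape != (3, 3, 3):
        raise ValueError("window must be 3x3x3")
    bitsvals = window.ravel()  # z slowest, x fastest == bit order
    mask = 0
    for n, v in enumerate(bitsvals):
        if v:
            mask |= 1 << n
    return mask


def mask_from_neighborhood26(neighbors: np.ndarray, center: bool = True) -> int:
    """27-bit mask from a 26-entry neighbor array (package neighborhood order)."""
    neighbors = np.asarray(neighbors, dtype=bool)
    if neighbors.shape != (26,):
        raise ValueError("expected 26 neighbor occupancies")
    mask = (1 << CENTER_BIT) if center else 0
    j = 0
    for n in range(27):
        if n == CENTER_BIT:
            continue
        if neighbors[j]:
            mask |= 1 << n
        j += 1
    return mask
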