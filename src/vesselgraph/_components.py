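"""Slice-streamed 26-connected component labeling.

Voxels are mergeable iff they carry the same nonzero value.  The volume is
consumed one z-slice at a time (only two value slices are resident), with a
union-find over provisional per-slice labels — the streaming analogue of a
full-volume flood fill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_STRUCT8 = np.ones((3, 3), dtype=bool)


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self):
        self.parent: list[int] = []

    def make(self) -> int:
        self.parent.append(len(self.parent))
        return len(self.parent) - 1

    def find(self, a: int) -> int:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


@dataclass
class LabelResult:
    """Components of equal-valued voxels.

    Components are numbered 0..n-1 in ascending order of their smallest
    linear voxel index (deterministic).
    """

    n: int
    values: np.ndarray          # (n,) value shared by each component
    voxels: list                # list of sorted linear-index arrays
    bbox: np.ndarray            # (n, 6): xmin, ymin, zmin, xmax, ymax, zmax

    def component_of(self) -> dict:
        out = {}
        for cid, vox in enumerate(self.voxels):
            for lin in vox:
                out[int(lin)] = cid
        return out


def streaming_label(value_slice_fn, dims) -> LabelResult:
    """Label 26-connected components of equal nonzero values.

    Parameters
    ----------
    value_slice_fn:
        Callable ``z -> int array (ny, nx)``; value 0 is background.  Called
        exactly once per slice, in ascending z order.
    dims:
        ``(nx, ny, nz)`` of the underlying grid.
    """
    nx, ny, nz = dims
    uf = _UnionFind()
    prov_value: list[int] = []
    members_lin: list[np.ndarray] = []   # per-slice linear indices
    members_gid: list[np.ndarray] = []   # matching provisional ids

    prev_vals = None
    prev_labels = None
    for z in range(nz):
        vals = np.asarray(value_slice_fn(z))
        labels = np.full((ny, nx), -1, dtype=np.int64)
        for v in np.unique(vals):
            if v == 0:
                continue
            mask = vals == v
            lab, nl = ndimage.label(mask, structure=_STRUCT8)
            base = len(uf.parent)
            for _ in range(nl):
                uf.make()
                prov_value.append(int(v))
            labels[mask] = base + lab[mask] - 1
        # merge with previous slice under all 9 in-plane offsets (26-conn)
        if prev_labels is not None:
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    cy0, cy1 = max(0, -dy), ny - max(0, dy)
                    cx0, cx1 = max(0, -dx), nx - max(0, dx)
                    if cy0 >= cy1 or cx0 >= cx1:
                        continue
                    cur_v = vals[cy0:cy1, cx0:cx1]
                    prv_v = prev_vals[cy0 + dy : cy1 + dy, cx0 + dx : cx1 + dx]
                    both = (cur_v > 0) & (cur_v == prv_v)
                    if not both.any():
                        continue
                    cur_l = labels[cy0:cy1, cx0:cx1][both]
                    prv_l = prev_labels[cy0 + dy : cy1 + dy, cx0 + dx : cx1 + dx][both]
                    pairs = np.unique(cur_l * np.int64(len(uf.parent) + 1) + prv_l)
                    for key in pairs:
                        uf.union(int(key // (len(uf.parent) + 1)), int(key % (len(uf.parent) + 1)))
        flat = labels.ravel()
        idx = np.flatnonzero(flat >= 0)
        if idx.size:
            members_lin.append(idx.astype(np.int64) + z * nx * ny)
            members_gid.append(flat[idx])
        prev_vals, prev_labels = vals, labels

    if not members_lin:
        return LabelResult(0, np.empty(0, dtype=np.int64), [], np.empty((0, 6), dtype=np.int64))

    lin = np.concatenate(members_lin)
    gid = np.concatenate(members_gid)
    roots = np.fromiter((uf.find(int(g)) for g in gid), dtype=np.int64, count=gid.size)

    # order components by smallest member linear index
    uniq_roots, inverse = np.unique(roots, return_inverse=True)
    min_lin = np.full(uniq_roots.size, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(min_lin, inverse, lin)
    order = np.argsort(min_lin, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    comp = rank[inverse]

    n = uniq_roots.size
    values = np.zeros(n, dtype=np.int64)
    values[comp] = [prov_value[int(g)] for g in gid]
    voxels: list[np.ndarray] = []
    sort_key = np.argsort(comp * np.int64(nx) * ny * nz + lin, kind="stable")
    lin_s = lin[sort_key]
    comp_s = comp[sort_key]
    starts = np.searchsorted(comp_s, np.arange(n + 1))
    bbox = np.empty((n, 6), dtype=np.int64)
    for c in range(n):
        vox = lin_s[starts[c] : starts[c + 1]]
        voxels.append(vox)
        x = vox % nx
        y = (vox // nx) % ny
        zz = vox // (nx * ny)
        bbox[c] = (x.min(), y.min(), zz.min(), x.max(), y.max(), zz.max())
    return LabelResult(n, values, voxels, bbox)
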