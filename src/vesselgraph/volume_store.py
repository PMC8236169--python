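"""Blocked binary volume storage with streamed access.

Every pipeline stage reads and writes voxel data exclusively through this
module.  Volumes are stored bit-packed (1 bit per voxel) and slice-aligned so
that single slices, blocks and individual voxels can be accessed without ever
materialising the full grid as a dense array.  Conversion to a dense array is
guarded by :data:`MAX_DENSE_VOXELS`; lowering it (e.g. in tests) turns any
accidental full-volume materialisation into a hard error.

Conventions
-----------
* ``dims = (nx, ny, nz)`` voxels per axis, ``spacing = (sx, sy, sz)`` in µm.
* Linear voxel index is x-fastest: ``lin = x + nx * (y + ny * z)``.
* Dense arrays handed in or out are indexed ``[z, y, x]`` (C-order, so that
  ``arr.ravel()`` enumerates voxels in linear-index order).
* The physical position of voxel ``(x, y, z)`` is the voxel centre
  ``((x + 0.5) sx, (y + 0.5) sy, (z + 0.5) sz)``.
* Any query outside ``dims`` returns background.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 32

#: Guard threshold for dense materialisation (voxels).  ``to_array`` raises
#: above this; pipeline internals never call it, only tests and small oracles.
MAX_DENSE_VOXELS = 512 ** 3

_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)


class VolumeFormatError(ValueError):
    """Raised for unsupported file formats."""


class DimensionalityError(ValueError):
    """Raised when input data is not three-dimensional."""


class DenseGuardError(MemoryError):
    """Raised when a dense materialisation would exceed :data:`MAX_DENSE_VOXELS`."""


def voxel_centers(coords: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Physical centre positions (µm) for integer voxel coordinates ``(N, 3)`` x,y,z."""
    return (np.asarray(coords, dtype=np.float64) + 0.5) * np.asarray(spacing, dtype=np.float64)


class VoxelGrid:
    """Binary 3D grid, bit-packed per z-slice.

    Parameters
    ----------
    dims:
        ``(nx, ny, nz)`` — strictly positive voxel counts per axis.
    spacing:
        ``(sx, sy, sz)`` — strictly positive physical voxel size in µm.
    """

    __slots__ = ("dims", "spacing", "_bits", "_stride")

    def __init__(self, dims: Sequence[int], spacing: Sequence[float] = (1.0, 1.0, 1.0)):
        dims = tuple(int(d) for d in dims)
        spacing = tuple(float(s) for s in spacing)
        if len(dims) != 3:
            raise DimensionalityError(f"expected 3 dims, got {len(dims)}")
        if any(d <= 0 for d in dims):
            raise ValueError(f"dims must be strictly positive, got {dims}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive reals, got {spacing}")
        self.dims = dims
        self.spacing = spacing
        nx, ny, nz = dims
        self._stride = (nx * ny + 7) // 8  # bytes per z-slice
        self._bits = np.zeros(self._stride * nz, dtype=np.uint8)

    # -- basic properties -------------------------------------------------

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def count_foreground(self) -> int:
        return int(_POPCOUNT[self._bits].sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return (
            self.dims == other.dims
            and self.spacing == other.spacing
            and np.array_equal(self._bits, other._bits)
        )

    def copy(self) -> "VoxelGrid":
        g = VoxelGrid(self.dims, self.spacing)
        g._bits[:] = self._bits
        return g

    def copy_empty(self) -> "VoxelGrid":
        return VoxelGrid(self.dims, self.spacing)

    # -- voxel / slice access ---------------------------------------------

    def get(self, x: int, y: int, z: int) -> bool:
        nx, ny, nz = self.dims
        if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
            return False
        pos = y * nx + x
        return bool((self._bits[z * self._stride + (pos >> 3)] >> (pos & 7)) & 1)

    def set(self, x: int, y: int, z: int, value: bool) -> None:
        nx, ny, nz = self.dims
        if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
            raise IndexError(f"voxel ({x},{y},{z}) outside dims {self.dims}")
        pos = y * nx + x
        byte = z * self._stride + (pos >> 3)
        if value:
            self._bits[byte] |= np.uint8(1 << (pos & 7))
        else:
            self._bits[byte] &= np.uint8(~(1 << (pos & 7)) & 0xFF)

    def get_slice(self, z: int) -> np.ndarray:
        """Occupancy of slice ``z`` as a bool array of shape ``(ny, nx)``."""
        nx, ny, nz = self.dims
        if not 0 <= z < nz:
            return np.zeros((ny, nx), dtype=bool)
        raw = self._bits[z * self._stride : (z + 1) * self._stride]
        return (
            np.unpackbits(raw, count=nx * ny, bitorder="little")
            .reshape(ny, nx)
            .astype(bool)
        )

    def set_slice(self, z: int, data: np.ndarray) -> None:
        nx, ny, nz = self.dims
        data = np.asarray(data, dtype=bool)
        if data.shape != (ny, nx):
            raise ValueError(f"slice shape {data.shape} != {(ny, nx)}")
        packed = np.packbits(data.ravel(), bitorder="little")
        self._bits[z * self._stride : z * self._stride + packed.size] = packed

    # -- dense conversion (guarded) ---------------------------------------

    @classmethod
    def from_array(
        cls, arr: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)
    ) -> "VoxelGrid":
        """Build a grid from a dense ``[z, y, x]`` array (nonzero = foreground)."""
        arr = np.asarray(arr)
        if arr.ndim != 3:
            raise DimensionalityError(f"expected 3D array, got {arr.ndim}D")
        nz, ny, nx = arr.shape
        grid = cls((nx, ny, nz), spacing)
        fg = arr != 0
        for z in range(nz):
            grid.set_slice(z, fg[z])
        return grid

    def to_array(self) -> np.ndarray:
        """Dense ``[z, y, x]`` bool array.  Guarded by :data:`MAX_DENSE_VOXELS`."""
        if self.n_voxels > MAX_DENSE_VOXELS:
            raise DenseGuardError(
                f"dense materialisation of {self.n_voxels} voxels exceeds the "
                f"guard threshold ({MAX_DENSE_VOXELS}); use slice/block streams"
            )
        nx, ny, nz = self.dims
        out = np.empty((nz, ny, nx), dtype=bool)
        for z in range(nz):
            out[z] = self.get_slice(z)
        return out

    # -- sparse accessors --------------------------------------------------

    def foreground_indices(self) -> np.ndarray:
        """Sorted linear indices (x-fastest) of all foreground voxels."""
        nx, ny, _ = self.dims
        per_slice = []
        for z in range(self.dims[2]):
            flat = self.get_slice(z).ravel()
            idx = np.flatnonzero(flat)
            if idx.size:
                per_slice.append(idx.astype(np.int64) + z * nx * ny)
        if not per_slice:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(per_slice)

    def foreground_coords(self) -> np.ndarray:
        """Integer ``(N, 3)`` array of foreground voxel coordinates (x, y, z)."""
        return self.lin_to_xyz(self.foreground_indices())

    def lin_to_xyz(self, lin: np.ndarray) -> np.ndarray:
        nx, ny, _ = self.dims
        lin = np.asarray(lin, dtype=np.int64)
        x = lin % nx
        y = (lin // nx) % ny
        z = lin // (nx * ny)
        return np.stack([x, y, z], axis=-1)

    def xyz_to_lin(self, coords: np.ndarray) -> np.ndarray:
        nx, ny, _ = self.dims
        coords = np.asarray(coords, dtype=np.int64)
        return coords[..., 0] + nx * (coords[..., 1] + ny * coords[..., 2])

    # -- block streaming ---------------------------------------------------

    def stream_blocks(
        self, block_size: int = DEFAULT_BLOCK_SIZE
    ) -> Iterator[Tuple[Tuple[int, int, int], np.ndarray]]:
        """Yield ``((bx, by, bz), payload)`` for every block exactly once.

        Blocks are cubes of ``block_size`` voxels, zero-padded at the grid
        boundary, emitted in deterministic order (bx fastest, bz slowest).
        Payload shape is ``(block_size,) * 3`` indexed ``[z, y, x]``.
        """
        nx, ny, nz = self.dims
        bs = int(block_size)
        nbx = -(-nx // bs)
        nby = -(-ny // bs)
        nbz = -(-nz // bs)
        for bz in range(nbz):
            z0 = bz * bs
            # only the slices covered by this block row are resident
            slices = [self.get_slice(z) for z in range(z0, min(z0 + bs, nz))]
            for by in range(nby):
                for bx in range(nbx):
                    payload = np.zeros((bs, bs, bs), dtype=bool)
                    y0, x0 = by * bs, bx * bs
                    for dz, sl in enumerate(slices):
                        chunk = sl[y0 : y0 + bs, x0 : x0 + bs]
                        payload[dz, : chunk.shape[0], : chunk.shape[1]] = chunk
                    yield (bx, by, bz), payload

    @classmethod
    def from_blocks(
        cls,
        dims: Sequence[int],
        spacing: Sequence[float],
        blocks: Iterator[Tuple[Tuple[int, int, int], np.ndarray]],
        block_size: int = DEFAULT_BLOCK_SIZE,
    ) -> "VoxelGrid":
        grid = cls(dims, spacing)
        nx, ny, nz = grid.dims
        bs = int(block_size)
        pending: dict[int, np.ndarray] = {}
        for (bx, by, bz), payload in blocks:
            for dz in range(min(bs, nz - bz * bs)):
                z = bz * bs + dz
                sl = pending.setdefault(z, np.zeros((ny, nx), dtype=bool))
                y0, x0 = by * bs, bx * bs
                h = min(bs, ny - y0)
                w = min(bs, nx - x0)
                sl[y0 : y0 + h, x0 : x0 + w] = payload[dz, :h, :w]
        for z, sl in pending.items():
            grid.set_slice(z, sl)
        return grid


@dataclass(frozen=True)
class ActiveSurface:
    """Sorted, duplicate-free linear indices of potentially deletable voxels."""

    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("active surface positions must be strictly increasing")

    def __len__(self) -> int:
        return int(self.positions.size)


def enumerate_surface(grid: VoxelGrid) -> ActiveSurface:
    """Foreground voxels with at least one background 26-neighbor.

    Voxels on the grid boundary count the outside as background.  Processing
    is slice-streamed with a three-slice window.
    """
    from scipy import ndimage

    nx, ny, nz = grid.dims
    out = []
    prev = np.zeros((ny, nx), dtype=bool)
    cur = grid.get_slice(0) if nz > 0 else prev
    for z in range(nz):
        nxt = grid.get_slice(z + 1) if z + 1 < nz else np.zeros((ny, nx), dtype=bool)
        window = np.stack([prev, cur, nxt])
        # min over the 3x3x3 window == 0 <=> some 26-neighbor (or self) is bg
        mn = ndimage.minimum_filter(
            window.astype(np.uint8), size=3, mode="constant", cval=0
        )[1]
        surf = cur & (mn == 0)
        idx = np.flatnonzero(surf.ravel())
        if idx.size:
            out.append(idx.astype(np.int64) + z * nx * ny)
        prev, cur = cur, nxt
    if not out:
        return ActiveSurface()
    return ActiveSurface(np.concatenate(out))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff", ".ome.tif", ".ome.tiff")
_HDF5_SUFFIXES = (".h5", ".hdf5")
_RAW_SUFFIXES = (".vgb",)


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower()
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_TIFF_SUFFIXES):
        return "tiff"
    if name.endswith(_HDF5_SUFFIXES):
        return "hdf5"
    if name.endswith(_RAW_SUFFIXES):
        return "raw"
    raise VolumeFormatError(f"unsupported volume format: {path}")


def load_volume(
    path, format_hint: str | None = None, dataset: str = "volume"
) -> VoxelGrid:
    """Load a binary volume; nonzero values become foreground.

    Spacing is read from file metadata where available and defaults to
    ``(1, 1, 1)`` µm with a logged warning otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise DimensionalityError(f"expected 3D NIfTI, got {data.ndim}D")
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
        # nibabel arrays are [x, y, z]; our dense convention is [z, y, x]
        return VoxelGrid.from_array(np.transpose(data, (2, 1, 0)), spacing)
    if fmt == "tiff":
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            spacing = _tiff_spacing(tf)
        if data.ndim != 3:
            raise DimensionalityError(f"expected 3D TIFF stack, got {data.ndim}D")
        if spacing is None:
            logger.warning("%s: no spacing metadata, defaulting to (1,1,1) µm", path)
            spacing = (1.0, 1.0, 1.0)
        return VoxelGrid.from_array(data, spacing)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise VolumeFormatError(f"dataset {dataset!r} not found in {path}")
            ds = f[dataset]
            if ds.ndim != 3:
                raise DimensionalityError(f"expected 3D dataset, got {ds.ndim}D")
            spacing = ds.attrs.get("spacing_um")
            if spacing is None:
                logger.warning("%s: no spacing attribute, defaulting to (1,1,1) µm", path)
                spacing = (1.0, 1.0, 1.0)
            nz, ny, nx = ds.shape
            grid = VoxelGrid((nx, ny, nz), tuple(float(s) for s in spacing))
            for z in range(nz):
                grid.set_slice(z, ds[z] != 0)
            return grid
    if fmt == "raw":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise VolumeFormatError(f"missing JSON sidecar for {path}")
        meta = json.loads(sidecar.read_text())
        grid = VoxelGrid(meta["dims"], meta.get("spacing", (1.0, 1.0, 1.0)))
        raw = np.fromfile(path, dtype=np.uint8)
        if raw.size != grid._bits.size:
            raise VolumeFormatError(
                f"payload size {raw.size} does not match dims {grid.dims}"
            )
        grid._bits[:] = raw
        return grid
    raise VolumeFormatError(f"unsupported format hint: {fmt}")


def _tiff_spacing(tf) -> tuple | None:
    try:
        if tf.imagej_metadata:
            meta = tf.imagej_metadata
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if xres and yres and "spacing" in meta:
                sx = xres.value[1] / xres.value[0]
                sy = yres.value[1] / yres.value[0]
                return (float(sx), float(sy), float(meta["spacing"]))
    except Exception:  # pragma: no cover - metadata best effort
        pass
    return None


def save_volume(grid: VoxelGrid, path, format_hint: str | None = None, dataset: str = "volume") -> None:
    """Write a grid to NIfTI / TIFF / HDF5 / raw-blocked format by suffix."""
    path = Path(path)
    fmt = _detect_format(path, format_hint)
    nx, ny, nz = grid.dims
    if fmt == "nifti":
        import nibabel as nib

        data = np.transpose(grid.to_array().astype(np.uint8), (2, 1, 0))
        affine = np.diag(list(grid.spacing) + [1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    if fmt == "tiff":
        import tifffile

        sx, sy, sz = grid.spacing
        tifffile.imwrite(
            str(path),
            grid.to_array().astype(np.uint8),
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um"},
        )
        return
    if fmt == "hdf5":
        import h5py

        bs = min(DEFAULT_BLOCK_SIZE, nx, ny, nz)
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(
                dataset, shape=(nz, ny, nx), dtype=np.uint8, chunks=(bs, bs, bs)
            )
            for z in range(nz):
                ds[z] = grid.get_slice(z).astype(np.uint8)
            ds.attrs["spacing_um"] = grid.spacing
        return
    if fmt == "raw":
        grid._bits.tofile(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "dims": list(grid.dims),
                    "spacing": list(grid.spacing),
                    "block_size": DEFAULT_BLOCK_SIZE,
                    "layout": "slice-aligned, bit-packed little-endian, x fastest",
                }
            )
        )
        return
    raise VolumeFormatError(f"unsupported format hint: {fmt}")
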