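"""Conversion of a raw volume into the on-disk bitBlock tree.

The reformatter streams the source volume through the pyramid one z-slab at a
time (default slab: two block-depths), so peak resident voxel data is bounded
by a slab of the current level rather than the whole volume.  For each level
it dices the slab into zero-padded cubes, splits every cube into bit-planes,
writes each plane as an LZW TIFF through :mod:`bitvox.store`, and
simultaneously downsamples the slab into a scratch memmap that becomes the
next level's source.  Downsampling is a 2x2x2 arithmetic mean (fewer voxels
in the neighborhood at odd edges), rounded half-up; a strided-subsampling
variant is available for callers who prefer nearest-neighbor reduction.
Conversion is lossless at level 1: reading every bit-plane back reproduces
the source voxel-exactly.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Protocol

import numpy as np
import tifffile

from .bitplane_codec import Block, split_planes
from .pyramid_plan import (
    BitPlaneRef,
    BlockCoord,
    DatasetMeta,
    LevelSpec,
    plan_pyramid,
)
from . import store

__all__ = [
    "SourceVolume",
    "ArraySource",
    "TiffStackSource",
    "SliceDirSource",
    "RawSource",
    "open_source",
    "downsample2x",
    "dice",
    "reformat",
    "ReformatConfig",
]

SENTINEL = ".incomplete"


class SourceVolume(Protocol):
    """Provider of voxel sub-arrays by half-open (x, y, z) box.

    Arrays are returned indexed ``[z, y, x]``; any in-bounds request yields
    exactly the requested shape.
    """

    dims: tuple[int, int, int]  # (x, y, z)
    bit_depth: int

    def read_box(
        self, x0: int, x1: int, y0: int, y1: int, z0: int, z1: int
    ) -> np.ndarray: ...


def _check_box(dims, x0, x1, y0, y1, z0, z1) -> None:
    if not (0 <= x0 < x1 <= dims[0] and 0 <= y0 < y1 <= dims[1] and 0 <= z0 < z1 <= dims[2]):
        raise ValueError(
            f"box ({x0}:{x1},{y0}:{y1},{z0}:{z1}) outside dims {dims}"
        )


@dataclass
class ArraySource:
    """In-memory volume, array indexed [z, y, x]."""

    array: np.ndarray

    def __post_init__(self) -> None:
        if self.array.ndim != 3:
            raise ValueError("ArraySource needs a 3D array")
        if self.array.dtype == np.uint8:
            self.bit_depth = 8
        elif self.array.dtype == np.uint16:
            self.bit_depth = 16
        else:
            raise ValueError(f"unsupported dtype {self.array.dtype}")
        z, y, x = self.array.shape
        self.dims = (x, y, z)

    def read_box(self, x0, x1, y0, y1, z0, z1) -> np.ndarray:
        _check_box(self.dims, x0, x1, y0, y1, z0, z1)
        return self.array[z0:z1, y0:y1, x0:x1]


class TiffStackSource:
    """Multi-page grayscale TIFF; pages are z-slices of shape (y, x)."""

    def __init__(self, path: Path | str):
        self.path = Path(path)
        self._tif = tifffile.TiffFile(self.path)
        page = self._tif.pages[0]
        ny, nx = page.shape
        nz = len(self._tif.pages)
        self.dims = (nx, ny, nz)
        if page.dtype == np.uint8:
            self.bit_depth = 8
        elif page.dtype == np.uint16:
            self.bit_depth = 16
        else:
            raise ValueError(f"unsupported TIFF dtype {page.dtype}")

    def read_box(self, x0, x1, y0, y1, z0, z1) -> np.ndarray:
        _check_box(self.dims, x0, x1, y0, y1, z0, z1)
        pages = [self._tif.pages[z].asarray()[y0:y1, x0:x1] for z in range(z0, z1)]
        return np.stack(pages, axis=0)

    def close(self) -> None:
        self._tif.close()


class SliceDirSource:
    """Directory of 2D TIFF slices, stacked in sorted filename order."""

    def __init__(self, directory: Path | str):
        self.directory = Path(directory)
        self.files = sorted(
            p for p in self.directory.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not self.files:
            raise ValueError(f"no TIFF slices in {directory}")
        first = tifffile.imread(self.files[0])
        ny, nx = first.shape
        self.dims = (nx, ny, len(self.files))
        if first.dtype == np.uint8:
            self.bit_depth = 8
        elif first.dtype == np.uint16:
            self.bit_depth = 16
        else:
            raise ValueError(f"unsupported slice dtype {first.dtype}")

    def read_box(self, x0, x1, y0, y1, z0, z1) -> np.ndarray:
        _check_box(self.dims, x0, x1, y0, y1, z0, z1)
        return np.stack(
            [tifffile.imread(self.files[z])[y0:y1, x0:x1] for z in range(z0, z1)],
            axis=0,
        )


class RawSource:
    """Headerless raw binary with a JSON sidecar.

    The sidecar (``<name>.json``) must give ``dims`` (x, y, z) and
    ``bit_depth``; voxels are x-fastest, then y, then z (C order [z, y, x]).
    """

    def __init__(self, path: Path | str, sidecar: Path | str | None = None):
        self.path = Path(path)
        sidecar = Path(sidecar) if sidecar else self.path.with_suffix(".json")
        info = json.loads(Path(sidecar).read_text())
        self.dims = tuple(info["dims"])
        self.bit_depth = int(info["bit_depth"])
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        x, y, z = self.dims
        self._mm = np.memmap(self.path, dtype=dtype, mode="r", shape=(z, y, x))

    def read_box(self, x0, x1, y0, y1, z0, z1) -> np.ndarray:
        _check_box(self.dims, x0, x1, y0, y1, z0, z1)
        return np.asarray(self._mm[z0:z1, y0:y1, x0:x1])


def open_source(path: Path | str) -> SourceVolume:
    """Open a TIFF stack, a directory of slices, or a raw file with sidecar."""
    path = Path(path)
    if path.is_dir():
        return SliceDirSource(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return TiffStackSource(path)
    return RawSource(path)


# ---------------------------------------------------------------------------
# downsampling

def _pair_reduce(sums: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum adjacent pairs along one axis; returns (pair sums, pair counts)."""
    n = sums.shape[axis]
    even = n - (n % 2)
    head = np.take(sums, range(0, even, 2), axis=axis) + np.take(
        sums, range(1, even, 2), axis=axis
    )
    counts = np.full(head.shape[axis], 2, dtype=np.int64)
    if n % 2:
        tail = np.take(sums, [n - 1], axis=axis)
        head = np.concatenate([head, tail], axis=axis)
        counts = np.append(counts, 1)
    return head, counts


def downsample2x(volume: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Halve a [z, y, x] volume along every axis (ceil at odd edges).

    ``mean``: each output voxel is the arithmetic mean of its up-to-2x2x2
    source neighborhood, rounded half-up.  ``stride``: keep every other voxel.
    """
    if volume.ndim != 3:
        raise ValueError("downsample2x needs a 3D array")
    if mode == "stride":
        return volume[::2, ::2, ::2].copy()
    if mode != "mean":
        raise ValueError(f"unknown downsample mode {mode!r}")
    sums = volume.astype(np.int64)
    axis_counts = []
    for axis in range(3):
        sums, counts = _pair_reduce(sums, axis)
        axis_counts.append(counts)
    cz, cy, cx = axis_counts
    counts = cz[:, None, None] * cy[None, :, None] * cx[None, None, :]
    rounded = (2 * sums + counts) // (2 * counts)  # floor(sum/count + 0.5)
    return rounded.astype(volume.dtype)


# ---------------------------------------------------------------------------
# dicing

def dice(
    level_volume: np.ndarray, block_size: int, r: int = 1
) -> Iterator[tuple[BlockCoord, Block]]:
    """Split a [z, y, x] level volume into zero-padded cubes.

    Blocks are yielded in (i, j, k) lexicographic order over the ceil grid;
    edge blocks are padded with zeros up to a full cube.
    """
    nz, ny, nx = level_volume.shape
    bit_depth = 8 if level_volume.dtype == np.uint8 else 16
    gz, gy, gx = (-(-n // block_size) for n in (nz, ny, nx))
    for i in range(gz):
        for j in range(gy):
            for k in range(gx):
                cube = level_volume[
                    i * block_size : (i + 1) * block_size,
                    j * block_size : (j + 1) * block_size,
                    k * block_size : (k + 1) * block_size,
                ]
                if cube.shape != (block_size,) * 3:
                    pad = [(0, block_size - s) for s in cube.shape]
                    cube = np.pad(cube, pad, constant_values=0)
                yield (
                    BlockCoord(r=r, k=k, j=j, i=i),
                    Block(data=np.ascontiguousarray(cube), bit_depth=bit_depth),
                )


# ---------------------------------------------------------------------------
# reformat driver

@dataclass
class ReformatConfig:
    downsample: str = "mean"  # "mean" or "stride"
    slab_depth: int | None = None  # z-depth streamed per pass; default 2*block
    force: bool = False
    name: str = "dataset"
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)


def _write_slab_blocks(
    root: Path, slab: np.ndarray, spec: LevelSpec, z_offset: int, block_size: int
) -> None:
    """Dice one z-slab (z_offset is a multiple of block_size) and write it."""
    i0 = z_offset // block_size
    for coord, block in dice(slab, block_size, r=spec.r):
        coord = BlockCoord(r=spec.r, k=coord.k, j=coord.j, i=coord.i + i0)
        for plane in split_planes(block):
            store.write_bitblock(root, BitPlaneRef(coord=coord, b=plane.b), plane)


def reformat(
    source: SourceVolume,
    out_root: Path | str,
    block_size: int = 128,
    config: ReformatConfig | None = None,
) -> DatasetMeta:
    """Convert a source volume into a complete bitBlock tree plus metadata.

    Writes ``count_files(plan, bit_depth)`` TIFF files and ``metadata.json``;
    a sentinel file flags partially written trees if conversion aborts.
    """
    config = config or ReformatConfig()
    out_root = Path(out_root)
    if (out_root / store.METADATA_NAME).is_file() and not (out_root / SENTINEL).exists():
        if not config.force:
            raise FileExistsError(
                f"{out_root} already holds a complete dataset (use force to overwrite)"
            )
        shutil.rmtree(out_root)
    out_root.mkdir(parents=True, exist_ok=True)

    meta = DatasetMeta(
        name=config.name,
        dims=tuple(source.dims),
        voxel_size=tuple(config.voxel_size),
        bit_depth=source.bit_depth,
        block_size=block_size,
        downsample=config.downsample,
    )
    plan = plan_pyramid(meta)
    slab_depth = config.slab_depth or 2 * block_size
    if slab_depth % block_size:
        raise ValueError("slab_depth must be a multiple of block_size")

    sentinel = out_root / SENTINEL
    sentinel.write_text("reformat in progress\n")
    scratch = out_root / ".tmp_levels"
    scratch.mkdir(exist_ok=True)
    dtype = np.uint8 if meta.bit_depth == 8 else np.uint16
    try:
        current: SourceVolume = source
        for spec in plan:
            dx, dy, dz = spec.dims_r
            is_last = spec.r == meta.levels
            next_mm = None
            if not is_last:
                ndx, ndy, ndz = plan[spec.r].dims_r
                next_mm = np.memmap(
                    scratch / f"level{spec.r + 1}.raw",
                    dtype=dtype, mode="w+", shape=(ndz, ndy, ndx),
                )
            for z0 in range(0, dz, slab_depth):
                z1 = min(z0 + slab_depth, dz)
                slab = current.read_box(0, dx, 0, dy, z0, z1)
                _write_slab_blocks(out_root, slab, spec, z0, block_size)
                if next_mm is not None:
                    ds = downsample2x(slab, config.downsample)
                    next_mm[z0 // 2 : z0 // 2 + ds.shape[0]] = ds
            if next_mm is not None:
                next_mm.flush()
                current = ArraySource(np.asarray(next_mm))
        store.write_metadata(out_root, meta)
    except Exception:
        raise
    else:
        sentinel.unlink()
    finally:
        shutil.rmtree(scratch, ignore_errors=True)
    return meta
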