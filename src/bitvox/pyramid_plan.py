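"""Multiresolution pyramid arithmetic.

Pure integer bookkeeping for the bit-plane-separated block pyramid: per-level
dimensions under recursive 2x ceil-halving, block grids, the stopping rule
(downsample until every axis is strictly below the block edge), and file
accounting.  No I/O happens here; every other module consumes these numbers.

Conventions fixed by this package (and recorded in dataset metadata):

* Level ``r = 1`` is the original resolution; level ``r + 1`` is a 2x
  downsampling of level ``r`` on every axis, with odd axes rounding *up*
  (``ceil(d / 2)``), so no voxel is ever dropped from coverage.
* Block indices ``i`` (z), ``j`` (y), ``k`` (x) are 0-based; bit-plane index
  ``b`` is 1-based with ``b = 1`` the most significant plane.
* Edge blocks count as full blocks (ceil grid); they are zero-padded when
  written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "DatasetMeta",
    "LevelSpec",
    "BlockCoord",
    "BitPlaneRef",
    "level_dims",
    "num_levels",
    "plan_pyramid",
    "count_files",
    "raw_size_bytes",
    "DEFAULT_BLOCK_SIZE",
]

DEFAULT_BLOCK_SIZE = 128

#: Codec conventions written into every metadata file so that an independent
#: reader never has to guess them.
CODEC_CONVENTIONS = {
    "scan_order": "x-fastest, then y, then z",
    "bit_order": "MSB-first within each packed byte",
    "plane_index": "b=1 is the most significant bit-plane",
    "block_index_origin": 0,
    "pad_value": 0,
}


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


@dataclass(frozen=True)
class LevelSpec:
    """Geometry of one pyramid level.

    ``dims_r`` are the voxel dimensions (x, y, z) at level ``r``; ``grid`` is
    the number of blocks along each axis (ceil division by the block edge).
    """

    r: int
    dims_r: tuple[int, int, int]
    grid: tuple[int, int, int]

    @property
    def n_blocks(self) -> int:
        return self.grid[0] * self.grid[1] * self.grid[2]


@dataclass(frozen=True)
class BlockCoord:
    """Address of one block: level ``r``, x-index ``k``, y-index ``j``,
    z-index ``i`` (all block indices 0-based)."""

    r: int
    k: int
    j: int
    i: int


@dataclass(frozen=True)
class BitPlaneRef:
    """One bit-plane file of one block; ``b`` runs 1 (MSB) .. bit depth."""

    coord: BlockCoord
    b: int


@dataclass
class DatasetMeta:
    """Global description of a converted dataset.

    ``dims`` are full-resolution voxel counts (x, y, z); ``voxel_size`` is in
    micrometres per voxel.  ``levels`` must equal
    :func:`num_levels` for the stated dims and block size — ``validate``
    enforces this so a hand-edited metadata file cannot silently disagree
    with the directory tree.
    """

    name: str
    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int = 8
    block_size: int = DEFAULT_BLOCK_SIZE
    levels: int = 0
    compression: str = "LZW"
    format_version: str = "1.0"
    conventions: dict = field(default_factory=lambda: dict(CODEC_CONVENTIONS))
    downsample: str = "mean"

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)  # type: ignore[assignment]
        if self.levels == 0:
            self.levels = num_levels(self.dims, self.block_size)
        self.validate()

    def validate(self) -> None:
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.block_size < 8 or self.block_size % 8:
            raise ValueError(
                f"block_size must be >= 8 and divisible by 8, got {self.block_size}"
            )
        expected = num_levels(self.dims, self.block_size)
        if self.levels != expected:
            raise ValueError(
                f"levels={self.levels} inconsistent with num_levels"
                f"({self.dims}, {self.block_size}) = {expected}"
            )

    @property
    def dtype_str(self) -> str:
        return "uint8" if self.bit_depth == 8 else "uint16"


def level_dims(dims: tuple[int, int, int], r: int) -> tuple[int, int, int]:
    """Voxel dimensions at level ``r``: ``ceil(d / 2**(r-1))`` per axis.

    Equivalent to applying ceil-halving ``r - 1`` times, since
    ``ceil(ceil(d/2)/2) == ceil(d/4)`` for integers.
    """
    if r < 1:
        raise ValueError(f"level index must be >= 1, got {r}")
    s = 1 << (r - 1)
    return tuple(_ceil_div(d, s) for d in dims)  # type: ignore[return-value]


def num_levels(dims: tuple[int, int, int], block_size: int = DEFAULT_BLOCK_SIZE) -> int:
    """Smallest L such that every axis of level L is strictly below
    ``block_size``.  A volume already smaller than one block yields 1."""
    if any(d < 1 for d in dims):
        raise ValueError(f"dims must be positive, got {dims}")
    r = 1
    while not all(d < block_size for d in level_dims(dims, r)):
        r += 1
    return r


def plan_pyramid(meta: DatasetMeta) -> list[LevelSpec]:
    """One :class:`LevelSpec` per level, 1 .. ``meta.levels``."""
    out = []
    for r in range(1, meta.levels + 1):
        d = level_dims(meta.dims, r)
        grid = tuple(_ceil_div(x, meta.block_size) for x in d)
        out.append(LevelSpec(r=r, dims_r=d, grid=grid))  # type: ignore[arg-type]
    return out


def count_files(plan: list[LevelSpec], planes_per_block: int) -> int:
    """Total number of on-disk files: blocks x planes, summed over levels.

    ``planes_per_block`` is the bit depth for the bit-plane layout, or 1 for
    a one-file-per-block layout.
    """
    if planes_per_block < 1:
        raise ValueError("planes_per_block must be >= 1")
    return sum(spec.n_blocks for spec in plan) * planes_per_block


def raw_size_bytes(dims: tuple[int, int, int], bit_depth: int) -> int:
    """Uncompressed size of the full-resolution volume in bytes."""
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    return math.prod(dims) * (bit_depth // 8)


def iter_block_coords(spec: LevelSpec) -> Iterator[BlockCoord]:
    """All block coordinates of one level in (i, j, k) lexicographic order."""
    nx, ny, nz = spec.grid
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                yield BlockCoord(r=spec.r, k=k, j=j, i=i)
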