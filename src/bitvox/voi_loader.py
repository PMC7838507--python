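"""Progressive volume-of-interest loading.

A navigation window is an axis-aligned box in full-resolution (level-1) voxel
coordinates.  The loader picks the resolution level from the window volume
and a per-request size cap *M* (in mebivoxels, default 20)::

    R = floor(log2(V / (1024 * 1024 * M))),   clamped to [1, levels]

so larger windows load coarser levels and a request never materially exceeds
the cap.  The covering blocks at that level are then streamed bit-plane by
bit-plane, most significant first: refinement *m* equals the stored VOI
quantized to its top *m* bits, so per-voxel error is bounded by
``2**(B - m) - 1`` and shrinks monotonically.  Half-bit mode stops after the
top half of the planes (top 4 of 8), halving the number of files transferred
at a bounded fidelity cost.  While refinement *m* is merged and handed to the
caller, the next plane is already being fetched on a background thread, so
merge and transfer overlap.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np

from .bitplane_codec import BitPlane, merge_planes
from .pyramid_plan import (
    BitPlaneRef,
    BlockCoord,
    DatasetMeta,
    level_dims,
    plan_pyramid,
)
from . import store

__all__ = [
    "VOIBox",
    "LoaderConfig",
    "ProgressiveVOI",
    "resolution_level",
    "blocks_for_box",
    "load_progressive",
    "load_full",
    "assemble",
    "local_fetcher",
    "http_fetcher",
]

FetchFn = Callable[[BitPlaneRef], BitPlane]


@dataclass(frozen=True)
class VOIBox:
    """Half-open [min, max) box in level-1 voxel coordinates."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int
    z_min: int
    z_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max and self.z_min < self.z_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def volume(self) -> int:
        return (
            (self.x_max - self.x_min)
            * (self.y_max - self.y_min)
            * (self.z_max - self.z_min)
        )

    def clipped(self, dims: tuple[int, int, int]) -> "VOIBox | None":
        """Intersection with the dataset extent, or None if disjoint."""
        x0, y0, z0 = max(self.x_min, 0), max(self.y_min, 0), max(self.z_min, 0)
        x1 = min(self.x_max, dims[0])
        y1 = min(self.y_max, dims[1])
        z1 = min(self.z_max, dims[2])
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            return None
        return VOIBox(x0, x1, y0, y1, z0, z1)


@dataclass
class LoaderConfig:
    """Loader tunables: size cap M (mebivoxels), half-bit flag, log base."""

    M: int = 20
    half_bit: bool = False
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")


@dataclass
class ProgressiveVOI:
    """One refinement step: the VOI after merging planes 1..m."""

    m: int
    data: np.ndarray
    level: int
    complete: bool
    box_level: tuple[int, int, int, int, int, int] = field(default=())  # type: ignore[assignment]


def resolution_level(box: VOIBox, meta: DatasetMeta, config: LoaderConfig | None = None) -> int:
    """Pick the pyramid level for a navigation window (floor of the log of
    window volume over the cap, clamped to the valid level range)."""
    config = config or LoaderConfig()
    ratio = box.volume / (1024 * 1024 * config.M)
    if ratio <= 0:
        raise ValueError("degenerate box")
    r_raw = math.floor(math.log(ratio, config.log_base))
    return max(1, min(meta.levels, r_raw))


def _to_level(box: VOIBox, r: int) -> tuple[int, int, int, int, int, int]:
    """Map a level-1 box to level-r voxel coordinates (floor min, ceil max)."""
    s = 1 << (r - 1)
    return (
        box.x_min // s, -(-box.x_max // s),
        box.y_min // s, -(-box.y_max // s),
        box.z_min // s, -(-box.z_max // s),
    )


def blocks_for_box(box: VOIBox, r: int, meta: DatasetMeta) -> list[BlockCoord]:
    """Minimal set of level-r block coordinates covering the box.

    The box is clipped to the dataset extent first; a box entirely outside
    yields an empty list.
    """
    if not 1 <= r <= meta.levels:
        raise ValueError(f"level {r} outside 1..{meta.levels}")
    clipped = box.clipped(meta.dims)
    if clipped is None:
        return []
    x0, x1, y0, y1, z0, z1 = _to_level(clipped, r)
    dr = level_dims(meta.dims, r)
    x1, y1, z1 = min(x1, dr[0]), min(y1, dr[1]), min(z1, dr[2])
    bs = meta.block_size
    return [
        BlockCoord(r=r, k=k, j=j, i=i)
        for i in range(z0 // bs, -(-z1 // bs))
        for j in range(y0 // bs, -(-y1 // bs))
        for k in range(x0 // bs, -(-x1 // bs))
    ]


def assemble(
    blocks: dict[BlockCoord, np.ndarray],
    box: VOIBox,
    r: int,
    meta: DatasetMeta,
) -> np.ndarray:
    """Stitch per-block arrays into the level-r crop of the box.

    Zero padding of edge blocks and any margin outside the box is discarded;
    the output shape equals the clipped level-r box extents ([z, y, x]).
    """
    clipped = box.clipped(meta.dims)
    if clipped is None:
        raise ValueError("box does not intersect the dataset")
    x0, x1, y0, y1, z0, z1 = _to_level(clipped, r)
    dr = level_dims(meta.dims, r)
    x1, y1, z1 = min(x1, dr[0]), min(y1, dr[1]), min(z1, dr[2])
    bs = meta.block_size
    dtype = np.uint8 if meta.bit_depth == 8 else np.uint16
    out = np.zeros((z1 - z0, y1 - y0, x1 - x0), dtype=dtype)
    for coord, data in blocks.items():
        bx0, by0, bz0 = coord.k * bs, coord.j * bs, coord.i * bs
        sx0, sx1 = max(x0, bx0), min(x1, bx0 + bs)
        sy0, sy1 = max(y0, by0), min(y1, by0 + bs)
        sz0, sz1 = max(z0, bz0), min(z1, bz0 + bs)
        if sx0 >= sx1 or sy0 >= sy1 or sz0 >= sz1:
            continue
        out[sz0 - z0 : sz1 - z0, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = data[
            sz0 - bz0 : sz1 - bz0, sy0 - by0 : sy1 - by0, sx0 - bx0 : sx1 - bx0
        ]
    return out


def _fetch_plane(
    fetch: FetchFn, coords: list[BlockCoord], b: int
) -> dict[BlockCoord, BitPlane]:
    return {c: fetch(BitPlaneRef(coord=c, b=b)) for c in coords}


def load_progressive(
    box: VOIBox,
    meta: DatasetMeta,
    source: FetchFn,
    config: LoaderConfig | None = None,
    r: int | None = None,
) -> Iterator[ProgressiveVOI]:
    """Stream a VOI plane-at-a-time, most significant plane first.

    Yields one :class:`ProgressiveVOI` per merged plane count m = 1..P where
    P is the bit depth (full-bit) or half of it (half-bit).  Refinement m is
    yielded as soon as every plane-m bitBlock of the covering set has
    arrived; plane m+1 is prefetched on a worker thread while the caller
    consumes refinement m.
    """
    config = config or LoaderConfig()
    if r is None:
        r = resolution_level(box, meta, config)
    coords = blocks_for_box(box, r, meta)
    if not coords:
        raise ValueError("box does not intersect the dataset")
    P = meta.bit_depth // 2 if config.half_bit else meta.bit_depth
    clipped = box.clipped(meta.dims)
    assert clipped is not None
    box_level = _to_level(clipped, r)

    acc: dict[BlockCoord, list[BitPlane]] = {c: [] for c in coords}
    with ThreadPoolExecutor(max_workers=1) as pool:
        future = pool.submit(_fetch_plane, source, coords, 1)
        for m in range(1, P + 1):
            arrived = future.result()
            if m < P:
                future = pool.submit(_fetch_plane, source, coords, m + 1)
            blocks: dict[BlockCoord, np.ndarray] = {}
            for c in coords:
                acc[c].append(arrived[c])
                blocks[c] = merge_planes(acc[c], meta.bit_depth).data
            yield ProgressiveVOI(
                m=m,
                data=assemble(blocks, box, r, meta),
                level=r,
                complete=(m == P),
                box_level=box_level,
            )


def load_full(
    box: VOIBox,
    meta: DatasetMeta,
    source: FetchFn,
    config: LoaderConfig | None = None,
    r: int | None = None,
) -> ProgressiveVOI:
    """Convenience: run the progressive loader to completion."""
    last = None
    for last in load_progressive(box, meta, source, config, r=r):
        pass
    assert last is not None
    return last


def local_fetcher(root: Path | str, meta: DatasetMeta) -> FetchFn:
    """Fetch function reading bitBlocks from a local tree."""
    return lambda ref: store.read_bitblock(root, ref, meta.block_size)


def http_fetcher(base_url: str, meta: DatasetMeta, retries: int = 3) -> FetchFn:
    """Fetch function retrieving bitBlocks over HTTP."""
    return lambda ref: store.fetch_bitblock(base_url, ref, meta.block_size, retries=retries)
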