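"""Lossless bit-plane decomposition of voxel blocks.

A block is a cubic ``(edge, edge, edge)`` array of unsigned B-bit voxels,
stored in memory as ``data[z, y, x]`` so that a C-order ravel traverses x
fastest, then y, then z.  :func:`split_planes` peels the block into B binary
planes (plane 1 = most significant bit) and packs each plane 8 bits per byte,
MSB first, giving a payload of exactly ``edge**3 / 8`` bytes irrespective of
content.  :func:`merge_planes` is the exact inverse; given only the top *m*
planes it reconstructs the value quantized to its top *m* bits, which is what
makes plane-at-a-time streaming a progressive refinement rather than a lossy
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Block",
    "BitPlane",
    "split_planes",
    "merge_planes",
    "quantize_top",
    "max_error_bound",
]


@dataclass
class Block:
    """Dense cubic voxel array with an explicit bit depth."""

    data: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        a = np.asarray(self.data)
        if a.ndim != 3 or len(set(a.shape)) != 1:
            raise ValueError(f"block must be cubic 3D, got shape {a.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        if a.dtype != dtype:
            if a.size and int(a.max(initial=0)) > (1 << self.bit_depth) - 1:
                raise ValueError("voxel values exceed bit depth")
            a = a.astype(dtype)
        self.data = a

    @property
    def edge(self) -> int:
        return self.data.shape[0]


@dataclass
class BitPlane:
    """Packed payload of one bit-plane of one block.

    ``payload`` holds ``block_size**3 / 8`` bytes: voxels in x-fastest scan
    order, 8 consecutive bits per byte, MSB first.
    """

    b: int
    payload: bytes
    block_size: int

    def __post_init__(self) -> None:
        expected = self.block_size**3 // 8
        if len(self.payload) != expected:
            raise ValueError(
                f"payload must be {expected} bytes for block {self.block_size}, "
                f"got {len(self.payload)}"
            )

    def unpack(self) -> np.ndarray:
        """Unpack to a binary (z, y, x) array of 0/1 uint8."""
        bits = np.unpackbits(np.frombuffer(self.payload, dtype=np.uint8))
        e = self.block_size
        return bits.reshape(e, e, e)


def split_planes(block: Block) -> list[BitPlane]:
    """Decompose a block into its B bit-planes, plane 1 first (MSB)."""
    B = block.bit_depth
    flat = block.data.ravel(order="C")
    planes = []
    for b in range(1, B + 1):
        bits = ((flat >> (B - b)) & 1).astype(np.uint8)
        payload = np.packbits(bits).tobytes()  # MSB-first within each byte
        planes.append(BitPlane(b=b, payload=payload, block_size=block.edge))
    return planes


def merge_planes(planes: Iterable[BitPlane], bit_depth: int) -> Block:
    """Reconstruct a block from any subset of its planes.

    Missing planes contribute zero, so merging planes {1..m} yields the
    top-m-bit quantization of the original values.  Duplicate plane indices
    are rejected.
    """
    planes = list(planes)
    if not planes:
        raise ValueError("merge_planes needs at least one plane (or use zeros)")
    edge = planes[0].block_size
    seen: set[int] = set()
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    acc = np.zeros((edge, edge, edge), dtype=dtype)
    for p in planes:
        if p.block_size != edge:
            raise ValueError("planes have inconsistent block sizes")
        if not 1 <= p.b <= bit_depth:
            raise ValueError(f"plane index {p.b} outside 1..{bit_depth}")
        if p.b in seen:
            raise ValueError(f"duplicate plane index {p.b}")
        seen.add(p.b)
        acc |= p.unpack().astype(dtype) << (bit_depth - p.b)
    return Block(data=acc, bit_depth=bit_depth)


def quantize_top(block: Block, m: int) -> Block:
    """Keep only the top ``m`` bits of every voxel: ``(v >> (B-m)) << (B-m)``.

    Identical to merging planes 1..m of :func:`split_planes`; kept as an
    independent closed form so progressive refinement can be cross-checked.
    """
    B = block.bit_depth
    if not 1 <= m <= B:
        raise ValueError(f"m must be in 1..{B}, got {m}")
    shift = B - m
    return Block(data=(block.data >> shift) << shift, bit_depth=B)


def max_error_bound(m: int, B: int) -> int:
    """Largest possible |v - quantize_top(v, m)| = ``2**(B-m) - 1``."""
    if not 1 <= m <= B:
        raise ValueError(f"m must be in 1..{B}, got {m}")
    return (1 << (B - m)) - 1


def merge_payload_arrays(
    payloads: Sequence[tuple[int, bytes]], bit_depth: int, edge: int
) -> np.ndarray:
    """Low-level merge used by the loader: (b, payload) pairs -> voxel array."""
    planes = [BitPlane(b=b, payload=p, block_size=edge) for b, p in payloads]
    if not planes:
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        return np.zeros((edge, edge, edge), dtype=dtype)
    return merge_planes(planes, bit_depth).data
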