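"""2D presentation and vector annotation.

Maximum-intensity projections (with a controllable slab thickness) and
orthogonal slices turn a loaded VOI into 2D images for inspection and
annotation.  Annotations are vector structures — points (somas), polylines
with an optional tube radius (neuron fibers), and closed planar contours
(e.g. a brain outline) — stored in *global* level-1 voxel coordinates so
they survive VOI changes.  Contours rasterize to binary masks under the
even-odd rule with a pixel-center test, which makes masks reproducible
bit-exactly.  Polylines export to the SWC morphology interchange format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np

__all__ = [
    "PointAnn",
    "LineAnn",
    "ContourAnn",
    "mip",
    "ortho_slices",
    "contour_to_mask",
    "save_annotations",
    "load_annotations",
    "export_swc",
    "import_swc",
]

_AXES = {"x": 2, "y": 1, "z": 0}  # name -> array axis for [z, y, x] volumes


@dataclass
class PointAnn:
    position: tuple[float, float, float]  # (x, y, z), level-1 voxels
    label: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite point {self.position}")


@dataclass
class LineAnn:
    vertices: list[tuple[float, float, float]]
    radius: float | None = None  # micrometres
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("a line needs at least two vertices")


@dataclass
class ContourAnn:
    axis: str  # "x", "y" or "z": the axis the slice plane is normal to
    slice_index: int
    vertices: list[tuple[float, float]]  # in-plane (col, row) coordinates
    label: str = ""
    closed: bool = field(default=True, init=False)  # implicit closure

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be x, y or z, got {self.axis!r}")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least three vertices")


# ---------------------------------------------------------------------------
# projections and slices

def mip(voi: np.ndarray, axis: str | int, center: int, thickness: int = 1) -> np.ndarray:
    """Maximum-intensity projection over a slab along one axis.

    The slab is the half-open range ``[center - t//2, center + ceil(t/2))``
    clipped to the volume; it must intersect the volume and thickness must
    be >= 1.  Thickness 1 returns the single slice at ``center``.
    """
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    n = voi.shape[ax]
    lo = max(center - thickness // 2, 0)
    hi = min(center + (thickness + 1) // 2, n)
    if lo >= hi:
        raise ValueError(f"slab [{lo},{hi}) does not intersect axis of length {n}")
    slab = np.take(voi, range(lo, hi), axis=ax)
    return slab.max(axis=ax)


def ortho_slices(
    voi: np.ndarray, point: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The XY, YZ and XZ planes through a point given as (x, y, z)."""
    x, y, z = point
    nz, ny, nx = voi.shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise ValueError(f"point {point} outside volume of shape (x,y,z)=({nx},{ny},{nz})")
    xy = voi[z, :, :]  # rows y, cols x
    yz = voi[:, :, x]  # rows z, cols y
    xz = voi[:, y, :]  # rows z, cols x
    return xy, yz, xz


# ---------------------------------------------------------------------------
# contour rasterization

def contour_to_mask(contour: ContourAnn, slice_dims: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed contour to a binary mask of shape (rows, cols).

    A pixel (row r, col c) is set iff its center (c, r) lies inside the
    polygon under the even-odd rule, tested with the standard half-open
    crossing count (edges at the pixel's y straddle it as [y1, y2)); this
    gives axis-aligned integer rectangles their exact half-open pixel count.
    """
    rows, cols = slice_dims
    vx = np.array([v[0] for v in contour.vertices], dtype=float)
    vy = np.array([v[1] for v in contour.vertices], dtype=float)
    area2 = np.abs(np.dot(vx, np.roll(vy, -1)) - np.dot(vy, np.roll(vx, -1)))
    if area2 == 0:
        warnings.warn("degenerate (zero-area) contour yields an empty mask")
        return np.zeros(slice_dims, dtype=bool)

    cx = np.arange(cols, dtype=float)
    cy = np.arange(rows, dtype=float)
    px = np.broadcast_to(cx[None, :], (rows, cols))
    py = np.broadcast_to(cy[:, None], (rows, cols))
    inside = np.zeros((rows, cols), dtype=bool)
    n = len(vx)
    for e in range(n):
        x1, y1 = vx[e], vy[e]
        x2, y2 = vx[(e + 1) % n], vy[(e + 1) % n]
        straddles = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (x2 - x1) * (py - y1) / (y2 - y1) + x1
        inside ^= straddles & (px < x_at)
    return inside


# ---------------------------------------------------------------------------
# annotation I/O

def _ann_to_obj(ann) -> dict:
    if isinstance(ann, PointAnn):
        return {"type": "point", "position": list(ann.position), "label": ann.label}
    if isinstance(ann, LineAnn):
        return {
            "type": "line",
            "vertices": [list(v) for v in ann.vertices],
            "radius": ann.radius,
            "label": ann.label,
        }
    if isinstance(ann, ContourAnn):
        return {
            "type": "contour",
            "axis": ann.axis,
            "slice_index": ann.slice_index,
            "vertices": [list(v) for v in ann.vertices],
            "label": ann.label,
        }
    raise TypeError(f"not an annotation: {ann!r}")


def _obj_to_ann(obj: dict):
    kind = obj.get("type")
    if kind == "point":
        return PointAnn(position=tuple(obj["position"]), label=obj.get("label", ""))
    if kind == "line":
        return LineAnn(
            vertices=[tuple(v) for v in obj["vertices"]],
            radius=obj.get("radius"),
            label=obj.get("label", ""),
        )
    if kind == "contour":
        return ContourAnn(
            axis=obj["axis"],
            slice_index=int(obj["slice_index"]),
            vertices=[tuple(v) for v in obj["vertices"]],
            label=obj.get("label", ""),
        )
    raise ValueError(f"unknown annotation type tag {kind!r}")


def save_annotations(
    path: Path | str,
    annotations: Sequence,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Path:
    """Write annotations as JSON; coordinates are level-1 voxels, with the
    voxel size recorded so readers can convert to micrometres."""
    path = Path(path)
    doc = {
        "coordinate_space": "level1_voxels",
        "voxel_size_um": list(voxel_size),
        "annotations": [_ann_to_obj(a) for a in annotations],
    }
    path.write_text(json.dumps(doc, indent=2))
    return path


def load_annotations(path: Path | str) -> list:
    doc = json.loads(Path(path).read_text())
    return [_obj_to_ann(o) for o in doc["annotations"]]


# ---------------------------------------------------------------------------
# SWC export

def export_swc(lines: Sequence[LineAnn], path: Path | str) -> Path:
    """Write polylines as SWC: one node per vertex, parented to the previous
    vertex, each line's first node a root (parent -1).  Node type 0
    (undefined); radius from the line's radius, defaulting to 1.0.
    """
    if not lines:
        raise ValueError("no lines to export")
    path = Path(path)
    rows = ["# SWC export: neuron fiber polylines", "# id type x y z radius parent"]
    nid = 0
    for line in lines:
        parent = -1
        for x, y, z in line.vertices:
            nid += 1
            radius = line.radius if line.radius is not None else 1.0
            rows.append(f"{nid} 0 {x:g} {y:g} {z:g} {radius:g} {parent}")
            parent = nid
    path.write_text("\n".join(rows) + "\n")
    return path


def import_swc(path: Path | str) -> list[LineAnn]:
    """Read an SWC file back into polylines (each root starts a new line)."""
    nodes: dict[int, tuple[tuple[float, float, float], float, int]] = {}
    order: list[int] = []
    for raw in Path(path).read_text().splitlines():
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        parts = raw.split()
        nid, _t = int(parts[0]), int(parts[1])
        x, y, z, radius = map(float, parts[2:6])
        parent = int(parts[6])
        nodes[nid] = ((x, y, z), radius, parent)
        order.append(nid)
    lines: list[LineAnn] = []
    current: list[tuple[float, float, float]] = []
    radius: float | None = None
    for nid in order:
        pos, rad, parent = nodes[nid]
        if parent == -1:
            if len(current) >= 2:
                lines.append(LineAnn(vertices=current, radius=radius))
            current, radius = [pos], rad
        else:
            current.append(pos)
    if len(current) >= 2:
        lines.append(LineAnn(vertices=current, radius=radius))
    return lines
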