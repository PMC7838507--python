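"""Synthetic fluorescence-microscopy phantoms with ground truth.

Sparse-labelling fluorescence data (e.g. GFP-expressing neurons imaged by
fMOST or light-sheet microscopy) is dominated by a dark background with a
small fraction of bright structure: roughly spherical somas and thin,
elongated fibers.  The generator emulates exactly that regime so the format,
codec and loader can be exercised end to end with no external data: Gaussian
soma blobs and random-walk fiber tubes on a low constant background, blurred
to mimic the optical point-spread function, with additive Gaussian read
noise, clipped and quantized to the target bit depth.  Every draw comes from
one seeded generator in a documented order (soma centers and radii first,
then fiber walks, then the noise field), so a given spec and seed always
produce the identical volume and truth list.

It deliberately does not model Poisson photon statistics, PSF anisotropy,
illumination gradients, or tile seams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .pyramid_plan import DatasetMeta
from .reformatter import ArraySource, ReformatConfig, reformat
from .view_annotate import LineAnn, PointAnn, save_annotations

__all__ = ["PhantomSpec", "make_phantom", "make_fixture_dataset", "PRESETS"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom volume.

    ``dims`` is (x, y, z) in voxels; intensities are in gray levels of the
    target bit depth; radii and sigmas in voxels.
    """

    dims: tuple[int, int, int] = (300, 256, 200)
    n_somas: int = 12
    soma_radius: tuple[float, float] = (4.0, 8.0)
    n_fibers: int = 8
    fiber_radius: float = 1.5
    fiber_steps: int = 60
    amplitude: int = 200
    background: int = 10
    blur_sigma: float = 1.5
    noise_sigma: float = 4.0
    bit_depth: int = 8
    seed: int = 42

    def __post_init__(self) -> None:
        if any(d < 32 for d in self.dims):
            raise ValueError("dims must be >= 32 per axis")
        if not self.background < self.amplitude <= (1 << self.bit_depth) - 1:
            raise ValueError("need background < amplitude <= max gray level")


#: Named parameter sets.  ``soma-fiber`` is the default high-contrast
#: phantom; ``contrast-low`` narrows the dynamic range so the lower
#: bit-planes carry visually relevant signal.
PRESETS: dict[str, PhantomSpec] = {
    "soma-fiber": PhantomSpec(),
    "contrast-low": PhantomSpec(amplitude=60, background=25, noise_sigma=8.0),
}


def _place_somas(rng: np.random.Generator, spec: PhantomSpec):
    """Uniform random centers, rejecting overlaps; bounded retries."""
    nx, ny, nz = spec.dims
    r_lo, r_hi = spec.soma_radius
    margin = r_hi + 2 * spec.blur_sigma
    centers: list[np.ndarray] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < spec.n_somas:
        attempts += 1
        if attempts > 200 * max(spec.n_somas, 1):
            raise RuntimeError(
                f"could not pack {spec.n_somas} somas into dims {spec.dims}"
            )
        c = rng.uniform([margin] * 3, [nx - margin, ny - margin, nz - margin])
        r = rng.uniform(r_lo, r_hi)
        # keep blobs separable after blurring: gap of both radii plus the
        # blurred skirts, so thresholding at half amplitude never merges them
        sep_ok = all(
            np.linalg.norm(c - p) >= (r + pr) + 4 * spec.blur_sigma + 2
            for p, pr in zip(centers, radii)
        )
        if sep_ok:
            centers.append(c)
            radii.append(r)
    return centers, radii


def _add_gaussian_blob(field: np.ndarray, center, sigma: float) -> None:
    """Add a unit-peak Gaussian blob, evaluated on a local window only."""
    nz, ny, nx = field.shape
    cx, cy, cz = center
    ext = int(np.ceil(4 * sigma))
    x0, x1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, nx)
    y0, y1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, ny)
    z0, z1 = max(int(cz) - ext, 0), min(int(cz) + ext + 1, nz)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
    field[z0:z1, y0:y1, x0:x1] += np.exp(-d2 / (2 * sigma**2))


def _fiber_walk(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Persistent random walk: unit steps with slowly drifting direction."""
    nx, ny, nz = spec.dims
    pos = rng.uniform([8, 8, 8], [nx - 8, ny - 8, nz - 8])
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    step = 3.0
    pts = [pos.copy()]
    for _ in range(spec.fiber_steps):
        direction += 0.35 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + step * direction
        pos = np.clip(pos, 2, [nx - 3, ny - 3, nz - 3])
        pts.append(pos.copy())
    return np.array(pts)


def _rasterize_tube(field: np.ndarray, pts: np.ndarray, radius: float) -> None:
    """Stamp unit intensity within ``radius`` of the polyline (dense samples)."""
    nz, ny, nx = field.shape
    ext = int(np.ceil(radius)) + 1
    for a, b in zip(pts[:-1], pts[1:]):
        seg_len = float(np.linalg.norm(b - a))
        n_samples = max(int(seg_len * 2), 1)
        for t in np.linspace(0.0, 1.0, n_samples, endpoint=False):
            cx, cy, cz = a + t * (b - a)
            x0, x1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, nx)
            y0, y1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, ny)
            z0, z1 = max(int(cz) - ext, 0), min(int(cz) + ext + 1, nz)
            if x0 >= x1 or y0 >= y1 or z0 >= z1:
                continue
            zz, yy, xx = np.meshgrid(
                np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
            )
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
            np.maximum(
                field[z0:z1, y0:y1, x0:x1],
                (d2 <= radius**2).astype(field.dtype),
                out=field[z0:z1, y0:y1, x0:x1],
            )


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, list]:
    """Generate one phantom volume ([z, y, x]) and its ground-truth list.

    Truth holds soma centers as points and fiber center-lines as lines, in
    (x, y, z) voxel coordinates of the generated (level-1) volume.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.dims
    structure = np.zeros((nz, ny, nx), dtype=np.float64)
    truth: list = []

    centers, radii = _place_somas(rng, spec)
    for c, r in zip(centers, radii):
        _add_gaussian_blob(structure, c, sigma=r / 2.0)
        truth.append(PointAnn(position=tuple(c), label="soma"))

    fibers = np.zeros_like(structure)
    for _ in range(spec.n_fibers):
        pts = _fiber_walk(rng, spec)
        _rasterize_tube(fibers, pts, spec.fiber_radius)
        truth.append(
            LineAnn(vertices=[tuple(p) for p in pts], radius=spec.fiber_radius, label="fiber")
        )
    structure = np.maximum(structure, 0.8 * fibers)

    field = spec.background + spec.amplitude * structure
    if spec.blur_sigma > 0:
        field = gaussian_filter(field, sigma=spec.blur_sigma)
    if spec.noise_sigma > 0:
        field = field + rng.normal(0.0, spec.noise_sigma, size=field.shape)
    vmax = (1 << spec.bit_depth) - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    volume = np.clip(np.rint(field), 0, vmax).astype(dtype)
    return volume, truth


def make_fixture_dataset(
    out_root: Path | str,
    spec: PhantomSpec | None = None,
    block_size: int = 32,
    name: str = "phantom",
    force: bool = False,
) -> DatasetMeta:
    """Phantom -> reformatted bitBlock tree + truth JSON; returns metadata."""
    spec = spec or PhantomSpec()
    volume, truth = make_phantom(spec)
    meta = reformat(
        ArraySource(volume),
        out_root,
        block_size=block_size,
        config=ReformatConfig(name=name, force=force),
    )
    save_annotations(Path(out_root) / "truth.json", truth)
    return meta


def spec_with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    return replace(spec, seed=seed)
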