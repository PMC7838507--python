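# Methods

## The format

`bitvox` stores a grayscale volume as a multiresolution pyramid of
fixed-size cubes, each cube decomposed into per-bit-plane files
("bitBlocks"). Three choices define the pyramid, and all three are forced
by the published accounting for a 13,913 × 18,000 × 5,115 whole-brain
volume (9 levels / 5,635,504 files at block 128, 7 levels / 11,578 files
at block 512):

* **Ceil-halving.** Level `r` has dimensions `ceil(d / 2^(r-1))` per axis.
  Iterated ceil-halving equals this closed form for integers, which the
  suite checks exhaustively over a wide range.
* **Stopping rule.** Downsampling stops at the first level whose *every*
  axis is *strictly* below the block edge. This is the unique reading that
  reproduces both published level counts from the same dimensions.
* **Ceil grids.** Edge blocks count (and are written) as full,
  zero-padded cubes. Zero is the natural pad in fluorescence imaging,
  where background is dark; padded voxels are cropped away at read time
  using the metadata extents, so they never reach a caller.

Index origins and byte order are not derivable from the accounting, so
they are fixed and recorded in every `metadata.json`: block indices
`i, j, k` are 0-based; the bit-plane index `b` is 1-based with `b = 1` the
most significant plane; voxels are scanned x-fastest, then y, then z; bits
pack MSB-first into bytes. Any conforming reader can interoperate from the
metadata alone.

## Serialization

A bitBlock payload is always `block_size³ / 8` bytes regardless of
content. It is wrapped in a single-image grayscale TIFF (8-bit samples,
width `block_size / 8`, height `block_size²`) and LZW-compressed with no
predictor: the payload bytes are packed bits, not intensities, so
horizontal differencing has no principled benefit. Lossy compression is
structurally excluded — a corrupted byte would flip bits of eight
different voxels at one significance level. TIFF reading/writing goes
through `tifffile`; the HTTP layer is a plain static file server (stdlib
`http.server`) plus a `urllib`-based fetcher with bounded retries (3 by
default), which the tests show is observationally identical to a local
read.

## Reformatting

The converter streams the source through the pyramid one z-slab at a time
(default slab: two block-depths, configurable as any multiple of the block
edge), so peak resident voxel data is bounded by a slab of the current
level — never the whole volume. Each slab is diced and written, and
simultaneously downsampled into a scratch memmap that becomes the next
level's source; slab starts are multiples of the (even) block edge, so
z-pairs never straddle a slab boundary. A sentinel file marks a tree as
in-progress and is removed only on success, so partial output is always
detectable. A parallel out-of-core scheduler is out of scope here; at the
volume sizes this package targets in tests, slab streaming preserves the
bounded-memory contract with far less machinery.

**Downsampling operator.** Each output voxel is the arithmetic mean of its
up-to-2×2×2 source neighborhood (fewer voxels at odd edges), computed in
exact integer arithmetic and rounded half-up:
`floor(sum/count + 1/2) = (2·sum + count) // (2·count)`. Mean reduction is
the standard anti-aliased choice for visualization pyramids; strided
subsampling is available behind `ReformatConfig(downsample="stride")` for
callers who want nearest-neighbor semantics. The choice affects voxel
values only, never dimensions or file counts.

## Progressive loading

A navigation window (an axis-aligned box in level-1 voxel coordinates)
selects a level via `R = floor(log_base(V / (2^20 · M)))`, clamped to
`[1, L]`, with `M = 20` mebivoxels and `base = 2` by default. Floor and
clamp are required to keep `R` a valid index for small windows. Two
genuinely open points, resolved as follows:

* With 2× downsampling per axis the per-level voxel count shrinks 8×, so
  base 8 would track the cap `M` tightly while base 2 coarsens faster than
  strictly necessary. The default follows the base-2 form; the base is a
  `LoaderConfig` field for callers who want the tight cap.
* `R` is interpreted as an absolute level index, not an offset from the
  currently displayed level.

The box is mapped to level `r` by `floor(min / 2^(r-1))` /
`ceil(max / 2^(r-1))` and covered by the minimal block set. Planes are
fetched most significant first; refinement `m` is handed to the caller as
soon as all plane-`m` blocks have arrived, and equals the stored VOI
quantized to its top `m` bits — voxel error ≤ `2^(B−m) − 1`, monotonically
non-increasing, zero at `m = B`. Plane `m+1` is prefetched on a worker
thread while the caller consumes refinement `m`, so merge and transfer
overlap. Half-bit mode stops at `m = B/2` (top 8 planes for 16-bit data)
and transfers exactly half the files.

## Presentation and annotation

MIP slabs are half-open `[center − ⌊t/2⌋, center + ⌈t/2⌉)` and clipped to
the volume; thickness 1 is the identity slice. Contours rasterize under
the even-odd rule with a pixel-center test implemented as a vectorized
crossing count; the suite checks it against an independent per-pixel
oracle on random simple polygons, and the half-open convention gives an
axis-aligned integer rectangle exactly `w·h` pixels. Annotations live in
global level-1 voxel coordinates (recorded with the voxel size for µm
conversion) so they survive VOI changes; polylines carry one optional
radius and export to SWC with each polyline a root-parented chain.

## The phantom generator

The generator emulates sparse-labelling fluorescence data: a dark
constant background (default 10) with bright Gaussian somas (peak 200,
radii 4–8 voxels, 12 per default volume) and thin random-walk fiber tubes
(radius 1.5 voxels, 8 fibers of 60 steps), blurred by an isotropic
Gaussian (σ = 1.5 voxels) standing in for the PSF, plus additive Gaussian
read noise (σ = 4), clipped and quantized to 8 bits. Soma placement is
rejection-sampled so that any two blobs stay separated by the sum of their
radii plus the blurred skirts; one seeded generator drives all draws in a
fixed order (somas, then fibers, then noise), so a spec and seed determine
the volume and truth list exactly. The default volume is 300 × 256 × 200
voxels converted at block 32 — small enough that the full
generate-reformat-measure cycle runs in seconds while still spanning five
pyramid levels with non-multiple-of-block edges on every axis.

This regime reproduces the qualitative storage asymmetry the format
exploits: structure is sparse, so high planes are mostly zero and
LZW-compress to a small fraction of the bytes (≈14% for the top four
planes on the default phantom), while read noise randomizes the low
planes and makes them nearly incompressible. The generator does *not*
model Poisson photon statistics, PSF anisotropy, illumination gradients,
or tile seams; Gaussian noise keeps determinism trivial and exercises the
codec identically. Passing tests therefore validate the format, codec,
accounting and streaming contracts — not photometric realism.

## Numerical and degenerate-input choices

* All pyramid arithmetic is exact integer arithmetic; no floats touch
  dimensions, grids or file counts.
* Downsampling rounds half-up, documented above and recorded in metadata.
* Degenerate VOI boxes (empty on any axis) are rejected; boxes partially
  outside the dataset are clipped, boxes fully outside yield an empty
  cover.
* Zero-area contours rasterize to an empty mask with a warning rather
  than an error, matching how viewers treat an accidental double-click.
* Metadata is schema-validated on read: a `levels` field inconsistent
  with the stated dimensions and block size is rejected outright.

## Known limitations

Single-channel grayscale only; no time series; no authentication, range
requests or caching on the HTTP path; no prefetching policy beyond
one-plane lookahead; conversion is single-process. Published wall-clock
and total-compressed-size figures are content- and hardware-dependent and
are not reproduced here.
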