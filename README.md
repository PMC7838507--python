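# bitvox

Mesoscopic whole-brain microscopy (fMOST, serial two-photon, light-sheet)
produces grayscale volumes of 10^12 voxels and more. Nobody renders such a
volume whole: viewers stream small volumes of interest (VOIs) out of a
multiresolution pyramid, and over a network even a single VOI can take
seconds to arrive — the user stares at a blank screen until the last byte
lands.

`bitvox` implements a storage format and streaming pipeline that removes
that wait by splitting storage *by bit significance*. It is aimed at people
building or scripting large-volume visualization and annotation pipelines.

## The format and the streaming model

A volume of dimensions `(X, Y, Z)` is recursively downsampled 2× per axis
(ceil at odd edges) into levels `r = 1, 2, …, L`, stopping at the first
level whose every axis is strictly below the block edge (default 128).
Each level is diced into non-overlapping cubes of `128³` voxels (edge
blocks zero-padded). Every cube of a `B`-bit volume is then decomposed
into `B` **bitBlocks**: bit-plane `b` (with `b = 1` the most significant
bit) of all voxels in x-fastest scan order, packed 8 bits per byte, stored
as one LZW-compressed TIFF at

```
level{r}_data/z{i}/y{j}/x{k}/{b}.tif
```

The decomposition is exact: merging planes `1..m` reconstructs each voxel
as `(v >> (B−m)) << (B−m)`, so the absolute error after `m` planes is at
most `2^(B−m) − 1` and falls monotonically to zero. A client therefore
renders a usable image after one plane and refines in place — and in
high-contrast fluorescence data the four most significant planes compress
to a small fraction of the total bytes, so the useful image arrives far
sooner than the full one. A *half-bit* mode stops after the top `B/2`
planes, halving the files transferred.

The level for a navigation window is chosen from its voxel volume `V` and
a per-request cap `M` (mebivoxels, default 20):

```
R = ⌊log₂( V / (1024·1024·M) )⌋ ,  clamped to [1, L]
```

## Worked example

Dry-run accounting for a published whole-mouse-brain geometry
(13,913 × 18,000 × 5,115 voxels, 8-bit):

```
$ bitvox plan --dims 13913x18000x5115 --block-size 128
dims 13913x18000x5115, block 128, 8-bit, layout bitplane
level                 dims           grid     blocks
    1     13913x18000x5115     109x141x40     614760
    2       6957x9000x2558       55x71x20      78100
    ...
    9             55x71x20          1x1x1          1
levels: 9
total blocks: 704,438
total files: 5,635,504
raw size: 1,280,969,910,000 bytes
```

9 levels and 5,635,504 bitBlock files (704,438 blocks × 8 planes); the raw
volume is 1.17 binary TB. With `--block-size 512 --layout block` the same
volume plans 7 levels and 11,578 one-file-per-block files.

A self-contained end-to-end run on a synthetic fluorescence phantom
(bright somas and fibers on a dark background):

```
$ bitvox synth /tmp/ds --dims 300x256x200 --block-size 32 --seed 42
phantom (300, 256, 200) (soma-fiber, seed 42) -> /tmp/ds: 5 levels, truth.json, phantom.tif

$ bitvox stats /tmp/ds --top 4
b,bytes,fraction
1,236966,0.016698
2,243464,0.017156
...
# top-4 planes: 14.33% of compressed bytes

$ bitvox fetch /tmp/ds --box 10:160,20:140,30:120 --level 1 --out /tmp/voi.tif
VOI level 1, shape (z,y,x)=(90, 120, 150), 8 planes merged -> /tmp/voi.tif
```

The stats line shows the asymmetry the format exploits: the four most
significant planes hold ~14% of the compressed bytes. The fetched VOI is a
voxel-exact crop of the phantom (streaming is lossless once all planes are
merged). `bitvox serve /tmp/ds --port 8080` exposes the same tree over
HTTP, and `bitvox fetch http://localhost:8080 …` is byte-identical to the
local read. `bitvox project` makes maximum-intensity projections or
orthogonal slices of a fetched VOI; `bitvox mask` rasterizes stored
contour annotations; point/line/contour annotations round-trip through
JSON and polylines export to SWC.

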