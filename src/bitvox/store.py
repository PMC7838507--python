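"""On-disk layout, bitBlock serialization, metadata I/O, HTTP serving.

Directory layout (one tree per dataset)::

    <root>/metadata.json
    <root>/level{r}_data/z{i}/y{j}/x{k}/{b}.tif

Each ``{b}.tif`` is one bitBlock: the packed payload of bit-plane ``b`` of
one block, written as a single grayscale TIFF image of 8-bit samples with
width ``block_size / 8`` and height ``block_size**2``, LZW-compressed with no
predictor.  The byte values are packed bits, not intensities, so a
differencing predictor would have nothing principled to exploit.  This TIFF
geometry is a declared dialect of the format and is recorded in metadata.

Serving is a plain static HTTP file server; a fetcher retrieves bitBlocks
over HTTP with bounded retries and is byte-for-byte equivalent to a local
read.
"""

from __future__ import annotations

import io
import json
import re
import threading
import time
import urllib.error
import urllib.request
from dataclasses import asdict
from functools import partial
from http.server import SimpleHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

import numpy as np
import tifffile

from .bitplane_codec import BitPlane
from .pyramid_plan import BitPlaneRef, BlockCoord, DatasetMeta, num_levels, plan_pyramid

__all__ = [
    "bitblock_relpath",
    "parse_relpath",
    "write_bitblock",
    "read_bitblock",
    "write_metadata",
    "read_metadata",
    "serve",
    "fetch_bitblock",
    "fetch_metadata",
    "plane_size_report",
    "BitBlockNotFound",
    "FormatError",
    "TransportError",
]

METADATA_NAME = "metadata.json"

_RELPATH_RE = re.compile(
    r"^level(\d+)_data/z(\d+)/y(\d+)/x(\d+)/(\d+)\.tif$"
)


class BitBlockNotFound(FileNotFoundError):
    """A requested bitBlock file does not exist; carries its relpath."""


class FormatError(ValueError):
    """A file on disk does not conform to the declared format."""


class TransportError(IOError):
    """HTTP transfer failed after exhausting retries."""


# ---------------------------------------------------------------------------
# path mapping

def bitblock_relpath(ref: BitPlaneRef) -> str:
    c = ref.coord
    return f"level{c.r}_data/z{c.i}/y{c.j}/x{c.k}/{ref.b}.tif"


def parse_relpath(relpath: str) -> BitPlaneRef:
    m = _RELPATH_RE.match(relpath.replace("\\", "/"))
    if not m:
        raise FormatError(f"not a bitBlock path: {relpath!r}")
    r, i, j, k, b = map(int, m.groups())
    return BitPlaneRef(coord=BlockCoord(r=r, k=k, j=j, i=i), b=b)


# ---------------------------------------------------------------------------
# bitBlock files

def _tiff_bytes(plane: BitPlane) -> bytes:
    e = plane.block_size
    img = np.frombuffer(plane.payload, dtype=np.uint8).reshape(e * e, e // 8)
    buf = io.BytesIO()
    tifffile.imwrite(buf, img, compression="lzw", predictor=False)
    return buf.getvalue()


def write_bitblock(root: Path | str, ref: BitPlaneRef, plane: BitPlane) -> Path:
    path = Path(root) / bitblock_relpath(ref)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(_tiff_bytes(plane))
    return path


def read_bitblock(root: Path | str, ref: BitPlaneRef, block_size: int) -> BitPlane:
    relpath = bitblock_relpath(ref)
    path = Path(root) / relpath
    if not path.is_file():
        raise BitBlockNotFound(relpath)
    return _decode_bitblock(path.read_bytes(), ref, block_size, str(path))


def _decode_bitblock(
    raw: bytes, ref: BitPlaneRef, block_size: int, origin: str
) -> BitPlane:
    try:
        img = tifffile.imread(io.BytesIO(raw))
    except Exception as exc:  # noqa: BLE001 - reraise as format error
        raise FormatError(f"unreadable TIFF at {origin}: {exc}") from exc
    expected = (block_size * block_size, block_size // 8)
    if img.dtype != np.uint8 or img.shape != expected:
        raise FormatError(
            f"bitBlock {origin} has shape {img.shape}/{img.dtype}, "
            f"expected {expected}/uint8"
        )
    return BitPlane(b=ref.b, payload=img.tobytes(), block_size=block_size)


# ---------------------------------------------------------------------------
# metadata

def write_metadata(root: Path | str, meta: DatasetMeta) -> Path:
    path = Path(root) / METADATA_NAME
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(meta), indent=2))
    return path


def read_metadata(root: Path | str) -> DatasetMeta:
    path = Path(root) / METADATA_NAME
    if not path.is_file():
        raise FormatError(f"missing {METADATA_NAME} under {root}")
    return _meta_from_json(path.read_text(), str(path))


def _meta_from_json(text: str, origin: str) -> DatasetMeta:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON in {origin}: {exc}") from exc
    required = {"name", "dims", "bit_depth", "block_size", "levels"}
    missing = required - obj.keys()
    if missing:
        raise FormatError(f"{origin} missing fields: {sorted(missing)}")
    obj["dims"] = tuple(obj["dims"])
    obj["voxel_size"] = tuple(obj.get("voxel_size", (1.0, 1.0, 1.0)))
    known = {
        "name", "dims", "voxel_size", "bit_depth", "block_size", "levels",
        "compression", "format_version", "conventions", "downsample",
    }
    try:
        return DatasetMeta(**{k: v for k, v in obj.items() if k in known})
    except ValueError as exc:
        raise FormatError(f"invalid metadata in {origin}: {exc}") from exc


# ---------------------------------------------------------------------------
# HTTP server / fetcher

class _QuietHandler(SimpleHTTPRequestHandler):
    def log_message(self, fmt: str, *args) -> None:  # pragma: no cover
        pass


class StoreServer:
    """Static HTTP server over a dataset root, run on a daemon thread."""

    def __init__(self, root: Path | str, port: int = 0, host: str = "127.0.0.1"):
        root = Path(root)
        if not (root / METADATA_NAME).is_file():
            raise FormatError(f"{root} has no {METADATA_NAME}; refusing to serve")
        handler = partial(_QuietHandler, directory=str(root))
        self._httpd = ThreadingHTTPServer((host, port), handler)
        self._thread = threading.Thread(
            target=self._httpd.serve_forever, daemon=True
        )
        self.root = root

    def start(self) -> "StoreServer":
        if not self._thread.is_alive():
            self._thread.start()
        return self

    @property
    def port(self) -> int:
        return self._httpd.server_address[1]

    @property
    def url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        self._thread.join(timeout=5)

    def __enter__(self) -> "StoreServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


def serve(root: Path | str, port: int = 8080, host: str = "127.0.0.1") -> StoreServer:
    """Start serving a dataset tree; returns a handle with ``.stop()``."""
    return StoreServer(root, port=port, host=host).start()


def _http_get(url: str, retries: int = 3, backoff: float = 0.2) -> bytes:
    last: Exception | None = None
    for attempt in range(retries):
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                return resp.read()
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise BitBlockNotFound(url) from exc
            last = exc
        except urllib.error.URLError as exc:
            last = exc
        if attempt < retries - 1:
            time.sleep(backoff * (attempt + 1))
    raise TransportError(f"GET {url} failed after {retries} attempts: {last}")


def fetch_bitblock(
    base_url: str, ref: BitPlaneRef, block_size: int, retries: int = 3
) -> BitPlane:
    url = base_url.rstrip("/") + "/" + bitblock_relpath(ref)
    raw = _http_get(url, retries=retries)
    return _decode_bitblock(raw, ref, block_size, url)


def fetch_metadata(base_url: str, retries: int = 3) -> DatasetMeta:
    url = base_url.rstrip("/") + "/" + METADATA_NAME
    try:
        raw = _http_get(url, retries=retries)
    except BitBlockNotFound as exc:
        raise FormatError(f"no {METADATA_NAME} at {base_url}") from exc
    return _meta_from_json(raw.decode(), url)


# ---------------------------------------------------------------------------
# statistics

def plane_size_report(root: Path | str, meta: DatasetMeta) -> list[dict]:
    """Per-bit-plane compressed byte totals over the whole tree.

    Returns one row per plane ``b`` with total bytes and the fraction of the
    dataset's compressed size; fractions sum to 1.
    """
    root = Path(root)
    totals = {b: 0 for b in range(1, meta.bit_depth + 1)}
    from .pyramid_plan import iter_block_coords

    for spec in plan_pyramid(meta):
        for coord in iter_block_coords(spec):
            for b in range(1, meta.bit_depth + 1):
                path = root / bitblock_relpath(BitPlaneRef(coord=coord, b=b))
                if not path.is_file():
                    raise BitBlockNotFound(str(path))
                totals[b] += path.stat().st_size
    grand = sum(totals.values())
    return [
        {"b": b, "bytes": n, "fraction": (n / grand if grand else 0.0)}
        for b, n in sorted(totals.items())
    ]


def top_planes_fraction(report: list[dict], top: int = 4) -> float:
    """Share of compressed bytes held by planes 1..top (0..1)."""
    return sum(row["fraction"] for row in report if row["b"] <= top)
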