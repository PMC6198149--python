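"""Readers and writers for the on-disk formats.

* image stacks: directories of per-section PNG/TIFF images (optionally
  tiled), described by a JSON volume descriptor;
* segmentation image stacks: RGB images encoding 16-bit IDs in the green
  (high byte) and blue (low byte) channels;
* a single-file sparse segmentation container holding the 16^3 chunks of
  every mip level (voxel payload serialized in Z-order, deflate
  compressed), indexed by a per-level tree of 16x16x16 pointer blocks,
  with the segment metadata embedded — file size scales with painted
  content, not with the nominal dataset extent;
* a line-oriented, tab-separated segment-metadata text format.

All round-trips are exact: IDs and voxels survive export/import
bit-identically, which is why segmentation export is restricted to
lossless image formats.
"""

from __future__ import annotations

import json
import os
import re
import struct
import warnings
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from PIL import Image

from . import segments as seg_mod
from .segments import Segment, SegmentTable
from .volume import (
    CHUNK_EDGE,
    CHUNK_VOXELS,
    VALUE_KINDS,
    CacheState,
    Chunk,
    ChunkedVolume,
    zorder_index,
)

__all__ = [
    "VolumeDescriptor",
    "PointerBlockTree",
    "import_image_stack",
    "export_image_stack",
    "export_id_images",
    "import_id_images",
    "encode_id_image",
    "decode_id_image",
    "save_segmentation",
    "load_segmentation",
    "export_metadata_text",
    "parse_metadata_text",
]

LOSSLESS_FORMATS = ("png", "tif", "raw")
IMPORT_FORMATS = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")

#: Z-order permutation of the 4096 voxels of a chunk (serialization order).
_ZORDER_PERM = np.empty(CHUNK_VOXELS, dtype=np.int64)
for _x in range(CHUNK_EDGE):
    for _y in range(CHUNK_EDGE):
        for _z in range(CHUNK_EDGE):
            _ZORDER_PERM[zorder_index(_x, _y, _z)] = (
                _x * CHUNK_EDGE * CHUNK_EDGE + _y * CHUNK_EDGE + _z
            )
_ZORDER_INV = np.argsort(_ZORDER_PERM)


# ---------------------------------------------------------------------------
# volume descriptor (JSON)
# ---------------------------------------------------------------------------

@dataclass
class VolumeDescriptor:
    """JSON-serializable description of a tiled on-disk image dataset.

    ``pattern`` is a Python format string with ``{level}``, ``{z}``,
    ``{row}`` and ``{col}`` placeholders, resolved relative to the
    descriptor file's directory.
    """

    name: str
    pattern: str
    tile_size_px: int
    dims_vx: tuple[int, int, int]
    voxel_size_nm: tuple[float, float, float]
    num_levels: int
    value_kind: str

    REQUIRED_PLACEHOLDERS = ("{level}", "{z}", "{row}", "{col}")

    def __post_init__(self):
        for ph in self.REQUIRED_PLACEHOLDERS:
            if ph.strip("{}") not in [f[1] for f in _format_fields(self.pattern)]:
                raise ValueError(f"tile pattern is missing the {ph} placeholder")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.tile_size_px < 1:
            raise ValueError("tile size must be positive")
        self.dims_vx = tuple(int(v) for v in self.dims_vx)
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)

    def tile_grid(self, level: int) -> tuple[int, int]:
        """(rows, cols) of the tile grid at a level."""
        f = 2 ** level
        ex = -(-self.dims_vx[0] // f)
        ey = -(-self.dims_vx[1] // f)
        return (-(-ey // self.tile_size_px), -(-ex // self.tile_size_px))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "VolumeDescriptor":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "VolumeDescriptor":
        return cls.from_json(Path(path).read_text())


def _format_fields(pattern: str):
    import string

    return [(lit, fname, spec, conv) for lit, fname, spec, conv in
            string.Formatter().parse(pattern) if fname is not None]


# ---------------------------------------------------------------------------
# pointer-block tree (fan-out 16 per axis)
# ---------------------------------------------------------------------------

class PointerBlockTree:
    """Index tree with 16x16x16 child pointers per block.

    Maps chunk coordinates of one mip level to integer storage records
    (e.g. file offsets).  Depth is the minimum needed to address the
    level's chunk grid; every inserted chunk is reachable from exactly
    one leaf pointer.
    """

    FANOUT = 16

    def __init__(self, grid_dims: tuple[int, int, int]):
        gx, gy, gz = (int(g) for g in grid_dims)
        if min(gx, gy, gz) < 1:
            raise ValueError("chunk grid dims must be positive")
        self.grid_dims = (gx, gy, gz)
        depth = 1
        while self.FANOUT ** depth < max(gx, gy, gz):
            depth += 1
        self.depth = depth
        self.root: dict = {}

    def _path(self, coord) -> list[tuple[int, int, int]]:
        cx, cy, cz = coord
        gx, gy, gz = self.grid_dims
        if not (0 <= cx < gx and 0 <= cy < gy and 0 <= cz < gz):
            raise KeyError(f"chunk coordinate {coord} outside grid {self.grid_dims}")
        steps = []
        for d in range(self.depth - 1, -1, -1):
            f = self.FANOUT ** d
            steps.append(((cx // f) % self.FANOUT, (cy // f) % self.FANOUT,
                          (cz // f) % self.FANOUT))
        return steps

    def insert(self, coord: tuple[int, int, int], record: int) -> None:
        node = self.root
        path = self._path(coord)
        for step in path[:-1]:
            node = node.setdefault(step, {})
        node[path[-1]] = int(record)

    def lookup(self, coord: tuple[int, int, int]) -> Optional[int]:
        node = self.root
        for step in self._path(coord):
            if not isinstance(node, dict) or step not in node:
                return None
            node = node[step]
        return node if isinstance(node, int) else None

    def items(self):
        """Yield (coord, record) for every leaf pointer."""

        def walk(node, prefix, d):
            for (ix, iy, iz), child in node.items():
                f = self.FANOUT ** (self.depth - 1 - d)
                nxt = (prefix[0] + ix * f, prefix[1] + iy * f, prefix[2] + iz * f)
                if isinstance(child, dict):
                    yield from walk(child, nxt, d + 1)
                else:
                    yield nxt, child

        yield from walk(self.root, (0, 0, 0), 0)

    def __len__(self) -> int:
        return sum(1 for _ in self.items())


# ---------------------------------------------------------------------------
# plain image helpers
# ---------------------------------------------------------------------------

def _read_image(path) -> np.ndarray:
    """Read an image as (X, Y) or (X, Y, 3) array (transposed from rows)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing image file: {path}")
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.transpose(1, 0, 2) if arr.ndim == 3 else arr.T


def _write_image(path, arr: np.ndarray, fmt: str) -> None:
    """Write an (X, Y[, 3]) array; transposes back to image row order."""
    path = Path(path)
    if fmt == "raw":
        img = arr.transpose(1, 0, 2) if arr.ndim == 3 else arr.T
        img.tofile(path)
        return
    img = arr.transpose(1, 0, 2) if arr.ndim == 3 else arr.T
    Image.fromarray(img).save(path)


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name)]


# ---------------------------------------------------------------------------
# image stack import / export
# ---------------------------------------------------------------------------

def import_image_stack(
    source,
    num_levels: int = 1,
    voxel_size_nm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    value_kind: str | None = None,
) -> ChunkedVolume:
    """Import a section-image directory or a tiled descriptor dataset.

    ``source`` is either a directory of per-section images (sections
    ordered by natural filename sort) or a :class:`VolumeDescriptor` /
    path to its JSON file.  Level-0 voxels equal the source pixels; the
    mip pyramid is computed during import.
    """
    if isinstance(source, VolumeDescriptor) or (
        isinstance(source, (str, Path)) and str(source).endswith(".json")
    ):
        return _import_descriptor(source, num_levels, voxel_size_nm, value_kind)
    src = Path(source)
    if not src.is_dir():
        raise FileNotFoundError(f"image stack directory not found: {src}")
    files = sorted(
        (p for p in src.iterdir() if p.suffix.lower() in IMPORT_FORMATS),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise ValueError(f"no importable section images in {src}")
    sections = [_read_image(p) for p in files]
    shapes = {s.shape for s in sections}
    if len(shapes) > 1:
        raise ValueError(
            f"inconsistent section dimensions/bit depths across the stack: {sorted(shapes)}"
        )
    stack = np.stack(sections, axis=2 if sections[0].ndim == 2 else 2)
    if sections[0].ndim == 3:  # (X, Y, 3) sections -> (X, Y, Z, 3)
        stack = np.stack(sections, axis=2)
    kind = value_kind or ("rgb24" if sections[0].ndim == 3 else "gray8")
    dims = (stack.shape[0], stack.shape[1], len(sections))
    vol = ChunkedVolume(dims, voxel_size_nm, kind, num_levels)
    vol.write_full(stack.astype(vol.dtype), 0)
    return vol


def _import_descriptor(source, num_levels, voxel_size_nm, value_kind) -> ChunkedVolume:
    if isinstance(source, VolumeDescriptor):
        desc, base = source, Path(".")
    else:
        desc, base = VolumeDescriptor.load(source), Path(source).parent
    kind = value_kind or desc.value_kind
    dims = desc.dims_vx
    vol = ChunkedVolume(dims, desc.voxel_size_nm, kind, desc.num_levels)
    ts = desc.tile_size_px
    rows, cols = desc.tile_grid(0)
    full = np.zeros(
        (dims[0], dims[1], dims[2]) + ((3,) if kind == "rgb24" else ()),
        dtype=vol.dtype,
    )
    for z in range(dims[2]):
        for row in range(rows):
            for col in range(cols):
                path = base / desc.pattern.format(level=0, z=z, row=row, col=col)
                tile = _read_image(path)
                x0, y0 = col * ts, row * ts
                dx = min(ts, dims[0] - x0)
                dy = min(ts, dims[1] - y0)
                full[x0:x0 + dx, y0:y0 + dy, z] = tile[:dx, :dy]
    vol.write_full(full, 0)
    return vol


def export_image_stack(
    vol: ChunkedVolume,
    out_dir,
    level: int = 0,
    bbox=None,
    fmt: str = "png",
    tile_size: int | None = None,
    prefix: str = "sec",
) -> list[str]:
    """Write a (sub)volume as per-section images or tile mosaics.

    Returns the files written.  A ``manifest.json`` sidecar records the
    exported geometry and flags tiles padded at the volume edge (padding
    value 0).
    """
    fmt = fmt.lower().lstrip(".")
    if fmt not in LOSSLESS_FORMATS:
        raise ValueError(
            f"unsupported export format {fmt!r}; lossless formats only: {LOSSLESS_FORMATS}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ex, ey, ez = vol.level_extent(level)
    bbox = tuple(bbox) if bbox is not None else (0, 0, 0, ex, ey, ez)
    x0, y0, z0, x1, y1, z1 = bbox
    block = vol.read_region(level, bbox)
    files = []
    padded = []
    if tile_size is None:
        for z in range(z1 - z0):
            name = f"{prefix}{z0 + z:04d}.{fmt}"
            _write_image(out / name, block[:, :, z], fmt)
            files.append(name)
    else:
        ts = int(tile_size)
        rows = -(-(y1 - y0) // ts)
        cols = -(-(x1 - x0) // ts)
        for z in range(z1 - z0):
            for row in range(rows):
                for col in range(cols):
                    tile_shape = (ts, ts) + block.shape[3:]
                    tile = np.zeros(tile_shape, dtype=block.dtype)
                    sub = block[col * ts:(col + 1) * ts, row * ts:(row + 1) * ts, z]
                    tile[: sub.shape[0], : sub.shape[1]] = sub
                    name = f"{prefix}{z0 + z:04d}_r{row:03d}_c{col:03d}.{fmt}"
                    _write_image(out / name, tile, fmt)
                    files.append(name)
                    if sub.shape[0] < ts or sub.shape[1] < ts:
                        padded.append(name)
    manifest = {
        "level": level,
        "bbox": list(bbox),
        "format": fmt,
        "tile_size": tile_size,
        "value_kind": vol.value_kind,
        "files": files,
        "padded_tiles": padded,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return files


# ---------------------------------------------------------------------------
# segment-ID image encoding (green = high byte, blue = low byte, red = 0)
# ---------------------------------------------------------------------------

def encode_id_image(ids: np.ndarray) -> np.ndarray:
    """(X, Y) uint16 IDs -> (X, Y, 3) RGB with G=ID//256, B=ID%256, R=0."""
    ids = np.asarray(ids, dtype=np.uint16)
    rgb = np.zeros(ids.shape + (3,), dtype=np.uint8)
    rgb[..., 1] = ids >> 8
    rgb[..., 2] = ids & 255
    return rgb


def decode_id_image(rgb: np.ndarray, warn_red: bool = True) -> np.ndarray:
    """Inverse of :func:`encode_id_image`; a nonzero red channel is ignored."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("ID images must be RGB")
    if warn_red and rgb[..., 0].any():
        warnings.warn("nonzero red channel in ID image; ignoring red bits")
    return (rgb[..., 1].astype(np.uint16) << 8) | rgb[..., 2].astype(np.uint16)


def export_id_images(
    seg_vol: ChunkedVolume, out_dir, level: int = 0, bbox=None,
    fmt: str = "png", prefix: str = "ids",
) -> list[str]:
    """Export a segmentation as RGB ID-encoded section images."""
    if seg_vol.value_kind != "id16":
        raise ValueError("only id16 volumes can be exported as ID images")
    if fmt.lower() not in ("png", "tif"):
        raise ValueError("ID images must use a lossless format (png/tif)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ex, ey, ez = seg_vol.level_extent(level)
    bbox = tuple(bbox) if bbox is not None else (0, 0, 0, ex, ey, ez)
    block = seg_vol.read_region(level, bbox)
    files = []
    for z in range(bbox[5] - bbox[2]):
        name = f"{prefix}{bbox[2] + z:04d}.{fmt}"
        _write_image(out / name, encode_id_image(block[:, :, z]), fmt)
        files.append(str(out / name))
    return files


def import_id_images(
    source,
    target_vol: ChunkedVolume | None = None,
    precedence: str = "source",
    num_levels: int = 1,
    voxel_size_nm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ChunkedVolume:
    """Decode ID-encoded section images, optionally merging onto a target.

    With a ``target_vol``, the decoded voxels are combined under the
    given precedence rule: ``"source"`` overwrites nonzero target voxels,
    ``"target"`` writes only where the target is empty.
    """
    if precedence not in ("source", "target"):
        raise ValueError("precedence must be 'source' or 'target'")
    src = Path(source)
    files = sorted(
        (p for p in src.iterdir()
         if p.suffix.lower() in (".png", ".tif", ".tiff") and p.stem != "manifest"),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise ValueError(f"no ID images found in {src}")
    sections = [decode_id_image(_read_image(p)) for p in files]
    ids = np.stack(sections, axis=2)
    if target_vol is None:
        vol = ChunkedVolume(ids.shape, voxel_size_nm, "id16", num_levels)
        vol.write_full(ids, 0)
        return vol
    if (ids.shape != target_vol.dims_vx):
        raise ValueError(
            f"ID stack shape {ids.shape} does not match target dims {target_vol.dims_vx}"
        )
    tgt = target_vol.read_full(0)
    if precedence == "source":
        write = ids != 0
    else:
        write = (ids != 0) & (tgt == 0)
    tgt[write] = ids[write]
    target_vol.write_full(tgt, 0)
    return target_vol


# ---------------------------------------------------------------------------
# sparse segmentation container
# ---------------------------------------------------------------------------

_MAGIC = b"VCSEG001"
_KIND_CODES = {"gray8": 1, "rgb24": 2, "id16": 3}
_KIND_NAMES = {v: k for k, v in _KIND_CODES.items()}


def _pack_chunk(chunk: Chunk) -> tuple[bytes, bytes]:
    vals = chunk.values.reshape(-1)[_ZORDER_INV]
    mask = chunk.mask.reshape(-1)[_ZORDER_INV]
    return (
        zlib.compress(vals.astype("<u2").tobytes()),
        zlib.compress(np.packbits(mask).tobytes()),
    )


def _unpack_chunk(vbytes: bytes, mbytes: bytes) -> Chunk:
    vals = np.frombuffer(zlib.decompress(vbytes), dtype="<u2")[_ZORDER_PERM]
    bits = np.unpackbits(
        np.frombuffer(zlib.decompress(mbytes), dtype=np.uint8), count=CHUNK_VOXELS
    ).astype(bool)[_ZORDER_PERM]
    return Chunk(
        values=vals.reshape((CHUNK_EDGE,) * 3).astype(np.uint16),
        mask=bits.reshape((CHUNK_EDGE,) * 3),
    )


def save_segmentation(vol: ChunkedVolume, table: SegmentTable, path) -> int:
    """Write a segmentation volume + metadata to a single sparse file.

    Only allocated chunks are stored (voxel payload in Z-order, deflate
    compressed); a per-level pointer-block tree indexes the chunk records
    by coordinate.  Returns the file size in bytes.
    """
    if vol.value_kind != "id16":
        raise ValueError("the segmentation container stores id16 volumes only")
    path = Path(path)
    meta = export_metadata_text(table).encode("utf-8")
    with open(path, "wb") as f:
        f.write(_MAGIC)
        f.write(struct.pack("<3q3dII", *vol.dims_vx, *vol.voxel_size_nm,
                            vol.num_levels, _KIND_CODES[vol.value_kind]))
        f.write(struct.pack("<Q", len(meta)))
        f.write(meta)
        trees = []
        for level in range(vol.num_levels):
            tree = PointerBlockTree(vol.chunk_grid(level))
            for key in sorted(vol.allocated_chunks):
                if key[0] != level:
                    continue
                chunk = vol.cache.get(key)
                if chunk is None or not chunk.mask.any():
                    continue
                vbytes, mbytes = _pack_chunk(chunk)
                offset = f.tell()
                f.write(struct.pack("<3iQQ", key[1], key[2], key[3],
                                    len(vbytes), len(mbytes)))
                f.write(vbytes)
                f.write(mbytes)
                tree.insert((key[1], key[2], key[3]), offset)
            trees.append(tree)
        # serialize the pointer trees: blocks of 4096 little-endian int64
        tree_offsets = []
        for tree in trees:
            tree_offsets.append(_write_tree(f, tree))
        footer_pos = f.tell()
        f.write(struct.pack(f"<{len(tree_offsets)}q", *tree_offsets))
        f.write(struct.pack("<q", footer_pos))
        size = f.tell()
    return size


def _write_tree(f, tree: PointerBlockTree) -> int:
    """Depth-first serialize pointer blocks; returns the root block offset."""

    def write_block(node, depth) -> int:
        ptrs = np.full(PointerBlockTree.FANOUT ** 3, -1, dtype="<i8")
        child_entries = []
        for (ix, iy, iz), child in node.items():
            slot = (ix * PointerBlockTree.FANOUT + iy) * PointerBlockTree.FANOUT + iz
            if isinstance(child, dict):
                child_entries.append((slot, write_block(child, depth + 1)))
            else:
                child_entries.append((slot, child))
        for slot, ptr in child_entries:
            ptrs[slot] = ptr
        offset = f.tell()
        f.write(struct.pack("<i", depth))
        f.write(ptrs.tobytes())
        return offset

    return write_block(tree.root, 0)


def load_segmentation(path, cache: CacheState | None = None) -> tuple[ChunkedVolume, SegmentTable]:
    """Load a sparse segmentation container saved by :func:`save_segmentation`.

    The returned volume's chunks are clean (file-backed): the cache may
    drop them under memory pressure and re-fetch them from the file.
    """
    path = Path(path)
    data_size = path.stat().st_size
    with open(path, "rb") as f:
        magic = f.read(8)
        if magic != _MAGIC:
            raise ValueError(f"not a segmentation container (bad magic at offset 0): {path}")
        hdr = f.read(struct.calcsize("<3q3dII"))
        if len(hdr) < struct.calcsize("<3q3dII"):
            raise ValueError(f"truncated container header at offset {8 + len(hdr)}")
        X, Y, Z, sx, sy, sz, num_levels, kind_code = struct.unpack("<3q3dII", hdr)
        (meta_len,) = struct.unpack("<Q", f.read(8))
        meta = f.read(meta_len).decode("utf-8")
        table = parse_metadata_text(meta)
        vol = ChunkedVolume((X, Y, Z), (sx, sy, sz), _KIND_NAMES[kind_code],
                            num_levels, cache=cache)
        # footer: last 8 bytes point at the tree-offset table
        f.seek(data_size - 8)
        (footer_pos,) = struct.unpack("<q", f.read(8))
        if not (0 <= footer_pos < data_size):
            raise ValueError(f"corrupt container footer at offset {data_size - 8}")
        f.seek(footer_pos)
        tree_offsets = struct.unpack(f"<{num_levels}q", f.read(8 * num_levels))
        for level, root_off in enumerate(tree_offsets):
            for coord, record in _iter_tree(f, root_off, vol.chunk_grid(level)):
                chunk = _read_chunk_record(f, record)
                vol.cache.put((level,) + coord, chunk, modified=False)
    vol.cache.mark_all_clean()
    vol.backing_keys = set(vol.cache.keys())
    vol.cache.fetcher = _make_fetcher(path)
    return vol, table


def _iter_tree(f, root_off: int, grid_dims):
    tree = PointerBlockTree(grid_dims)
    fanout = PointerBlockTree.FANOUT

    def walk(offset, prefix, depth):
        f.seek(offset)
        (blk_depth,) = struct.unpack("<i", f.read(4))
        ptrs = np.frombuffer(f.read(8 * fanout ** 3), dtype="<i8")
        for slot in np.nonzero(ptrs != -1)[0]:
            ix, rem = divmod(int(slot), fanout * fanout)
            iy, iz = divmod(rem, fanout)
            fct = fanout ** (tree.depth - 1 - depth)
            nxt = (prefix[0] + ix * fct, prefix[1] + iy * fct, prefix[2] + iz * fct)
            if depth + 1 < tree.depth:
                yield from walk(int(ptrs[slot]), nxt, depth + 1)
            else:
                yield nxt, int(ptrs[slot])

    yield from walk(root_off, (0, 0, 0), 0)


def _read_chunk_record(f, offset: int) -> Chunk:
    f.seek(offset)
    cx, cy, cz, vlen, mlen = struct.unpack("<3iQQ", f.read(struct.calcsize("<3iQQ")))
    return _unpack_chunk(f.read(vlen), f.read(mlen))


def _make_fetcher(path):
    index_cache: dict = {}

    def fetch(key):
        if not index_cache:
            with open(path, "rb") as f:
                f.seek(8)
                hdr = struct.unpack("<3q3dII", f.read(struct.calcsize("<3q3dII")))
                num_levels = hdr[6]
                (meta_len,) = struct.unpack("<Q", f.read(8))
                size = Path(path).stat().st_size
                f.seek(size - 8)
                (footer_pos,) = struct.unpack("<q", f.read(8))
                f.seek(footer_pos)
                offsets = struct.unpack(f"<{num_levels}q", f.read(8 * num_levels))
                dims = hdr[:3]
                tmp = ChunkedVolume(dims, (1, 1, 1), "id16", num_levels)
                for level, root in enumerate(offsets):
                    for coord, rec in _iter_tree(f, root, tmp.chunk_grid(level)):
                        index_cache[(level,) + coord] = rec
        rec = index_cache.get(key)
        if rec is None:
            return None
        with open(path, "rb") as f:
            return _read_chunk_record(f, rec)

    return fetch


# ---------------------------------------------------------------------------
# segment metadata text
# ---------------------------------------------------------------------------

_META_HEADER = (
    "# vastcore segmentation metadata v1\n"
    "# id\tparent\tlabel\tcolor1\tcolor2\tpattern\tanchor\tbbox\tcollapsed\n"
)


def _quote(label: str) -> str:
    body = (label.replace("\\", "\\\\").replace("\t", "\\t")
            .replace("\n", "\\n").replace('"', '""'))
    return '"' + body + '"'


def _unquote(field: str, lineno: int) -> str:
    if len(field) < 2 or field[0] != '"' or field[-1] != '"':
        raise ValueError(f"metadata line {lineno}: label must be quoted: {field!r}")
    body = field[1:-1].replace('""', '"')
    out = []
    i = 0
    while i < len(body):
        if body[i] == "\\" and i + 1 < len(body):
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(body[i + 1], body[i + 1]))
            i += 2
        else:
            out.append(body[i])
            i += 1
    return "".join(out)


def export_metadata_text(table: SegmentTable) -> str:
    """Serialize a segment table to tab-separated text (one line/segment)."""
    lines = [_META_HEADER.rstrip("\n")]
    for seg in table:
        anchor = ",".join(map(str, seg.anchor)) if seg.anchor is not None else "-"
        bbox = ",".join(map(str, seg.bbox)) if seg.bbox is not None else "-"
        lines.append("\t".join([
            str(seg.id),
            str(seg.parent_id),
            _quote(seg.label),
            ",".join(map(str, seg.color1)),
            ",".join(map(str, seg.color2)),
            str(seg.pattern),
            anchor,
            bbox,
            "1" if seg.collapsed else "0",
        ]))
    return "\n".join(lines) + "\n"


def parse_metadata_text(text: str) -> SegmentTable:
    """Parse the tab-separated metadata dialect back into a table.

    Raises ``ValueError`` naming the offending line for duplicate IDs,
    dangling parents, or malformed fields.
    """
    records: list[tuple[int, Segment]] = []
    seen: dict[int, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(
                f"metadata line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        try:
            seg = Segment(
                id=int(fields[0]),
                parent_id=int(fields[1]),
                label=_unquote(fields[2], lineno),
                color1=tuple(int(v) for v in fields[3].split(",")),
                color2=tuple(int(v) for v in fields[4].split(",")),
                pattern=int(fields[5]),
                anchor=None if fields[6] == "-" else tuple(int(v) for v in fields[6].split(",")),
                bbox=None if fields[7] == "-" else tuple(int(v) for v in fields[7].split(",")),
                collapsed=fields[8].strip() == "1",
            )
        except ValueError as exc:
            raise ValueError(f"metadata line {lineno}: {exc}") from None
        if seg.id in seen:
            raise ValueError(
                f"metadata line {lineno}: duplicate segment id {seg.id} "
                f"(first seen on line {seen[seg.id]})"
            )
        seen[seg.id] = lineno
        records.append((lineno, seg))
    table = SegmentTable()
    added: set[int] = set()
    pending = records
    while pending:
        progressed = []
        stuck = []
        for lineno, seg in pending:
            if seg.parent_id == 0 or seg.parent_id in added:
                table.add(seg)
                added.add(seg.id)
                progressed.append(seg.id)
            else:
                stuck.append((lineno, seg))
        if not progressed:
            lineno, seg = stuck[0]
            raise ValueError(
                f"metadata line {lineno}: segment {seg.id} references "
                f"missing parent {seg.parent_id}"
            )
        pending = stuck
    return table
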