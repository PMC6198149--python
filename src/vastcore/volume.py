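"""Sparse chunked multiresolution voxel volumes.

A :class:`ChunkedVolume` stores 8-bit grayscale, 24-bit RGB or 16-bit
segment-ID voxel data in 16x16x16-voxel chunks, allocated on demand.  The
volume carries an XY mipmap pyramid: level ``L`` halves the X and Y extent
of level ``L-1`` while the section (Z) count is unchanged at every level,
matching the strongly anisotropic serial-section geometry the container is
built for.

Explicit data may live at any mip level.  A write at level ``L`` is
*authoritative*: it removes explicit finer-level data under its footprint
and re-reduces all coarser levels, so a voxel's effective value is its own
explicit value if present, otherwise the value inherited (by 2x2 XY
replication per level) from the nearest coarser level holding explicit
data, otherwise the background value 0.

Chunks are held in an LRU cache (:class:`CacheState`).  Unmodified chunks
are evicted first; modified chunks are never dropped — when the cache
overflows with dirty chunks they are spilled to a disk-backed store.
"""

from __future__ import annotations

import os
import tempfile
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import numpy as np

__all__ = [
    "CHUNK_EDGE",
    "CHUNK_VOXELS",
    "VALUE_KINDS",
    "MAX_SEGMENT_ID",
    "ChunkedVolume",
    "CacheState",
    "Chunk",
    "create_volume",
    "zorder_index",
    "zorder_decode",
    "read_region",
    "write_region",
    "reduce_to_coarser",
    "effective_value",
    "cache_evict",
]

#: Edge length of a storage chunk, in voxels, on every axis at every level.
CHUNK_EDGE = 16
#: Voxels per chunk.
CHUNK_VOXELS = CHUNK_EDGE ** 3
#: Largest representable segment ID (16-bit labels; 0 is background).
MAX_SEGMENT_ID = 65535

#: value_kind -> (numpy dtype, number of channels; 0 means scalar).
VALUE_KINDS = {
    "gray8": (np.uint8, 0),
    "rgb24": (np.uint8, 3),
    "id16": (np.uint16, 0),
}


# ---------------------------------------------------------------------------
# Z-order (Morton) chunk-internal addressing
# ---------------------------------------------------------------------------

def zorder_index(x: int, y: int, z: int) -> int:
    """Morton-interleave chunk-local coordinates into a linear index.

    Bit ``b`` of ``x`` lands on bit ``3b`` of the result, ``y`` on ``3b+1``
    and ``z`` on ``3b+2``, so ``(1,0,0) -> 1``, ``(0,1,0) -> 2`` and
    ``(0,0,1) -> 4``.  The map is a bijection [0,16)^3 -> [0,4096).
    """
    if not (0 <= x < CHUNK_EDGE and 0 <= y < CHUNK_EDGE and 0 <= z < CHUNK_EDGE):
        raise ValueError(f"chunk-local coordinate out of range: {(x, y, z)}")
    idx = 0
    for b in range(4):
        idx |= ((x >> b) & 1) << (3 * b)
        idx |= ((y >> b) & 1) << (3 * b + 1)
        idx |= ((z >> b) & 1) << (3 * b + 2)
    return idx


def zorder_decode(idx: int) -> tuple[int, int, int]:
    """Inverse of :func:`zorder_index`."""
    if not (0 <= idx < CHUNK_VOXELS):
        raise ValueError(f"z-order index out of range: {idx}")
    x = y = z = 0
    for b in range(4):
        x |= ((idx >> (3 * b)) & 1) << b
        y |= ((idx >> (3 * b + 1)) & 1) << b
        z |= ((idx >> (3 * b + 2)) & 1) << b
    return x, y, z


def morton_code(x: int, y: int, z: int, bits: int = 21) -> int:
    """General Morton code for global voxel coordinates (tie-break ordering)."""
    code = 0
    for b in range(bits):
        code |= ((x >> b) & 1) << (3 * b)
        code |= ((y >> b) & 1) << (3 * b + 1)
        code |= ((z >> b) & 1) << (3 * b + 2)
    return code


# ---------------------------------------------------------------------------
# Chunk + cache
# ---------------------------------------------------------------------------

@dataclass
class Chunk:
    """One 16^3 storage block: values plus a per-voxel explicitness mask."""

    values: np.ndarray  # (16,16,16) or (16,16,16,3)
    mask: np.ndarray    # (16,16,16) bool; True where data is explicit


class CacheState:
    """LRU chunk cache with a disk spill store for modified chunks.

    Eviction removes least-recently-used *unmodified* chunks first; a
    modified chunk is never discarded.  If the resident set exceeds
    capacity and every resident chunk is dirty, dirty chunks are moved to
    the spill store (a temp directory) rather than dropped.  Unmodified
    chunks are dropped only when a ``fetcher`` can restore them (e.g. a
    backing container file); otherwise they are spilled as well, so no
    data ever vanishes.
    """

    def __init__(self, capacity_chunks: int = 4096, spill_dir: str | None = None):
        if capacity_chunks < 1:
            raise ValueError("cache capacity must be >= 1 chunk")
        self.capacity = int(capacity_chunks)
        self._spill_dir = spill_dir
        self._tmp: Optional[tempfile.TemporaryDirectory] = None
        self.resident: "OrderedDict[tuple, Chunk]" = OrderedDict()
        self.modified: set[tuple] = set()
        self.spilled: dict[tuple, str] = {}
        self.fetcher: Optional[Callable[[tuple], Optional[Chunk]]] = None
        self._spill_seq = 0

    # -- basic bookkeeping --------------------------------------------------

    def __len__(self) -> int:
        return len(self.resident) + len(self.spilled)

    def __contains__(self, key: tuple) -> bool:
        return key in self.resident or key in self.spilled

    def keys(self) -> set[tuple]:
        return set(self.resident) | set(self.spilled)

    def touch(self, key: tuple) -> None:
        if key in self.resident:
            self.resident.move_to_end(key)

    def _spill_path(self) -> str:
        if self._spill_dir is None:
            if self._tmp is None:
                self._tmp = tempfile.TemporaryDirectory(prefix="vastcore-spill-")
            self._spill_dir = self._tmp.name
        os.makedirs(self._spill_dir, exist_ok=True)
        self._spill_seq += 1
        return os.path.join(self._spill_dir, f"chunk{self._spill_seq:08d}.npz")

    # -- access -------------------------------------------------------------

    def get(self, key: tuple, modify: bool = False) -> Optional[Chunk]:
        """Return the chunk for ``key``, unspilling or re-fetching if needed.

        ``modify=True`` flags the chunk dirty *before* any eviction runs,
        so a chunk about to be mutated can never be silently spilled in a
        stale state between lookup and mutation.
        """
        if key in self.resident:
            self.resident.move_to_end(key)
            if modify:
                self.modified.add(key)
            return self.resident[key]
        if key in self.spilled:
            path = self.spilled.pop(key)
            with np.load(path) as f:
                chunk = Chunk(values=f["values"], mask=f["mask"].astype(bool))
            os.unlink(path)
            self.resident[key] = chunk
            if modify:
                self.modified.add(key)
            self.evict()
            return chunk
        if self.fetcher is not None:
            chunk = self.fetcher(key)
            if chunk is not None:
                self.resident[key] = chunk
                if modify:
                    self.modified.add(key)
                self.evict()
                return chunk
        return None

    def put(self, key: tuple, chunk: Chunk, modified: bool = True) -> None:
        self.resident[key] = chunk
        self.resident.move_to_end(key)
        if modified:
            self.modified.add(key)
        self.evict()

    def discard(self, key: tuple) -> None:
        """Forget a chunk entirely (used when a chunk becomes empty)."""
        self.resident.pop(key, None)
        self.modified.discard(key)
        path = self.spilled.pop(key, None)
        if path is not None and os.path.exists(path):
            os.unlink(path)

    def mark_modified(self, key: tuple) -> None:
        if key in self.resident:
            self.modified.add(key)

    def mark_all_clean(self) -> None:
        self.modified.clear()

    # -- eviction -----------------------------------------------------------

    def evict(self) -> list[tuple]:
        """Shrink the resident set to capacity; return the keys removed.

        LRU unmodified chunks go first.  Modified chunks (and unmodified
        chunks with no fetcher to restore them) are spilled to disk, never
        dropped.
        """
        evicted: list[tuple] = []
        while len(self.resident) > self.capacity:
            victim = None
            for key in self.resident:  # iteration order == recency order
                if key not in self.modified:
                    victim = key
                    break
            if victim is not None:
                chunk = self.resident.pop(victim)
                if self.fetcher is None:
                    self._spill(victim, chunk)
                evicted.append(victim)
            else:
                # every resident chunk is dirty: spill the LRU one
                key, chunk = next(iter(self.resident.items()))
                del self.resident[key]
                self._spill(key, chunk)
                evicted.append(key)
        return evicted

    def _spill(self, key: tuple, chunk: Chunk) -> None:
        path = self._spill_path()
        np.savez(path, values=chunk.values, mask=chunk.mask)
        self.spilled[key] = path


def cache_evict(state: CacheState, needed_chunks: int = 0) -> list[tuple]:
    """Evict enough chunks that ``needed_chunks`` more fit within capacity.

    Returns the list of evicted keys; modified chunks are spilled to the
    disk store rather than discarded.
    """
    target = max(1, state.capacity - int(needed_chunks))
    saved = state.capacity
    state.capacity = target
    try:
        return state.evict()
    finally:
        state.capacity = saved


# ---------------------------------------------------------------------------
# The volume
# ---------------------------------------------------------------------------

def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


class ChunkedVolume:
    """Sparse chunked voxel volume with an XY mipmap pyramid.

    Parameters
    ----------
    dims_vx : (X, Y, Z) voxel counts at level 0.
    voxel_size_nm : (sx, sy, sz) voxel edge lengths in nanometers.
    value_kind : "gray8", "rgb24" or "id16".
    num_levels : number of mip levels; level 0 is full resolution.
    cache : optional :class:`CacheState`; one is created if omitted.
    """

    def __init__(
        self,
        dims_vx: tuple[int, int, int],
        voxel_size_nm: tuple[float, float, float] = (1.0, 1.0, 1.0),
        value_kind: str = "gray8",
        num_levels: int = 1,
        cache: CacheState | None = None,
    ):
        dims = tuple(int(d) for d in dims_vx)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"volume dims must be three positive integers, got {dims_vx}")
        if value_kind not in VALUE_KINDS:
            raise ValueError(
                f"unknown value_kind {value_kind!r}; expected one of {sorted(VALUE_KINDS)}"
            )
        num_levels = int(num_levels)
        if num_levels < 1:
            raise ValueError("num_levels must be >= 1")
        if 2 ** (num_levels - 1) > max(dims[0], dims[1]):
            raise ValueError(
                f"too many mip levels ({num_levels}) for XY extent {dims[:2]}"
            )
        self.dims_vx = dims
        self.voxel_size_nm = tuple(float(s) for s in voxel_size_nm)
        self.value_kind = value_kind
        self.num_levels = num_levels
        self.dtype, self.channels = VALUE_KINDS[value_kind]
        self.cache = cache if cache is not None else CacheState()
        #: chunk keys held by a backing store (set by container loading);
        #: these may be dropped from the cache and re-fetched on demand
        self.backing_keys: set[tuple] = set()

    # -- geometry -----------------------------------------------------------

    def level_extent(self, level: int) -> tuple[int, int, int]:
        """(X, Y, Z) voxel extent at a mip level; Z is never reduced."""
        self._check_level(level)
        X, Y, Z = self.dims_vx
        f = 2 ** level
        return (_ceil_div(X, f), _ceil_div(Y, f), Z)

    def chunk_grid(self, level: int) -> tuple[int, int, int]:
        ex, ey, ez = self.level_extent(level)
        return (_ceil_div(ex, CHUNK_EDGE), _ceil_div(ey, CHUNK_EDGE), _ceil_div(ez, CHUNK_EDGE))

    def _check_level(self, level: int) -> None:
        if not (0 <= level < self.num_levels):
            raise ValueError(f"unknown mip level {level} (volume has {self.num_levels})")

    def _check_bbox(self, level: int, bbox) -> tuple[int, int, int, int, int, int]:
        x0, y0, z0, x1, y1, z1 = (int(v) for v in bbox)
        ex, ey, ez = self.level_extent(level)
        if not (0 <= x0 < x1 <= ex and 0 <= y0 < y1 <= ey and 0 <= z0 < z1 <= ez):
            raise ValueError(
                f"bbox {tuple(bbox)} outside level-{level} extent {(ex, ey, ez)}"
            )
        return x0, y0, z0, x1, y1, z1

    def _chunk_shape(self) -> tuple:
        s: tuple = (CHUNK_EDGE, CHUNK_EDGE, CHUNK_EDGE)
        return s + (self.channels,) if self.channels else s

    def _value_shape(self, dx: int, dy: int, dz: int) -> tuple:
        s: tuple = (dx, dy, dz)
        return s + (self.channels,) if self.channels else s

    # -- chunk access -------------------------------------------------------

    @property
    def allocated_chunks(self) -> set[tuple]:
        return self.cache.keys() | self.backing_keys

    def _get_chunk(self, key: tuple, create: bool = False, modify: bool = False) -> Optional[Chunk]:
        chunk = self.cache.get(key, modify=modify)
        if chunk is None and create:
            chunk = Chunk(
                values=np.zeros(self._chunk_shape(), dtype=self.dtype),
                mask=np.zeros((CHUNK_EDGE,) * 3, dtype=bool),
            )
            self.cache.put(key, chunk, modified=True)
        return chunk

    def free_chunk(self, level: int, chunk_coord: tuple[int, int, int]) -> None:
        """Drop a chunk from storage (used when it holds no explicit data)."""
        key = (level,) + tuple(chunk_coord)
        self.cache.discard(key)
        self.backing_keys.discard(key)

    def _chunks_overlapping(self, level: int, box) -> Iterator[tuple[tuple, tuple]]:
        """Yield (key, (cx,cy,cz)) for grid chunks overlapping a level box."""
        x0, y0, z0, x1, y1, z1 = box
        for cx in range(x0 // CHUNK_EDGE, _ceil_div(x1, CHUNK_EDGE)):
            for cy in range(y0 // CHUNK_EDGE, _ceil_div(y1, CHUNK_EDGE)):
                for cz in range(z0 // CHUNK_EDGE, _ceil_div(z1, CHUNK_EDGE)):
                    yield (level, cx, cy, cz), (cx, cy, cz)

    # -- explicit-plane access (one level, no inheritance) -------------------

    def read_explicit(self, level: int, bbox) -> tuple[np.ndarray, np.ndarray]:
        """Dense (values, explicit-mask) for one level; no inheritance."""
        x0, y0, z0, x1, y1, z1 = self._check_bbox(level, bbox)
        dx, dy, dz = x1 - x0, y1 - y0, z1 - z0
        out = np.zeros(self._value_shape(dx, dy, dz), dtype=self.dtype)
        mask = np.zeros((dx, dy, dz), dtype=bool)
        for key, (cx, cy, cz) in self._chunks_overlapping(level, (x0, y0, z0, x1, y1, z1)):
            if key not in self.cache and key not in self.backing_keys:
                continue
            chunk = self.cache.get(key)
            if chunk is None:
                continue
            ox, oy, oz = cx * CHUNK_EDGE, cy * CHUNK_EDGE, cz * CHUNK_EDGE
            sx0, sy0, sz0 = max(x0 - ox, 0), max(y0 - oy, 0), max(z0 - oz, 0)
            sx1 = min(x1 - ox, CHUNK_EDGE)
            sy1 = min(y1 - oy, CHUNK_EDGE)
            sz1 = min(z1 - oz, CHUNK_EDGE)
            dst = (
                slice(ox + sx0 - x0, ox + sx1 - x0),
                slice(oy + sy0 - y0, oy + sy1 - y0),
                slice(oz + sz0 - z0, oz + sz1 - z0),
            )
            src = (slice(sx0, sx1), slice(sy0, sy1), slice(sz0, sz1))
            out[dst] = chunk.values[src]
            mask[dst] = chunk.mask[src]
        return out, mask

    def _write_explicit(self, level: int, bbox, values: np.ndarray, explicit: bool = True) -> None:
        """Set (or clear) explicit data over a level box, chunk by chunk."""
        x0, y0, z0, x1, y1, z1 = self._check_bbox(level, bbox)
        for key, (cx, cy, cz) in self._chunks_overlapping(level, (x0, y0, z0, x1, y1, z1)):
            if not explicit and key not in self.cache and key not in self.backing_keys:
                continue
            chunk = self._get_chunk(key, create=explicit, modify=True)
            if chunk is None:
                continue
            ox, oy, oz = cx * CHUNK_EDGE, cy * CHUNK_EDGE, cz * CHUNK_EDGE
            sx0, sy0, sz0 = max(x0 - ox, 0), max(y0 - oy, 0), max(z0 - oz, 0)
            sx1 = min(x1 - ox, CHUNK_EDGE)
            sy1 = min(y1 - oy, CHUNK_EDGE)
            sz1 = min(z1 - oz, CHUNK_EDGE)
            dst = (slice(sx0, sx1), slice(sy0, sy1), slice(sz0, sz1))
            if explicit:
                src = (
                    slice(ox + sx0 - x0, ox + sx1 - x0),
                    slice(oy + sy0 - y0, oy + sy1 - y0),
                    slice(oz + sz0 - z0, oz + sz1 - z0),
                )
                chunk.values[dst] = values[src]
                chunk.mask[dst] = True
                self.cache.mark_modified(key)
            else:
                chunk.values[dst] = 0
                chunk.mask[dst] = False
                if not chunk.mask.any():
                    self.cache.discard(key)
                    self.backing_keys.discard(key)
                else:
                    self.cache.mark_modified(key)

    # -- public reads -------------------------------------------------------

    def read_region(self, level: int, bbox) -> np.ndarray:
        """Dense effective values over a half-open box at a mip level.

        Unallocated regions read as 0; non-explicit voxels inherit by XY
        replication from the nearest coarser level with explicit data.
        Reading allocates nothing.
        """
        x0, y0, z0, x1, y1, z1 = self._check_bbox(level, bbox)
        dx, dy, dz = x1 - x0, y1 - y0, z1 - z0
        out = np.zeros(self._value_shape(dx, dy, dz), dtype=self.dtype)
        for lev in range(self.num_levels - 1, level - 1, -1):
            scale = 2 ** (lev - level)
            ex, ey, _ = self.level_extent(lev)
            cx0, cy0 = x0 // scale, y0 // scale
            cx1 = min(_ceil_div(x1, scale), ex)
            cy1 = min(_ceil_div(y1, scale), ey)
            if cx0 >= cx1 or cy0 >= cy1:
                continue
            vals, mask = self.read_explicit(lev, (cx0, cy0, z0, cx1, cy1, z1))
            if not mask.any():
                continue
            vals = np.repeat(np.repeat(vals, scale, axis=0), scale, axis=1)
            mask = np.repeat(np.repeat(mask, scale, axis=0), scale, axis=1)
            offx, offy = x0 - cx0 * scale, y0 - cy0 * scale
            vals = vals[offx:offx + dx, offy:offy + dy]
            mask = mask[offx:offx + dx, offy:offy + dy]
            out[mask] = vals[mask]
        return out

    def effective_value(self, level: int, x: int, y: int, z: int):
        """Effective value of one voxel (explicit, inherited, or 0)."""
        block = self.read_region(level, (x, y, z, x + 1, y + 1, z + 1))
        if self.channels:
            return tuple(int(v) for v in block[0, 0, 0])
        return block[0, 0, 0].item()

    # -- public writes ------------------------------------------------------

    def _validate_values(self, values: np.ndarray, bbox) -> np.ndarray:
        x0, y0, z0, x1, y1, z1 = bbox
        want = self._value_shape(x1 - x0, y1 - y0, z1 - z0)
        values = np.asarray(values)
        if values.shape != want:
            raise ValueError(f"values shape {values.shape} does not match bbox shape {want}")
        if self.value_kind == "id16":
            vmax = int(values.max(initial=0))
            vmin = int(values.min(initial=0))
            if vmin < 0 or vmax > MAX_SEGMENT_ID:
                raise ValueError(
                    f"segment IDs must be in [0, {MAX_SEGMENT_ID}] "
                    f"(16-bit labels); got value {vmax if vmax > MAX_SEGMENT_ID else vmin}"
                )
        elif values.dtype != np.uint8:
            vmax = int(values.max(initial=0))
            vmin = int(values.min(initial=0))
            if vmin < 0 or vmax > 255:
                raise ValueError("8-bit image values must be in [0, 255]")
        return values.astype(self.dtype, copy=False)

    def write_region(self, level: int, bbox, values: np.ndarray) -> int:
        """Write a dense block at a mip level; returns voxels changed.

        The write is authoritative for its footprint: explicit data at
        finer levels under the footprint is deleted and every coarser
        level is re-reduced over it.
        """
        box = self._check_bbox(level, bbox)
        values = self._validate_values(values, box)
        before = self.read_region(level, box)
        self._write_explicit(level, box, values, explicit=True)
        # clear explicit finer data under the footprint
        x0, y0, z0, x1, y1, z1 = box
        for fl in range(level - 1, -1, -1):
            scale = 2 ** (level - fl)
            ex, ey, _ = self.level_extent(fl)
            fbox = (x0 * scale, y0 * scale, z0, min(x1 * scale, ex), min(y1 * scale, ey), z1)
            self._write_explicit(fl, fbox, None, explicit=False)
        # re-reduce every coarser level over the footprint, bottom-up
        self._reduce_cascade(level, box)
        after = self.read_region(level, box)
        if self.channels:
            return int(np.count_nonzero((before != after).any(axis=-1)))
        return int(np.count_nonzero(before != after))

    # -- reduction ----------------------------------------------------------

    def _reduce_block(self, fine: np.ndarray) -> np.ndarray:
        """Reduce a fine block (even X/Y extents) by 2x2 in XY.

        Images use the rounded (half-up) mean; ID volumes use the majority
        label among the 2x2 children with ties broken by the smallest ID.
        """
        dx, dy = fine.shape[0] // 2, fine.shape[1] // 2
        quads = np.stack(
            [fine[0::2, 0::2], fine[1::2, 0::2], fine[0::2, 1::2], fine[1::2, 1::2]],
            axis=0,
        )
        if self.value_kind == "id16":
            s = np.sort(quads.astype(np.int64), axis=0)
            counts = (s[None, :, ...] == s[:, None, ...]).sum(axis=0)
            key = counts * (1 << 17) - s
            pick = np.argmax(key, axis=0)
            return np.take_along_axis(s, pick[None, ...], axis=0)[0].astype(self.dtype)
        total = quads.astype(np.uint32).sum(axis=0)
        return ((total + 2) // 4).astype(self.dtype)

    def reduce_to_coarser(self, level: int, footprint) -> np.ndarray:
        """Re-reduce level+1 over the coarser image of ``footprint``.

        ``footprint`` is a half-open box at ``level``.  Returns the updated
        coarser-level values over the reduced footprint.
        """
        self._check_level(level)
        if level + 1 >= self.num_levels:
            raise ValueError(f"level {level + 1} does not exist")
        x0, y0, z0, x1, y1, z1 = self._check_bbox(level, footprint)
        cex, cey, _ = self.level_extent(level + 1)
        cbox = (x0 // 2, y0 // 2, z0, min(_ceil_div(x1, 2), cex), min(_ceil_div(y1, 2), cey), z1)
        fex, fey, _ = self.level_extent(level)
        fx1 = min(cbox[3] * 2, fex)
        fy1 = min(cbox[4] * 2, fey)
        fine = self.read_region(level, (cbox[0] * 2, cbox[1] * 2, z0, fx1, fy1, z1))
        # pad odd trailing edges by replication so every coarse voxel has 4 children
        px = (cbox[3] - cbox[0]) * 2 - fine.shape[0]
        py = (cbox[4] - cbox[1]) * 2 - fine.shape[1]
        if px or py:
            pad = [(0, px), (0, py), (0, 0)] + ([(0, 0)] if self.channels else [])
            fine = np.pad(fine, pad, mode="edge")
        coarse = self._reduce_block(fine)
        self._write_explicit(level + 1, cbox, coarse, explicit=True)
        return coarse

    def _reduce_cascade(self, level: int, box) -> None:
        x0, y0, z0, x1, y1, z1 = box
        for lev in range(level, self.num_levels - 1):
            self.reduce_to_coarser(lev, (x0, y0, z0, x1, y1, z1))
            ex, ey, _ = self.level_extent(lev + 1)
            x0, y0 = x0 // 2, y0 // 2
            x1, y1 = min(_ceil_div(x1, 2), ex), min(_ceil_div(y1, 2), ey)

    # -- convenience --------------------------------------------------------

    def read_full(self, level: int = 0) -> np.ndarray:
        ex, ey, ez = self.level_extent(level)
        return self.read_region(level, (0, 0, 0, ex, ey, ez))

    def write_full(self, values: np.ndarray, level: int = 0) -> int:
        ex, ey, ez = self.level_extent(level)
        return self.write_region(level, (0, 0, 0, ex, ey, ez), values)

    def copy(self) -> "ChunkedVolume":
        out = ChunkedVolume(
            self.dims_vx, self.voxel_size_nm, self.value_kind, self.num_levels
        )
        for key in self.allocated_chunks:
            chunk = self.cache.get(key)
            out.cache.put(key, Chunk(chunk.values.copy(), chunk.mask.copy()))
        return out


# ---------------------------------------------------------------------------
# module-level operation aliases
# ---------------------------------------------------------------------------

def create_volume(dims_vx, voxel_size_nm=(1.0, 1.0, 1.0), value_kind="gray8",
                  num_levels=1, cache=None) -> ChunkedVolume:
    """Create an empty sparse volume; every voxel at every level reads 0."""
    return ChunkedVolume(dims_vx, voxel_size_nm, value_kind, num_levels, cache)


def read_region(vol: ChunkedVolume, level: int, bbox) -> np.ndarray:
    return vol.read_region(level, bbox)


def write_region(vol: ChunkedVolume, level: int, bbox, values) -> int:
    return vol.write_region(level, bbox, values)


def reduce_to_coarser(vol: ChunkedVolume, level: int, footprint) -> np.ndarray:
    return vol.reduce_to_coarser(level, footprint)


def effective_value(vol: ChunkedVolume, level: int, x: int, y: int, z: int):
    return vol.effective_value(level, x, y, z)
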