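"""Segment metadata and hierarchy.

Segments are the unit of annotation: each carries a label, two 24-bit RGB
display colors plus a pattern index (so that far more than 2^24 visually
distinct objects can be displayed), an anchor point used as a bookmark, a
bounding box, and a position in a rooted hierarchy tree.  Folder nodes are
themselves segments; collapsing a folder makes every segment below it
display in the folder's colors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .volume import MAX_SEGMENT_ID, ChunkedVolume

__all__ = [
    "Segment",
    "SegmentTable",
    "encode_color_key",
    "decode_color_key",
    "resolve_display_color",
    "collect",
    "weld",
    "delete_subtree",
    "recompute_extents",
]

RGB = tuple[int, int, int]

#: Number of distinct fill patterns a segment can combine with its two colors.
NUM_PATTERNS = 16


def _check_rgb(color) -> RGB:
    r, g, b = (int(c) for c in color)
    if not all(0 <= c <= 255 for c in (r, g, b)):
        raise ValueError(f"RGB components must be in [0, 255]: {color}")
    return (r, g, b)


def rgb_to_int(color: RGB) -> int:
    r, g, b = _check_rgb(color)
    return (r << 16) | (g << 8) | b


def int_to_rgb(value: int) -> RGB:
    if not (0 <= value < 1 << 24):
        raise ValueError(f"24-bit color out of range: {value}")
    return ((value >> 16) & 255, (value >> 8) & 255, value & 255)


def encode_color_key(color1, color2, pattern: int) -> int:
    """Pack two 24-bit colors and a 16-way pattern into one integer key.

    ``key = (color1 * 2^24 + color2) * 16 + pattern`` — an injective map
    onto [0, 2^52), the display color space of the annotation model.
    """
    c1 = color1 if isinstance(color1, int) else rgb_to_int(color1)
    c2 = color2 if isinstance(color2, int) else rgb_to_int(color2)
    if not (0 <= c1 < 1 << 24 and 0 <= c2 < 1 << 24):
        raise ValueError("colors must be 24-bit values")
    if not (0 <= pattern < NUM_PATTERNS):
        raise ValueError(f"pattern must be in [0, {NUM_PATTERNS}): {pattern}")
    return ((c1 << 24) | c2) * NUM_PATTERNS + pattern


def decode_color_key(key: int) -> tuple[int, int, int]:
    """Inverse of :func:`encode_color_key`: (color1, color2, pattern)."""
    if not (0 <= key < 1 << 52):
        raise ValueError(f"color key out of range: {key}")
    pattern = key % NUM_PATTERNS
    packed = key // NUM_PATTERNS
    return (packed >> 24, packed & ((1 << 24) - 1), pattern)


@dataclass
class Segment:
    """One segment record; ``parent_id == 0`` means a child of the root."""

    id: int
    parent_id: int = 0
    label: str = ""
    color1: RGB = (255, 0, 0)
    color2: RGB = (128, 0, 0)
    pattern: int = 0
    anchor: Optional[tuple[int, int, int]] = None
    bbox: Optional[tuple[int, int, int, int, int, int]] = None  # half-open; None = empty
    collapsed: bool = False

    def __post_init__(self):
        if not (1 <= self.id <= MAX_SEGMENT_ID):
            raise ValueError(f"segment id must be in [1, {MAX_SEGMENT_ID}]: {self.id}")
        self.color1 = _check_rgb(self.color1)
        self.color2 = _check_rgb(self.color2)
        if not (0 <= self.pattern < NUM_PATTERNS):
            raise ValueError(f"pattern must be in [0, {NUM_PATTERNS}): {self.pattern}")


class SegmentTable:
    """Rooted tree of :class:`Segment` records, keyed by ID.

    The root (ID 0) is virtual: it is not a segment and cannot be deleted
    or recolored.  Traversal order is depth-first in child-insertion order.
    """

    def __init__(self):
        self._segments: dict[int, Segment] = {}
        self._children: dict[int, list[int]] = {0: []}

    # -- container protocol --------------------------------------------------

    def __len__(self) -> int:
        return len(self._segments)

    def __contains__(self, seg_id: int) -> bool:
        return seg_id in self._segments

    def __getitem__(self, seg_id: int) -> Segment:
        try:
            return self._segments[seg_id]
        except KeyError:
            raise KeyError(f"unknown segment id {seg_id}") from None

    def ids(self) -> list[int]:
        """All segment IDs in depth-first traversal order."""
        return [s.id for s in self]

    def __iter__(self) -> Iterator[Segment]:
        stack = list(reversed(self._children[0]))
        while stack:
            sid = stack.pop()
            yield self._segments[sid]
            stack.extend(reversed(self._children.get(sid, [])))

    # -- construction --------------------------------------------------------

    def add(self, segment: Segment | None = None, **kwargs) -> Segment:
        seg = segment if segment is not None else Segment(**kwargs)
        if seg.id in self._segments:
            raise ValueError(f"duplicate segment id {seg.id}")
        if seg.parent_id != 0 and seg.parent_id not in self._segments:
            raise ValueError(f"parent id {seg.parent_id} does not exist")
        self._segments[seg.id] = seg
        self._children.setdefault(seg.id, [])
        self._children.setdefault(seg.parent_id, []).append(seg.id)
        return seg

    def next_free_id(self, start: int = 1) -> int:
        sid = max(1, start)
        while sid in self._segments:
            sid += 1
        if sid > MAX_SEGMENT_ID:
            raise ValueError("no free segment ids left (16-bit limit)")
        return sid

    # -- tree queries --------------------------------------------------------

    def children(self, seg_id: int) -> list[int]:
        if seg_id != 0 and seg_id not in self._segments:
            raise KeyError(f"unknown segment id {seg_id}")
        return list(self._children.get(seg_id, []))

    def descendants(self, seg_id: int) -> list[int]:
        """Strict descendants of ``seg_id`` in depth-first order."""
        out: list[int] = []
        stack = list(reversed(self.children(seg_id)))
        while stack:
            sid = stack.pop()
            out.append(sid)
            stack.extend(reversed(self._children.get(sid, [])))
        return out

    def root_path(self, seg_id: int) -> list[int]:
        """IDs from the root's child down to ``seg_id`` (inclusive)."""
        path = []
        sid = seg_id
        while sid != 0:
            path.append(sid)
            sid = self[sid].parent_id
        return list(reversed(path))

    def in_branch(self, seg_id: int, branch_id: int) -> bool:
        """True if ``seg_id`` is ``branch_id`` or one of its descendants."""
        return branch_id in self.root_path(seg_id)

    def find(self, query: str) -> list[Segment]:
        """Linear scan for segments by ID string or label substring."""
        q = query.lower()
        return [
            s for s in self
            if q in s.label.lower() or q == str(s.id)
        ]

    # -- display-color resolution -------------------------------------------

    def resolve_display_color(self, seg_id: int) -> tuple[RGB, RGB, int]:
        """Display colors of a segment under the folder-collapse rule.

        Returns the (color1, color2, pattern) of the outermost collapsed
        ancestor on the segment's root-path, or the segment's own colors
        when no ancestor is collapsed.
        """
        for sid in self.root_path(seg_id)[:-1]:  # proper ancestors, root-first
            seg = self[sid]
            if seg.collapsed:
                return (seg.color1, seg.color2, seg.pattern)
        seg = self[seg_id]
        return (seg.color1, seg.color2, seg.pattern)

    # -- structural edits ----------------------------------------------------

    def collect(self, seg_id: int, dest_folder_id: int) -> None:
        """Reparent (translocate) a segment under a destination folder."""
        seg = self[seg_id]
        if dest_folder_id != 0:
            if dest_folder_id not in self._segments:
                raise KeyError(f"unknown destination folder {dest_folder_id}")
            if dest_folder_id == seg_id or seg_id in self.root_path(dest_folder_id):
                raise ValueError(
                    f"moving segment {seg_id} under {dest_folder_id} would create a cycle"
                )
        self._children[seg.parent_id].remove(seg_id)
        seg.parent_id = dest_folder_id
        self._children.setdefault(dest_folder_id, []).append(seg_id)

    def _remove_record(self, seg_id: int) -> None:
        seg = self._segments.pop(seg_id)
        self._children[seg.parent_id].remove(seg_id)
        self._children.pop(seg_id, None)

    def copy(self) -> "SegmentTable":
        out = SegmentTable()
        for seg in self:
            out.add(replace(seg))
        return out


# ---------------------------------------------------------------------------
# voxel-touching operations
# ---------------------------------------------------------------------------

def _relabel_voxels(vol: ChunkedVolume, mapping: dict[int, int]) -> int:
    """Apply an ID->ID map to all level-0 voxels; returns voxels changed."""
    if not mapping:
        return 0
    arr = vol.read_full(0)
    lut = np.arange(MAX_SEGMENT_ID + 1, dtype=np.uint16)
    for src, dst in mapping.items():
        lut[src] = dst
    new = lut[arr]
    if np.array_equal(new, arr):
        return 0
    return vol.write_full(new, 0)


def weld(table: SegmentTable, vol: ChunkedVolume, folder_id: int) -> int:
    """Relabel every descendant of a folder to a single surviving segment.

    The survivor is the lowest descendant ID; all other descendant records
    are removed and their voxels relabeled, so total labeled voxel mass is
    conserved.  Returns the surviving ID.
    """
    members = table.descendants(folder_id)
    if folder_id != 0:
        table[folder_id]  # raises on unknown id
    if not members:
        raise ValueError(f"folder {folder_id} has no descendant segments to weld")
    survivor = min(members)
    mapping = {m: survivor for m in members if m != survivor}
    _relabel_voxels(vol, mapping)
    # merge bounding boxes into the survivor
    boxes = [table[m].bbox for m in members if table[m].bbox is not None]
    surv = table[survivor]
    if boxes:
        arr = np.array(boxes)
        surv.bbox = tuple(arr[:, :3].min(axis=0)) + tuple(arr[:, 3:].max(axis=0))
    # survivor may currently sit below a removed member: hoist it first
    if any(m in mapping for m in table.root_path(survivor)[:-1]):
        table.collect(survivor, folder_id)
    for m in sorted(mapping, key=lambda m: -len(table.root_path(m))):
        for child in table.children(m):
            table.collect(child, survivor if child != survivor else folder_id)
        table._remove_record(m)
    return survivor


def delete_subtree(table: SegmentTable, vol: ChunkedVolume, seg_id: int) -> int:
    """Erase a segment and its whole subtree from table and volume.

    Returns the number of voxels cleared.  The root cannot be deleted.
    """
    if seg_id == 0:
        raise ValueError("the root folder cannot be deleted")
    doomed = [seg_id] + table.descendants(seg_id)
    cleared = _relabel_voxels(vol, {d: 0 for d in doomed})
    for d in sorted(doomed, key=lambda m: -len(table.root_path(m))):
        table._remove_record(d)
    return cleared


def recompute_extents(table: SegmentTable, vol: ChunkedVolume) -> SegmentTable:
    """Refresh every segment's bounding box (and unset anchors) from voxels.

    The bounding box is the tight half-open box over the segment's level-0
    voxels; empty segments get an empty box.  An unset anchor defaults to
    the segment's first voxel in scan order; a set anchor is only replaced
    when it no longer falls inside the segment's box.
    """
    arr = vol.read_full(0)
    for seg in table:
        coords = np.argwhere(arr == seg.id)
        if coords.size == 0:
            seg.bbox = None
            continue
        lo = coords.min(axis=0)
        hi = coords.max(axis=0) + 1
        seg.bbox = tuple(int(v) for v in lo) + tuple(int(v) for v in hi)
        if seg.anchor is None or not all(
            l <= a < h for a, l, h in zip(seg.anchor, lo, hi)
        ):
            seg.anchor = tuple(int(v) for v in coords[0])
    return table


def table_from_volume(vol: ChunkedVolume, label_prefix: str = "segment") -> SegmentTable:
    """Build a flat table covering every nonzero ID present in a volume."""
    arr = vol.read_full(0)
    table = SegmentTable()
    rng = np.random.default_rng(12345)  # stable distinct display colors
    for sid in np.unique(arr):
        sid = int(sid)
        if sid == 0:
            continue
        c1 = tuple(int(v) for v in rng.integers(32, 256, 3))
        c2 = tuple(int(v) for v in rng.integers(0, 128, 3))
        table.add(id=sid, label=f"{label_prefix} {sid}", color1=c1, color2=c2)
    recompute_extents(table, vol)
    return table


# module-level aliases matching the operation surface -----------------------

def resolve_display_color(table: SegmentTable, seg_id: int):
    return table.resolve_display_color(seg_id)


def collect(table: SegmentTable, seg_id: int, dest_folder_id: int) -> SegmentTable:
    table.collect(seg_id, dest_folder_id)
    return table
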