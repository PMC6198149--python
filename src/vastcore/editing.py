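"""Masked voxel painting and filling.

Every edit is the intersection of up to three masks:

* the **pen mask** — voxels under the rasterized pen stroke;
* the **target mask** — which voxels of the segmentation being edited are
  admissible (paint over everything, only background, or only voxels of
  the paint ID's direct parent segment);
* an optional **source mask** from a *different* layer (trans-layer
  masking): voxels whose source value lies in a brightness range, or
  equals a picked value, restricted to the contiguous region containing
  the seed.  This is how a boundary-probability map or a candidate
  automatic segmentation guides manual painting.

Painting with ID 0 erases.  After a stroke, closed empty contours can be
auto-filled, and the Z-gap filler can bridge skipped sections between
same-ID voxels at the same XY position up to a maximum depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage

from .segments import SegmentTable
from .volume import ChunkedVolume

__all__ = [
    "MaskSpec",
    "PenStroke",
    "make_pen_mask",
    "target_mask",
    "source_mask",
    "apply_stroke",
    "zgap_fill",
    "flood_fill",
    "pick",
]

TARGET_MODES = ("paint_all", "background_only", "parent_only")
SOURCE_MODES = ("none", "value_range", "picked_value")

#: 6-connected 3D structuring element (no diagonal adjacency).
STRUCT_3D = ndimage.generate_binary_structure(3, 1)
#: 4-connected in-section element embedded in 3D (no Z adjacency).
STRUCT_2D = np.zeros((3, 3, 3), dtype=bool)
STRUCT_2D[0, 1, 1] = STRUCT_2D[2, 1, 1] = STRUCT_2D[1, 0, 1] = STRUCT_2D[1, 2, 1] = True
STRUCT_2D[1, 1, 1] = True


@dataclass
class MaskSpec:
    """Declarative constraint for one edit.

    ``value_range`` is inclusive; ``channel`` selects the source channel
    for RGB source layers (ignored for grayscale).  ``restrict_level``
    pins the edit to one mip level so a minimum resolution is guaranteed.
    ``max_paint_depth`` enables Z-gap filling up to that many sections.
    """

    target_mode: str = "paint_all"
    source_mode: str = "none"
    value_range: tuple[int, int] = (0, 255)
    channel: int = 0
    restrict_level: Optional[int] = None
    max_paint_depth: int = 0
    auto_close: bool = False

    def __post_init__(self):
        if self.target_mode not in TARGET_MODES:
            raise ValueError(f"unknown target_mode {self.target_mode!r}")
        if self.source_mode not in SOURCE_MODES:
            raise ValueError(f"unknown source_mode {self.source_mode!r}")
        lo, hi = self.value_range
        if lo > hi:
            raise ValueError(f"value_range lo > hi: {self.value_range}")
        if self.max_paint_depth < 0:
            raise ValueError("max_paint_depth must be >= 0")


@dataclass
class PenStroke:
    """A pen stroke on one section: polyline of centers plus a tip size."""

    z: int
    centers: list[tuple[int, int]]
    diameter: int = 1
    paint_id: int = 0  # 0 erases
    level: int = 0

    def __post_init__(self):
        if self.diameter < 1:
            raise ValueError("pen diameter must be >= 1 voxel")
        if not self.centers:
            raise ValueError("stroke needs at least one center")


def _disk_offsets(diameter: int) -> np.ndarray:
    """Integer (dx, dy) offsets whose center distance is <= diameter/2."""
    r = diameter / 2.0
    n = int(np.floor(r))
    dx, dy = np.mgrid[-n:n + 1, -n:n + 1]
    keep = dx * dx + dy * dy <= r * r + 1e-9
    return np.stack([dx[keep], dy[keep]], axis=1)


def make_pen_mask(stroke: PenStroke, section_extent: tuple[int, int] | None = None) -> set:
    """Rasterize a stroke into a set of (x, y, z) voxel coordinates.

    The mask is the union of Euclidean disks (radius = diameter/2, ties
    included) stamped at every voxel step along the polyline joining
    consecutive centers.
    """
    offsets = _disk_offsets(stroke.diameter)
    voxels: set[tuple[int, int, int]] = set()
    pts = [tuple(map(int, c)) for c in stroke.centers]
    for (x0, y0), (x1, y1) in zip(pts, pts[1:] or pts):
        steps = max(abs(x1 - x0), abs(y1 - y0), 1)
        for t in range(steps + 1):
            cx = int(round(x0 + (x1 - x0) * t / steps))
            cy = int(round(y0 + (y1 - y0) * t / steps))
            for dx, dy in offsets:
                voxels.add((cx + int(dx), cy + int(dy), stroke.z))
    if section_extent is not None:
        ex, ey = section_extent
        voxels = {(x, y, z) for x, y, z in voxels if 0 <= x < ex and 0 <= y < ey}
    return voxels


def _coords_array(coords: Iterable[tuple]) -> np.ndarray:
    arr = np.array(sorted(coords), dtype=np.int64)
    return arr.reshape(-1, 3)


def target_mask(
    seg_vol: ChunkedVolume,
    mode: str,
    paint_id: int,
    table: Optional[SegmentTable],
    footprint: Iterable[tuple],
    level: int = 0,
) -> set:
    """Subset of ``footprint`` admissible under the target-layer mode."""
    coords = _coords_array(footprint)
    if coords.size == 0:
        return set()
    if mode == "paint_all":
        return {tuple(c) for c in coords}
    if mode == "background_only":
        want = 0
    elif mode == "parent_only":
        if table is None or paint_id not in table:
            raise ValueError("parent_only mode needs the paint id in the segment table")
        parent = table[paint_id].parent_id
        if parent == 0:
            raise ValueError(
                f"segment {paint_id} has no parent segment (parent is the root folder)"
            )
        want = parent
    else:
        raise ValueError(f"unknown target_mode {mode!r}")
    vals = np.array([seg_vol.effective_value(level, *c) for c in coords])
    return {tuple(c) for c, v in zip(coords, vals) if v == want}


def _source_values(source_vol: ChunkedVolume, level: int, channel: int) -> np.ndarray:
    vals = source_vol.read_full(level)
    if source_vol.channels:
        vals = vals[..., channel]
    return vals


def source_mask(
    source_vol: ChunkedVolume,
    spec: MaskSpec,
    seed: tuple[int, int, int],
    footprint: Iterable[tuple],
    level: int = 0,
    three_d: bool = False,
) -> set:
    """Subset of ``footprint`` admissible under the source-layer mask.

    The in-range (or picked-value) voxels are restricted to the connected
    component containing the seed: 4-connected within a section, or
    6-connected when ``three_d``.  This is what makes a boundary map act
    as a fence — only the seeded "room" is admissible.
    """
    if spec.source_mode == "none":
        raise ValueError("source_mask called with source_mode='none'")
    vals = _source_values(source_vol, level, spec.channel)
    sx, sy, sz = seed
    if spec.source_mode == "picked_value":
        picked = vals[sx, sy, sz]
        admissible = vals == picked
    else:
        lo, hi = spec.value_range
        admissible = (vals >= lo) & (vals <= hi)
    if not admissible[sx, sy, sz]:
        raise ValueError(f"seed {seed} is outside the source mask")
    struct = STRUCT_3D if three_d else STRUCT_2D
    labels, _ = ndimage.label(admissible, structure=struct)
    region = labels == labels[sx, sy, sz]
    return {c for c in footprint if region[c[0], c[1], c[2]]}


def _write_coords(seg_vol: ChunkedVolume, coords: set, value: int, level: int) -> int:
    """Read-modify-write the bounding box of a coordinate set."""
    if not coords:
        return 0
    arr = _coords_array(coords)
    lo = arr.min(axis=0)
    hi = arr.max(axis=0) + 1
    bbox = (*lo, *hi)
    block = seg_vol.read_region(level, bbox)
    block[arr[:, 0] - lo[0], arr[:, 1] - lo[1], arr[:, 2] - lo[2]] = value
    return seg_vol.write_region(level, bbox, block)


def _auto_close(
    seg_vol: ChunkedVolume, painted: set, z: int, level: int
) -> set:
    """Empty voxels on section ``z`` fully enclosed by the painted set.

    "Enclosed" means: background components of the painted set's section
    footprint (padded by one voxel) that cannot be reached from the
    footprint border.
    """
    if not painted:
        return set()
    arr = _coords_array(painted)
    ex, ey, _ = seg_vol.level_extent(level)
    x0, y0 = np.maximum(arr[:, :2].min(axis=0) - 1, 0)
    x1 = min(arr[:, 0].max() + 2, ex)
    y1 = min(arr[:, 1].max() + 2, ey)
    w, h = x1 - x0, y1 - y0
    stroke = np.zeros((w, h), dtype=bool)
    stroke[arr[:, 0] - x0, arr[:, 1] - y0] = True
    open_space = ~stroke
    labels, _ = ndimage.label(open_space, structure=ndimage.generate_binary_structure(2, 1))
    border = np.zeros_like(open_space)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    outside = np.unique(labels[border & open_space])
    enclosed = open_space & ~np.isin(labels, outside)
    if not enclosed.any():
        return set()
    section = seg_vol.read_region(level, (x0, y0, z, x1, y1, z + 1))[:, :, 0]
    fill = enclosed & (section == 0)  # only empty voxels are auto-filled
    xs, ys = np.nonzero(fill)
    return {(int(x + x0), int(y + y0), z) for x, y in zip(xs, ys)}


def apply_stroke(
    seg_vol: ChunkedVolume,
    stroke: PenStroke,
    spec: MaskSpec,
    table: Optional[SegmentTable] = None,
    source_vol: Optional[ChunkedVolume] = None,
) -> set:
    """Apply a masked pen stroke; returns the set of voxels written.

    The painted set is ``pen_mask ∩ target_mask ∩ source_mask``; closed
    empty contours are filled if requested, then the Z-gap filler runs.
    """
    level = stroke.level
    if spec.restrict_level is not None and level != spec.restrict_level:
        raise ValueError(
            f"stroke level {level} violates restrict_level={spec.restrict_level}"
        )
    if spec.source_mode != "none" and source_vol is None:
        raise ValueError("spec requests a source mask but no source layer was given")
    ex, ey, ez = seg_vol.level_extent(level)
    if not (0 <= stroke.z < ez):
        raise ValueError(f"stroke section {stroke.z} outside volume")
    pen = make_pen_mask(stroke, (ex, ey))
    painted = target_mask(seg_vol, spec.target_mode, stroke.paint_id, table, pen, level)
    if spec.source_mode != "none":
        seed = (int(stroke.centers[0][0]), int(stroke.centers[0][1]), stroke.z)
        painted &= source_mask(source_vol, spec, seed, painted, level)
    written = set(painted)
    if spec.auto_close and stroke.paint_id != 0:
        written |= _auto_close(seg_vol, painted, stroke.z, level)
    _write_coords(seg_vol, written, stroke.paint_id, level)
    if spec.max_paint_depth > 0 and stroke.paint_id != 0:
        written |= zgap_fill(
            seg_vol, written, stroke.paint_id, spec.max_paint_depth,
            target_mode=spec.target_mode, table=table, level=level,
        )
    return written


def zgap_fill(
    seg_vol: ChunkedVolume,
    painted: Iterable[tuple],
    paint_id: int,
    max_depth: int,
    target_mode: str = "paint_all",
    table: Optional[SegmentTable] = None,
    level: int = 0,
) -> set:
    """Bridge Z gaps between same-ID voxels at the same XY position.

    For every painted voxel, scan up to ``max_depth`` sections in each Z
    direction; when a voxel carrying ``paint_id`` is found at distance
    ``k <= max_depth``, the ``k - 1`` intervening voxels are filled with
    the paint ID, subject to the target mode.  Returns the voxels filled.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1 for Z-gap filling")
    _, _, ez = seg_vol.level_extent(level)
    filled: set[tuple[int, int, int]] = set()
    for x, y, z in painted:
        for step in (1, -1):
            for k in range(2, max_depth + 1):
                zt = z + step * k
                if not (0 <= zt < ez):
                    break
                if seg_vol.effective_value(level, x, y, zt) == paint_id:
                    for zi in range(min(z, zt) + 1, max(z, zt)):
                        filled.add((x, y, zi))
                    break
    if filled:
        filled = target_mask(seg_vol, target_mode, paint_id, table, filled, level)
        filled = {c for c in filled
                  if seg_vol.effective_value(level, *c) != paint_id}
        _write_coords(seg_vol, filled, paint_id, level)
    return filled


def flood_fill(
    seg_vol: ChunkedVolume,
    seed: tuple[int, int, int],
    new_id: int,
    spec: MaskSpec | None = None,
    dimensionality: str = "3D",
    table: Optional[SegmentTable] = None,
    source_vol: Optional[ChunkedVolume] = None,
    level: int = 0,
) -> int:
    """Recolor the masked connected component containing ``seed``.

    Connectivity is 4-connected within a section (2D) or 6-connected (3D).
    The fill predicate is: same current ID as the seed, intersected with
    the target-mode and (optional) source-layer masks.  Returns the voxel
    count recolored; a seed excluded by the mask fills nothing.
    """
    spec = spec or MaskSpec()
    if dimensionality not in ("2D", "3D"):
        raise ValueError("dimensionality must be '2D' or '3D'")
    ex, ey, ez = seg_vol.level_extent(level)
    sx, sy, sz = (int(v) for v in seed)
    if not (0 <= sx < ex and 0 <= sy < ey and 0 <= sz < ez):
        raise ValueError(f"seed {seed} outside volume extent {(ex, ey, ez)}")
    vals = seg_vol.read_full(level)
    seed_val = vals[sx, sy, sz]
    admissible = vals == seed_val
    if spec.target_mode == "background_only":
        admissible &= vals == 0
    elif spec.target_mode == "parent_only":
        if table is None or new_id not in table:
            raise ValueError("parent_only fill needs the new id in the segment table")
        parent = table[new_id].parent_id
        if parent == 0:
            raise ValueError(f"segment {new_id} has no parent segment")
        admissible &= vals == parent
    if spec.source_mode != "none":
        if source_vol is None:
            raise ValueError("spec requests a source mask but no source layer was given")
        svals = _source_values(source_vol, level, spec.channel)
        if spec.source_mode == "picked_value":
            admissible &= svals == svals[sx, sy, sz]
        else:
            lo, hi = spec.value_range
            admissible &= (svals >= lo) & (svals <= hi)
    if not admissible[sx, sy, sz]:
        warnings.warn(f"flood fill seed {seed} is excluded by the mask; nothing filled")
        return 0
    struct = STRUCT_3D if dimensionality == "3D" else STRUCT_2D
    labels, _ = ndimage.label(admissible, structure=struct)
    region = labels == labels[sx, sy, sz]
    if dimensionality == "2D":
        keep = np.zeros_like(region)
        keep[:, :, sz] = region[:, :, sz]
        region = keep
    count = int(region.sum())
    vals[region] = new_id
    seg_vol.write_full(vals, level)
    return count


def pick(vol: ChunkedVolume, point: tuple[int, int, int], level: int = 0):
    """Pipette: the effective value/ID at a point (inherits across levels)."""
    return vol.effective_value(level, *point)
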