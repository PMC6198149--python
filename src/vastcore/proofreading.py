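"""Split/merge proofreading of segmentations.

Automatic segmentations contain *split errors* (one true object carries
several labels) and *merge errors* (several true objects share one
label).  Splits are corrected by welding; mergers by disconnecting and
relabeling connected components.  Independently produced segmentations
of the same stack are combined voxel-by-voxel under a source/target
precedence rule with segment-ID renumbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .segments import Segment, SegmentTable
from .volume import MAX_SEGMENT_ID, ChunkedVolume

__all__ = [
    "MergePolicy",
    "split_components",
    "merge_volumes",
    "truncate_id_24",
    "rand_index",
]

#: 6-connected structuring element used for component analysis.
_STRUCT = ndimage.generate_binary_structure(3, 1)


def _morton_codes(coords: np.ndarray, bits: int = 21) -> np.ndarray:
    """Vectorized Morton codes of (N, 3) voxel coordinates."""
    x, y, z = (coords[:, i].astype(np.int64) for i in range(3))
    code = np.zeros(len(coords), dtype=np.int64)
    for b in range(bits):
        code |= ((x >> b) & 1) << (3 * b)
        code |= ((y >> b) & 1) << (3 * b + 1)
        code |= ((z >> b) & 1) << (3 * b + 2)
    return code


def split_components(
    seg_vol: ChunkedVolume, table: SegmentTable, seg_id: int, level: int = 0
) -> list[int]:
    """Split a label into its 6-connected components.

    The largest component keeps ``seg_id`` (ties broken by the smallest
    Morton code of the component's first voxel); every further component
    is relabeled to a fresh ID added as a sibling of ``seg_id``.  Voxel
    mass is conserved.  Returns the list of new IDs (may be empty).
    """
    seg = table[seg_id]
    arr = seg_vol.read_full(level)
    mask = arr == seg_id
    if not mask.any():
        raise ValueError(f"segment {seg_id} has no voxels")
    labels, n = ndimage.label(mask, structure=_STRUCT)
    if n <= 1:
        return []
    comps = []
    for comp in range(1, n + 1):
        coords = np.argwhere(labels == comp)
        size = len(coords)
        codes = _morton_codes(coords)
        comps.append((comp, size, int(codes.min())))
    # keeper: largest, then smallest component-minimum Morton index
    comps.sort(key=lambda t: (-t[1], t[2]))
    new_ids: list[int] = []
    next_id = 1
    for comp, _, _ in comps[1:]:
        next_id = table.next_free_id(next_id)
        table.add(
            id=next_id,
            parent_id=seg.parent_id,
            label=f"{seg.label} (part {len(new_ids) + 2})" if seg.label else "",
            color1=seg.color1,
            color2=seg.color2,
            pattern=seg.pattern,
        )
        arr[labels == comp] = next_id
        new_ids.append(next_id)
    seg_vol.write_full(arr, level)
    from .segments import recompute_extents

    recompute_extents(table, seg_vol)
    return new_ids


@dataclass
class MergePolicy:
    """How two segmentations are combined.

    ``precedence`` resolves voxel conflicts: ``"source"`` lets nonzero
    source voxels overwrite the target, ``"target"`` write-protects
    nonzero target voxels (only empty ones receive source data).
    ``renumber`` maps source IDs: ``"offset"`` shifts colliding IDs to the
    lowest free target IDs, ``"keep"`` retains them (collisions merge
    labels), or an explicit ``{src: dst}`` dict.
    """

    precedence: str = "target"
    renumber: str | dict = "offset"

    def __post_init__(self):
        if self.precedence not in ("source", "target"):
            raise ValueError(f"precedence must be 'source' or 'target': {self.precedence}")
        if not (isinstance(self.renumber, dict) or self.renumber in ("offset", "keep")):
            raise ValueError(f"unknown renumber policy {self.renumber!r}")


def _build_id_map(
    source_ids: np.ndarray, target_table: SegmentTable, policy: MergePolicy
) -> dict[int, int]:
    if isinstance(policy.renumber, dict):
        id_map = {int(k): int(v) for k, v in policy.renumber.items()}
        missing = [i for i in source_ids if int(i) not in id_map]
        if missing:
            raise ValueError(f"explicit id map misses source ids {missing}")
    elif policy.renumber == "keep":
        id_map = {int(i): int(i) for i in source_ids}
    else:  # offset colliding ids to the lowest free ids
        id_map = {}
        next_id = 1
        for sid in sorted(int(i) for i in source_ids):
            if sid in target_table:
                next_id = target_table.next_free_id(next_id)
                while next_id in id_map.values():
                    next_id = target_table.next_free_id(next_id + 1)
                id_map[sid] = next_id
            else:
                id_map[sid] = sid
    if any(v > MAX_SEGMENT_ID or v < 1 for v in id_map.values()):
        raise ValueError("id renumbering overflows the 16-bit segment-id limit")
    return id_map


def merge_volumes(
    target_vol: ChunkedVolume,
    target_table: SegmentTable,
    source_vol: ChunkedVolume,
    source_table: Optional[SegmentTable],
    policy: MergePolicy | None = None,
    folder_label: str = "merged",
) -> tuple[ChunkedVolume, SegmentTable, dict[int, int]]:
    """Merge a source segmentation onto a target, voxel by voxel.

    Returns ``(merged_volume, merged_table, id_map)``.  The merged table
    is the target table with the (renumbered) source tree appended under
    a new folder.  Conflicts follow ``policy.precedence``.
    """
    policy = policy or MergePolicy()
    if target_vol.dims_vx != source_vol.dims_vx or target_vol.num_levels != source_vol.num_levels:
        raise ValueError("source and target volumes must share dims and mip levels")
    tgt = target_vol.read_full(0)
    src = source_vol.read_full(0)
    source_ids = np.unique(src)
    source_ids = source_ids[source_ids != 0]
    id_map = _build_id_map(source_ids, target_table, policy)

    lut = np.zeros(MAX_SEGMENT_ID + 1, dtype=np.uint16)
    for s, d in id_map.items():
        lut[s] = d
    src_mapped = lut[src]

    merged = tgt.copy()
    if policy.precedence == "source":
        write = src_mapped != 0
    else:
        write = (src_mapped != 0) & (tgt == 0)
    merged[write] = src_mapped[write]

    out_vol = ChunkedVolume(
        target_vol.dims_vx, target_vol.voxel_size_nm, "id16", target_vol.num_levels
    )
    out_vol.write_full(merged, 0)

    out_table = target_table.copy()
    if source_table is not None and len(source_table):
        folder_id = out_table.next_free_id(
            max((v for v in id_map.values()), default=0) + 1
        )
        out_table.add(id=folder_id, label=folder_label, color1=(128, 128, 128))
        for seg in source_table:
            nid = id_map.get(seg.id)
            if nid is None:  # source segment without voxels keeps/remaps lazily
                nid = seg.id if seg.id not in out_table else out_table.next_free_id()
                id_map[seg.id] = nid
        for seg in source_table:
            nid = id_map[seg.id]
            parent = id_map.get(seg.parent_id, folder_id) if seg.parent_id else folder_id
            if nid in out_table:
                continue  # 'keep' collision: records merge under the target's entry
            out_table.add(
                id=nid, parent_id=parent, label=seg.label, color1=seg.color1,
                color2=seg.color2, pattern=seg.pattern, anchor=seg.anchor,
                bbox=seg.bbox, collapsed=seg.collapsed,
            )
    return out_vol, out_table, id_map


def truncate_id_24(id64: int) -> int:
    """Truncate an external object ID to the 24 displayable bits.

    IDs are reduced modulo 2^24, except that an exact nonzero multiple of
    2^24 maps to the sentinel 2^24 - 1 so it cannot collide with the
    background value 0 and silently disappear.
    """
    id64 = int(id64)
    if id64 < 0:
        raise ValueError("object ids must be non-negative")
    m = id64 % (1 << 24)
    if m == 0 and id64 != 0:
        return (1 << 24) - 1
    return m


def rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Rand index between two labelings of the same voxel grid.

    1.0 means the partitions agree exactly up to label renaming.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("labelings must have the same size")
    n = a.size
    if n < 2:
        return 1.0
    pairs = a.astype(np.int64) * 65536 + b.astype(np.int64)
    _, nij = np.unique(pairs, return_counts=True)
    _, ai = np.unique(a, return_counts=True)
    _, bj = np.unique(b, return_counts=True)

    def c2(x):
        x = x.astype(np.float64)
        return float((x * (x - 1) / 2).sum())

    total = n * (n - 1) / 2.0
    agree = total + 2 * c2(nij) - c2(ai) - c2(bj)
    return agree / total
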