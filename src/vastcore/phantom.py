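"""Deterministic synthetic phantoms for testing the annotation pipeline.

The generator emulates the gross statistics of a serial-section EM
volume: neurite-like tubes (random-walk centerlines dilated to a
radius), compact blobs (somata/organelles), bright interiors bounded by
a one-voxel dark membrane, and additive Gaussian noise.  From the
ground-truth labels it can derive a boundary-probability map and inject
controlled split/merge errors to produce a candidate segmentation whose
scripted repair can be verified exactly.

Everything is reproducible: the same spec and seed yield bit-identical
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .segments import SegmentTable, table_from_volume
from .volume import ChunkedVolume

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_boundary_map",
    "corrupt_segmentation",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic EM-like phantom.

    Defaults mimic an anisotropic serial-section stack (6x6x30 nm
    voxels): a handful of tubes running roughly along Z plus compact
    blobs, bright interiors (~180) with dark one-voxel membranes (~40)
    on a mid-gray background, and mild sensor noise (sd 10 gray levels).
    """

    dims: tuple[int, int, int] = (48, 48, 24)
    voxel_size_nm: tuple[float, float, float] = (6.0, 6.0, 30.0)
    num_levels: int = 3
    n_tubes: int = 3
    n_blobs: int = 2
    tube_radius_vx: float = 3.0
    blob_radius_vx: float = 4.0
    interior_gray: int = 180
    membrane_gray: int = 40
    background_gray: int = 120
    noise_sd: float = 10.0
    min_gap_vx: int = 1
    seed: int = 0


def _tube_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """One neurite-like tube: smoothed random-walk centerline dilated in XY."""
    X, Y, Z = spec.dims
    r = spec.tube_radius_vx
    margin = int(np.ceil(r)) + spec.min_gap_vx
    x = rng.uniform(margin, X - margin)
    y = rng.uniform(margin, Y - margin)
    drift = rng.normal(0, 1.0, size=(Z, 2))
    # exponential smoothing keeps the centerline gently winding
    for i in range(1, Z):
        drift[i] = 0.7 * drift[i - 1] + 0.3 * drift[i]
    mask = np.zeros(spec.dims, dtype=bool)
    xi, yi = np.mgrid[0:X, 0:Y]
    for z in range(Z):
        x = float(np.clip(x + drift[z, 0], margin, X - margin))
        y = float(np.clip(y + drift[z, 1], margin, Y - margin))
        mask[:, :, z] |= (xi - x) ** 2 + (yi - y) ** 2 <= r * r
    return mask


def _blob_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    X, Y, Z = spec.dims
    r = spec.blob_radius_vx
    # Z radius shrunk by the section anisotropy
    rz = max(1.0, r * spec.voxel_size_nm[0] / spec.voxel_size_nm[2])
    margin_xy = int(np.ceil(r)) + spec.min_gap_vx
    margin_z = int(np.ceil(rz))
    cx = rng.uniform(margin_xy, X - margin_xy)
    cy = rng.uniform(margin_xy, Y - margin_xy)
    cz = rng.uniform(margin_z, max(margin_z + 1, Z - margin_z))
    xi, yi, zi = np.mgrid[0:X, 0:Y, 0:Z]
    return ((xi - cx) / r) ** 2 + ((yi - cy) / r) ** 2 + ((zi - cz) / rz) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[ChunkedVolume, ChunkedVolume]:
    """Generate (image volume gray8, ground-truth segmentation id16).

    Objects are placed disjointly with at least ``min_gap_vx`` background
    voxels between them (the membrane gap every real segmentation
    boundary has); an overcrowded spec that cannot be placed raises.
    """
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = spec.dims
    labels = np.zeros(spec.dims, dtype=np.uint16)
    forbidden = np.zeros(spec.dims, dtype=bool)
    next_id = 1
    makers = [_tube_mask] * spec.n_tubes + [_blob_mask] * spec.n_blobs
    for make in makers:
        placed = False
        for _ in range(40):
            mask = make(spec, rng)
            if not mask.any() or (mask & forbidden).any():
                continue
            labels[mask] = next_id
            grown = ndimage.binary_dilation(
                mask, structure=_STRUCT6, iterations=spec.min_gap_vx
            )
            forbidden |= grown
            next_id += 1
            placed = True
            break
        if not placed:
            raise ValueError(
                f"overcrowded phantom spec: could not place object {next_id} "
                f"disjointly in dims {spec.dims}"
            )

    image = np.full(spec.dims, spec.background_gray, dtype=np.float64)
    interior = labels != 0
    image[interior] = spec.interior_gray
    # one-voxel membrane at the border of every object
    eroded = np.zeros_like(interior)
    for sid in range(1, next_id):
        m = labels == sid
        border = m & ~ndimage.binary_erosion(m, structure=_STRUCT6)
        image[border] = spec.membrane_gray
    image += rng.normal(0, spec.noise_sd, size=spec.dims)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    img_vol = ChunkedVolume(spec.dims, spec.voxel_size_nm, "gray8", spec.num_levels)
    img_vol.write_full(image, 0)
    seg_vol = ChunkedVolume(spec.dims, spec.voxel_size_nm, "id16", spec.num_levels)
    seg_vol.write_full(labels, 0)
    return img_vol, seg_vol


def make_boundary_map(
    truth_vol: ChunkedVolume, blur_sigma: float = 0.0
) -> ChunkedVolume:
    """Boundary-probability map: 255 where a 6-neighbor differs, else 0.

    Interiors of the truth objects stay 6-connected within the low-value
    region, so a value-range mask of [0, 127] fences each object.
    """
    labels = truth_vol.read_full(0)
    boundary = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        a = np.swapaxes(labels, 0, axis)
        d = a[1:] != a[:-1]
        b = np.swapaxes(boundary, 0, axis)
        b[1:] |= d
        b[:-1] |= d
    bmap = np.where(boundary, 255, 0).astype(np.float64)
    if blur_sigma > 0:
        bmap = ndimage.gaussian_filter(bmap, blur_sigma)
    out = ChunkedVolume(
        truth_vol.dims_vx, truth_vol.voxel_size_nm, "gray8", truth_vol.num_levels
    )
    out.write_full(np.clip(np.rint(bmap), 0, 255).astype(np.uint8), 0)
    return out


def corrupt_segmentation(
    truth_vol: ChunkedVolume,
    split_rate: float = 0.0,
    merge_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ChunkedVolume, list[dict]]:
    """Inject split and merge errors into a copy of the truth labels.

    Splits cut a chosen object at a random interior Z plane into two IDs.
    Mergers relabel a chosen pair of *distinct* nearby objects to one ID
    — a pure label-level error (no bridging voxels are painted), the way
    an automatic segmentation confuses two membrane-separated objects.
    Every injected error is recorded in the returned ledger.
    """
    if not (0 <= split_rate <= 1 and 0 <= merge_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = truth_vol.read_full(0).copy()
    ledger: list[dict] = []
    ids = [int(i) for i in np.unique(labels) if i != 0]
    next_id = max(ids, default=0) + 1

    for sid in ids:
        if rng.random() >= split_rate:
            continue
        zs = np.unique(np.argwhere(labels == sid)[:, 2])
        if len(zs) < 2:
            continue
        zc = int(rng.choice(zs[1:]))  # both halves stay non-empty
        half = (labels == sid) & (np.arange(labels.shape[2])[None, None, :] >= zc)
        labels[half] = next_id
        ledger.append({"kind": "split", "original_id": sid,
                       "new_id": next_id, "z_cut": zc})
        next_id += 1

    # merge candidates exclude split products so each injected error can be
    # repaired independently of the others
    split_ids = {e["original_id"] for e in ledger} | {e["new_id"] for e in ledger}
    current = [int(i) for i in np.unique(labels) if i != 0 and i not in split_ids]
    rng.shuffle(current)
    # pair nearby objects (by centroid) and merge with probability merge_rate
    if len(current) >= 2 and merge_rate > 0:
        centroids = {
            sid: np.argwhere(labels == sid).mean(axis=0) for sid in current
        }
        used: set[int] = set()
        for sid in current:
            if sid in used:
                continue
            if rng.random() >= merge_rate:
                continue
            others = [o for o in current if o != sid and o not in used]
            if not others:
                break
            dists = [np.linalg.norm(centroids[sid] - centroids[o]) for o in others]
            partner = others[int(np.argmin(dists))]
            labels[labels == partner] = sid
            used |= {sid, partner}
            ledger.append({"kind": "merge", "kept_id": sid, "absorbed_id": partner})

    out = ChunkedVolume(
        truth_vol.dims_vx, truth_vol.voxel_size_nm, "id16", truth_vol.num_levels
    )
    out.write_full(labels, 0)
    return out, ledger
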