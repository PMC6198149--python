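# vastcore

A headless Python library and CLI for **volumetric annotation and
segmentation of large 3D image stacks**, aimed at connectomics-style
workflows: serial-section electron microscopy volumes in which neurites,
organelles and other structures are labeled by voxel painting, corrected
by split/merge proofreading, and exported as meshes and measurements.

The computational core is a **sparse, chunked, multiresolution voxel
store**. Image (8-bit gray / 24-bit RGB) and segmentation (16-bit ID)
layers are held in 16×16×16-voxel chunks allocated on demand and indexed
by a fan-out-16³ pointer-block tree, so storage scales with painted
content rather than with the nominal extent of the dataset — an empty
teravoxel-scale segmentation costs essentially nothing. Each layer
carries powers-of-two **XY mipmaps** (Z is never reduced; serial sections
are strongly anisotropic), and edits may happen *at any mip level*: a
write at level *L* is authoritative for its footprint, finer explicit
data beneath it is cleared and coarser levels are re-reduced, while reads
inherit from the nearest coarser explicit level by 2×2 replication.
Chunks live in an LRU cache that evicts unmodified blocks first and
spills dirty blocks to disk rather than ever dropping them.

On top of the store:

- **Segment hierarchy** — each segment has a label, two 24-bit RGB
  colors plus one of 16 patterns (a display-color space of 2⁵², packed as
  `(c₁·2²⁴ + c₂)·16 + pattern`), an anchor point, a bounding box and a
  position in a rooted folder tree; collapsed folders recolor their
  subtree, and folders can be collected, welded into a single segment, or
  deleted with their subtree.
- **Masked painting and filling** — every edit is the intersection of a
  rasterized pen mask, a target-mode mask (paint all / background only /
  direct parent only) and optionally a *trans-layer* source mask: a
  brightness range or picked value in a separate layer, restricted to the
  contiguous region around the seed. That lets a boundary-probability map
  or candidate automatic segmentation act as a fence for manual strokes
  and 2D/3D flood fills. Closed empty contours can auto-fill, and the
  Z-gap filler bridges up to *k* skipped sections between same-ID voxels
  at the same XY position (paint an outline every 8th section with max
  depth ±8 and the 7 skipped sections fill in).
- **Proofreading** — relabel disconnected components (split correction),
  merge independently produced segmentations voxel-by-voxel under source
  or target precedence with ID renumbering, and truncate external ≥24-bit
  object IDs safely (multiples of 2²⁴ map to a sentinel, not to 0).
- **Export and measurement** — voxel-face surface meshes (Wavefront
  OBJ/MTL, one group and material per segment), marching-cubes
  isosurfaces, particle clouds at component centroids, textured boxes and
  exact-length scale bars, cardinal-axis projection images (max /
  first-hit / Lambert-illuminated), composited 2D sections with
  per-branch opacity and patterns, plus volume, surface-area and distance
  measurements in nm.
- **Synthetic phantoms** — deterministic EM-like volumes (tubes, blobs,
  membranes, noise), derived boundary maps, and split/merge error
  injection with a ledger, so the whole pipeline is testable without any
  external data.

## Worked example

Generate a phantom, corrupt its ground truth with split and merge
errors, repair it with the proofreading operations, and measure a
segment:

```python
import numpy as np
from vastcore import (PhantomSpec, make_phantom, corrupt_segmentation,
                      split_components, weld, rand_index, measure, segment_mesh)
from vastcore.segments import table_from_volume

image, truth = make_phantom(PhantomSpec(dims=(48, 48, 24), seed=7))
candidate, errors = corrupt_segmentation(truth, split_rate=0.7,
                                         merge_rate=0.7, seed=8)

table = table_from_volume(candidate)
for e in errors:                       # mergers: relabel components
    if e["kind"] == "merge":
        split_components(candidate, table, e["kept_id"])
for e in errors:                       # splits: weld the parts back
    if e["kind"] == "split":
        folder = table.next_free_id()
        table.add(id=folder, label="repair")
        table.collect(e["original_id"], folder)
        table.collect(e["new_id"], folder)
        weld(table, candidate, folder)

print(f"Rand index after repair: "
      f"{rand_index(truth.read_full(0), candidate.read_full(0)):.3f}")
stats = measure(truth, 1)
print(f"segment 1: {stats['voxel_count']} voxels, "
      f"{stats['volume_nm3']:.0f} nm^3, {stats['surface_area_nm2']:.0f} nm^2")
mesh = segment_mesh(truth, [1])
print(f"mesh: {len(mesh.faces)} triangles, closed={mesh.is_closed()}")
```

Output:

```
Rand index after repair: 1.000
segment 1: 676 voxels, 730080 nm^3, 111744 nm^2
mesh: 1616 triangles, closed=True
```

A Rand index of 1.0 means the repaired candidate partitions the voxels
exactly like the ground truth (label names aside). The volume is the
voxel count times the 6×6×30 nm voxel volume; the surface area sums the
triangles of the blocky voxel-face mesh and therefore overestimates a
smooth anatomical surface — smoothing is left to downstream 3D tools.

The same flows are available from the shell, e.g.:

```sh
vastcore fixtures phantom --seed 7 --out ph/
vastcore fixtures corrupt --truth ph/truth.vseg --seed 8 --out cand.vseg
vastcore split cand.vseg --id 4
vastcore measure ph/truth.vseg --id 1
vastcore mesh ph/truth.vseg --ids 1,2,3 --out cells.obj
```

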