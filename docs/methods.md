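# Methods

This note documents the models and procedures implemented in `vastcore`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic phantoms do and do not emulate.

## The storage model

A `ChunkedVolume` stores voxel data of one kind — `gray8` (8-bit
grayscale), `rgb24` (24-bit color) or `id16` (16-bit segment IDs, 0 =
background, so at most 65 535 distinct segments per layer) — in
16×16×16-voxel chunks allocated only where data has been written.
Unallocated space reads as 0 everywhere. Within the single-file
segmentation container, chunk payloads are serialized in Z-order (Morton
interleave, x in the least-significant bit of each 3-bit group, then y,
then z) and deflate-compressed; a per-level tree of 16×16×16 pointer
blocks maps chunk coordinates to file offsets, with the minimum depth
needed to address the level's chunk grid. File size therefore grows with
painted content, not with the nominal dataset extent: an empty
2²⁰×2²⁰×1000 segmentation serializes to the pointer roots and header
only (~160 kB).

**Mipmaps.** Level *L* halves the X and Y extent of level *L−1*
(`ceil(dims/2^L)`); Z is never reduced, because serial-section data is
strongly anisotropic (the default phantom voxel is 6×6×30 nm, so
sections are already ~5× coarser in Z). Images reduce by the arithmetic
mean of each 2×2 XY quad, rounded half-up; ID volumes reduce by majority
vote with ties broken toward the smallest ID — a deterministic rule that
keeps the dominant label and never invents one. Odd trailing edges are
handled by edge replication so every coarse voxel has four children.

**Cross-level semantics.** Edits are allowed at any mip level (paint a
soma at level 3 as cheaply as a spine neck at level 0). We adopt an
*authoritative-write* rule: a write at level *L* deletes explicit
finer-level data under its (scaled) footprint and re-reduces every
coarser level over it; a read at level *L* returns the explicit value if
present, otherwise the value inherited by 2×2-per-level XY replication
from the nearest coarser level with explicit data, otherwise 0.
Explicitness is tracked per voxel (a boolean mask per chunk), so partial
coarse strokes coexist with fine detail outside their footprint. This is
one consistent resolution of the cross-level combination problem; its
virtues are determinism and testability — the whole store is verified
against a dense shadow-pyramid model that applies the same rules with
naive per-voxel loops.

**Cache.** Chunks live in an LRU cache (default capacity 4096 chunks ≈
32 Mvoxels for id16). Eviction removes least-recently-used *unmodified*
chunks first; modified chunks are never discarded — when the cache
overflows with dirty chunks they are spilled to a disk store (a temp
directory, or `--tmpdir`). Unmodified chunks are dropped outright only
when a backing container file can restore them; an in-memory volume has
no such file, so its clean chunks are spilled as well rather than lost.
A chunk about to be mutated is flagged dirty atomically at lookup time,
closing the window in which it could be spilled in a stale state.

## Formats

- **Image stacks**: directories of per-section PNG/TIFF images (BMP/JPEG
  accepted on import), sections ordered by natural filename sort; or a
  tiled layout described by a JSON volume descriptor (name, tile
  pattern with `{level}/{z}/{row}/{col}` placeholders, tile size, dims,
  voxel size, levels, value kind). Export is restricted to lossless
  formats (PNG/TIFF/RAW) because lossy compression of ID images destroys
  labels; tile mosaics at the volume edge are zero-padded and flagged in
  a JSON manifest.
- **ID images**: segment IDs are encoded in RGB sections with green =
  ID div 256 and blue = ID mod 256, red reserved as 0 (a nonzero red
  channel on import warns and is ignored). The encoding is exact for all
  65 536 IDs. Import onto an existing volume applies the same
  source/target precedence rule as volume merging.
- **Metadata text**: one tab-separated line per segment (ID, parent,
  quoted label, two colors, pattern, anchor, bbox, collapse flag) with a
  `#` comment header. Labels are quoted with doubled quotes and
  backslash escapes for tabs/newlines, so arbitrary label text round-trips.
  Parsing reports duplicate IDs and dangling parents with line numbers.

## Editing

Every paint operation writes the intersection of up to three masks
(pen ∩ target ∩ source):

- **Pen mask**: the union of Euclidean disks of diameter *d* (ties at
  exactly *d*/2 included, so a diameter-3 tip covers the full 3×3
  neighborhood) stamped at every voxel step along the stroke polyline.
- **Target mask**: `paint_all`, `background_only` (current ID 0), or
  `parent_only` (current ID equals the paint ID's direct parent — the
  mode used to carve a child object out of its parent when correcting
  merge errors).
- **Source mask** (trans-layer masking): voxels of a *different* layer
  whose value lies in an inclusive range (boundary-probability maps:
  select the interior) or equals the value picked at the seed (candidate
  segmentations: select one object), restricted to the connected
  component containing the seed. We interpret the range mask as
  contiguous (seeded component) rather than accepting all in-range
  voxels under the pen: without contiguity a boundary map would not act
  as a fence, which is the point of the mode. The same rule applies to
  picked values for consistency.

Connectivity is 4-connected within a section and 6-connected in 3D,
preventing diagonal leakage across one-voxel membranes. Painting with
ID 0 erases. With auto-close enabled, background regions of the stroke's
section footprint that cannot be reached from the footprint border are
filled too; only *empty* (ID 0) voxels are auto-filled, regardless of
target mode, and source masks are not applied to the enclosed interior —
a deliberately closed contour has already passed its masks.

**Z-gap fill** (max paint depth *k* ≥ 1): after painting, each painted
XY position scans up to *k* sections in both Z directions; if a voxel
with the paint ID is found at distance *j* ≤ *k*, the *j*−1 intervening
voxels are filled, subject to the target mode but not to source masks
(the scan concerns the paint layer only). Filling is monotone in *k*.
Outlining an object every 8th section with *k* = 8 fills the 7 skipped
sections wherever the outlines overlap in XY.

**Flood fill** recolors the masked connected component of the seed
(same current ID as the seed ∩ target ∩ source), in 2D or 3D. A seed
excluded by its own mask fills nothing and warns.

## Segment hierarchy

Folders are ordinary segments; the root (ID 0) is virtual. Display
colors resolve through the collapse rule: a segment shows the colors of
the outermost collapsed ancestor on its root path, else its own. The
color key packs two 24-bit colors and a 4-bit pattern into 52 bits.
`collect` reparents with a cycle guard; `weld` relabels all descendants
of a folder to the lowest descendant ID (survivor choice is a
convention; the lowest ID is stable under repetition) and conserves
voxel mass; `delete_subtree` erases records and voxels together.
Anchors are set on first recompute and never moved unless they fall
outside the recomputed bounding box.

## Proofreading

`split_components` relabels each 6-connected component of an ID beyond
the largest to fresh sibling IDs; the largest keeps the ID, with ties
broken by the smallest Morton code among each component's voxels (any
deterministic rule works; Morton order is cheap and stable).
`merge_volumes` combines two segmentations voxel-by-voxel: source
precedence overwrites nonzero target voxels, target precedence protects
them. Source IDs colliding with target IDs are shifted to the lowest
free IDs by default (or kept, or remapped explicitly); the map is
returned and written by the CLI. External automatic segmentations with
more than 24 bits of ID are truncated modulo 2²⁴ for display, with exact
nonzero multiples of 2²⁴ mapped to the sentinel 2²⁴−1 so no object
silently becomes background; distinct IDs can still collide after
truncation (rare spurious mergers, corrected like any merge error).

## Rendering and measurement

Segment meshes are blocky voxel-face meshes: two counter-clockwise
outward triangles per exposed face, scaled by the per-level voxel size
to nanometers, one OBJ group + material per segment. They are closed
(every directed edge balanced by its reverse) by construction; objects
with diagonal voxel contacts are closed but not 2-manifold along those
edges. Summed triangle area overestimates smooth anatomy — smoothing is
deliberately left to downstream tools, and the voxel-face area equals
the exposed-face closed form exactly (a 6×6×30 nm voxel: 792 nm²).
Isosurfaces use interpolated marching cubes on grayscale layers (on a
smooth radial field a sphere's area is recovered to well under 5%).
Particle clouds instance a prototype mesh at each 6-connected component
centroid (mean voxel center, +0.5 voxel convention). Projections along
cardinal axes support per-ray maximum, first-hit color, and first-hit
modulated by Lambertian shading of depth-gradient normals with ambient
0.2 and configurable light direction — a simple illumination model
chosen for its lack of parameters. Section compositing colors
segmentation pixels through the collapse rule, with per-pixel opacity
Alpha or SelAlpha depending on membership in the selected branch, and
patterns (16 fixed 8×8 bitmaps defined in the code) interpolating
between the two segment colors by pattern strength; image layers pass
through gain/offset filters and blend in normal, add or multiply mode.
Volume = voxel count × voxel volume; distances are Euclidean on
anisotropically scaled coordinates.

## Synthetic phantoms

`make_phantom` emulates the gross layout of an anisotropic EM stack:
neurite-like tubes (exponentially smoothed random-walk centerlines
dilated to a 3-voxel XY radius) and compact blobs, bright interiors
(gray 180) bounded by a one-voxel membrane (gray 40) on a mid-gray
background (120), with additive Gaussian noise (sd 10) clipped to
[0, 255], at a 6×6×30 nm voxel size and 48×48×24 voxel default extent
(small enough that dense oracles stay cheap). Objects are placed with at
least a one-voxel background gap — the membrane separation real
segmentation boundaries have. The phantom is reproducible bit-for-bit
from its seed. It does **not** emulate EM texture, staining artifacts,
section loss or alignment error, so passing tests demonstrate the
correctness of the operations, not robustness to real-image noise.

`make_boundary_map` marks voxels with a differing 6-neighbor at 255
(optionally blurred), leaving object interiors connected within the
low-value region — the input contract of range-masked painting.
`corrupt_segmentation` injects split errors (cut an object at a random
interior Z plane, both halves non-empty) and merge errors (relabel the
nearest other object to a chosen object's ID). Merge errors are
label-level: no bridging voxels are painted, matching how an automatic
segmentation confuses two membrane-separated objects, which is what
makes component splitting the correct repair. Bridged mergers — where
objects genuinely share voxels — require erasing the contact first, and
are exercised separately in the editing tests. Split products are
excluded from merging so each ledger entry can be repaired
independently; scripted repair (split the mergers, weld the splits)
restores the ground-truth partition exactly (Rand index 1.0).

## Numerical and interface choices

- Coordinates are 0-based `(x, y, z)` with half-open bounding boxes; in
  memory arrays are indexed `[x, y, z]`, transposed to row-major image
  order at the image I/O boundary. OBJ output is in nanometers,
  right-handed.
- Chunk compression is lossless deflate only; lossy codecs are out of
  scope because the container's primary cargo is IDs.
- The container byte layout is this package's own (magic `VCSEG001`,
  little-endian); compatibility with any external binary format is a
  non-goal.
- All randomness flows through seeded `numpy` generators; CLI seeds are
  flags. Problem sizes in the test-suite and acceptance script (volumes
  of ≤ 64³ voxels, 200 randomized edit scripts, 40×40×20 phantoms) were
  chosen so dense brute-force oracles remain exact companions to every
  operation.

## Known limitations

- One segmentation value per voxel per layer; overlapping labels need
  multiple layers.
- The authoritative-write rule is a design choice, not a reconstruction
  of any particular interactive tool's internals.
- No multi-user synchronization, provenance tracking, skeletons, mesh
  decimation/smoothing, or interactive rendering; the library surface
  plus the CLI is the interface, and view-dependent prefetching is out
  of scope.
- `weld` and `delete_subtree` relabel at level 0 and re-reduce; on
  volumes painted only at coarse levels this materializes level-0 data
  over the affected bounding boxes.
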