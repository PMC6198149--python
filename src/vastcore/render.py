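"""Offline rendering, mesh export and measurement.

Segment surfaces are exported as blocky voxel-face meshes: one quad per
exposed face between a segment voxel and a non-segment voxel, scaled by
the (anisotropic) voxel size to nanometers.  Summing triangle areas of
such a mesh overestimates the true anatomical surface (voxel roughness);
smoothing is deliberately left to downstream 3D packages.  Isosurfaces
of image layers use interpolated marching cubes instead.  Projection
images along the cardinal axes support maximum-intensity, first-hit and
Lambert-illuminated modes, and 2D section compositing reproduces the
layer/opacity/pattern display semantics of the interactive tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .segments import SegmentTable
from .volume import ChunkedVolume

__all__ = [
    "TriangleMesh",
    "LayerView",
    "segment_mesh",
    "isosurface_mesh",
    "particle_cloud",
    "box_mesh",
    "scalebar_mesh",
    "projection_image",
    "composite_section",
    "measure",
    "point_distance",
    "PATTERNS",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# triangle meshes + OBJ writing
# ---------------------------------------------------------------------------

@dataclass
class MeshGroup:
    name: str
    color: tuple[int, int, int]
    face_start: int
    face_count: int


@dataclass
class TriangleMesh:
    """Vertex/triangle soup in nanometer coordinates with object groups."""

    vertices: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    faces: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    groups: list[MeshGroup] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def surface_area(self) -> float:
        return float(self.triangle_areas().sum())

    def edge_incidence(self) -> dict[tuple[int, int], int]:
        """Count of faces incident on each undirected edge."""
        counts: dict[tuple[int, int], int] = {}
        for tri in self.faces:
            for i in range(3):
                e = (int(tri[i]), int(tri[(i + 1) % 3]))
                e = (min(e), max(e))
                counts[e] = counts.get(e, 0) + 1
        return counts

    def _directed_edges(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for tri in self.faces:
            for i in range(3):
                e = (int(tri[i]), int(tri[(i + 1) % 3]))
                counts[e] = counts.get(e, 0) + 1
        return counts

    def is_closed(self) -> bool:
        """True when the surface has no boundary.

        Every directed edge is balanced by its reverse, so the mesh
        encloses a volume.  Voxel-face meshes of objects with diagonal
        voxel contacts are closed but not 2-manifold along those edges
        (incidence 4 instead of 2); see :meth:`is_manifold`.
        """
        if self.is_empty:
            return False
        d = self._directed_edges()
        return all(d.get((b, a), 0) == c for (a, b), c in d.items())

    def is_manifold(self) -> bool:
        """True when every edge is shared by exactly two triangles."""
        if self.is_empty:
            return False
        return all(c == 2 for c in self.edge_incidence().values())

    def merged_with(self, other: "TriangleMesh") -> "TriangleMesh":
        off = len(self.vertices)
        foff = len(self.faces)
        groups = list(self.groups) + [
            MeshGroup(g.name, g.color, g.face_start + foff, g.face_count)
            for g in other.groups
        ]
        return TriangleMesh(
            vertices=np.vstack([self.vertices, other.vertices]),
            faces=np.vstack([self.faces, other.faces + off]),
            groups=groups,
        )

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, dtype=float),
                            self.faces.copy(), list(self.groups))

    # -- OBJ/MTL ------------------------------------------------------------

    def write_obj(self, path) -> None:
        """Write Wavefront OBJ (nm units) with a material per group."""
        path = Path(path)
        mtl_path = path.with_suffix(".mtl")
        with open(path, "w") as f:
            f.write(f"mtllib {mtl_path.name}\n")
            for v in self.vertices:
                f.write(f"v {v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
            groups = self.groups or [MeshGroup("object", (200, 200, 200), 0, len(self.faces))]
            for g in groups:
                f.write(f"g {g.name}\nusemtl {g.name}\n")
                for tri in self.faces[g.face_start:g.face_start + g.face_count]:
                    f.write(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
        with open(mtl_path, "w") as f:
            for g in (self.groups or groups):
                r, gg, b = (c / 255.0 for c in g.color)
                f.write(f"newmtl {g.name}\nKd {r:.4f} {gg:.4f} {b:.4f}\n\n")


def _quads_to_mesh(corners: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(N, 4, 3) quad corners -> deduplicated vertices + 2N triangles."""
    if len(corners) == 0:
        return np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64)
    flat = corners.reshape(-1, 3)
    verts, inv = np.unique(flat, axis=0, return_inverse=True)
    quads = inv.reshape(-1, 4)
    faces = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
    # interleave so each quad's two triangles stay adjacent
    faces = np.empty((len(quads) * 2, 3), dtype=np.int64)
    faces[0::2] = quads[:, [0, 1, 2]]
    faces[1::2] = quads[:, [0, 2, 3]]
    return verts.astype(float), faces


# quad corner offsets per face direction, ordered counter-clockwise when
# seen from outside (normals point away from the voxel)
_FACE_TEMPLATES = {
    (-1, 0, 0): [(0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)],
    (1, 0, 0): [(1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)],
    (0, -1, 0): [(0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)],
    (0, 1, 0): [(0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0)],
    (0, 0, -1): [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)],
    (0, 0, 1): [(0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],
}


def _voxel_face_quads(mask: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Quad corners (nm) for every exposed face of a boolean voxel mask."""
    padded = np.pad(mask, 1)
    quads = []
    for (dx, dy, dz), template in _FACE_TEMPLATES.items():
        neighbor = padded[
            1 + dx: 1 + dx + mask.shape[0],
            1 + dy: 1 + dy + mask.shape[1],
            1 + dz: 1 + dz + mask.shape[2],
        ]
        exposed = mask & ~neighbor
        coords = np.argwhere(exposed)
        if len(coords) == 0:
            continue
        t = np.asarray(template, dtype=float)  # (4, 3)
        quads.append((coords[:, None, :] + t[None, :, :]) * scale)
    if not quads:
        return np.zeros((0, 4, 3))
    return np.concatenate(quads, axis=0)


def segment_mesh(
    seg_vol: ChunkedVolume,
    ids: Sequence[int],
    level: int = 0,
    table: Optional[SegmentTable] = None,
) -> TriangleMesh:
    """Voxel-face surface mesh of one or more segments, one group per ID.

    Vertices are in nanometers (voxel index x voxel size at the chosen
    level); each mesh of a finite object is closed by construction.
    """
    arr = seg_vol.read_full(level)
    sx, sy, sz = seg_vol.voxel_size_nm
    scale = np.array([sx * 2 ** level, sy * 2 ** level, sz])
    mesh = TriangleMesh()
    for sid in ids:
        m = arr == sid
        if not m.any():
            warnings.warn(f"segment {sid} has no voxels at level {level}; empty group")
            continue
        verts, faces = _quads_to_mesh(_voxel_face_quads(m, scale))
        color = (200, 200, 200)
        if table is not None and sid in table:
            color = table.resolve_display_color(sid)[0]
        part = TriangleMesh(verts, faces, [MeshGroup(f"segment_{sid}", color, 0, len(faces))])
        mesh = mesh.merged_with(part)
    return mesh


def isosurface_mesh(
    image_vol: ChunkedVolume, threshold: float, level: int = 0
) -> TriangleMesh:
    """Marching-cubes isosurface of a grayscale layer, scaled to nm."""
    if image_vol.value_kind != "gray8":
        raise ValueError("isosurfaces are defined on grayscale image layers")
    from skimage import measure as sk_measure

    arr = image_vol.read_full(level).astype(np.float32)
    if not (arr.min() < threshold < arr.max()):
        return TriangleMesh()
    sx, sy, sz = image_vol.voxel_size_nm
    verts, faces, _, _ = sk_measure.marching_cubes(
        arr, level=threshold, spacing=(sx * 2 ** level, sy * 2 ** level, sz)
    )
    return TriangleMesh(
        verts.astype(float), faces.astype(np.int64),
        [MeshGroup("isosurface", (220, 220, 220), 0, len(faces))],
    )


def particle_cloud(
    seg_vol: ChunkedVolume,
    seg_id: int,
    prototype: TriangleMesh,
    level: int = 0,
) -> tuple[TriangleMesh, list[tuple[float, float, float]]]:
    """Instance a prototype mesh at the centroid of every painted region.

    Regions are 6-connected components of the ID; centroids are mean
    voxel centers in nm.  Returns (compound mesh, centroid list); the
    component count is ``len(centroids)``.
    """
    arr = seg_vol.read_full(level)
    labels, n = ndimage.label(arr == seg_id, structure=_STRUCT6)
    sx, sy, sz = seg_vol.voxel_size_nm
    scale = np.array([sx * 2 ** level, sy * 2 ** level, sz])
    centroids = []
    mesh = TriangleMesh()
    for comp in range(1, n + 1):
        coords = np.argwhere(labels == comp)
        centroid = tuple(((coords + 0.5).mean(axis=0) * scale).tolist())
        centroids.append(centroid)
        inst = prototype.translated(centroid)
        inst.groups = [
            MeshGroup(f"{g.name}_{comp}", g.color, g.face_start, g.face_count)
            for g in inst.groups
        ]
        mesh = mesh.merged_with(inst)
    return mesh, centroids


def _cuboid_quads(lo, hi) -> np.ndarray:
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    size = hi - lo
    quads = []
    for direction, template in _FACE_TEMPLATES.items():
        t = np.asarray(template, dtype=float) * size + lo
        quads.append(t[None, :, :])
    return np.concatenate(quads, axis=0)


def box_mesh(
    bbox_nm,
    mode: str = "solid",
    color: tuple[int, int, int] = (255, 255, 255),
    wire_thickness_nm: float = 10.0,
    texture_vol: ChunkedVolume | None = None,
    bbox_vx=None,
    level: int = 0,
) -> tuple[TriangleMesh, dict[str, np.ndarray]]:
    """Cuboid mesh for a box in nm: solid, wireframe, or textured.

    ``textured`` samples the six boundary sections of ``bbox_vx`` from
    ``texture_vol`` and returns them as face-keyed images alongside the
    solid mesh.  Wireframe mode builds the 12 edges as thin cuboids.
    """
    x0, y0, z0, x1, y1, z1 = (float(v) for v in bbox_nm)
    if not (x0 < x1 and y0 < y1 and z0 < z1):
        raise ValueError(f"degenerate box: {bbox_nm}")
    textures: dict[str, np.ndarray] = {}
    if mode == "solid":
        verts, faces = _quads_to_mesh(_cuboid_quads((x0, y0, z0), (x1, y1, z1)))
        mesh = TriangleMesh(verts, faces, [MeshGroup("box", color, 0, len(faces))])
    elif mode == "wireframe":
        t = wire_thickness_nm
        edges = []
        xs, ys, zs = (x0, x1), (y0, y1), (z0, z1)
        mesh = TriangleMesh()
        # 4 edges along each axis
        for y in ys:
            for z in zs:
                edges.append(((x0, y - t / 2, z - t / 2), (x1, y + t / 2, z + t / 2)))
        for x in xs:
            for z in zs:
                edges.append(((x - t / 2, y0, z - t / 2), (x + t / 2, y1, z + t / 2)))
        for x in xs:
            for y in ys:
                edges.append(((x - t / 2, y - t / 2, z0), (x + t / 2, y + t / 2, z1)))
        for i, (lo, hi) in enumerate(edges):
            verts, faces = _quads_to_mesh(_cuboid_quads(lo, hi))
            mesh = mesh.merged_with(
                TriangleMesh(verts, faces, [MeshGroup(f"edge_{i}", color, 0, len(faces))])
            )
    elif mode == "textured":
        if texture_vol is None or bbox_vx is None:
            raise ValueError("textured mode needs texture_vol and bbox_vx")
        vx0, vy0, vz0, vx1, vy1, vz1 = (int(v) for v in bbox_vx)
        ex, ey, ez = texture_vol.level_extent(level)
        if not (0 <= vx0 < vx1 <= ex and 0 <= vy0 < vy1 <= ey and 0 <= vz0 < vz1 <= ez):
            raise ValueError("textured box must lie within the volume")
        block = texture_vol.read_region(level, (vx0, vy0, vz0, vx1, vy1, vz1))
        textures = {
            "z0": np.array(block[:, :, 0]),
            "z1": np.array(block[:, :, -1]),
            "y0": np.array(block[:, 0, :]),
            "y1": np.array(block[:, -1, :]),
            "x0": np.array(block[0, :, :]),
            "x1": np.array(block[-1, :, :]),
        }
        verts, faces = _quads_to_mesh(_cuboid_quads((x0, y0, z0), (x1, y1, z1)))
        mesh = TriangleMesh(verts, faces, [MeshGroup("box", color, 0, len(faces))])
    else:
        raise ValueError(f"unknown box mode {mode!r}")
    return mesh, textures


def scalebar_mesh(
    length_nm: float,
    thickness_nm: float = 50.0,
    origin_nm=(0.0, 0.0, 0.0),
    axis: int = 0,
    color: tuple[int, int, int] = (255, 255, 255),
) -> TriangleMesh:
    """Cuboid scale bar of exactly the requested length along an axis."""
    lo = np.asarray(origin_nm, dtype=float)
    hi = lo + thickness_nm
    hi[axis] = lo[axis] + float(length_nm)
    verts, faces = _quads_to_mesh(_cuboid_quads(lo, hi))
    return TriangleMesh(verts, faces, [MeshGroup("scalebar", color, 0, len(faces))])


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def _as_rgb(block: np.ndarray, vol: ChunkedVolume,
            table: Optional[SegmentTable]) -> np.ndarray:
    """Voxel block -> float RGB in [0, 255] (IDs via display colors)."""
    if vol.value_kind == "rgb24":
        return block.astype(np.float64)
    if vol.value_kind == "gray8":
        return np.repeat(block[..., None].astype(np.float64), 3, axis=-1)
    # id16: map through the display-color table
    lut = np.zeros((65536, 3))
    ids = np.unique(block)
    for sid in ids[ids != 0]:
        sid = int(sid)
        if table is not None and sid in table:
            lut[sid] = table.resolve_display_color(sid)[0]
        else:  # stable fallback color from the id
            rng = np.random.default_rng(sid)
            lut[sid] = rng.integers(64, 256, 3)
    return lut[block]


def projection_image(
    vol: ChunkedVolume,
    axis: str = "Z",
    method: str = "max",
    bbox=None,
    level: int = 0,
    table: Optional[SegmentTable] = None,
    light_dir=(1.0, 1.0, 1.0),
    ambient: float = 0.2,
) -> np.ndarray:
    """Project a volume along a cardinal axis into an RGB image.

    ``max`` takes the per-ray maximum; ``first-hit`` the color of the
    first nonzero voxel along the ray; ``illuminated`` modulates the
    first hit by Lambert shading of the depth-map gradient normal.
    """
    axis = axis.upper()
    if axis not in "XYZ":
        raise ValueError(f"axis must be X, Y or Z: {axis}")
    ax = "XYZ".index(axis)
    ex, ey, ez = vol.level_extent(level)
    bbox = tuple(bbox) if bbox is not None else (0, 0, 0, ex, ey, ez)
    block = vol.read_region(level, bbox)
    rgb = _as_rgb(block, vol, table)
    occupied = block.any(axis=-1) if block.ndim == 4 else block != 0
    if method == "max":
        img = rgb.max(axis=ax)
    elif method in ("first-hit", "illuminated"):
        n = block.shape[ax]
        depth_idx = np.argmax(np.moveaxis(occupied, ax, 0), axis=0)
        any_hit = np.moveaxis(occupied, ax, 0).any(axis=0)
        first = np.take_along_axis(
            np.moveaxis(rgb, ax, 0), depth_idx[None, ..., None], axis=0
        )[0]
        img = np.where(any_hit[..., None], first, 0.0)
        if method == "illuminated":
            sxyz = np.array(vol.voxel_size_nm) * [2 ** level, 2 ** level, 1]
            depth = np.where(any_hit, depth_idx, n).astype(np.float64) * sxyz[ax]
            uv_axes = [i for i in range(3) if i != ax]
            gu, gv = np.gradient(depth, sxyz[uv_axes[0]], sxyz[uv_axes[1]])
            # surface normal in the (u, v, toward-viewer) frame
            normal = np.stack([-gu, -gv, np.ones_like(gu)], axis=-1)
            normal /= np.linalg.norm(normal, axis=-1, keepdims=True)
            light = np.asarray(light_dir, dtype=float)[:3]
            light = light / np.linalg.norm(light)
            lam = np.clip((normal * light).sum(axis=-1), 0.0, 1.0)
            shade = ambient + (1.0 - ambient) * lam
            img = img * np.where(any_hit, shade, 0.0)[..., None]
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# 2D compositing
# ---------------------------------------------------------------------------

def _make_patterns() -> np.ndarray:
    """16 fixed 8x8 binary pattern bitmaps (pattern 0 is solid color1)."""
    i, j = np.mgrid[0:8, 0:8]
    pats = [
        np.zeros((8, 8), bool),             # 0 solid
        (i + j) % 2 == 0,                   # 1 fine checker
        (i // 2 + j // 2) % 2 == 0,         # 2 coarse checker
        i % 2 == 0,                         # 3 horizontal stripes
        j % 2 == 0,                         # 4 vertical stripes
        (i + j) % 4 == 0,                   # 5 sparse diagonal
        (i - j) % 4 == 0,                   # 6 anti-diagonal
        (i % 4 == 0) & (j % 4 == 0),        # 7 sparse dots
        (i % 4 < 2) & (j % 4 < 2),          # 8 dot blocks
        (i % 4 == 2) | (j % 4 == 2),        # 9 grid
        i % 4 < 2,                          # 10 wide horizontal
        j % 4 < 2,                          # 11 wide vertical
        ((i + j) % 8) < 4,                  # 12 wide diagonal
        ((i - j) % 8) < 4,                  # 13 wide anti-diagonal
        ((i - 3.5) ** 2 + (j - 3.5) ** 2) < 6,  # 14 dot
        ((i - 3.5) ** 2 + (j - 3.5) ** 2) >= 6,  # 15 ring/inverse dot
    ]
    return np.stack(pats, axis=0)


PATTERNS = _make_patterns()


@dataclass
class LayerView:
    """Display settings of one layer in a composite.

    ``alpha`` applies to unselected segments (or the whole image layer);
    ``sel_alpha`` to segments inside the selected branch when
    ``selected_id`` is set.  Image layers pass through a per-channel
    ``gain`` and additive ``offset`` before blending.
    """

    volume: ChunkedVolume
    table: Optional[SegmentTable] = None
    alpha: float = 1.0
    sel_alpha: Optional[float] = None
    selected_id: Optional[int] = None
    pattern_strength: float = 0.0
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    blend_mode: str = "normal"

    def __post_init__(self):
        self.alpha = float(np.clip(self.alpha, 0.0, 1.0))
        if self.sel_alpha is not None:
            self.sel_alpha = float(np.clip(self.sel_alpha, 0.0, 1.0))
        self.pattern_strength = float(np.clip(self.pattern_strength, 0.0, 1.0))
        if self.blend_mode not in ("normal", "add", "multiply"):
            raise ValueError(f"unknown blend mode {self.blend_mode!r}")


def _seg_layer_rgba(view: LayerView, z: int, bbox, level: int):
    vol = view.volume
    block = vol.read_region(level, (bbox[0], bbox[1], z, bbox[2], bbox[3], z + 1))[:, :, 0]
    rgb = np.zeros(block.shape + (3,))
    alpha = np.zeros(block.shape)
    table = view.table or SegmentTable()
    xs, ys = np.mgrid[bbox[0]:bbox[2], bbox[1]:bbox[3]]
    pat_idx = (xs % 8, ys % 8)
    for sid in np.unique(block):
        sid = int(sid)
        if sid == 0:
            continue
        m = block == sid
        if sid in table:
            c1, c2, pat = table.resolve_display_color(sid)
        else:
            rng = np.random.default_rng(sid)
            c1 = tuple(int(v) for v in rng.integers(64, 256, 3))
            c2, pat = c1, 0
        on = PATTERNS[pat][pat_idx]  # pattern bitmap tiled over the section
        t = view.pattern_strength * on
        color = (1 - t[..., None]) * np.asarray(c1, float) + t[..., None] * np.asarray(c2, float)
        rgb[m] = color[m]
        a = view.alpha
        if view.selected_id is not None and view.sel_alpha is not None:
            if sid in table and table.in_branch(sid, view.selected_id):
                a = view.sel_alpha
        alpha[m] = a
    return rgb, alpha


def _img_layer_rgba(view: LayerView, z: int, bbox, level: int):
    vol = view.volume
    block = vol.read_region(level, (bbox[0], bbox[1], z, bbox[2], bbox[3], z + 1))[:, :, 0]
    if vol.value_kind == "gray8":
        rgb = np.repeat(block[..., None].astype(np.float64), 3, axis=-1)
    else:
        rgb = block.astype(np.float64)
    rgb = rgb * np.asarray(view.gain) + np.asarray(view.offset)
    rgb = np.clip(rgb, 0, 255)
    alpha = np.full(rgb.shape[:2], view.alpha)
    return rgb, alpha


def composite_section(
    layers: Sequence[LayerView],
    z: int,
    bbox=None,
    level: int = 0,
) -> np.ndarray:
    """Composite one section of several layers bottom-to-top into RGB.

    Segmentation pixels are colored through the collapse-aware display
    color, with per-pixel opacity Alpha or SelAlpha depending on branch
    selection; patterns interpolate between the segment's two colors.
    """
    if not layers:
        raise ValueError("need at least one layer")
    geoms = {(lv.volume.level_extent(level)) for lv in layers}
    if len(geoms) > 1:
        raise ValueError(f"layers disagree on geometry at level {level}: {geoms}")
    ex, ey, _ = layers[0].volume.level_extent(level)
    bbox = tuple(bbox) if bbox is not None else (0, 0, ex, ey)
    out = np.zeros((bbox[2] - bbox[0], bbox[3] - bbox[1], 3))
    for view in layers:
        if view.volume.value_kind == "id16":
            rgb, alpha = _seg_layer_rgba(view, z, bbox, level)
        else:
            rgb, alpha = _img_layer_rgba(view, z, bbox, level)
        a = alpha[..., None]
        if view.blend_mode == "normal":
            out = a * rgb + (1 - a) * out
        elif view.blend_mode == "add":
            out = out + a * rgb
        else:  # multiply
            out = (1 - a) * out + a * out * (rgb / 255.0)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def measure(seg_vol: ChunkedVolume, seg_id: int, level: int = 0) -> dict:
    """Voxel count, volume (nm^3), mesh surface area (nm^2) and bbox.

    The surface area sums the triangle areas of the voxel-face mesh and
    therefore overestimates smooth anatomical surfaces.
    """
    arr = seg_vol.read_full(level)
    mask = arr == seg_id
    count = int(mask.sum())
    sx, sy, sz = seg_vol.voxel_size_nm
    voxel_vol = (sx * 2 ** level) * (sy * 2 ** level) * sz
    result = {
        "voxel_count": count,
        "volume_nm3": count * voxel_vol,
        "surface_area_nm2": 0.0,
        "bbox": None,
    }
    if count:
        coords = np.argwhere(mask)
        lo, hi = coords.min(axis=0), coords.max(axis=0) + 1
        result["bbox"] = tuple(int(v) for v in lo) + tuple(int(v) for v in hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result["surface_area_nm2"] = segment_mesh(seg_vol, [seg_id], level).surface_area()
    return result


def point_distance(p1, p2, voxel_size_nm) -> float:
    """Euclidean distance in nm between two voxel coordinates."""
    s = np.asarray(voxel_size_nm, dtype=float)
    d = (np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)) * s
    return float(np.linalg.norm(d))
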