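"""Paint engine: pen/target/source masks, strokes, Z-gap fill, flood fill."""

import numpy as np
import pytest

from vastcore import (
    ChunkedVolume,
    MaskSpec,
    PenStroke,
    SegmentTable,
    apply_stroke,
    flood_fill,
    make_pen_mask,
    pick,
    source_mask,
    target_mask,
    zgap_fill,
)
from conftest import make_id_volume


def gray_volume(arr):
    vol = ChunkedVolume(arr.shape, value_kind="gray8")
    vol.write_full(arr.astype(np.uint8), 0)
    return vol


def brute_disk_union(centers, z, diameter):
    """Independent pen-mask oracle: enumerate distances to the polyline."""
    out = set()
    r = diameter / 2.0
    pts = centers if len(centers) > 1 else centers * 2
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        steps = max(abs(x1 - x0), abs(y1 - y0), 1)
        for t in range(steps + 1):
            cx = round(x0 + (x1 - x0) * t / steps)
            cy = round(y0 + (y1 - y0) * t / steps)
            for dx in range(-diameter, diameter + 1):
                for dy in range(-diameter, diameter + 1):
                    if dx * dx + dy * dy <= r * r + 1e-9:
                        out.add((cx + dx, cy + dy, z))
    return out


class TestPenMask:
    def test_diameter_one_is_single_voxel(self):
        assert make_pen_mask(PenStroke(z=0, centers=[(5, 5)])) == {(5, 5, 0)}

    def test_diameter_three_covers_nine_voxels(self):
        # all offsets with Euclidean distance <= 1.5, corners included (sqrt2)
        mask = make_pen_mask(PenStroke(z=2, centers=[(4, 4)], diameter=3))
        assert len(mask) == 9
        assert mask == brute_disk_union([(4, 4)], 2, 3)

    def test_two_adjacent_centers_two_voxels(self):
        mask = make_pen_mask(PenStroke(z=0, centers=[(1, 1), (2, 1)]))
        assert mask == {(1, 1, 0), (2, 1, 0)}

    @pytest.mark.parametrize("seed", range(4))
    def test_polyline_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        centers = [tuple(int(v) for v in rng.integers(5, 25, 2)) for _ in range(4)]
        d = int(rng.integers(1, 6))
        stroke = PenStroke(z=1, centers=centers, diameter=d)
        assert make_pen_mask(stroke) == brute_disk_union(centers, 1, d)

    def test_section_clipping(self):
        mask = make_pen_mask(PenStroke(z=0, centers=[(0, 0)], diameter=5),
                             section_extent=(4, 4))
        assert all(0 <= x < 4 and 0 <= y < 4 for x, y, _ in mask)


class TestTargetMask:
    def test_background_only_selects_zero_voxels(self):
        arr = np.zeros((8, 8, 1), np.uint16)
        arr[0:4] = 3
        vol = make_id_volume(arr)
        foot = {(x, y, 0) for x in range(8) for y in range(8)}
        got = target_mask(vol, "background_only", 5, None, foot)
        assert got == {(x, y, 0) for x in range(4, 8) for y in range(8)}

    def test_parent_only_selects_parent_voxels(self):
        arr = np.zeros((8, 8, 1), np.uint16)
        arr[2:6, 2:6, 0] = 4
        vol = make_id_volume(arr)
        table = SegmentTable()
        table.add(id=4, label="parent")
        table.add(id=9, parent_id=4, label="child")
        foot = {(x, y, 0) for x in range(8) for y in range(8)}
        got = target_mask(vol, "parent_only", 9, table, foot)
        assert got == {(x, y, 0) for x in range(2, 6) for y in range(2, 6)}

    def test_paint_all_is_identity(self):
        vol = make_id_volume(np.zeros((4, 4, 1), np.uint16))
        foot = {(1, 1, 0), (2, 2, 0)}
        assert target_mask(vol, "paint_all", 1, None, foot) == foot

    def test_parent_only_without_parent_rejected(self):
        vol = make_id_volume(np.zeros((4, 4, 1), np.uint16))
        table = SegmentTable()
        table.add(id=9)
        with pytest.raises(ValueError, match="parent"):
            target_mask(vol, "parent_only", 9, table, {(0, 0, 0)})


def two_room_map():
    """Boundary map: two low-value rooms separated by a high wall."""
    arr = np.full((11, 7, 1), 10, np.uint8)
    arr[:, 0, 0] = arr[:, -1, 0] = 200
    arr[0, :, 0] = arr[-1, :, 0] = 200
    arr[5, :, 0] = 200  # dividing wall
    return gray_volume(arr)


class TestSourceMask:
    def test_range_mask_limits_to_seeded_room(self):
        src = two_room_map()
        spec = MaskSpec(source_mode="value_range", value_range=(0, 127))
        foot = {(x, y, 0) for x in range(11) for y in range(7)}
        got = source_mask(src, spec, (2, 3, 0), foot)
        assert got == {(x, y, 0) for x in range(1, 5) for y in range(1, 6)}

    def test_picked_value_selects_connected_id_region(self):
        arr = np.zeros((10, 10, 1), np.uint16)
        arr[0:3, 0:3, 0] = 9
        arr[7:9, 7:9, 0] = 9  # disconnected, same value
        src = make_id_volume(arr)
        spec = MaskSpec(source_mode="picked_value")
        foot = {(x, y, 0) for x in range(10) for y in range(10)}
        got = source_mask(src, spec, (1, 1, 0), foot)
        assert got == {(x, y, 0) for x in range(3) for y in range(3)}

    def test_seed_outside_range_rejected(self):
        src = two_room_map()
        spec = MaskSpec(source_mode="value_range", value_range=(0, 127))
        with pytest.raises(ValueError, match="seed"):
            source_mask(src, spec, (0, 0, 0), set())

    @pytest.mark.parametrize("seed", range(4))
    def test_random_maze_matches_flood_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = np.where(rng.random((16, 16, 1)) < 0.4, 200, 10).astype(np.uint8)
        arr[8, 8, 0] = 10
        src = gray_volume(arr)
        spec = MaskSpec(source_mode="value_range", value_range=(0, 127))
        foot = {(x, y, 0) for x in range(16) for y in range(16)}
        got = source_mask(src, spec, (8, 8, 0), foot)
        # brute-force 4-connected flood over the thresholded section
        ok = arr[:, :, 0] <= 127
        seen = {(8, 8)}
        frontier = [(8, 8)]
        while frontier:
            x, y = frontier.pop()
            for nx, ny in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
                if 0 <= nx < 16 and 0 <= ny < 16 and ok[nx, ny] and (nx, ny) not in seen:
                    seen.add((nx, ny))
                    frontier.append((nx, ny))
        assert got == {(x, y, 0) for x, y in seen}


class TestApplyStroke:
    def test_stroke_outside_source_mask_paints_nothing(self):
        seg = make_id_volume(np.zeros((11, 7, 1), np.uint16))
        src = two_room_map()
        spec = MaskSpec(source_mode="value_range", value_range=(0, 127))
        stroke = PenStroke(z=0, centers=[(2, 3)], diameter=1, paint_id=5)
        # stroke inside room one, but footprint pushed into the wall:
        wall_stroke = PenStroke(z=0, centers=[(5, 3)], diameter=1, paint_id=5)
        with pytest.raises(ValueError):
            apply_stroke(seg, wall_stroke, spec, source_vol=src)
        assert not seg.read_full(0).any()

    def test_closed_contour_auto_fills_interior(self):
        import math

        seg = make_id_volume(np.zeros((32, 32, 2), np.uint16))
        centers = [
            (int(round(16 + 8 * math.cos(a))), int(round(16 + 8 * math.sin(a))))
            for a in np.linspace(0, 2 * np.pi, 80)
        ]
        stroke = PenStroke(z=0, centers=centers, diameter=3, paint_id=2)
        apply_stroke(seg, stroke, MaskSpec(auto_close=True))
        assert seg.effective_value(0, 16, 16, 0) == 2  # interior filled

    def test_painted_set_is_three_mask_intersection(self):
        rng = np.random.default_rng(3)
        arr = rng.choice([0, 4], size=(16, 16, 1), p=[0.5, 0.5]).astype(np.uint16)
        seg = make_id_volume(arr)
        srcarr = np.where(rng.random((16, 16, 1)) < 0.5, 10, 200).astype(np.uint8)
        seed = (8, 8)
        srcarr[seed[0], seed[1], 0] = 10
        src = gray_volume(srcarr)
        spec = MaskSpec(target_mode="background_only", source_mode="value_range",
                        value_range=(0, 127))
        stroke = PenStroke(z=0, centers=[seed], diameter=9, paint_id=7)
        written = apply_stroke(seg, stroke, spec, source_vol=src)
        pen = make_pen_mask(stroke, (16, 16))
        tgt = {c for c in pen if arr[c[0], c[1], 0] == 0}
        srcm = source_mask(src, spec, seed + (0,), pen)
        assert written == (pen & tgt & srcm)
        out = seg.read_full(0)
        for c in written:
            assert out[c[0], c[1], 0] == 7
        # background_only: pre-existing voxels untouched
        assert ((out == 4) == (arr == 4)).all()

    def test_erase_then_repaint_is_identity(self):
        arr = np.zeros((16, 16, 1), np.uint16)
        arr[4:10, 4:10, 0] = 3
        seg = make_id_volume(arr)
        stroke_e = PenStroke(z=0, centers=[(6, 6)], diameter=5, paint_id=0)
        erased = apply_stroke(seg, stroke_e, MaskSpec())
        stroke_p = PenStroke(z=0, centers=[(6, 6)], diameter=5, paint_id=3)
        apply_stroke(seg, stroke_p, MaskSpec())
        np.testing.assert_array_equal(seg.read_full(0), arr)
        assert erased  # the erase did remove voxels


class TestZGapFill:
    def _painted_disk(self, seg, z, paint_id=3, diameter=5):
        from vastcore.editing import _write_coords

        disk = make_pen_mask(PenStroke(z=z, centers=[(8, 8)], diameter=diameter,
                                       paint_id=paint_id))
        _write_coords(seg, disk, paint_id, 0)
        return disk

    def test_depth_eight_fills_seven_skipped_sections(self):
        seg = make_id_volume(np.zeros((16, 16, 12), np.uint16))
        self._painted_disk(seg, 0)
        top = self._painted_disk(seg, 8)
        filled = zgap_fill(seg, top, 3, 8)
        zs = {z for _, _, z in filled}
        assert zs == set(range(1, 8))
        arr = seg.read_full(0)
        for z in range(1, 8):
            np.testing.assert_array_equal(arr[:, :, z], arr[:, :, 0])

    def test_gap_beyond_depth_not_filled(self):
        seg = make_id_volume(np.zeros((16, 16, 12), np.uint16))
        self._painted_disk(seg, 0)
        top = self._painted_disk(seg, 9)
        assert zgap_fill(seg, top, 3, 8) == set()

    def test_monotone_in_depth(self):
        rng = np.random.default_rng(6)
        base = (rng.random((6, 6, 14)) < 0.25).astype(np.uint16) * 3
        fills = []
        for depth in (2, 4, 8):
            seg = make_id_volume(base.copy())
            painted = {tuple(c) for c in np.argwhere(base == 3)}
            fills.append(zgap_fill(seg, painted, 3, depth))
        assert fills[0] <= fills[1] <= fills[2]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_column_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = (rng.random((5, 5, 16)) < 0.3).astype(np.uint16) * 7
        depth = 4
        seg = make_id_volume(base.copy())
        painted = {tuple(map(int, c)) for c in np.argwhere(base == 7)}
        filled = zgap_fill(seg, painted, 7, depth)
        # oracle: per XY column, fill gaps of length < depth between 7s
        want = set()
        for x in range(5):
            for y in range(5):
                zs = [z for z in range(16) if base[x, y, z] == 7]
                for a, b in zip(zs, zs[1:]):
                    if 2 <= b - a <= depth:
                        want |= {(x, y, z) for z in range(a + 1, b)}
        assert filled == want
        out = seg.read_full(0)
        assert {tuple(map(int, c)) for c in np.argwhere(out == 7)} == painted | want


class TestFloodFill:
    def test_only_seeded_component_recolored(self):
        arr = np.zeros((16, 16, 2), np.uint16)
        arr[0:3, 0:3, :] = 5
        arr[10:12, 10:12, :] = 5
        seg = make_id_volume(arr)
        n = flood_fill(seg, (1, 1, 0), 6, dimensionality="3D")
        out = seg.read_full(0)
        assert n == 18
        assert (out[0:3, 0:3, :] == 6).all()
        assert (out[10:12, 10:12, :] == 5).all()

    def test_boundary_map_fence_creates_one_region(self):
        src = two_room_map()
        seg = make_id_volume(np.zeros((11, 7, 1), np.uint16))
        spec = MaskSpec(source_mode="value_range", value_range=(0, 127))
        n = flood_fill(seg, (2, 3, 0), 1, spec, dimensionality="2D", source_vol=src)
        out = seg.read_full(0)
        assert n == (out == 1).sum() == 4 * 5  # room one only
        assert not out[6:, :, :].any()

    def test_diagonal_blobs_are_separate_in_6conn(self):
        arr = np.zeros((6, 6, 1), np.uint16)
        arr[1, 1, 0] = 5
        arr[2, 2, 0] = 5  # touches only diagonally
        seg = make_id_volume(arr)
        n = flood_fill(seg, (1, 1, 0), 6, dimensionality="3D")
        assert n == 1
        assert seg.effective_value(0, 2, 2, 0) == 5

    def test_masked_seed_warns_and_fills_nothing(self):
        arr = np.zeros((6, 6, 1), np.uint16)
        arr[1, 1, 0] = 5
        seg = make_id_volume(arr)
        spec = MaskSpec(target_mode="background_only")
        with pytest.warns(UserWarning, match="seed"):
            n = flood_fill(seg, (1, 1, 0), 6, spec)
        assert n == 0

    def test_picked_source_copy_reproduces_component_exactly(self):
        """Masked fill with a perfect source reproduces the source object."""
        rng = np.random.default_rng(8)
        src_arr = np.zeros((20, 20, 6), np.uint16)
        src_arr[3:9, 3:9, 1:5] = 11
        src_arr[12:17, 12:18, 0:3] = 13
        src = make_id_volume(src_arr)
        seg = make_id_volume(np.zeros((20, 20, 6), np.uint16))
        spec = MaskSpec(source_mode="picked_value")
        n = flood_fill(seg, (4, 4, 2), 1, spec, dimensionality="3D", source_vol=src)
        out = seg.read_full(0)
        np.testing.assert_array_equal(out == 1, src_arr == 11)
        assert n == int((src_arr == 11).sum())


class TestPick:
    def test_background_and_painted(self):
        arr = np.zeros((8, 8, 1), np.uint16)
        arr[2, 2, 0] = 9
        seg = make_id_volume(arr)
        assert pick(seg, (0, 0, 0)) == 0
        assert pick(seg, (2, 2, 0)) == 9

    def test_coarse_paint_inherited_at_level_zero(self):
        seg = ChunkedVolume((32, 32, 2), value_kind="id16", num_levels=2)
        seg.write_region(1, (4, 4, 0, 6, 6, 1), np.full((2, 2, 1), 5, np.uint16))
        assert pick(seg, (9, 9, 0), level=0) == 5
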