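"""Volume store: chunking, Z-order, mip pyramid, cross-level reads, cache."""

import numpy as np
import pytest

from vastcore import (
    CHUNK_EDGE,
    CacheState,
    ChunkedVolume,
    cache_evict,
    create_volume,
    zorder_decode,
    zorder_index,
)

# ---------------------------------------------------------------------------
# independent shadow-pyramid oracle (dense, per-voxel, no shared code paths)
# ---------------------------------------------------------------------------


class ShadowPyramid:
    """Dense reference model of the multi-level store.

    Keeps per-level explicit value and mask arrays and applies the
    authoritative-write rule with plain Python loops.
    """

    def __init__(self, dims, num_levels):
        self.dims = dims
        self.num_levels = num_levels
        self.vals = []
        self.mask = []
        for lev in range(num_levels):
            ex, ey, ez = self.extent(lev)
            self.vals.append(np.zeros((ex, ey, ez), dtype=np.int64))
            self.mask.append(np.zeros((ex, ey, ez), dtype=bool))

    def extent(self, lev):
        X, Y, Z = self.dims
        f = 2 ** lev
        return (-(-X // f), -(-Y // f), Z)

    def effective(self, lev, x, y, z):
        for l in range(lev, self.num_levels):
            f = 2 ** (l - lev)
            cx, cy = x // f, y // f
            if self.mask[l][cx, cy, z]:
                return self.vals[l][cx, cy, z]
        return 0

    def read(self, lev, bbox):
        x0, y0, z0, x1, y1, z1 = bbox
        out = np.zeros((x1 - x0, y1 - y0, z1 - z0), dtype=np.int64)
        for x in range(x0, x1):
            for y in range(y0, y1):
                for z in range(z0, z1):
                    out[x - x0, y - y0, z - z0] = self.effective(lev, x, y, z)
        return out

    @staticmethod
    def _majority(vals):
        best, best_count = None, -1
        for v in sorted(set(vals)):
            c = vals.count(v)
            if c > best_count:
                best, best_count = v, c
        return best

    def write(self, lev, bbox, values, kind="id16"):
        x0, y0, z0, x1, y1, z1 = bbox
        self.vals[lev][x0:x1, y0:y1, z0:z1] = values
        self.mask[lev][x0:x1, y0:y1, z0:z1] = True
        # clear all finer explicit data under the footprint
        for fl in range(lev):
            f = 2 ** (lev - fl)
            fex, fey, _ = self.extent(fl)
            self.mask[fl][x0 * f:min(x1 * f, fex), y0 * f:min(y1 * f, fey), z0:z1] = False
            self.vals[fl][x0 * f:min(x1 * f, fex), y0 * f:min(y1 * f, fey), z0:z1] = 0
        # re-reduce coarser levels bottom-up over the footprint
        fx0, fy0, fx1, fy1 = x0, y0, x1, y1
        for cl in range(lev + 1, self.num_levels):
            cex, cey, _ = self.extent(cl)
            cx0, cy0 = fx0 // 2, fy0 // 2
            cx1, cy1 = min(-(-fx1 // 2), cex), min(-(-fy1 // 2), cey)
            fex, fey, _ = self.extent(cl - 1)
            for cx in range(cx0, cx1):
                for cy in range(cy0, cy1):
                    for z in range(z0, z1):
                        children = [
                            self.effective(cl - 1, min(2 * cx + dx, fex - 1),
                                           min(2 * cy + dy, fey - 1), z)
                            for dx in (0, 1) for dy in (0, 1)
                        ]
                        if kind == "id16":
                            v = self._majority(children)
                        else:
                            v = (sum(children) + 2) // 4
                        self.vals[cl][cx, cy, z] = v
                        self.mask[cl][cx, cy, z] = True
            fx0, fy0, fx1, fy1 = cx0, cy0, cx1, cy1


def random_box(rng, extent, max_edge=10):
    x0 = int(rng.integers(0, extent[0]))
    y0 = int(rng.integers(0, extent[1]))
    z0 = int(rng.integers(0, extent[2]))
    x1 = int(rng.integers(x0 + 1, min(x0 + max_edge, extent[0]) + 1))
    y1 = int(rng.integers(y0 + 1, min(y0 + max_edge, extent[1]) + 1))
    z1 = int(rng.integers(z0 + 1, min(z0 + max_edge, extent[2]) + 1))
    return (x0, y0, z0, x1, y1, z1)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


class TestCreateVolume:
    def test_level_extents_halve_xy_only(self):
        vol = create_volume((32, 32, 4), value_kind="gray8", num_levels=2)
        assert vol.level_extent(1) == (16, 16, 4)

    def test_single_voxel_volume_reads_zero(self):
        vol = create_volume((1, 1, 1))
        assert vol.effective_value(0, 0, 0, 0) == 0

    def test_mip_chain_4096_to_256(self):
        vol = create_volume((4096, 4096, 8), value_kind="gray8", num_levels=5)
        edges = [vol.level_extent(lev)[0] for lev in range(5)]
        assert edges == [4096, 2048, 1024, 512, 256]

    @pytest.mark.parametrize(
        "dims,kind,levels",
        [((0, 4, 4), "gray8", 1), ((4, 4, 4), "float", 1), ((4, 4, 4), "gray8", 4)],
    )
    def test_invalid_construction_rejected(self, dims, kind, levels):
        with pytest.raises(ValueError):
            create_volume(dims, value_kind=kind, num_levels=levels)

    def test_empty_volume_allocates_no_chunks(self):
        vol = create_volume((64, 64, 64), value_kind="id16", num_levels=2)
        vol.read_full(0)
        assert len(vol.allocated_chunks) == 0


class TestZOrder:
    def test_low_bit_examples(self):
        assert zorder_index(0, 0, 0) == 0
        assert zorder_index(1, 0, 0) == 1
        assert zorder_index(0, 1, 0) == 2
        assert zorder_index(0, 0, 1) == 4

    def test_bijection_over_all_4096_triples(self):
        seen = {
            zorder_index(x, y, z)
            for x in range(CHUNK_EDGE)
            for y in range(CHUNK_EDGE)
            for z in range(CHUNK_EDGE)
        }
        assert seen == set(range(CHUNK_EDGE ** 3))

    def test_decode_inverts_encode(self):
        for idx in range(0, 4096, 37):
            assert zorder_index(*zorder_decode(idx)) == idx

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            zorder_index(16, 0, 0)


# ---------------------------------------------------------------------------
# reads/writes
# ---------------------------------------------------------------------------


class TestReadWrite:
    def test_round_trip_constant_block(self):
        vol = create_volume((32, 32, 4), value_kind="gray8", num_levels=1)
        block = np.full((8, 8, 2), 7, dtype=np.uint8)
        vol.write_region(0, (4, 4, 1, 12, 12, 3), block)
        assert (vol.read_region(0, (4, 4, 1, 12, 12, 3)) == 7).all()

    def test_aligned_chunk_write_allocates_one_chunk(self):
        vol = create_volume((64, 64, 16), value_kind="id16", num_levels=1)
        vol.write_region(0, (16, 16, 0, 32, 32, 16), np.ones((16, 16, 16), np.uint16))
        assert len(vol.allocated_chunks) == 1

    def test_id_range_limits(self):
        vol = create_volume((4, 4, 4), value_kind="id16")
        vol.write_region(0, (0, 0, 0, 1, 1, 1), np.array([[[65535]]]))
        with pytest.raises(ValueError):
            vol.write_region(0, (0, 0, 0, 1, 1, 1), np.array([[[65536]]]))

    def test_write_returns_changed_count(self):
        vol = create_volume((8, 8, 1), value_kind="id16")
        n = vol.write_region(0, (0, 0, 0, 4, 4, 1), np.ones((4, 4, 1), np.uint16))
        assert n == 16
        n = vol.write_region(0, (0, 0, 0, 4, 4, 1), np.ones((4, 4, 1), np.uint16))
        assert n == 0

    def test_coarse_write_replicates_to_fine(self):
        vol = create_volume((32, 32, 4), value_kind="id16", num_levels=2)
        vol.write_region(1, (2, 2, 0, 4, 4, 1), np.full((2, 2, 1), 9, np.uint16))
        fine = vol.read_region(0, (4, 4, 0, 8, 8, 1))
        assert (fine == 9).all()

    def test_fine_write_overrides_inherited_coarse(self):
        vol = create_volume((32, 32, 4), value_kind="id16", num_levels=2)
        vol.write_region(1, (0, 0, 0, 4, 4, 1), np.full((4, 4, 1), 9, np.uint16))
        vol.write_region(0, (0, 0, 0, 1, 1, 1), np.zeros((1, 1, 1), np.uint16))
        assert vol.effective_value(0, 0, 0, 0) == 0
        assert vol.effective_value(0, 1, 1, 0) == 9

    def test_bbox_outside_extent_rejected(self):
        vol = create_volume((8, 8, 2))
        with pytest.raises(ValueError):
            vol.read_region(0, (0, 0, 0, 9, 8, 2))
        with pytest.raises(ValueError):
            vol.read_region(1, (0, 0, 0, 1, 1, 1))

    def test_free_all_zero_chunk_leaves_reads_unchanged(self):
        vol = create_volume((32, 32, 4), value_kind="id16")
        vol.write_region(0, (0, 0, 0, 16, 16, 4), np.zeros((16, 16, 4), np.uint16))
        before = vol.read_full(0)
        vol.free_chunk(0, (0, 0, 0))
        assert np.array_equal(vol.read_full(0), before)


class TestReduction:
    def test_gray_mean_round_half_up(self):
        vol = create_volume((2, 2, 1), value_kind="gray8", num_levels=2)
        vol.write_region(0, (0, 0, 0, 2, 2, 1),
                         np.array([[[10], [20]], [[10], [20]]], np.uint8))
        assert vol.read_region(1, (0, 0, 0, 1, 1, 1))[0, 0, 0] == 15

    def test_label_majority(self):
        vol = create_volume((2, 2, 1), value_kind="id16", num_levels=2)
        vol.write_region(0, (0, 0, 0, 2, 2, 1),
                         np.array([[[5], [9]], [[5], [0]]], np.uint16))
        assert vol.read_region(1, (0, 0, 0, 1, 1, 1))[0, 0, 0] == 5

    def test_label_tie_takes_smallest_id(self):
        vol = create_volume((2, 2, 1), value_kind="id16", num_levels=2)
        vol.write_region(0, (0, 0, 0, 2, 2, 1),
                         np.array([[[3], [7]], [[7], [3]]], np.uint16))
        assert vol.read_region(1, (0, 0, 0, 1, 1, 1))[0, 0, 0] == 3

    def test_reduce_idempotent(self):
        vol = create_volume((16, 16, 2), value_kind="id16", num_levels=2)
        rng = np.random.default_rng(3)
        vol.write_full(rng.integers(0, 4, (16, 16, 2)).astype(np.uint16), 0)
        first = vol.reduce_to_coarser(0, (0, 0, 0, 16, 16, 2))
        second = vol.reduce_to_coarser(0, (0, 0, 0, 16, 16, 2))
        assert np.array_equal(first, second)

    def test_replication_of_reduction_is_identity_on_constant(self):
        vol = create_volume((8, 8, 1), value_kind="gray8", num_levels=2)
        vol.write_full(np.full((8, 8, 1), 42, np.uint8), 0)
        assert (vol.read_region(1, (0, 0, 0, 4, 4, 1)) == 42).all()
        assert (vol.read_full(0) == 42).all()


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_multilevel_scripts_match_shadow_model(self, seed):
        """Random mixed-level writes read back exactly like the dense model."""
        dims, levels = (20, 12, 6), 3
        rng = np.random.default_rng(seed)
        vol = ChunkedVolume(dims, value_kind="id16", num_levels=levels)
        shadow = ShadowPyramid(dims, levels)
        for _ in range(15):
            lev = int(rng.integers(0, levels))
            ext = vol.level_extent(lev)
            box = random_box(rng, ext, max_edge=6)
            vals = rng.integers(0, 5, (box[3] - box[0], box[4] - box[1], box[5] - box[2]))
            vol.write_region(lev, box, vals.astype(np.uint16))
            shadow.write(lev, box, vals)
        for lev in range(levels):
            ext = vol.level_extent(lev)
            full = (0, 0, 0) + ext
            got = vol.read_region(lev, full).astype(np.int64)
            want = shadow.read(lev, full)
            np.testing.assert_array_equal(got, want, err_msg=f"level {lev}")

    def test_sparsity_bound(self):
        rng = np.random.default_rng(11)
        vol = ChunkedVolume((64, 64, 64), value_kind="id16", num_levels=1)
        touched = np.zeros((64, 64, 64), dtype=bool)
        for _ in range(10):
            box = random_box(rng, (64, 64, 64), max_edge=12)
            vol.write_region(
                0, box,
                rng.integers(1, 9, (box[3] - box[0], box[4] - box[1], box[5] - box[2]))
                .astype(np.uint16),
            )
            touched[box[0]:box[3], box[1]:box[4], box[2]:box[5]] = True
        # each allocated chunk must contain at least one touched voxel
        for (lev, cx, cy, cz) in vol.allocated_chunks:
            sub = touched[cx * 16:(cx + 1) * 16, cy * 16:(cy + 1) * 16,
                          cz * 16:(cz + 1) * 16]
            assert sub.any()


# ---------------------------------------------------------------------------
# cache
# ---------------------------------------------------------------------------


class ReferenceLRU:
    """Brute-force simulation of the cache contract."""

    def __init__(self, capacity):
        self.capacity = capacity
        self.order = []  # LRU first
        self.modified = set()
        self.spilled = set()

    def touch(self, key, modify):
        if key in self.order:
            self.order.remove(key)
        elif key in self.spilled:
            self.spilled.discard(key)
        self.order.append(key)
        if modify:
            self.modified.add(key)
        while len(self.order) > self.capacity:
            clean = [k for k in self.order if k not in self.modified]
            victim = clean[0] if clean else self.order[0]
            self.order.remove(victim)
            self.spilled.add(victim)  # no fetcher: everything is spilled


class TestCache:
    def _put(self, state, key, modified=False):
        from vastcore.volume import Chunk

        state.put(key, Chunk(np.zeros((16, 16, 16), np.uint16),
                             np.zeros((16, 16, 16), bool)), modified=modified)

    def test_lru_evicts_oldest_clean(self, tmp_path):
        state = CacheState(2, str(tmp_path))
        for key in ("A", "B", "C"):
            self._put(state, key)
        assert "A" not in state.resident
        assert set(state.resident) == {"B", "C"}

    def test_modified_chunk_never_dropped(self, tmp_path):
        state = CacheState(2, str(tmp_path))
        self._put(state, "A", modified=True)
        self._put(state, "B")
        self._put(state, "C")
        assert "A" in state.resident  # B (clean LRU) went instead
        assert "B" not in state.resident and "B" in state.spilled

    def test_all_dirty_overflow_spills_not_drops(self, tmp_path):
        state = CacheState(2, str(tmp_path))
        for key in ("A", "B", "C"):
            self._put(state, key, modified=True)
        assert set(state.resident) | set(state.spilled) == {"A", "B", "C"}
        # spilled dirty chunk comes back intact
        assert state.get("A") is not None

    def test_cache_evict_frees_room(self, tmp_path):
        state = CacheState(4, str(tmp_path))
        for key in "ABCD":
            self._put(state, key)
        evicted = cache_evict(state, needed_chunks=2)
        assert len(state.resident) <= 2
        assert evicted

    @pytest.mark.parametrize("seed", range(5))
    def test_random_scripts_match_reference_lru(self, seed, tmp_path):
        """Touch/modify scripts: resident set reproducible, no dirty loss."""
        rng = np.random.default_rng(seed)
        cap = int(rng.integers(2, 6))
        state = CacheState(cap, str(tmp_path / f"s{seed}"))
        ref = ReferenceLRU(cap)
        keys = [f"k{i}" for i in range(10)]
        for _ in range(60):
            key = keys[int(rng.integers(0, len(keys)))]
            modify = bool(rng.integers(0, 2))
            if state.get(key, modify=modify) is None:
                self._put(state, key, modified=modify)
            ref.touch(key, modify)
        assert list(state.resident) == ref.order
        assert state.modified == ref.modified
        # contract: every modified chunk is resident or spilled — never lost
        assert ref.modified <= set(state.resident) | set(state.spilled)
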