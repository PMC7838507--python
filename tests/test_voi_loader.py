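"""VOI loader: level selection, block covers, progressive refinement."""

import numpy as np
import pytest

from bitvox import (
    BitPlaneRef,
    DatasetMeta,
    LoaderConfig,
    VOIBox,
    blocks_for_box,
    load_full,
    load_progressive,
    local_fetcher,
    max_error_bound,
    resolution_level,
)
from bitvox.bitplane_codec import Block, quantize_top

BRAIN = DatasetMeta(name="brain", dims=(13913, 18000, 5115), block_size=128)


class TestResolutionLevel:
    def test_formula_on_power_of_two_volume(self):
        # 1024*1024*160 voxels / (2^20 * 20) = 8 -> floor(log2 8) = 3
        box = VOIBox(0, 1024, 0, 1024, 0, 160)
        assert resolution_level(box, BRAIN, LoaderConfig(M=20)) == 3

    def test_small_window_clamps_to_level_one(self):
        box = VOIBox(0, 64, 0, 64, 0, 64)
        assert resolution_level(box, BRAIN, LoaderConfig(M=20)) == 1

    def test_full_extent_clamps_to_coarsest(self):
        box = VOIBox(0, 13913, 0, 18000, 0, 5115)
        # floor(log2(1,280,969,910,000 / 20,971,520)) = 15, clamped to 9
        assert resolution_level(box, BRAIN, LoaderConfig(M=20)) == 9

    def test_monotone_in_window_volume(self):
        sizes = [64, 256, 512, 1024, 4096, 13913]
        levels = [
            resolution_level(VOIBox(0, s, 0, s, 0, max(s // 8, 1)), BRAIN)
            for s in sizes
        ]
        assert levels == sorted(levels)

    def test_cap_property_on_power_of_eight_ratios(self):
        # V = 8^n * 2^20 * M: unclamped R = 3n+... with base 2 the loaded
        # level-R VOI has V / 8^(R-1) voxels; check it against the cap.
        M = 20
        cfg = LoaderConfig(M=M)
        for n in (1, 2):
            side = int(round((8**n * 2**20 * M) ** (1 / 3)))
            # adjust to an exact power-of-eight ratio via a cuboid
            v = 8**n * 2**20 * M
            x = 2 ** ((v.bit_length() - 1) // 3)
            while v % x:
                x //= 2
            rest = v // x
            y = 2 ** ((rest.bit_length() - 1) // 2)
            while rest % y:
                y //= 2
            z = rest // y
            box = VOIBox(0, x, 0, y, 0, z)
            assert box.volume == v
            r = resolution_level(box, BRAIN, cfg)
            if r < BRAIN.levels:  # unclamped
                loaded = box.volume / 8 ** (r - 1)
                assert loaded <= 2**20 * M * 8 ** (2 / 3)  # base-2 slack

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            VOIBox(0, 0, 0, 10, 0, 10)


class TestBlocksForBox:
    def test_single_block(self):
        assert len(blocks_for_box(VOIBox(0, 128, 0, 128, 0, 128), 1, BRAIN)) == 1

    def test_x_spanning_box(self):
        coords = blocks_for_box(VOIBox(0, 130, 0, 10, 0, 128), 1, BRAIN)
        assert sorted((c.k, c.j, c.i) for c in coords) == [(0, 0, 0), (1, 0, 0)]

    def test_level_scaling(self):
        coords = blocks_for_box(VOIBox(0, 256, 0, 256, 0, 256), 2, BRAIN)
        assert len(coords) == 1  # level-2 extent [0,128)^3

    def test_outside_box_is_empty(self):
        box = VOIBox(20000, 21000, 0, 10, 0, 10)
        assert blocks_for_box(box, 1, BRAIN) == []

    def test_all_coords_within_grid(self, dataset_meta):
        box = VOIBox(100, 290, 30, 250, 50, 190)
        for r in range(1, dataset_meta.levels + 1):
            for c in blocks_for_box(box, r, dataset_meta):
                from bitvox.pyramid_plan import plan_pyramid

                grid = plan_pyramid(dataset_meta)[r - 1].grid
                assert 0 <= c.k < grid[0] and 0 <= c.j < grid[1] and 0 <= c.i < grid[2]


@pytest.fixture(scope="module")
def loaded(dataset):
    root, meta = dataset
    fetch = local_fetcher(root, meta)
    box = VOIBox(10, 160, 20, 140, 30, 120)
    return meta, box, list(load_progressive(box, meta, fetch, r=1))


class TestProgressive:
    def test_emits_one_refinement_per_plane(self, loaded):
        meta, _box, seq = loaded
        assert [v.m for v in seq] == list(range(1, meta.bit_depth + 1))
        assert [v.complete for v in seq] == [False] * 7 + [True]

    def test_final_refinement_matches_source_crop(self, loaded, phantom_volume):
        _meta, box, seq = loaded
        crop = phantom_volume[box.z_min : box.z_max, box.y_min : box.y_max,
                              box.x_min : box.x_max]
        np.testing.assert_array_equal(seq[-1].data, crop)

    def test_each_refinement_is_top_m_quantization(self, loaded, phantom_volume):
        meta, box, seq = loaded
        crop = phantom_volume[box.z_min : box.z_max, box.y_min : box.y_max,
                              box.x_min : box.x_max]
        for voi in seq:
            q = quantize_top(Block(_cube(crop), 8), voi.m).data
            expected = q[: crop.shape[0], : crop.shape[1], : crop.shape[2]]
            np.testing.assert_array_equal(voi.data, expected)

    def test_error_monotone_and_bounded(self, loaded, phantom_volume):
        meta, box, seq = loaded
        crop = phantom_volume[box.z_min : box.z_max, box.y_min : box.y_max,
                              box.x_min : box.x_max].astype(np.int64)
        prev = None
        for voi in seq:
            err = np.abs(crop - voi.data.astype(np.int64))
            assert err.max() <= max_error_bound(voi.m, meta.bit_depth)
            if prev is not None:
                assert np.all(err <= prev)
            prev = err
        assert prev.max() == 0

    def test_half_bit_transfers_half_the_files(self, dataset):
        root, meta = dataset
        box = VOIBox(0, 96, 0, 96, 0, 64)
        counts = {}
        for half in (False, True):
            fetched: list[BitPlaneRef] = []
            base = local_fetcher(root, meta)

            def counting(ref, base=base, fetched=fetched):
                fetched.append(ref)
                return base(ref)

            seq = list(load_progressive(box, meta, counting,
                                        LoaderConfig(half_bit=half), r=1))
            counts[half] = len(fetched)
            assert seq[-1].complete
            assert seq[-1].m == (meta.bit_depth // 2 if half else meta.bit_depth)
        assert counts[True] * 2 == counts[False]

    def test_half_bit_final_equals_top_half_quantization(self, dataset, phantom_volume):
        root, meta = dataset
        fetch = local_fetcher(root, meta)
        box = VOIBox(40, 104, 40, 104, 40, 104)
        final = load_full(box, meta, fetch, LoaderConfig(half_bit=True), r=1)
        crop = phantom_volume[40:104, 40:104, 40:104]
        np.testing.assert_array_equal(final.data, (crop >> 4) << 4)

    def test_missing_bitblock_names_the_ref(self, dataset):
        root, meta = dataset

        def flaky(ref):
            from bitvox.store import BitBlockNotFound, read_bitblock

            if ref.b == 3:
                raise BitBlockNotFound(f"gone: plane {ref.b}")
            return read_bitblock(root, ref, meta.block_size)

        box = VOIBox(0, 32, 0, 32, 0, 32)
        seq = load_progressive(box, meta, flaky, r=1)
        next(seq)  # m=1 fine
        with pytest.raises(Exception, match="plane 3"):
            for _ in seq:
                pass

    def test_edge_box_excludes_padding(self, dataset, phantom_volume):
        root, meta = dataset
        fetch = local_fetcher(root, meta)
        x1, y1, z1 = meta.dims
        box = VOIBox(x1 - 20, x1 + 50, y1 - 20, y1 + 50, z1 - 20, z1 + 50)
        voi = load_full(box, meta, fetch, r=1)
        assert voi.data.shape == (20, 20, 20)
        np.testing.assert_array_equal(voi.data, phantom_volume[-20:, -20:, -20:])


def _cube(a: np.ndarray) -> np.ndarray:
    """Zero-pad an array to a cube (smallest edge covering all axes)."""
    e = max(a.shape)
    e = -(-e // 8) * 8
    out = np.zeros((e, e, e), a.dtype)
    out[: a.shape[0], : a.shape[1], : a.shape[2]] = a
    return out
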