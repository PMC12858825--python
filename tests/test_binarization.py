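import numpy as np
import pytest

from barcode_screen import (
    binarize_frame,
    compile_ib_metrics,
    downsample_binary,
    region_stats,
)
from barcode_screen.binarization import BinaryFrameRecord, robust_max
from barcode_screen.errors import ParameterError, PipelineError

from oracles import brute_region_stats


def record(I=0.0, I2=0.0, V=0.0, C=0, idx=0):
    return BinaryFrameRecord(frame_index=idx, connected=C, max_island_area=I,
                             second_island_area=I2, max_void_area=V,
                             island_count=0, void_count=0)


class TestBinarizeFrame:
    def test_mean_relative_threshold(self):
        frame = np.zeros((4, 4))
        frame[:, :2] = 200.0  # mean 100, threshold 110
        binary, thr = binarize_frame(frame, percent_offset=10)
        assert thr == pytest.approx(110.0)
        assert binary.sum() == 8 and binary[:, :2].all()

    def test_constant_frame_all_dark(self):
        binary, _ = binarize_frame(np.full((8, 8), 100.0), percent_offset=10)
        assert not binary.any()

    def test_scale_invariance(self, rng):
        frame = rng.uniform(0, 255, (16, 16))
        b1, _ = binarize_frame(frame, 10)
        b7, _ = binarize_frame(frame * 7.0, 10)
        np.testing.assert_array_equal(b1, b7)

    def test_negative_offset_rejected(self):
        with pytest.raises(ParameterError):
            binarize_frame(np.ones((4, 4)), percent_offset=-1)


class TestDownsampleBinary:
    def test_identity_at_p1(self, rng):
        stack = rng.integers(0, 2, (3, 8, 8)).astype(bool)
        np.testing.assert_array_equal(downsample_binary(stack, 1), stack)

    @pytest.mark.parametrize("window,expected", [
        ([[1, 1], [1, 0]], 1),   # mean 0.75
        ([[1, 0], [0, 0]], 0),   # mean 0.25
        ([[1, 1], [0, 0]], 1),   # mean 0.50: majority rule is >= 0.5
    ])
    def test_majority_rule(self, window, expected):
        out = downsample_binary(np.array(window), 2)
        assert out.shape == (1, 1) and int(out[0, 0]) == expected

    def test_partial_windows_use_available_pixels(self):
        frame = np.ones((3, 3), dtype=bool)
        frame[2, :] = False  # trailing 1x3 row-window: mean 0 -> 0
        out = downsample_binary(frame, 2)
        assert out.shape == (2, 2)
        assert out[0].all() and not out[1].any()

    def test_oversized_window_rejected(self):
        with pytest.raises(ParameterError):
            downsample_binary(np.ones((4, 4), dtype=bool), 5)


class TestRegionStats:
    def test_full_width_stripe_percolates(self):
        frame = np.zeros((10, 10), dtype=int)
        frame[3:5, :] = 1
        r = region_stats(frame)
        assert r.connected == 1
        assert r.max_island_area == pytest.approx(0.2)

    def test_isolated_corners(self):
        frame = np.zeros((3, 3), dtype=int)
        frame[[0, 0, 2, 2], [0, 2, 0, 2]] = 1
        r = region_stats(frame)
        assert r.island_count == 4 and r.connected == 0
        assert r.max_island_area == r.second_island_area == pytest.approx(1 / 9)

    def test_antidiagonal_connects_under_8(self):
        frame = np.eye(8, dtype=int)[:, ::-1]
        r = region_stats(frame)
        assert r.connected == 1 and r.island_count == 1
        assert brute_region_stats(frame.tolist())[0] == 1

    def test_all_black_and_all_white(self):
        black = region_stats(np.zeros((6, 6), dtype=int))
        assert (black.max_island_area, black.max_void_area, black.connected) == (0.0, 1.0, 0)
        white = region_stats(np.ones((6, 6), dtype=int))
        assert (white.max_island_area, white.max_void_area, white.connected) == (1.0, 0.0, 1)

    def test_area_fractions_partition_fov(self, rng):
        for _ in range(20):
            frame = (rng.random((12, 12)) > 0.5).astype(int)
            r = region_stats(frame)
            # island + void pixels tile the frame exactly
            assert frame.sum() + (1 - frame).sum() == frame.size
            assert r.max_island_area + r.max_void_area <= 1.0 + 1e-12

    def test_matches_flood_fill_oracle_32x32(self, rng):
        for density in (0.3, 0.5, 0.7):
            for _ in range(30):
                frame = (rng.random((32, 32)) < density).astype(int)
                r = region_stats(frame)
                conn, mi, si, mv, ni, nv = brute_region_stats(frame.tolist())
                assert (r.connected, r.island_count, r.void_count) == (conn, ni, nv)
                assert r.max_island_area == pytest.approx(mi)
                assert r.second_island_area == pytest.approx(si)
                assert r.max_void_area == pytest.approx(mv)

    def test_complementarity_without_diagonal_contacts(self):
        # coarse blocks: no diagonal-only contacts, so the 8/4 duality is inert
        frame = np.zeros((8, 8), dtype=int)
        frame[0:4, 0:4] = 1
        frame[6:8, 0:8] = 1
        inv = 1 - frame
        r, ri = region_stats(frame), region_stats(inv)
        assert ri.max_void_area == pytest.approx(r.max_island_area)
        assert ri.max_island_area == pytest.approx(r.max_void_area)


class TestCompileIB:
    def test_connectivity_fraction(self):
        recs = [record(C=1) for _ in range(4)] + [record(C=0) for _ in range(6)]
        assert compile_ib_metrics(recs).C == pytest.approx(0.4)

    def test_robust_max_top_10_percent(self):
        recs = [record(I=0.01 * (i + 1), idx=i) for i in range(20)]
        m = compile_ib_metrics(recs, top_frac=10)
        assert m.I == pytest.approx((0.20 + 0.19) / 2)

    def test_static_series_unit_ratios(self):
        recs = [record(I=0.3, V=0.2, idx=i) for i in range(10)]
        m = compile_ib_metrics(recs, X=5)
        assert m.delta_I == pytest.approx(1.0)
        assert m.delta_V == pytest.approx(1.0)

    def test_time_reversal_inverts_ratios(self):
        areas = np.linspace(0.1, 0.5, 10)
        recs = [record(I=a, V=0.6 - a, idx=i) for i, a in enumerate(areas)]
        fwd = compile_ib_metrics(recs, X=10)
        rev = compile_ib_metrics(recs[::-1], X=10)
        assert rev.delta_I == pytest.approx(1 / fwd.delta_I)
        assert rev.delta_V == pytest.approx(1 / fwd.delta_V)

    def test_connectivity_order_invariant_but_ratios_not(self, rng):
        areas = np.linspace(0.1, 0.5, 8)
        recs = [record(I=a, V=0.1, C=int(i % 2), idx=i) for i, a in enumerate(areas)]
        perm = [recs[i] for i in rng.permutation(8)]
        assert compile_ib_metrics(perm).C == compile_ib_metrics(recs).C
        assert compile_ib_metrics(recs, X=15).delta_I != pytest.approx(1.0)

    def test_initial_window_islands(self):
        recs = [record(I=0.5, I2=0.2, idx=0)] + [record(I=0.1, I2=0.05, idx=i)
                                                 for i in range(1, 20)]
        m = compile_ib_metrics(recs, X=5)  # n_X = 1
        assert m.I01 == pytest.approx(0.5) and m.I02 == pytest.approx(0.2)
        assert m.I01 >= m.I02

    def test_zero_initial_area_flags_sentinel(self):
        recs = [record(I=0.0, V=0.0, idx=0)] + [record(I=0.3, V=0.2, idx=i)
                                                for i in range(1, 10)]
        m = compile_ib_metrics(recs, X=5)
        assert np.isnan(m.delta_I) and m.delta_I_undefined
        assert np.isnan(m.delta_V) and m.delta_V_undefined

    def test_empty_records_rejected(self):
        with pytest.raises(PipelineError):
            compile_ib_metrics([])

    def test_robust_max_floor_of_one(self):
        assert robust_max([0.7], top_frac=10) == pytest.approx(0.7)
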