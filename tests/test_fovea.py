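import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from foveoct import (
    FoveaParams,
    PhantomSpec,
    add_speckle,
    column_centroids,
    extract_subvolume,
    generate_phantom,
    locate_fovea,
    preprocess_slice,
    slice_pit_metric,
)
from foveoct.fovea import _extraction_window, central_bounds, otsu_threshold
from foveoct.volume_io import BScanStack

from naive_reference import naive_centroids, naive_preprocess


class TestPreprocessSlice:
    def test_bimodal_image_splits_exactly(self):
        img = np.full((64, 64), 20, dtype=np.uint8)
        img[: 64 // 2] = 200
        mask, degenerate = preprocess_slice(img)
        assert not degenerate
        # any valid Otsu split between the two modes labels the bright half
        interior = mask[5:-5]  # blur mixes classes only near the boundary rows
        assert interior[: 32 - 5].all()
        assert not interior[32 + 5 - 5 :].any()

    def test_constant_image_degenerate(self):
        mask, degenerate = preprocess_slice(np.zeros((32, 32), dtype=np.uint8))
        assert degenerate and not mask.any()

    def test_matches_naive_reference(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8).astype(np.uint8)
            mask, flag = preprocess_slice(img)
            ref_mask, ref_flag = naive_preprocess(img)
            assert flag == ref_flag
            np.testing.assert_array_equal(mask, ref_mask)

    def test_central_bounds_cover_roughly_35_percent(self):
        for w in (64, 100, 128, 512, 513):
            lo, hi = central_bounds(w)
            assert abs((hi - lo) - 0.35 * w) <= 1.0

    def test_otsu_on_bimodal_histogram(self):
        img = np.array([[20] * 8 + [200] * 8] * 4, dtype=np.uint8)
        t = otsu_threshold(img)
        assert 20 < t <= 200

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess_slice(np.zeros((3, 64), dtype=np.uint8))


class TestColumnCentroids:
    def test_forced_arithmetic(self):
        mask = np.array([[0], [0], [1], [1]])
        assert column_centroids(mask)[0] == pytest.approx(3.5)  # rows 3 and 4

    def test_empty_column_sentinel_is_height(self):
        mask = np.zeros((4, 2), dtype=bool)
        mask[1, 0] = True
        cy = column_centroids(mask)
        assert cy[0] == pytest.approx(2.0)
        assert cy[1] == 4.0  # sentinel H

    @given(hnp.arrays(dtype=np.bool_, shape=(32, 16)))
    @settings(max_examples=30, deadline=None)
    def test_matches_double_loop_reference(self, mask):
        np.testing.assert_allclose(column_centroids(mask), naive_centroids(mask), atol=1e-9)


class TestSlicePitMetric:
    def test_in_range_identity(self):
        prof = slice_pit_metric(np.array([10.0, 7.5, 12.0]), slice_index=64)
        assert prof.raw_metric == 7.5 and prof.penalized_metric == 7.5

    def test_out_of_range_penalty_added(self):
        prof = slice_pit_metric(np.array([10.0, 7.5, 12.0]), slice_index=58)
        assert prof.raw_metric == 7.5 and prof.penalized_metric == 207.5

    def test_sentinel_propagates(self):
        prof = slice_pit_metric(np.full(4, 512.0), slice_index=64)
        assert prof.penalized_metric == 512.0

    def test_penalized_never_below_raw(self, rng):
        for idx in (1, 59, 64, 69, 70, 128):
            cy = rng.uniform(1, 128, size=8)
            prof = slice_pit_metric(cy, idx)
            assert prof.penalized_metric >= prof.raw_metric
            assert (prof.penalized_metric == prof.raw_metric) == (59 <= idx <= 69)


class TestLocateFovea:
    def test_clean_phantom_ground_truth(self):
        stack, pit = generate_phantom(PhantomSpec(pit_slice=64, seed=0))
        result = locate_fovea(stack)
        assert result.fovea_index == pit
        assert result.window == (48, 80)
        assert not result.used_fallback

    def test_tilted_speckled_phantom_within_one_slice(self):
        stack, pit = generate_phantom(PhantomSpec(pit_slice=66, tilt_deg=6.0, seed=1))
        noisy = add_speckle(stack, "multiplicative_gamma", L=4.0, seed=2)
        assert abs(locate_fovea(noisy).fovea_index - pit) <= 1

    def test_all_black_volume_falls_back_to_slice_64(self):
        stack = BScanStack(np.zeros((128, 64, 64), dtype=np.uint8))
        result = locate_fovea(stack)
        assert result.fovea_index == 64
        assert result.used_fallback

    def test_fallback_clipped_to_short_volume(self):
        stack = BScanStack(np.zeros((10, 64, 64), dtype=np.uint8))
        result = locate_fovea(stack)
        assert result.fovea_index == 10
        assert result.used_fallback and result.short_volume

    def test_ties_break_to_lowest_slice_index(self):
        # every slice identical: all raw metrics equal, penalty leaves
        # [59, 69] tied, and the scan picks the first of them
        img = np.zeros((64, 64), dtype=np.uint8)
        img[30:40] = 200
        stack = BScanStack(np.repeat(img[None], 128, axis=0))
        assert locate_fovea(stack).fovea_index == 59

    def test_penalty_keeps_selection_in_range_for_moderate_pits(self):
        # pit well outside the clinical range, advantage far below P=200
        stack, _ = generate_phantom(PhantomSpec(pit_slice=40, seed=2))
        result = locate_fovea(stack)
        assert 59 <= result.fovea_index <= 69

    def test_exceptional_out_of_range_signal_overrides_penalty(self):
        # H = 300: an out-of-range slice whose raw advantage exceeds P wins,
        # the intended behaviour of an additive (unscaled) penalty
        vol = np.zeros((128, 300, 64), dtype=np.uint8)
        vol[:, 240:280, :] = 200  # deep retina everywhere
        vol[39] = 0
        vol[39, 10:50, :] = 200  # slice 40: all tissue near the top (raw ~30 vs ~260)
        result = locate_fovea(BScanStack(vol))
        assert result.fovea_index == 40

    def test_deterministic(self):
        stack, _ = generate_phantom(PhantomSpec(pit_slice=61, tilt_deg=-4.0, seed=3))
        noisy = add_speckle(stack, "multiplicative_gamma", L=4.0, seed=4)
        a, b = locate_fovea(noisy), locate_fovea(noisy)
        assert a.fovea_index == b.fovea_index and a.window == b.window


class TestExtractSubvolume:
    @pytest.mark.parametrize(
        "fovea,expected",
        [(64, (48, 80)), (10, (1, 33)), (125, (96, 128)), (1, (1, 33)), (128, (96, 128))],
    )
    def test_window_placement(self, fovea, expected):
        stack = BScanStack(np.zeros((128, 8, 8), dtype=np.uint8))
        sub, window = extract_subvolume(stack, fovea)
        assert window == expected
        assert sub.depth == 33

    def test_exhaustive_windows_valid(self):
        params = FoveaParams()
        for fovea in range(1, 129):
            _, window, _, short = _extraction_window(128, fovea, params)
            assert not short
            assert window[1] - window[0] + 1 == 33
            assert 1 <= window[0] and window[1] <= 128

    def test_slices_copied_not_aliased(self):
        stack = BScanStack(np.zeros((128, 8, 8), dtype=np.uint8))
        sub, window = extract_subvolume(stack, 64)
        sub.slices[0, 0, 0] = 99
        assert stack.slices[window[0] - 1, 0, 0] == 0

    def test_short_volume_returned_whole(self):
        stack = BScanStack(np.zeros((20, 8, 8), dtype=np.uint8))
        sub, window = extract_subvolume(stack, 10)
        assert sub.depth == 20 and window == (1, 20)

    def test_out_of_range_fovea_rejected(self):
        stack = BScanStack(np.zeros((128, 8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            extract_subvolume(stack, 0)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FoveaParams(r_start=70, r_end=69)
        with pytest.raises(ValueError):
            FoveaParams(central_frac=0.0)
        with pytest.raises(ValueError):
            FoveaParams(penalty=-1.0)
        with pytest.raises(ValueError):
            FoveaParams(n_adj=64, total_slices=100)
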