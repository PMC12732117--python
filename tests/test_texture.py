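"""Texture primitives: quantization, co-occurrence, run lengths, features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from corticalization.texture import (
    CoocParams,
    QuantizationConfig,
    QuantizedROI,
    compute_features,
    cooc_matrix,
    difference_entropy,
    long_run_emphasis,
    quantize,
    run_length_matrix,
)

ALL_DIRECTIONS = (0, 45, 90, 135)


class TestQuantize:
    def test_two_point_mapping(self):
        roi = quantize(np.array([[0, 255], [255, 0]]), QuantizationConfig(n_levels=2))
        assert roi.levels.tolist() == [[0, 1], [1, 0]]
        assert roi.raw_mean == 127.5
        assert not roi.degenerate

    def test_constant_patch_is_degenerate_not_error(self):
        roi = quantize(np.full((4, 4), 77), QuantizationConfig(n_levels=16))
        assert roi.levels.max() == 0
        assert roi.raw_mean == 77
        assert roi.degenerate

    def test_minmax_spans_full_level_range(self, rng):
        patch = rng.integers(0, 256, size=(16, 16))
        roi = quantize(patch, QuantizationConfig(n_levels=64))
        assert roi.levels.min() == 0
        assert roi.levels.max() == 63

    def test_matches_binning_oracle_bin_by_bin(self, rng):
        for _ in range(20):
            patch = rng.integers(0, 256, size=(16, 16))
            roi = quantize(patch, QuantizationConfig(n_levels=64))
            np.testing.assert_array_equal(
                roi.levels, oracles.naive_quantize_minmax(patch, 64)
            )

    def test_mean_3sigma_clips_outliers(self, rng):
        patch = rng.normal(128, 10, size=(32, 32))
        patch[0, 0] = 4000.0  # far outlier
        roi = quantize(patch, QuantizationConfig(n_levels=32, mode="mean-3sigma"))
        # the outlier must not own the entire top range by itself
        assert (roi.levels == roi.levels.max()).sum() >= 1
        assert roi.levels[0, 0] == roi.levels.max()
        interior = np.delete(roi.levels.ravel(), 0)
        assert interior.max() > 0  # normal data still spread over levels

    def test_raw_mean_is_prequantization_mean(self, rng):
        patch = rng.integers(0, 4096, size=(10, 10))
        roi = quantize(patch, QuantizationConfig(n_levels=8))
        assert roi.raw_mean == pytest.approx(patch.mean())

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.empty((0, 0)))


class TestCoocMatrix:
    def test_hand_enumerated_1x6(self):
        # levels 0,0,0,1,1,1 at d=1: ordered pairs (0,0)x2, (1,1)x2, (0,1)x1,
        # each counted both ways under symmetry -> 10 total
        roi = QuantizedROI(np.array([[0, 0, 0, 1, 1, 1]]), 2, 0.5)
        (mat,) = cooc_matrix(roi, CoocParams(distance=1, directions=(0,)))
        np.testing.assert_allclose(mat.entries, np.array([[0.4, 0.1], [0.1, 0.4]]))
        np.testing.assert_allclose(mat.diff_marginal, [0.8, 0.2])

    def test_constant_roi_concentrates_on_diagonal(self):
        roi = QuantizedROI(np.zeros((6, 6), dtype=int), 4, 50.0)
        (mat,) = cooc_matrix(roi, CoocParams(distance=2, directions=(0,)))
        assert mat.entries[0, 0] == 1.0
        marg = mat.diff_marginal
        assert marg[0] == 1.0 and marg[1:].sum() == 0.0

    @pytest.mark.parametrize("distance", [1, 2, 5])
    @pytest.mark.parametrize("angle", ALL_DIRECTIONS)
    def test_matches_pair_enumeration_oracle(self, rng, distance, angle):
        for _ in range(5):
            lv = rng.integers(0, 8, size=(12, 12))
            roi = QuantizedROI(lv, 8, float(lv.mean()))
            (mat,) = cooc_matrix(roi, CoocParams(distance=distance, directions=(angle,)))
            expected = oracles.naive_cooc_counts(lv, 8, distance, angle)
            np.testing.assert_allclose(mat.entries, expected / expected.sum(), atol=1e-12)
            np.testing.assert_allclose(
                mat.diff_marginal, oracles.naive_diff_marginal(expected), atol=1e-12
            )

    def test_normalized_and_symmetric_many_random_rois(self, rng):
        # normalization and symmetry as a bulk property sweep
        for _ in range(300):
            shape = (rng.integers(3, 10), rng.integers(3, 10))
            lv = rng.integers(0, 6, size=shape)
            roi = QuantizedROI(lv, 6, float(lv.mean()))
            d = int(rng.integers(1, min(shape)))
            for mat in cooc_matrix(roi, CoocParams(distance=d, directions=ALL_DIRECTIONS)):
                assert mat.entries.sum() == pytest.approx(1.0, abs=1e-9)
                np.testing.assert_allclose(mat.entries, mat.entries.T, atol=1e-12)
                assert mat.diff_marginal.sum() == pytest.approx(1.0, abs=1e-9)

    def test_offset_too_large_raises(self):
        roi = QuantizedROI(np.zeros((4, 4), dtype=int), 2, 0.0)
        with pytest.raises(ValueError):
            cooc_matrix(roi, CoocParams(distance=4, directions=(0,)))


class TestDifferenceEntropy:
    def test_degenerate_distribution_is_zero(self):
        assert difference_entropy(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_uniform_over_10_bins_is_one_in_base10(self):
        assert difference_entropy(np.full(10, 0.1)) == pytest.approx(1.0)

    def test_two_point_example(self):
        # -(0.8 log10 0.8 + 0.2 log10 0.2)
        val = difference_entropy(np.array([0.8, 0.2]))
        assert val == pytest.approx(0.21732201, abs=1e-6)
        # cross-check against an independent entropy routine
        from scipy.stats import entropy

        assert val == pytest.approx(entropy([0.8, 0.2]) / np.log(10), abs=1e-12)

    def test_natural_log_base(self):
        val = difference_entropy(np.full(4, 0.25), log_base=np.e)
        assert val == pytest.approx(np.log(4))

    def test_unnormalized_marginal_rejected(self):
        with pytest.raises(ValueError):
            difference_entropy(np.array([0.5, 0.4]))

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=32))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_by_log_ng_with_equality_iff_uniform(self, weights):
        p = np.array(weights) / np.sum(weights)
        h = difference_entropy(p)
        ng = p.size
        assert -1e-12 <= h <= np.log10(ng) + 1e-12
        if np.allclose(p, 1.0 / ng):
            assert h == pytest.approx(np.log10(ng))
        elif np.max(p) - np.min(p) > 1e-6:
            assert h < np.log10(ng) - 1e-12


class TestRunLengthMatrix:
    def test_two_maximal_runs(self):
        roi = QuantizedROI(np.array([[0, 0, 0, 1, 1, 1]]), 2, 0.5)
        rlm = run_length_matrix(roi, 0)
        assert rlm.counts[0, 2] == 1 and rlm.counts[1, 2] == 1
        assert rlm.counts.sum() == 2

    def test_constant_roi_one_run_per_row(self):
        roi = QuantizedROI(np.zeros((5, 7), dtype=int), 3, 0.0)
        rlm = run_length_matrix(roi, 0)
        assert rlm.counts[0, 6] == 5
        assert rlm.total_runs == 5

    @pytest.mark.parametrize("angle", ALL_DIRECTIONS)
    def test_matches_run_scanning_oracle(self, rng, angle):
        for _ in range(5):
            lv = rng.integers(0, 8, size=(12, 12))
            roi = QuantizedROI(lv, 8, float(lv.mean()))
            rlm = run_length_matrix(roi, angle)
            np.testing.assert_array_equal(
                rlm.counts, oracles.naive_rlm_counts(lv, 8, angle)
            )

    @pytest.mark.parametrize("angle", ALL_DIRECTIONS)
    def test_every_pixel_in_exactly_one_run(self, rng, angle):
        for _ in range(50):
            shape = (rng.integers(2, 15), rng.integers(2, 15))
            lv = rng.integers(0, 5, size=shape)
            roi = QuantizedROI(lv, 5, float(lv.mean()))
            assert run_length_matrix(roi, angle).total_pixels == lv.size


class TestLongRunEmphasis:
    def test_all_runs_length_one_gives_lower_bound(self):
        roi = QuantizedROI(np.array([[0, 1, 0, 1], [1, 0, 1, 0]]), 2, 0.5)
        assert long_run_emphasis(run_length_matrix(roi, 0)) == 1.0

    def test_constant_roi_gives_cols_squared(self):
        roi = QuantizedROI(np.zeros((4, 9), dtype=int), 2, 0.0)
        assert long_run_emphasis(run_length_matrix(roi, 0)) == 81.0

    def test_enumerated_two_run_matrix(self):
        # two runs of length 3 -> (2*9)/2 = 9
        roi = QuantizedROI(np.array([[0, 0, 0, 1, 1, 1]]), 2, 0.5)
        assert long_run_emphasis(run_length_matrix(roi, 0)) == 9.0

    def test_at_least_one_on_random_rois(self, rng):
        for _ in range(100):
            lv = rng.integers(0, 4, size=(rng.integers(2, 12), rng.integers(2, 12)))
            roi = QuantizedROI(lv, 4, float(lv.mean()))
            assert long_run_emphasis(run_length_matrix(roi, 0)) >= 1.0


class TestComputeFeatures:
    def test_constant_patch_composition(self):
        f = compute_features(np.full((8, 30), 77.0))
        assert f.dif_entr == 0.0
        assert f.lng_r_emph == 900.0  # C^2 horizontally
        assert f.mean_optical_density == 77.0
        assert f.degenerate

    def test_checkerboard_all_neighbours_differ(self):
        cb = (np.indices((16, 16)).sum(axis=0) % 2) * 255
        f = compute_features(
            cb, QuantizationConfig(n_levels=2), CoocParams(distance=1, directions=(0,))
        )
        # diff marginal is [0, 1]: entropy 0; every horizontal run has length 1
        assert f.dif_entr == 0.0
        assert f.lng_r_emph == 1.0

    @pytest.mark.parametrize("angle", ALL_DIRECTIONS)
    def test_matches_monolithic_reference(self, rng, angle):
        patch = rng.integers(0, 256, size=(20, 20))
        f = compute_features(
            patch, QuantizationConfig(n_levels=16), CoocParams(distance=2, directions=(angle,))
        )
        de, lre, mod = oracles.naive_features(patch, 16, 2, angle)
        assert f.dif_entr == pytest.approx(de, abs=1e-12)
        assert f.lng_r_emph == pytest.approx(lre, abs=1e-12)
        assert f.mean_optical_density == pytest.approx(mod)

    def test_multi_direction_average_of_feature_values(self, rng):
        patch = rng.integers(0, 256, size=(16, 16))
        f = compute_features(
            patch, QuantizationConfig(n_levels=8),
            CoocParams(distance=1, directions=ALL_DIRECTIONS),
        )
        des = [f.per_direction[a]["dif_entr"] for a in ALL_DIRECTIONS]
        lres = [f.per_direction[a]["lng_r_emph"] for a in ALL_DIRECTIONS]
        assert f.dif_entr == pytest.approx(np.mean(des))
        assert f.lng_r_emph == pytest.approx(np.mean(lres))

    def test_agreement_with_skimage_glcm(self, rng):
        # independent library cross-check of the co-occurrence counts
        skimage = pytest.importorskip("skimage.feature")
        lv = rng.integers(0, 8, size=(12, 12))
        from corticalization.texture import QuantizedROI, cooc_matrix as cm

        roi = QuantizedROI(lv, 8, float(lv.mean()))
        (mat,) = cm(roi, CoocParams(distance=3, directions=(0,)))
        ref = skimage.graycomatrix(
            lv.astype(np.uint8), [3], [0], levels=8, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(mat.entries, ref, atol=1e-12)
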