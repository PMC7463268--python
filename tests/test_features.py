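"""Histogram moments, GLCM construction and Haralick feature formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irtexture import (
    GLCM,
    GLCM_FEATURES,
    FeatureConfig,
    GrayImage,
    ParameterError,
    RegionMask,
    compute_glcm,
    extract_features,
    haralick_features,
    histogram,
    histogram_features,
    quantize,
)
from irtexture.features import QuantizedImage, _entropy

from conftest import random_quantized
from oracles import glcm_bruteforce, haralick_literal


def _qimg(levels, ng):
    levels = np.asarray(levels, dtype=np.int32)
    return QuantizedImage(levels=levels, ng=ng, bin_edges=np.array([]))


def _glcm_from_p(P, ng, direction=0):
    return GLCM(
        P=np.asarray(P, float),
        direction=direction,
        distance=1,
        symmetric=True,
        pair_count=1,
        ng=ng,
    )


class TestQuantize:
    def test_bin_arithmetic_8bit_to_8_levels(self):
        img = GrayImage(np.array([[0, 255], [128, 10]]), bit_depth=8)
        q = quantize(img, None, ng=8)
        assert q.levels[0, 0] == 1
        assert q.levels[0, 1] == 8
        assert q.levels[1, 0] == 5

    def test_binary_image_two_levels(self):
        img = GrayImage(np.array([[0, 255], [255, 0]]), bit_depth=8)
        q = quantize(img, None, ng=2)
        assert set(np.unique(q.levels)) == {1, 2}

    def test_constant_image_maps_to_level_one(self):
        img = GrayImage(np.full((4, 4), 7), bit_depth=8)
        q = quantize(img, None, ng=8)
        assert (q.levels == 1).all()

    def test_masked_pixels_carry_sentinel(self):
        img = GrayImage(np.arange(16).reshape(4, 4), bit_depth=8)
        mask = RegionMask(np.eye(4, dtype=bool))
        q = quantize(img, mask, ng=4)
        assert (q.levels[~mask.flags] == 0).all()
        assert (q.levels[mask.flags] >= 1).all()


class TestHistogram:
    def test_direct_count(self):
        q = _qimg([[1, 1], [2, 2]], ng=2)
        h = histogram(q)
        assert h.probabilities[0] == pytest.approx(0.5)
        assert h.probabilities[1] == pytest.approx(0.5)
        assert h.counts.sum() == 4

    def test_mask_restricts_counts(self):
        q = _qimg([[1, 1], [2, 2]], ng=2)
        mask = RegionMask(np.array([[True, True], [False, False]]))
        h = histogram(q, mask)
        assert h.probabilities[0] == pytest.approx(1.0)
        assert h.probabilities[1] == 0.0

    def test_normalization_on_random_levels(self, rng):
        q = _qimg(rng.integers(1, 9, size=(10, 10)), ng=8)
        h = histogram(q)
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


class TestHistogramFeatures:
    def test_single_level_degenerate(self):
        q = _qimg(np.full((3, 3), 3), ng=8)
        feats, undefined = histogram_features(histogram(q))
        assert feats["hist_mean"] == pytest.approx(3.0)
        assert feats["hist_variance"] == 0.0
        assert feats["hist_energy"] == pytest.approx(1.0)
        assert feats["hist_entropy"] == 0.0
        assert undefined == {"hist_skewness", "hist_kurtosis"}

    def test_two_level_hand_values(self):
        q = _qimg([[1, 2], [2, 1]], ng=2)
        feats, undefined = histogram_features(histogram(q))
        assert feats["hist_mean"] == pytest.approx(1.5)
        assert feats["hist_variance"] == pytest.approx(0.25)
        assert feats["hist_skewness"] == pytest.approx(0.0, abs=1e-12)
        assert feats["hist_kurtosis"] == pytest.approx(1.0)
        assert feats["hist_energy"] == pytest.approx(0.5)
        assert feats["hist_entropy"] == pytest.approx(math.log(2))
        assert not undefined

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_histogram_has_zero_skewness(self, seed):
        rng = np.random.default_rng(seed)
        half = rng.integers(1, 4, size=4)
        levels = np.concatenate(
            [np.repeat([1, 2, 3, 4], half), np.repeat([8, 7, 6, 5], half)]
        )
        q = _qimg(levels.reshape(1, -1), ng=8)
        feats, _ = histogram_features(histogram(q))
        assert feats["hist_skewness"] == pytest.approx(0.0, abs=1e-12)


class TestComputeGLCM:
    def test_constant_image_single_entry(self):
        g = compute_glcm(_qimg(np.full((4, 4), 3), ng=8), None, 0)
        assert g.P[2, 2] == pytest.approx(1.0)
        assert g.P.sum() == pytest.approx(1.0)

    def test_two_by_two_hand_enumeration(self):
        g = compute_glcm(_qimg([[1, 2], [1, 2]], ng=2), None, 0, symmetric=True)
        assert g.P[0, 1] == pytest.approx(0.5)
        assert g.P[1, 0] == pytest.approx(0.5)
        assert g.P[0, 0] == g.P[1, 1] == 0.0

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_bruteforce_on_random_masked_images(self, rng, direction, symmetric):
        for _ in range(25):
            levels, mask = random_quantized(rng)
            g = compute_glcm(_qimg(levels, ng=6), mask, direction, symmetric=symmetric)
            expected = glcm_bruteforce(levels, direction, symmetric=symmetric, ng=6)
            np.testing.assert_allclose(g.P, expected, atol=1e-12)

    def test_symmetric_matrix_is_symmetric(self, rng):
        levels, mask = random_quantized(rng)
        g = compute_glcm(_qimg(levels, ng=6), mask, 45, symmetric=True)
        np.testing.assert_allclose(g.P, g.P.T, atol=0)

    def test_marginals_sum_to_one(self, rng):
        levels, mask = random_quantized(rng)
        g = compute_glcm(_qimg(levels, ng=6), mask, 135)
        for marginal in (g.px, g.py, g.p_sum, g.p_diff):
            assert marginal.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sparse_mask_raises_naming_direction(self):
        levels = np.zeros((4, 4), dtype=np.int32)
        levels[0, 0] = 1  # single in-mask pixel: no pair in any direction
        with pytest.raises(ParameterError, match="90"):
            compute_glcm(_qimg(levels, ng=2), None, 90)

    def test_distance_two_skips_neighbour(self):
        levels = np.array([[1, 2, 1, 2]])
        g = compute_glcm(_qimg(levels, ng=2), None, 0, d=2, symmetric=False)
        # pairs at offset 2: (1,1) and (2,2)
        assert g.P[0, 0] == pytest.approx(0.5)
        assert g.P[1, 1] == pytest.approx(0.5)


class TestHaralickFeatures:
    def test_single_diagonal_matrix(self):
        P = np.zeros((3, 3))
        P[1, 1] = 1.0
        feats, undefined = haralick_features(_glcm_from_p(P, 3))
        assert feats["glcm_contrast"] == 0.0
        assert feats["glcm_dissimilarity"] == 0.0
        assert feats["glcm_homogeneity"] == pytest.approx(1.0)
        assert feats["glcm_energy"] == pytest.approx(1.0)
        assert feats["glcm_entropy"] == 0.0
        assert feats["glcm_maximum_probability"] == pytest.approx(1.0)
        assert feats["glcm_idn"] == pytest.approx(1.0)
        assert feats["glcm_idmn"] == pytest.approx(1.0)
        assert "glcm_correlation" in undefined

    def test_checkerboard_hand_values(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        feats, undefined = haralick_features(_glcm_from_p(P, 2))
        assert feats["glcm_contrast"] == pytest.approx(1.0)
        assert feats["glcm_dissimilarity"] == pytest.approx(1.0)
        assert feats["glcm_homogeneity"] == pytest.approx(0.5)
        assert feats["glcm_energy"] == pytest.approx(0.5)
        assert feats["glcm_entropy"] == pytest.approx(math.log(2))
        assert feats["glcm_correlation"] == pytest.approx(-1.0)
        assert feats["glcm_sum_average"] == pytest.approx(3.0)
        assert feats["glcm_sum_variance"] == pytest.approx(0.0)
        assert feats["glcm_maximum_probability"] == pytest.approx(0.5)
        assert not undefined

    def test_matches_literal_formula_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            ng = int(rng.integers(2, 7))
            M = rng.random((ng, ng)) + 1e-3
            M = M + M.T
            P = M / M.sum()
            feats, _ = haralick_features(_glcm_from_p(P, ng))
            expected = haralick_literal(P)
            for name in GLCM_FEATURES:
                assert feats[name] == pytest.approx(expected[name], abs=1e-10), name

    def test_contrast_equals_difference_moment_identity(self, rng):
        levels, mask = random_quantized(rng)
        g = compute_glcm(_qimg(levels, ng=6), mask, 0)
        feats, _ = haralick_features(g)
        k = np.arange(g.ng, dtype=float)
        assert feats["glcm_contrast"] == pytest.approx(
            float(k**2 @ g.p_diff), abs=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_bounds_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        ng = int(rng.integers(2, 9))
        M = rng.random((ng, ng))
        M[M < 0.3] = 0  # allow sparse matrices
        if M.sum() == 0:
            M[0, 0] = 1.0
        P = (M + M.T) / (M + M.T).sum()
        g = _glcm_from_p(P, ng)
        feats, undefined = haralick_features(g)
        for name in ("glcm_energy", "glcm_homogeneity", "glcm_maximum_probability",
                     "glcm_idn", "glcm_idmn"):
            assert 0 < feats[name] <= 1 + 1e-12, name
        if "glcm_correlation" not in undefined:
            assert -1 - 1e-9 <= feats["glcm_correlation"] <= 1 + 1e-9
        assert 0 <= feats["glcm_imc2"] < 1
        for name in ("glcm_entropy", "glcm_sum_entropy", "glcm_difference_entropy"):
            assert -1e-12 <= feats[name] <= 2 * math.log(ng) + 1e-9, name


class TestExtractFeatures:
    def test_all_true_mask_equals_no_mask(self, random_image):
        full = RegionMask.full(random_image.pixels.shape)
        a = extract_features(random_image, full)
        b = extract_features(random_image, None)
        assert a.values == b.values

    def test_rotation_swaps_0_and_90_and_preserves_average(self, random_image):
        cfg = FeatureConfig()
        a = extract_features(random_image, None, cfg)
        rotated = GrayImage(np.rot90(random_image.pixels), bit_depth=8)
        b = extract_features(rotated, None, cfg)
        for name in GLCM_FEATURES:
            assert a.per_direction[f"{name}_0"] == pytest.approx(
                b.per_direction[f"{name}_90"], abs=1e-9
            )
            assert a.per_direction[f"{name}_45"] == pytest.approx(
                b.per_direction[f"{name}_135"], abs=1e-9
            )
            if not (math.isnan(a.values[name]) and math.isnan(b.values[name])):
                assert a.values[name] == pytest.approx(b.values[name], abs=1e-9)

    def test_iid_noise_has_low_correlation_smooth_field_high(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(5)
        noise = rng.integers(0, 256, size=(256, 256))
        fv = extract_features(GrayImage(noise), None)
        assert abs(fv.values["glcm_correlation"]) < 0.1
        smooth = gaussian_filter(rng.standard_normal((256, 256)), 8.0)
        smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min()) * 255
        fv2 = extract_features(GrayImage(np.rint(smooth)), None)
        assert fv2.values["glcm_correlation"] > 0.5

    def test_entropy_helper_skips_zero_terms(self):
        assert _entropy(np.array([0.0, 1.0, 0.0])) == 0.0
        assert _entropy(np.array([0.5, 0.5])) == pytest.approx(math.log(2))
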