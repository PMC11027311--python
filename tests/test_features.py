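"""Quantization, GLCM construction, the 22+20 statistics, and the extractor."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from gistrad import (
    FEATURE_NAMES,
    RadiomicFeatureExtractor,
    compute_glcm,
    extract_features,
    fos_statistics,
    glcm_statistics,
    quantize,
)
from gistrad.features import (
    ANGLE_OFFSETS,
    DISTANCES,
    FOS_NAMES,
    GLCM_STAT_NAMES,
    EmptyGLCMError,
    GLCMMatrix,
    QuantizedROI,
)

from gistrad import erode, scaled_radius, threshold_mask
from gistrad.synthetic import SyntheticParams, TextureEffect, generate_image

from ._oracles import fos_bruteforce, glcm_bruteforce, glcm_stats_bruteforce
from .conftest import random_roi


class TestQuantize:
    def test_endpoints_map_to_first_and_last_bin(self):
        pixels = np.arange(256).reshape(16, 16)
        q = quantize(pixels, np.ones((16, 16), bool), 8)
        assert q.levels[0, 0] == 1
        assert q.levels[15, 15] == 8

    def test_constant_roi_all_bin_one(self):
        q = quantize(np.full((4, 4), 7), np.ones((4, 4), bool), 8)
        assert (q.levels == 1).all()

    def test_midpoint_rule(self):
        pixels = np.array([[10, 20, 30, 40]])
        q = quantize(pixels, np.ones((1, 4), bool), 2)
        assert q.levels.tolist() == [[1, 1, 2, 2]]

    def test_non_roi_pixels_marked_absent(self):
        mask = np.array([[True, False]])
        q = quantize(np.array([[5, 9]]), mask, 4)
        assert q.levels[0, 1] == 0

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.ones((2, 2)), np.ones((2, 2), bool), 1)


class TestComputeGLCM:
    def test_constant_roi_single_cell(self):
        q = quantize(np.full((5, 5), 9), np.ones((5, 5), bool), 8)
        for d in (1, 2):
            G = compute_glcm(q, d)
            assert G.p[0, 0] == 1.0
            assert G.p.sum() == 1.0

    def test_toy_grid_matches_bruteforce_horizontal(self):
        levels = np.array(
            [[1, 1, 2, 2], [1, 1, 2, 2], [1, 3, 3, 3], [3, 3, 4, 4]], dtype=np.int32
        )
        q = QuantizedROI(levels=levels, n_levels=4, quantization_range=(1, 4))
        G = compute_glcm(q, 1, angles=((0, 1),), symmetric=False)
        expected = glcm_bruteforce(levels, 4, 1, ((0, 1),), symmetric=False)
        np.testing.assert_allclose(G.p, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_on_random_rois(self, seed):
        rng = np.random.default_rng(seed)
        pixels, mask = random_roi(rng, shape=(12, 12))
        q = quantize(pixels, mask, 6)
        d = int(rng.integers(1, 4))
        symmetric = bool(rng.integers(0, 2))
        try:
            G = compute_glcm(q, d, symmetric=symmetric)
        except EmptyGLCMError:
            return
        expected = glcm_bruteforce(q.levels, 6, d, ANGLE_OFFSETS, symmetric)
        np.testing.assert_allclose(G.p, expected, atol=1e-12)

    def test_agrees_with_skimage_on_full_rectangle(self):
        # independent library cross-check on an unmasked image
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
        rng = np.random.default_rng(0)
        pixels = rng.integers(0, 256, (20, 20))
        mask = np.ones((20, 20), bool)
        q = quantize(pixels, mask, 8)
        G = compute_glcm(q, 3, angles=((0, 1),), symmetric=True)
        ref = graycomatrix(
            (q.levels - 1).astype(np.uint8),
            distances=[3],
            angles=[0],
            levels=8,
            symmetric=True,
            normed=True,
        )[:, :, 0, 0]
        np.testing.assert_allclose(G.p, ref, atol=1e-12)

    def test_normalization_and_symmetry(self, rng):
        pixels, mask = random_roi(rng)
        q = quantize(pixels, mask, 8)
        G = compute_glcm(q, 1, symmetric=True)
        assert abs(G.p.sum() - 1.0) < 1e-9
        np.testing.assert_array_equal(G.p, G.p.T)

    def test_roi_too_small_for_distance(self):
        q = quantize(np.array([[150.0]]), np.array([[True]]), 4)
        with pytest.raises(EmptyGLCMError, match="distance 3"):
            compute_glcm(q, 3)


class TestGLCMStatistics:
    def test_single_cell_matrix_degenerate_values(self):
        p = np.zeros((8, 8))
        p[0, 0] = 1.0
        G = GLCMMatrix(p=p, distance=1, angles=ANGLE_OFFSETS, symmetric=True, pair_count=10)
        s = glcm_statistics(G)
        assert s["Contrast"] == 0
        assert s["Dissimilarity"] == 0
        assert s["Energy"] == 1
        assert s["Entropy"] == 0
        assert s["Maximum_probability"] == 1
        assert s["Cluster_shade"] == 0
        assert s["Correlation_m"] == 0  # degenerate marginals -> defined as 0

    def test_two_level_diagonal_hand_values(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        G = GLCMMatrix(p=p, distance=1, angles=ANGLE_OFFSETS, symmetric=True, pair_count=4)
        s = glcm_statistics(G)
        assert s["Contrast"] == 0
        assert s["Energy"] == 0.5
        assert abs(s["Entropy"] - np.log(2)) < 1e-12

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((8, 8))
        p /= p.sum()
        G = GLCMMatrix(p=p, distance=1, angles=ANGLE_OFFSETS, symmetric=False, pair_count=100)
        s = glcm_statistics(G)
        expected = glcm_stats_bruteforce(p)
        assert set(s) == set(GLCM_STAT_NAMES)
        for name in GLCM_STAT_NAMES:
            assert s[name] == pytest.approx(expected[name], abs=1e-10), name


class TestFOSStatistics:
    def test_constant_roi_degenerate_values(self):
        s = fos_statistics(np.full(20, 42.0))
        assert s["Standard_deviation"] == 0
        assert s["Skewness"] == 0
        assert s["Kurtosis"] == 0
        assert s["Range_all"] == 0 and s["Range5"] == 0 and s["Range2"] == 0

    def test_direct_formulas_small_sample(self):
        s = fos_statistics(np.array([10, 20, 30, 40]))
        assert s["Mean"] == 25
        assert s["Range_all"] == 30

    def test_symmetric_sample_has_zero_skewness(self):
        assert fos_statistics(np.array([1, 2, 3, 4, 5]))["Skewness"] == pytest.approx(0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_direct_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(100, 30, size=int(rng.integers(5, 200)))
        s = fos_statistics(v)
        expected = fos_bruteforce(v)
        assert set(s) == set(FOS_NAMES)
        for name in FOS_NAMES:
            assert s[name] == pytest.approx(expected[name], abs=1e-10), name


class TestExtractFeatures:
    def test_exactly_130_named_features(self, rng):
        pixels = rng.integers(100, 256, (40, 40))
        mask = np.ones((40, 40), bool)
        f = extract_features(pixels, mask)
        assert len(f) == 130
        assert list(f.index) == list(FEATURE_NAMES)
        suffixed = [n for n in f.index if n.split("_")[-1] in {"1", "3", "5", "9", "11"}]
        assert len(suffixed) == 110
        assert f.notna().all() and np.isfinite(f).all()

    def test_deterministic(self, rng):
        pixels = rng.integers(100, 256, (40, 40))
        mask = np.ones((40, 40), bool)
        pd.testing.assert_series_equal(
            extract_features(pixels, mask), extract_features(pixels, mask)
        )

    def test_fos_invariant_under_mirroring(self, rng):
        pixels = rng.integers(100, 256, (30, 30))
        mask = rng.random((30, 30)) < 0.8
        f = extract_features(pixels, mask)
        f_mirror = extract_features(np.fliplr(pixels), np.fliplr(mask))
        pd.testing.assert_series_equal(f[list(FOS_NAMES)], f_mirror[list(FOS_NAMES)])

    def test_glcm_features_invariant_under_intensity_shift(self, rng):
        # min-max quantization removes any additive intensity offset
        pixels = rng.integers(100, 200, (30, 30)).astype(float)
        mask = np.ones((30, 30), bool)
        glcm_cols = [f"{s}_{d}" for s in GLCM_STAT_NAMES for d in DISTANCES]
        f = extract_features(pixels, mask)
        f_shift = extract_features(pixels + 37.0, mask)
        pd.testing.assert_series_equal(f[glcm_cols], f_shift[glcm_cols])

    def test_roi_too_small_names_image(self):
        pixels = np.arange(16).reshape(4, 4) * 20.0
        with pytest.raises(EmptyGLCMError, match="imgZ"):
            extract_features(pixels, np.ones((4, 4), bool), image_id="imgZ")


class TestPlantedTextureSensitivity:
    """Each generator texture channel moves its signature feature's group
    mean in the planted direction (high- vs low-latent groups)."""

    @pytest.mark.parametrize(
        "effect,feature",
        [
            (TextureEffect(0.0, 3.0, 0.0), "Standard_deviation"),
            (TextureEffect(0.5, 0.0, 0.0), "Cluster_shade_3"),
            (TextureEffect(0.0, 0.0, 0.2), "Skewness"),
        ],
        ids=["spread", "cluster_shade", "skew"],
    )
    def test_group_means_shift_in_planted_direction(self, effect, feature):
        params = SyntheticParams(
            n_images=8, image_shape=(96, 96), texture_effect=effect
        )
        rng = np.random.default_rng(1)
        means = {}
        for latent in (0.0, 100.0):
            vals = []
            for _ in range(200):
                img = generate_image(params, "Normal", latent, rng, laterality="L")
                mask = threshold_mask(img.pixels)
                roi = erode(mask, scaled_radius(img.pixels.shape[0]))
                vals.append(extract_features(img.pixels, roi.mask)[feature])
            means[latent] = np.mean(vals)
        assert means[100.0] > means[0.0]


class TestRadiomicFeatureExtractor:
    def test_sklearn_api_roundtrip(self, rng):
        est = RadiomicFeatureExtractor(n_levels=6)
        est2 = clone(est)
        assert est2.get_params()["n_levels"] == 6
        pixels = rng.integers(100, 256, (40, 40))
        mask = np.ones((40, 40), bool)
        out = est.fit([]).transform([(pixels, mask, "a"), (pixels, mask, "b")])
        assert out.shape == (2, 130)
        assert list(out.columns) == list(est.get_feature_names_out())
        np.testing.assert_allclose(out.iloc[0], out.iloc[1])
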