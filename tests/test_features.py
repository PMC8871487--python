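"""Feature definitions against brute-force oracles and invariances."""

import numpy as np
import pytest

from radstab.features import (BAND_NAMES, DiscretizationRule, FeatureConfig,
                              discretize, firstorder, shape2d,
                              glcm_features, glcm_matrix,
                              glrlm_features, glrlm_matrix,
                              glszm_features, glszm_matrix,
                              gldm_features, gldm_matrix,
                              extract_frame, wavelet_variants)
from radstab.features.extract import extract_all, long_to_wide, wide_to_long

import oracles

DIRECTIONS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]


def random_frame(rng, n=8, n_levels=4, p_mask=0.8):
    levels = rng.integers(1, n_levels + 1, (n, n))
    mask = rng.random((n, n)) < p_mask
    if mask.sum() < 2:
        mask[0, 0] = mask[0, 1] = True
    return levels, mask


class TestDiscretize:
    def test_constant_region_maps_to_level_one(self):
        lv, ng = discretize(np.full((4, 4), 3.3), np.ones((4, 4), bool),
                            DiscretizationRule(n_bins=32))
        assert set(lv.ravel()) == {1}

    def test_fixed_bin_width(self):
        img = np.arange(256, dtype=float).reshape(16, 16)
        lv, ng = discretize(img, np.ones((16, 16), bool),
                            DiscretizationRule(mode="fixed_bin_width", bin_width=64))
        assert ng == 4
        assert set(lv.ravel()) == {1, 2, 3, 4}

    def test_matches_brute_force_binning(self, rng):
        img = rng.normal(size=(10, 10))
        mask = rng.random((10, 10)) < 0.7
        mask[0, 0] = True
        lv, ng = discretize(img, mask, DiscretizationRule(n_bins=8))
        x = img[mask]
        lo, hi = x.min(), x.max()
        edges = np.linspace(lo, hi, 9)
        expected = np.clip(np.searchsorted(edges[1:-1], x, side="right") + 1, 1, 8)
        assert np.array_equal(np.sort(lv[mask]), np.sort(expected))
        assert lv[~mask].sum() == 0


class TestFirstOrder:
    def test_small_sample_arithmetic(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        f = firstorder(img, np.ones((2, 2), bool))
        assert f["Mean"] == 2.5
        assert f["Range"] == 3.0
        assert f["Median"] == 2.5

    def test_constant_region_histogram(self):
        f = firstorder(np.full((5, 5), 9.0), np.ones((5, 5), bool))
        assert f["Uniformity"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_gaussian_moments(self, rng):
        x = rng.standard_normal((40, 25))
        f = firstorder(x, np.ones(x.shape, bool))
        assert f["Skewness"] == pytest.approx(0.0, abs=0.25)
        assert f["Kurtosis"] == pytest.approx(0.0, abs=0.5)

    def test_moment_formula_oracle(self, rng):
        x = rng.normal(2.0, 3.0, size=(6, 6))
        f = firstorder(x, np.ones((6, 6), bool))
        v = x.ravel()
        assert f["Variance"] == pytest.approx(np.mean((v - v.mean()) ** 2), abs=1e-12)
        z = (v - v.mean()) / v.std()
        assert f["Skewness"] == pytest.approx(np.mean(z**3), abs=1e-12)
        assert f["MeanAbsoluteDeviation"] == pytest.approx(
            np.mean(np.abs(v - v.mean())), abs=1e-12)

    def test_shift_moves_mean_only(self, rng):
        img = rng.normal(size=(12, 12))
        mask = np.ones((12, 12), bool)
        cfg = FeatureConfig(families=("firstorder", "glcm"))
        a = extract_frame(img, mask, 1.0, cfg)
        b = extract_frame(img + 100.0, mask, 1.0, cfg)
        assert b["original.firstorder.Mean"] - a["original.firstorder.Mean"] == \
            pytest.approx(100.0, abs=1e-9)
        for k in a:
            if "glcm" in k:  # discretized features are shift-invariant
                assert b[k] == pytest.approx(a[k], abs=1e-9)


class TestShape2D:
    def test_disk_sphericity(self):
        yy, xx = np.mgrid[0:49, 0:49]
        disk = (yy - 24) ** 2 + (xx - 24) ** 2 <= 20**2
        s = shape2d(disk, 1.0)
        assert 0.95 <= s["Sphericity"] <= 1.02

    def test_two_to_one_ellipse_elongation(self):
        yy, xx = np.mgrid[0:64, 0:64]
        ell = ((xx - 31.5) / 24) ** 2 + ((yy - 31.5) / 12) ** 2 <= 1.0
        s = shape2d(ell, 1.0)
        # sqrt(lambda_minor/lambda_major) equals the semi-axis ratio b/a
        assert s["Elongation"] == pytest.approx(0.5, abs=0.05)
        # independent moment oracle on the rasterized ellipse
        pts = np.argwhere(ell).astype(float)
        evals = np.sort(np.linalg.eigvalsh(np.cov(pts.T, bias=True)))
        assert s["Elongation"] == pytest.approx(np.sqrt(evals[0] / evals[1]),
                                                abs=1e-9)

    def test_square_area_and_max_diameter(self):
        mask = np.zeros((16, 16), bool)
        mask[3:13, 3:13] = True
        s = shape2d(mask, 1.0)
        assert s["PixelSurface"] == 100.0
        # pixel-centre convention: corner-to-corner distance is 9*sqrt(2)
        assert s["MaximumDiameter"] == pytest.approx(9 * np.sqrt(2), abs=1.0)
        # exhaustive pairwise oracle
        pts = np.argwhere(mask).astype(float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)).max()
        assert s["MaximumDiameter"] == pytest.approx(d, abs=1e-12)

    def test_rejects_empty_and_disconnected(self):
        with pytest.raises(ValueError):
            shape2d(np.zeros((4, 4), bool), 1.0)
        two = np.zeros((8, 8), bool)
        two[0, 0] = two[7, 7] = True
        with pytest.raises(ValueError):
            shape2d(two, 1.0)


class TestMatrixOracles:
    """Implementation vs plain-loop enumeration on random 8x8 frames."""

    @pytest.mark.parametrize("seed", range(25))
    def test_matrices_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        levels, mask = random_frame(rng)
        ng = 4
        for off in DIRECTIONS:
            assert np.array_equal(glcm_matrix(levels, mask, off, ng),
                                  oracles.glcm_pairs(levels.tolist(), mask.tolist(),
                                                     off, ng))
            assert np.array_equal(
                glrlm_matrix(levels, mask, off, ng),
                oracles.glrlm_runs(levels.tolist(), mask.tolist(), off, ng, 8))
        assert np.array_equal(
            glszm_matrix(levels, mask, ng),
            oracles.glszm_zones(levels.tolist(), mask.tolist(), ng, int(mask.sum())))
        assert np.array_equal(gldm_matrix(levels, mask, ng),
                              oracles.gldm_dependences(levels.tolist(), mask.tolist(), ng))

    def test_hand_counted_two_by_two(self):
        levels = np.array([[1, 1], [2, 2]])
        mask = np.ones((2, 2), bool)
        m0 = glcm_matrix(levels, mask, (0, 1), 2)
        assert np.array_equal(m0, [[2, 0], [0, 2]])   # (1,1) and (2,2), symmetric
        m90 = glcm_matrix(levels, mask, (-1, 0), 2)
        assert np.array_equal(m90, [[0, 2], [2, 0]])  # two (1,2) pairs, symmetric

    def test_checkerboard_contrast_and_energy(self):
        levels = 1 + (np.indices((8, 8)).sum(axis=0) % 2)
        mask = np.ones((8, 8), bool)
        f = glcm_features(levels, mask, 2)
        # 0 and 90 degrees alternate strictly: per-direction joint energy 0.5,
        # contrast 1; diagonals are constant-level: energy 1, contrast 0
        m0 = glcm_matrix(levels, mask, (0, 1), 2) / glcm_matrix(levels, mask, (0, 1), 2).sum()
        assert np.allclose(m0, [[0, 0.5], [0.5, 0]])
        assert f["Contrast"] == pytest.approx(0.5)   # mean of (1, 0, 1, 0)
        assert f["JointEnergy"] == pytest.approx(0.5, abs=0.01)

    def test_constant_region_degenerate_conventions(self):
        levels = np.ones((5, 5), int)
        mask = np.ones((5, 5), bool)
        f = glcm_features(levels, mask, 1)
        assert f["Contrast"] == 0.0
        assert f["JointEntropy"] == 0.0
        assert f["Correlation"] == 1.0  # convention for zero variance
        z = glszm_features(levels, mask, 1)
        assert z["SizeZoneNonUniformity"] == 1.0  # single zone
        assert z["ZonePercentage"] == pytest.approx(1 / 25)

    def test_single_row_run_counts(self):
        levels = np.array([[1, 1, 2, 2]])
        mask = np.ones((1, 4), bool)
        m = glrlm_matrix(levels, mask, (0, 1), 2)
        assert m[0, 1] == 1 and m[1, 1] == 1 and m.sum() == 2
        f = glrlm_features(levels, mask, 2)
        assert np.isfinite(list(f.values())).all()

    def test_rotation_invariance_of_direction_averaged_features(self, rng):
        levels, mask = random_frame(rng, n=10)
        for fn in (glcm_features, glrlm_features, glszm_features, gldm_features):
            a = fn(levels, mask, 4)
            b = fn(np.rot90(levels).copy(), np.rot90(mask).copy(), 4)
            for k in a:
                assert a[k] == pytest.approx(b[k], abs=1e-12), (fn.__name__, k)

    def test_normalizations_sum_to_one(self, rng):
        levels, mask = random_frame(rng)
        for off in DIRECTIONS:
            m = glcm_matrix(levels, mask, off, 4)
            if m.sum():
                assert (m / m.sum()).sum() == pytest.approx(1.0, abs=1e-12)


class TestWavelets:
    def test_constant_image_has_no_detail(self):
        bands = wavelet_variants(np.full((16, 16), 5.0))
        for name in ("LH", "HL", "HH"):
            assert np.abs(bands[name]).max() < 1e-8

    def test_horizontal_ramp_band_selectivity(self):
        ramp = np.tile(np.arange(16.0), (16, 1))  # varies along x only
        bands = wavelet_variants(ramp)
        assert (bands["HL"] ** 2).sum() < 1e-12   # no vertical detail
        assert (bands["LH"] ** 2).sum() > 1.0

    def test_band_shapes_match_frame(self):
        img = np.random.default_rng(0).normal(size=(13, 9))
        bands = wavelet_variants(img)
        assert set(bands) == set(BAND_NAMES)
        assert all(b.shape == (13, 9) for b in bands.values())

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError):
            wavelet_variants(np.ones((6, 6)))


class TestExtractAll:
    def test_feature_count_bookkeeping(self, rng):
        img = rng.normal(size=(16, 16))
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        n_int = len(extract_frame(img, mask, 1.0,
                                  FeatureConfig(wavelets=False))) - 8  # minus shape
        full = extract_frame(img, mask, 1.0, FeatureConfig(wavelets=True))
        assert len(full) == 5 * n_int + 8

    def test_rows_and_determinism(self, small_cohort, small_feature_table):
        # 8 lesions x (1 manual + 12 variants) rows
        assert small_feature_table.shape[0] == 8 * 13
        assert small_feature_table.index.is_unique
        assert np.isfinite(small_feature_table.to_numpy()).all()

    def test_lesion_order_permutation_invariance(self, small_cohort):
        from radstab import preprocess
        rule = preprocess.CropRule(box_size=40)
        kept, _ = preprocess.crop_cohort(small_cohort.cases[:3], rule)
        t1 = extract_all(kept, FeatureConfig())
        kept_rev, _ = preprocess.crop_cohort(small_cohort.cases[:3][::-1], rule)
        t2 = extract_all(kept_rev, FeatureConfig())
        assert t1.sort_index().equals(t2.sort_index())

    def test_long_wide_round_trip(self, small_feature_table):
        long = wide_to_long(small_feature_table)
        back = long_to_wide(long)
        back.index.names = small_feature_table.index.names
        back = back[small_feature_table.columns]  # pivot sorts columns
        assert np.allclose(back.sort_index().to_numpy(),
                           small_feature_table.sort_index().to_numpy())
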