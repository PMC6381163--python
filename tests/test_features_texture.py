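import numpy as np
import pytest

from radln.features import texture as tx
from radln.features.texture import (PreconditionError, compute_glcm,
                                    dependence_matrix, glgcm_features,
                                    glrlm_features, gray_gradient_matrix,
                                    haralick_features, histogram_features,
                                    ngldm_features, quantize_gray_levels,
                                    run_length_matrix, tamura_features)

import oracles
from conftest import random_masked_image

ORACLE_SEEDS = list(range(50))


def full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestQuantize:
    def test_constant_region_all_level_zero(self):
        q = quantize_gray_levels(np.full((5, 5), 0.4), full_mask((5, 5)), 16)
        assert (q.levels == 0).all()

    def test_range_endpoints(self):
        img = np.array([[0.0, 1.0]])
        q = quantize_gray_levels(img, full_mask((1, 2)), 16)
        assert q.levels.tolist() == [[0, 15]]

    def test_uniform_ramp_equal_occupancy(self):
        # direct binning oracle: 64-pixel ramp into 4 bins -> 16 per bin (+-1)
        img = np.linspace(0, 1, 64).reshape(8, 8)
        q = quantize_gray_levels(img, full_mask((8, 8)), 4)
        counts = np.bincount(q.levels.ravel(), minlength=4)
        assert (np.abs(counts - 16) <= 1).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(PreconditionError):
            quantize_gray_levels(np.zeros((3, 3)), np.zeros((3, 3), bool), 8)

    def test_shift_invariance(self, rng):
        img = rng.random((8, 8))
        mask = rng.random((8, 8)) < 0.8
        q1 = quantize_gray_levels(img, mask, 16)
        q2 = quantize_gray_levels(img + 0.17, mask, 16)
        np.testing.assert_array_equal(q1.levels[mask], q2.levels[mask])


class TestGLCM:
    def test_constant_region_single_cell(self):
        q = quantize_gray_levels(np.full((4, 4), 0.5), full_mask((4, 4)), 16)
        P = compute_glcm(q)
        assert P.matrix[0, 0] == pytest.approx(1.0)
        assert P.matrix.sum() == pytest.approx(1.0)

    def test_toy_image_horizontal_counts(self):
        # 0011 / 0011 / 0222 / 2233, horizontal only, symmetric counts:
        # 12 adjacent pairs counted in both directions -> total 24; the four
        # (0,0) pairs come from rows 1-3: (0,0),(0,0) in rows 1 and 2 -> 2
        # pairs, doubled = 4
        levels = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
        q = tx.QuantizedImage(levels=levels, n_levels=4,
                              mask=full_mask((4, 4)), bounds=(0, 3))
        P = compute_glcm(q, angles=(0,), normalized=False)
        assert P.matrix.sum() == 24
        assert P.matrix[0, 0] == 4
        expected = oracles.glcm_by_enumeration(levels, full_mask((4, 4)), 4,
                                               angles=(0,))
        np.testing.assert_array_equal(P.matrix, expected)

    def test_checkerboard_no_diagonal_mass(self):
        levels = np.indices((6, 6)).sum(axis=0) % 2
        q = tx.QuantizedImage(levels=levels, n_levels=2,
                              mask=full_mask((6, 6)), bounds=(0, 1))
        P = compute_glcm(q, angles=(0,))
        assert P.matrix[0, 0] == 0 and P.matrix[1, 1] == 0

    @pytest.mark.parametrize("seed", ORACLE_SEEDS)
    def test_matches_enumeration_on_random_masked_images(self, seed):
        levels, mask = random_masked_image(seed)
        q = tx.QuantizedImage(levels=levels, n_levels=4, mask=mask, bounds=(0, 3))
        try:
            P = compute_glcm(q, normalized=False)
        except PreconditionError:
            return
        expected = oracles.glcm_by_enumeration(levels, mask, 4)
        np.testing.assert_array_equal(P.matrix, expected)

    def test_no_pairs_rejected(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = mask[3, 3] = True   # isolated pixels
        q = quantize_gray_levels(np.eye(5), mask, 4)
        with pytest.raises(PreconditionError):
            compute_glcm(q, angles=(0,))


class TestHaralick:
    def test_constant_image_degenerate_conventions(self):
        P = np.zeros((16, 16)); P[0, 0] = 1.0
        f = haralick_features(P)
        assert f["glcm_energy"] == 1.0
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_inverse_difference_moment"] == 1.0
        assert f["glcm_correlation"] == 0.0

    def test_uniform_matrix_closed_form(self):
        P = np.full((4, 4), 1 / 16)
        f = haralick_features(P)
        assert f["glcm_entropy"] == pytest.approx(4.0)       # log2(16) bits
        assert f["glcm_energy"] == pytest.approx(1 / 16)

    @pytest.mark.parametrize("seed", ORACLE_SEEDS[:10])
    def test_matches_double_loop_oracle(self, seed):
        levels, mask = random_masked_image(seed)
        q = tx.QuantizedImage(levels=levels, n_levels=4, mask=mask, bounds=(0, 3))
        try:
            P = compute_glcm(q)
        except PreconditionError:
            return
        expected = oracles.haralick_by_double_loop(P.matrix)
        ours = haralick_features(P)
        for k in expected:
            assert ours[k] == pytest.approx(expected[k], abs=1e-10), k

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            haralick_features(np.ones((4, 4)))


class TestGLRLM:
    def test_single_run_closed_form(self):
        levels = np.zeros((1, 4), dtype=int)
        q = tx.QuantizedImage(levels=levels, n_levels=4,
                              mask=full_mask((1, 4)), bounds=(0, 1))
        f = glrlm_features(q, angles=(0,))
        assert f["glrlm_sre"] == pytest.approx(1 / 16)
        assert f["glrlm_lre"] == pytest.approx(16)
        assert f["glrlm_rp"] == pytest.approx(1 / 4)

    def test_alternating_unit_runs(self):
        levels = np.array([[0, 1, 0, 1, 0, 1]])
        q = tx.QuantizedImage(levels=levels, n_levels=2,
                              mask=full_mask((1, 6)), bounds=(0, 1))
        f = glrlm_features(q, angles=(0,))
        assert f["glrlm_sre"] == pytest.approx(1.0)
        assert f["glrlm_lre"] == pytest.approx(1.0)
        assert f["glrlm_rp"] == pytest.approx(1.0)

    def test_mask_gap_breaks_runs(self):
        levels = np.zeros((1, 5), dtype=int)
        mask = np.array([[True, True, False, True, True]])
        q = tx.QuantizedImage(levels=levels, n_levels=2, mask=mask, bounds=(0, 0))
        R = run_length_matrix(q, 0)
        assert R[0, 1] == 2          # two runs of length 2
        assert R.sum() == 2

    @pytest.mark.parametrize("seed", ORACLE_SEEDS)
    def test_matches_run_scanning_oracle(self, seed):
        levels, mask = random_masked_image(seed, n_levels=2)
        q = tx.QuantizedImage(levels=levels, n_levels=2, mask=mask, bounds=(0, 1))
        ours = glrlm_features(q)
        expected = oracles.glrlm_by_scanning(levels, mask, 2)
        for k in expected:
            assert ours[k] == pytest.approx(expected[k], abs=1e-10), k

    def test_run_pixel_total_conservation(self):
        # sum of run length * count = in-mask pixel count, per angle
        for seed in range(10):
            levels, mask = random_masked_image(seed)
            q = tx.QuantizedImage(levels=levels, n_levels=4, mask=mask,
                                  bounds=(0, 3))
            for ang in (0, 90):
                R = run_length_matrix(q, ang)
                r = np.arange(1, R.shape[1] + 1)
                assert (R * r).sum() == mask.sum()


class TestGLGCM:
    def test_constant_region_degenerate(self):
        f = glgcm_features(np.full((6, 6), 0.5), full_mask((6, 6)))
        assert f["glgcm_energy"] == pytest.approx(1.0)
        assert f["glgcm_mixed_entropy"] == 0.0
        assert f["glgcm_gray_entropy"] == 0.0
        assert f["glgcm_inertia"] == 0.0
        assert f["glgcm_correlation"] == 0.0

    def test_ramp_single_gradient_level(self):
        # vertical ramp: constant gradient -> one gradient level -> gradient
        # nonuniformity at its maximum (1); gray marginal spread over levels.
        # Mask excludes the image border where Sobel edge padding perturbs
        # the otherwise-constant gradient.
        img = np.tile(np.linspace(0, 1, 12)[:, None], (1, 12))
        mask = np.zeros((12, 12), bool)
        mask[1:-1, 1:-1] = True
        f = glgcm_features(img, mask, gray_levels=8)
        assert f["glgcm_gradient_nonuniformity"] == pytest.approx(1.0)
        assert f["glgcm_gray_nonuniformity"] < 0.5

    @pytest.mark.parametrize("seed", ORACLE_SEEDS[:15])
    def test_matches_double_loop_oracle(self, seed):
        g = np.random.default_rng(seed)
        img = g.random((10, 10))
        mask = g.random((10, 10)) < 0.85
        if mask.sum() < 9:
            return
        H = gray_gradient_matrix(img, mask, gray_levels=16, gradient_levels=8)
        expected = oracles.glgcm_descriptors_by_double_loop(H)
        ours = tx.glgcm_descriptors(H)
        for k in expected:
            assert ours[k] == pytest.approx(expected[k], abs=1e-10), k

    def test_mask_too_small(self):
        with pytest.raises(PreconditionError):
            glgcm_features(np.random.default_rng(0).random((4, 4)),
                           np.eye(4, dtype=bool))


class TestNGLDM:
    def test_constant_region(self):
        q = quantize_gray_levels(np.full((4, 4), 0.3), full_mask((4, 4)), 8)
        f = ngldm_features(q)
        # 4 interior pixels, each with 8 equal neighbors
        assert f["ngldm_entropy"] == 0.0
        assert f["ngldm_second_moment"] == pytest.approx(4.0)   # = N
        assert f["ngldm_large_number_emphasis"] == pytest.approx(64.0)

    def test_checkerboard_zero_dependence(self):
        levels = np.indices((5, 5)).sum(axis=0) % 2
        q = tx.QuantizedImage(levels=levels, n_levels=2,
                              mask=full_mask((5, 5)), bounds=(0, 1))
        Q = dependence_matrix(q, distance=1, tolerance=0)
        # the 4 edge neighbors differ, the 4 diagonal neighbors are equal:
        # every interior pixel has dependence exactly 4
        assert Q[:, 4].sum() == 9
        assert Q.sum() == 9

    @pytest.mark.parametrize("seed", ORACLE_SEEDS)
    def test_matches_neighbor_counting_oracle(self, seed):
        levels, mask = random_masked_image(seed, n_levels=2)
        q = tx.QuantizedImage(levels=levels, n_levels=2, mask=mask, bounds=(0, 1))
        try:
            Q = dependence_matrix(q)
        except PreconditionError:
            return
        expected = oracles.ngldm_by_counting(levels, mask, 2)
        np.testing.assert_array_equal(Q, expected)

    def test_interior_count_conservation(self):
        from scipy import ndimage
        for seed in range(10):
            levels, mask = random_masked_image(seed)
            q = tx.QuantizedImage(levels=levels, n_levels=4, mask=mask,
                                  bounds=(0, 3))
            interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
            if not interior.any():
                continue
            assert dependence_matrix(q).sum() == interior.sum()

    def test_no_interior_rejected(self):
        q = quantize_gray_levels(np.ones((2, 8)), full_mask((2, 8)), 4)
        with pytest.raises(PreconditionError):
            ngldm_features(q)


class TestTamura:
    def test_constant_region_degenerate(self):
        f = tamura_features(np.full((12, 12), 0.6), full_mask((12, 12)))
        assert f["tamura_contrast"] == 0.0
        assert f["tamura_coarseness"] == 1.0     # k*=0 by the tie rule
        assert f["tamura_directionality"] == 0.0

    def test_two_level_contrast_closed_form(self):
        # two-point distribution with p=q=1/2 at {0.2, 0.8}:
        # sigma = 0.3, kurtosis = mu4/sigma^4 = 1 -> contrast = 0.3
        img = np.zeros((8, 8)) + 0.2
        img[:, ::2] = 0.8
        f = tamura_features(img, full_mask((8, 8)))
        assert f["tamura_contrast"] == pytest.approx(0.3, abs=1e-12)

    def test_stripes_more_directional_than_noise(self):
        wins = 0
        for rep in range(20):
            g = np.random.default_rng(rep)
            stripes = np.tile((np.arange(16) % 4 < 2).astype(float), (16, 1)) \
                + 0.05 * g.standard_normal((16, 16))
            noise = g.random((16, 16))
            m = full_mask((16, 16))
            d_s = tamura_features(stripes, m)["tamura_directionality"]
            d_n = tamura_features(noise, m)["tamura_directionality"]
            wins += d_s > d_n
        assert wins >= 18

    def test_small_bbox_rejected(self):
        with pytest.raises(PreconditionError):
            tamura_features(np.ones((6, 6)), full_mask((6, 6)))


class TestHistogram:
    def test_constant_region(self):
        f = histogram_features(np.full((5, 5), 0.4), full_mask((5, 5)))
        assert f["hist_mean"] == pytest.approx(0.4)
        assert f["hist_variance"] == pytest.approx(0.0, abs=1e-12)
        assert f["hist_skewness"] == 0.0
        assert f["hist_kurtosis"] == 0.0
        assert f["hist_energy"] == 1.0
        assert f["hist_entropy"] == 0.0

    def test_uniform_histogram_closed_form(self):
        # one pixel per bin -> uniform p over 256 bins
        img = np.arange(256, dtype=float).reshape(16, 16) / 255
        f = histogram_features(img, full_mask((16, 16)))
        assert f["hist_entropy"] == pytest.approx(8.0)
        assert f["hist_energy"] == pytest.approx(1 / 256)

    def test_two_point_distribution(self):
        img = np.array([[0.2, 0.8], [0.8, 0.2]])
        f = histogram_features(img, full_mask((2, 2)))
        assert f["hist_mean"] == pytest.approx(0.5)
        assert f["hist_variance"] == pytest.approx(0.09)
        assert f["hist_entropy"] == pytest.approx(1.0)


class TestCrossFamilyInvariants:
    def test_gray_level_shift_invariance(self):
        # adding a constant leaves every quantized-matrix feature unchanged
        g = np.random.default_rng(5)
        img = g.random((12, 12)) * 0.5
        mask = g.random((12, 12)) < 0.9
        for fn in (
            lambda im: haralick_features(compute_glcm(
                quantize_gray_levels(im, mask, 16))),
            lambda im: glrlm_features(quantize_gray_levels(im, mask, 16)),
            lambda im: ngldm_features(quantize_gray_levels(im, mask, 16)),
            lambda im: glgcm_features(im, mask, gray_levels=16),
        ):
            a, b = fn(img), fn(img + 0.3)
            for k in a:
                assert a[k] == pytest.approx(b[k], abs=1e-9), k

    def test_rotation_consistency(self):
        # 90-degree rotation leaves angle-averaged GLCM/GLRLM unchanged
        g = np.random.default_rng(6)
        img = g.random((10, 10))
        mask = g.random((10, 10)) < 0.9
        imr, mr = np.rot90(img), np.rot90(mask)
        a = haralick_features(compute_glcm(quantize_gray_levels(img, mask, 8)))
        b = haralick_features(compute_glcm(quantize_gray_levels(imr, mr, 8)))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k
        a = glrlm_features(quantize_gray_levels(img, mask, 8))
        b = glrlm_features(quantize_gray_levels(imr, mr, 8))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k

    def test_entropy_nonnegative_energy_in_unit_interval(self):
        g = np.random.default_rng(8)
        img = g.random((12, 12))
        mask = g.random((12, 12)) < 0.9
        vals = {}
        vals |= haralick_features(compute_glcm(quantize_gray_levels(img, mask, 16)))
        vals |= glgcm_features(img, mask, gray_levels=16)
        vals |= ngldm_features(quantize_gray_levels(img, mask, 16))
        vals |= histogram_features(img, mask)
        for k, v in vals.items():
            if k.endswith("entropy"):
                assert v >= 0, k
            if k.endswith("energy"):
                assert 0 < v <= 1, k
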