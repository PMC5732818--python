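"""Worked-example and property tests for the feature families."""

import numpy as np
import pytest
from scipy import ndimage

from brute_force import ngtdm_sums
from ecrad.features import glgcm, matrices
from ecrad.features.histogram import first_order_stats, histogram_features
from ecrad.features.manifest import feature_manifest
from ecrad.features.shape import shape_features
from ecrad.features.transforms import gabor_bank, gabor_features, log_features
from ecrad.preprocess import quantize_gray_levels


def full(shape):
    return np.ones(shape, dtype=bool)


class TestManifest:
    def test_inventory_counts(self):
        m = feature_manifest()
        assert len(m) == 214
        assert m.count(dimensionality="3D") == 60
        assert m.count(dimensionality="2D") == 154
        assert len(set(m.names)) == 214

    def test_family_breakdown(self):
        m = feature_manifest()
        assert m.count(family="shape") == 4
        assert m.count(family="histogram") == 12
        assert m.count(family="transform") == 80
        assert m.count(family="texture") == 214 - 4 - 12 - 80


class TestHistogram:
    def test_symmetric_sample_has_zero_skewness(self):
        s = first_order_stats(np.array([1, 2, 3]), 16)
        assert s["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert s["mean"] == 2.0

    def test_moments_match_direct_computation(self):
        x = np.array([0, 0, 0, 0, 15], dtype=float)
        s = first_order_stats(x, 16)
        mu, var = x.mean(), x.var()
        z = (x - mu) / np.sqrt(var)
        assert s["variance"] == pytest.approx(var)
        assert s["skewness"] == pytest.approx((z ** 3).mean())
        assert s["kurtosis"] == pytest.approx((z ** 4).mean())

    def test_single_level_delta_histogram(self):
        s = first_order_stats(np.full(9, 5.0), 16)
        assert s == {"mean": 5.0, "variance": 0.0, "skewness": 0.0,
                     "kurtosis": 0.0, "energy": 1.0, "entropy": 0.0}

    def test_entropy_nondecreasing_in_quantization_depth(self, rng):
        """Finer gray-level quantization cannot lose histogram information."""
        data = rng.normal(size=(12, 12, 12))
        mask = rng.random(data.shape) < 0.7
        entropies = []
        for k in (4, 5, 6, 7):
            roi = quantize_gray_levels(data, mask, k=k)
            h = histogram_features(roi.levels, mask, 2 ** k)
            entropies.append(h["entropy"])
        assert all(b >= a - 1e-9 for a, b in zip(entropies, entropies[1:]))


class TestGlcm:
    def test_worked_3x3_example(self):
        img = np.array([[0, 0, 1], [0, 1, 1], [2, 2, 2]])
        counts = matrices.glcm_matrix(img, full(img.shape), 3, offsets=[(0, 1)])
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 0] = 2
        expected[0, 1] = expected[1, 0] = 2
        expected[1, 1] = 2
        expected[2, 2] = 4
        np.testing.assert_array_equal(counts, expected)
        assert counts.sum() == 12

    def test_constant_image_degenerate_features(self):
        img = np.zeros((4, 4), dtype=int)
        f = matrices.glcm_features(
            matrices.glcm_matrix(img, full(img.shape), 4))
        assert f["Entropy"] == 0.0
        assert f["Energy"] == 1.0
        assert f["Contrast"] == 0.0
        assert f["Correlation"] == 0.0  # zero-variance convention

    def test_checkerboard_contrast_and_energy(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        f = matrices.glcm_features(
            matrices.glcm_matrix(img, full(img.shape), 2, offsets=[(0, 1)]))
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Energy"] == pytest.approx(0.5)

    def test_rotation_invariance_of_direction_averaged_features(self, rng):
        """The symmetric 4-direction 2D matrix is unchanged by 90-degree
        image rotation (the offset set maps onto itself up to sign)."""
        img = rng.integers(0, 5, size=(7, 9))
        a = matrices.glcm_matrix(img, full(img.shape), 5)
        b = matrices.glcm_matrix(np.rot90(img), full((9, 7)), 5)
        np.testing.assert_array_equal(a, b)


class TestGlrlm:
    def test_single_row_run_enumeration(self):
        img = np.array([[0, 0, 0, 1]])
        counts = matrices.glrlm_matrix(img, full(img.shape), 2, (0, 1))
        assert counts[0, 2] == 1  # run of level 0, length 3
        assert counts[1, 0] == 1  # run of level 1, length 1
        assert counts.sum() == 2
        f = matrices._rl_style_features(counts, 4, matrices._GLRLM_NAMES)
        assert f["RP"] == pytest.approx(2 / 4)

    def test_constant_row_long_run_emphasis(self):
        img = np.zeros((1, 8), dtype=int)
        counts = matrices.glrlm_matrix(img, full(img.shape), 2, (0, 1))
        f = matrices._rl_style_features(counts, 8, matrices._GLRLM_NAMES)
        assert f["LRE"] == pytest.approx(64.0)

    def test_alternating_row_short_run_emphasis(self):
        img = np.array([[0, 1, 0, 1]])
        counts = matrices.glrlm_matrix(img, full(img.shape), 2, (0, 1))
        f = matrices._rl_style_features(counts, 4, matrices._GLRLM_NAMES)
        assert f["SRE"] == pytest.approx(1.0)

    def test_rotation_invariance_of_direction_average(self, rng):
        img = rng.integers(0, 4, size=(6, 8))
        fa = matrices.glrlm_features(img, full(img.shape), 4)
        fb = matrices.glrlm_features(np.rot90(img), full((8, 6)), 4)
        for k in fa:
            assert fa[k] == pytest.approx(fb[k], rel=1e-12), k


class TestGlszm:
    def test_zone_sizes_4_1_1(self):
        img = np.array([
            [0, 0, 1],
            [0, 0, 2],
            [3, 3, 3],
        ])
        # restrict mask so zones have sizes {4, 1, 1}
        mask = np.array([[1, 1, 1], [1, 1, 1], [0, 0, 0]], dtype=bool)
        f = matrices.glszm_features(img, mask, 4)
        assert f["LZE"] == pytest.approx((16 + 1 + 1) / 3)

    def test_constant_image_single_zone(self):
        img = np.zeros((3, 4), dtype=int)
        f = matrices.glszm_features(img, full(img.shape), 2)
        assert f["LZE"] == pytest.approx(144.0)

    def test_all_distinct_levels(self):
        img = np.arange(9).reshape(3, 3)
        f = matrices.glszm_features(img, full(img.shape), 9)
        assert f["LZE"] == pytest.approx(1.0)
        assert f["SZE"] == pytest.approx(1.0)


class TestNgtdm:
    def test_constant_image(self):
        img = np.zeros((4, 4), dtype=int)
        f = matrices.ngtdm_features(img, full(img.shape), 4)
        assert f["Contrast"] == 0.0

    def test_center_pixel_difference_by_hand(self):
        img = np.zeros((3, 3), dtype=int)
        img[1, 1] = 3
        n_i, s_i = matrices.ngtdm_table(img, full(img.shape), 4)
        # center: |3 - 0| = 3; each border pixel sees the center among its
        # neighbors -> s_0 = sum over 8 border pixels of 3/n_neighbors
        assert s_i[3] == pytest.approx(3.0)
        corner = 3 / 3          # corners have 3 neighbors, one is the center
        edge = 3 / 5            # edge centers have 5 neighbors
        assert s_i[0] == pytest.approx(4 * corner + 4 * edge)
        n_ref, s_ref = ngtdm_sums(img, full(img.shape), 4)
        np.testing.assert_allclose(s_i, s_ref)
        np.testing.assert_allclose(n_i, n_ref)

    def test_smooth_gradient_coarser_than_checkerboard(self):
        grad = np.repeat(np.arange(8) // 4, 8).reshape(8, 8).astype(int)
        checker = np.indices((8, 8)).sum(axis=0) % 2
        f_grad = matrices.ngtdm_features(grad, full((8, 8)), 2)
        f_check = matrices.ngtdm_features(checker, full((8, 8)), 2)
        assert f_grad["Coarseness"] > f_check["Coarseness"]


class TestGlgcm:
    def test_constant_section_all_mass_in_bin_zero(self):
        img = np.full((5, 5), 3, dtype=int)
        counts = glgcm.glgcm_matrix(img, full(img.shape), 4)
        assert counts.sum() == 9  # 3x3 interior of a 5x5 section
        assert counts[:, 1:].sum() == 0

    def test_joint_histogram_conserves_interior_pixels(self, rng):
        img = rng.integers(0, 8, size=(9, 9))
        mask = rng.random((9, 9)) < 0.9
        counts = glgcm.glgcm_matrix(img, mask, 8)
        interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
        assert counts.sum() == interior.sum()

    def test_vertical_step_concentrates_gradient_mass(self):
        img = np.zeros((4, 4), dtype=int)
        img[:, 2:] = 1
        counts = glgcm.glgcm_matrix(img, full(img.shape), 2)
        # interior pixels: columns 1-2 of rows 1-2; all four sit on the step
        # and share one gradient magnitude -> one nonzero gradient bin per level
        assert counts.sum() == 4
        nz_cols = np.nonzero(counts.sum(axis=0))[0]
        assert len(nz_cols) == 1


class TestShape:
    def test_digital_sphere(self):
        z, y, x = np.mgrid[-12:13, -12:13, -12:13]
        mask = (x ** 2 + y ** 2 + z ** 2) <= 100
        f = shape_features(mask, (1, 1, 1))
        assert f["solidity"] > 0.95
        assert f["eccentricity"] < 0.1
        assert f["size"] == pytest.approx(20.0, abs=1.0)
        assert f["volume"] == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        f = shape_features(mask, (0.97, 0.97, 2.5))
        assert f["volume"] == pytest.approx(0.97 * 0.97 * 2.5)
        assert f["size"] == 0.0
        assert f["solidity"] == 1.0
        assert f["eccentricity"] == 0.0

    def test_two_to_one_ellipsoid_eccentricity(self):
        z, y, x = np.mgrid[-20:21, -20:21, -20:21]
        mask = (x / 20.0) ** 2 + (y / 10.0) ** 2 + (z / 10.0) ** 2 <= 1
        f = shape_features(mask, (1, 1, 1))
        assert f["eccentricity"] == pytest.approx(np.sqrt(1 - 0.25), abs=0.05)


class TestLog:
    def test_constant_image_degenerate_conventions(self):
        img = np.full((24, 24), 9.0)
        f = log_features(img, full(img.shape))
        for sigma in ("1", "2", "2.5"):
            # truncated discrete LoG kernels leave a tiny DC residual, so
            # the mean is only near zero; the response is exactly flat
            assert f[f"sigma{sigma}_mean"] == pytest.approx(0.0, abs=0.01)
            assert f[f"sigma{sigma}_variance"] == pytest.approx(0.0, abs=1e-9)
            assert f[f"sigma{sigma}_energy"] == 1.0
            assert f[f"sigma{sigma}_entropy"] == 0.0

    def test_delta_input_reproduces_negated_kernel_peak(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        resp = ndimage.gaussian_laplace(img, 1.0, mode="nearest")
        assert np.unravel_index(np.abs(resp).argmax(), resp.shape) == (15, 15)
        assert resp[15, 15] < 0  # center of the (negated) LoG kernel

    @pytest.mark.parametrize("blob_sigma,expected", [(1.0, 1.0), (2.0, 2.0)])
    def test_scale_selectivity_on_gaussian_blob(self, blob_sigma, expected):
        """With scale normalization (sigma^2), the filter closest to the blob
        scale responds strongest; oracle = evaluating all three filters."""
        grid = np.arange(41) - 20.0
        xx, yy = np.meshgrid(grid, grid)
        blob = np.exp(-(xx ** 2 + yy ** 2) / (2 * blob_sigma ** 2))
        peaks = {}
        for sigma in (1.0, 2.0, 2.5):
            resp = ndimage.gaussian_laplace(blob, sigma, mode="nearest")
            peaks[sigma] = sigma ** 2 * np.abs(resp).max()
        assert max(peaks, key=peaks.get) == expected


class TestGabor:
    def test_bank_has_40_filters(self):
        bank = gabor_bank()
        assert len(bank) == 40
        assert {(s, o) for s, o, _ in bank} == {
            (s, o) for s in range(1, 6) for o in range(1, 9)}

    def test_zero_image_all_msa_zero(self):
        img = np.zeros((24, 24))
        f = gabor_features(img, full(img.shape))
        for s in range(1, 6):
            for o in range(1, 9):
                assert f[f"MSA-{s}{o}"] == 0.0
                assert f[f"MSE-{s}{o}"] == 0.0

    @pytest.mark.parametrize("o_true", [1, 3, 5])
    def test_grating_orientation_selectivity(self, o_true):
        """A sinusoidal grating at orientation (o-1)*pi/8 and a bank frequency
        maximizes MSA at that orientation among the 8 filters of its scale."""
        freqs = np.geomspace(0.05, 0.4, 5)
        s = 4
        theta = (o_true - 1) * np.pi / 8
        grid = np.arange(48)
        rr, cc = np.meshgrid(grid, grid, indexing="ij")
        # image convention: theta measured with x = columns, y = rows
        phase = 2 * np.pi * freqs[s - 1] * (cc * np.cos(theta)
                                            + rr * np.sin(theta))
        img = np.cos(phase)
        f = gabor_features(img, full(img.shape))
        msa = {o: f[f"MSA-{s}{o}"] for o in range(1, 9)}
        assert max(msa, key=msa.get) == o_true
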