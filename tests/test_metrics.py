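"""Evaluation metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

from staincycle.imaging_io import ImageTile
from staincycle.metrics import (SSIMParams, evaluate_sets, fid,
                                fid_from_moments, kid, pcc, psnr,
                                random_projection_embedding, ssim_index)
from staincycle.synthetic_microscopy import SceneParams, generate_dataset


class TestPSNR:
    def test_identical_images_return_infinity(self, rng):
        a = rng.random((8, 8))
        assert psnr(a, a.copy()) == float("inf")

    def test_full_scale_error_is_zero_db(self):
        a = np.zeros((4, 4))
        b = np.ones((4, 4))
        assert psnr(a, b, max_value=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_mse_gives_twenty_db(self):
        # MSE = MAX^2/100 -> 10 log10(100) = 20 dB
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)
        assert psnr(a, b, max_value=1.0) == pytest.approx(20.0, abs=1e-10)

    def test_raw_ratio_mode_is_unlogged(self):
        a = np.zeros((4, 4))
        b = np.full((4, 4), 0.5)
        assert psnr(a, b, raw_ratio=True) == pytest.approx(10.0 / 0.25)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPCC:
    def test_self_correlation_is_one(self, rng):
        a = rng.random((6, 6))
        assert pcc(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelation_is_minus_one(self, rng):
        a = rng.random((6, 6)) - 0.5
        assert pcc(a, -a + 3.0) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_from_scratch_covariance(self, rng):
        a, b = rng.random((5, 5)), rng.random((5, 5))
        x, y = a.ravel(), b.ravel()
        oracle = (((x - x.mean()) * (y - y.mean())).mean()
                  / (x.std() * y.std()))
        assert pcc(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pcc(np.ones((4, 4)), np.random.default_rng(0).random((4, 4)))


class TestSSIM:
    def test_identity_is_exactly_one_in_both_modes(self, rng):
        a = rng.random((16, 16))
        assert ssim_index(a, a.copy(), SSIMParams(mode="global")) == pytest.approx(1.0)
        assert ssim_index(a, a.copy(), SSIMParams(mode="windowed")) == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        # mu_a=0.2, mu_b=0.8, sigma terms vanish; second factor is c2/c2 = 1
        a = np.full((8, 8), 0.2)
        b = np.full((8, 8), 0.8)
        params = SSIMParams(mode="global", c1=1e-4, c2=9e-4, dynamic_range=1.0)
        expected = (2 * 0.2 * 0.8 + 1e-4) / (0.2 ** 2 + 0.8 ** 2 + 1e-4)
        assert ssim_index(a, b, params) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.47066, abs=1e-5)

    def test_global_mode_matches_term_by_term_oracle(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        params = SSIMParams(mode="global")
        c1, c2 = params.resolved()
        mu_a, mu_b = a.mean(), b.mean()
        var_a, var_b = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        oracle = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)
                  / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))
        assert ssim_index(a, b, params) == pytest.approx(oracle, abs=1e-10)

    def test_windowed_mode_cross_checked_against_skimage(self, rng):
        from skimage.metrics import structural_similarity
        a, b = rng.random((32, 32)), rng.random((32, 32))
        ours = ssim_index(a, b, SSIMParams(mode="windowed", dynamic_range=1.0))
        ref = structural_similarity(a, b, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False, data_range=1.0)
        assert ours == pytest.approx(ref, abs=1e-7)

    def test_bounded_in_minus_one_one(self, rng):
        for _ in range(5):
            a, b = rng.random((12, 12)), rng.random((12, 12))
            v = ssim_index(a, b, SSIMParams(mode="global"))
            assert -1.0 <= v <= 1.0


class TestFID:
    def test_identical_sets_give_zero(self, rng):
        X = rng.normal(size=(50, 4))
        assert fid(X, X.copy()) <= 1e-8

    def test_one_dimensional_mean_shift_closed_form(self):
        # N(0,1) vs N(3,1): FID = (3-0)^2 = 9 (moments supplied exactly)
        assert fid_from_moments([0.0], [[1.0]], [3.0], [[1.0]]) == pytest.approx(9.0, abs=1e-6)

    def test_one_dimensional_variance_ratio_closed_form(self):
        # equal means, variances 1 and 4: Tr(1 + 4 - 2*2) = 1
        assert fid_from_moments([0.0], [[1.0]], [0.0], [[4.0]]) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry(self, rng):
        X, Y = rng.normal(size=(30, 3)), rng.normal(1.0, 2.0, size=(40, 3))
        assert fid(X, Y) == pytest.approx(fid(Y, X), rel=1e-9)

    def test_matrix_square_root_validated_by_squaring(self, rng):
        from scipy import linalg as sla
        X = rng.normal(size=(60, 5))
        Y = rng.normal(0.5, 1.5, size=(70, 5))
        cov_x = np.cov(X, rowvar=False)
        cov_y = np.cov(Y, rowvar=False)
        prod = cov_x @ cov_y
        S = np.real(sla.sqrtm(prod))
        assert np.linalg.norm(S @ S - prod) / np.linalg.norm(prod) <= 1e-6

    def test_sample_estimate_converges_to_gaussian_closed_form(self):
        rng = np.random.default_rng(77)
        X = rng.normal(0.0, 1.0, size=(10_000, 1))
        Y = rng.normal(1.0, 1.0, size=(10_000, 1))
        assert fid(X, Y) == pytest.approx(1.0, abs=0.05)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            fid(rng.normal(size=(10, 3)), rng.normal(size=(10, 4)))


class TestKID:
    def test_kernel_value_at_origin(self):
        # k(0, 0) = (0/d + 1)^3 = 1
        from staincycle.metrics import _poly_kernel
        z = np.zeros((1, 5))
        assert _poly_kernel(z, z)[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_matches_double_loop_unbiased_estimator(self, n, rng):
        d = 4
        X = rng.normal(size=(n, d))
        Y = rng.normal(0.5, 1.0, size=(n, d))
        k = lambda x, y: (x @ y / d + 1.0) ** 3
        sxx = sum(k(X[i], X[j]) for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
        syy = sum(k(Y[i], Y[j]) for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
        sxy = sum(k(X[i], Y[j]) for i in range(n) for j in range(n)) / n ** 2
        assert kid(X, Y) == pytest.approx(sxx + syy - 2 * sxy, abs=1e-12)

    def test_symmetry(self, rng):
        X, Y = rng.normal(size=(8, 3)), rng.normal(size=(9, 3))
        assert kid(X, Y) == pytest.approx(kid(Y, X), abs=1e-12)

    def test_unbiased_near_zero_for_same_distribution(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(200):
            X = rng.normal(size=(10, 2))
            Y = rng.normal(size=(10, 2))
            vals.append(kid(X, Y))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-12

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ValueError):
            kid(rng.normal(size=(1, 3)), rng.normal(size=(5, 3)))


class TestEmbeddingAndReport:
    def test_embedding_is_deterministic(self, rng):
        emb = random_projection_embedding(d=16, seed=3)
        img = rng.random((32, 32, 2)).astype(np.float32)
        assert np.array_equal(emb(img), emb(img.copy()))
        assert emb(img).shape == (16,)

    def test_identity_evaluation_is_perfect(self):
        a, b, pairing = generate_dataset(6, seed=8, paired=True,
                                         params=SceneParams(field_size_px=64))
        report = evaluate_sets(b, b, pairing=pairing,
                               embedding=random_projection_embedding(d=8))
        assert report.n_pairs == 6
        assert all(np.isinf(v) for v in report.per_pair["psnr_db"])
        assert report.ssim_mean == pytest.approx(1.0)
        assert report.pcc_mean == pytest.approx(1.0)
        assert report.fid <= 1e-8
        assert "randproj" in report.embedding

    def test_mean_sd_matches_independent_aggregation(self, rng):
        tiles_g = [ImageTile(rng.random((16, 16, 1), dtype=np.float32)) for _ in range(5)]
        tiles_r = [ImageTile(rng.random((16, 16, 1), dtype=np.float32)) for _ in range(5)]
        report = evaluate_sets(tiles_g, tiles_r, pairing=np.arange(5),
                               embedding=random_projection_embedding(d=4),
                               ssim_params=SSIMParams(mode="global"))
        ss = report.per_pair["ssim"]
        assert report.ssim_mean == pytest.approx(np.mean(ss))
        assert report.ssim_sd == pytest.approx(np.std(ss, ddof=1))

    def test_missing_pairing_skips_paired_metrics(self, rng):
        tiles = [ImageTile(rng.random((16, 16, 1), dtype=np.float32)) for _ in range(4)]
        report = evaluate_sets(tiles, tiles, pairing=None,
                               embedding=random_projection_embedding(d=4))
        assert report.n_pairs == 0
        assert np.isnan(report.ssim_mean)
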