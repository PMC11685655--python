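"""Every objective term against brute-force per-pixel oracles and identities."""

import numpy as np
import pytest

from staincycle.losses import (LossConfig, SSIMLossParams, cycle_loss,
                               lsgan_losses, otsu_threshold, saliency_loss,
                               saliency_mask, ssim_loss, total_loss)
from staincycle.metrics import SSIMParams, ssim_index
from staincycle.nn import Tensor


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def brute_force_saliency(a, ga, b, gb, cfg: LossConfig) -> float:
    """Direct per-pixel evaluation of the two saliency terms."""
    g = cfg.sigmoid_gain
    term_a = np.abs(_sigmoid((a - cfg.threshold_A) * g)
                    - _sigmoid((ga - cfg.threshold_B) * g)).mean()
    term_b = np.abs(_sigmoid((b - cfg.threshold_B) * g)
                    - _sigmoid((gb - cfg.threshold_A) * g)).mean()
    return float(term_a + term_b)


class TestLSGAN:
    def test_perfect_discriminator_has_zero_loss(self):
        d, _ = lsgan_losses(np.ones(5), np.zeros(5))
        assert d.item() == pytest.approx(0.0)

    def test_half_scores_give_half(self):
        d, _ = lsgan_losses(np.full(4, 0.5), np.full(4, 0.5))
        assert d.item() == pytest.approx(0.5)

    def test_perfect_generator_has_zero_loss(self):
        _, g = lsgan_losses(np.zeros(3), np.ones(3))
        assert g.item() == pytest.approx(0.0)

    def test_matches_brute_force_on_random_scores(self, rng):
        real, fake = rng.normal(size=7), rng.normal(size=7)
        d, g = lsgan_losses(real, fake)
        assert d.item() == pytest.approx(np.mean((real - 1) ** 2) + np.mean(fake ** 2), rel=1e-12)
        assert g.item() == pytest.approx(np.mean((fake - 1) ** 2), rel=1e-12)

    def test_empty_scores_raise(self):
        with pytest.raises(ValueError):
            lsgan_losses(np.array([]), np.ones(3))


class TestCycle:
    def test_perfect_reconstruction_is_zero(self, rng):
        a = rng.random((2, 3, 4, 4))
        b = rng.random((2, 3, 4, 4))
        assert cycle_loss(a, a.copy(), b, b.copy()).item() == pytest.approx(0.0)

    def test_constant_offset_one_direction_gives_offset(self, rng):
        a = rng.random((1, 1, 4, 4)) * 0.5
        b = rng.random((1, 1, 4, 4))
        c = 0.25
        assert cycle_loss(a, a + c, b, b.copy()).item() == pytest.approx(c, rel=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        a, ra = rng.random((2, 1, 4, 4)), rng.random((2, 1, 4, 4))
        b, rb = rng.random((2, 1, 4, 4)), rng.random((2, 1, 4, 4))
        oracle = np.abs(ra - a).mean() + np.abs(rb - b).mean()
        assert cycle_loss(a, ra, b, rb).item() == pytest.approx(oracle, rel=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            cycle_loss(rng.random((1, 1, 4, 4)), rng.random((1, 1, 5, 5)),
                       rng.random((1, 1, 4, 4)), rng.random((1, 1, 4, 4)))


class TestSSIMLoss:
    def test_identity_reconstruction_is_zero(self, rng):
        a = rng.random((2, 1, 8, 8))
        b = rng.random((2, 1, 8, 8))
        assert ssim_loss(a, a.copy(), b, b.copy()).item() == pytest.approx(0.0, abs=1e-12)

    def test_bounded_in_zero_four(self, rng):
        for _ in range(5):
            val = ssim_loss(rng.random((1, 1, 8, 8)), rng.random((1, 1, 8, 8)),
                            rng.random((1, 1, 8, 8)), rng.random((1, 1, 8, 8))).item()
            assert 0.0 <= val <= 4.0

    def test_composes_from_independent_metric_oracle(self, rng):
        a, ra = rng.random((1, 1, 8, 8)), rng.random((1, 1, 8, 8))
        b, rb = rng.random((1, 1, 8, 8)), rng.random((1, 1, 8, 8))
        val = ssim_loss(a, ra, b, rb, SSIMLossParams(mode="global")).item()
        s1 = ssim_index(a[0, 0], ra[0, 0], SSIMParams(mode="global"))
        s2 = ssim_index(b[0, 0], rb[0, 0], SSIMParams(mode="global"))
        assert val == pytest.approx(2.0 - s1 - s2, abs=1e-10)

    def test_windowed_mode_matches_metric_on_valid_windows(self, rng):
        a, ra = rng.random((1, 1, 16, 16)), rng.random((1, 1, 16, 16))
        val = ssim_loss(a, ra, a.copy(), ra.copy(),
                        SSIMLossParams(mode="windowed")).item()
        s = ssim_index(a[0, 0], ra[0, 0], SSIMParams(mode="windowed"))
        assert val == pytest.approx(2.0 * (1.0 - s), abs=1e-9)


class TestSaliencyMask:
    def test_value_at_threshold_is_half(self):
        assert saliency_mask(np.array([0.3]), 0.3)[0] == pytest.approx(0.5)

    def test_saturation_beyond_point_four(self):
        m = saliency_mask(np.array([0.9]), 0.5, gain=100.0)
        assert abs(m[0] - 1.0) < 1e-15
        m = saliency_mask(np.array([0.1]), 0.5, gain=100.0)
        assert m[0] < 1e-15

    def test_sigmoid_minus_one_value(self):
        # x = 0.49, T = 0.5, gain 100 -> sigmoid(-1) = 1/(1+e)
        val = saliency_mask(np.array([0.49]), 0.5, gain=100.0)[0]
        assert val == pytest.approx(1.0 / (1.0 + np.e), abs=1e-12)
        assert val == pytest.approx(0.2689414213699951, abs=1e-12)

    def test_monotone_and_open_unit_interval(self, rng):
        x = np.sort(rng.random(50))
        m = saliency_mask(x, 0.5, gain=10.0)
        assert np.all(np.diff(m) >= 0)
        assert np.all((m > 0) & (m < 1))

    def test_high_gain_converges_to_hard_indicator(self, rng):
        x = rng.random(200)
        x = x[np.abs(x - 0.5) >= 0.01]  # away from the threshold
        m = saliency_mask(x, 0.5, gain=1e4)
        assert np.abs(m - (x > 0.5)).max() < 1e-10

    def test_tensor_input_returns_tensor(self):
        out = saliency_mask(Tensor(np.array([0.5])), 0.5)
        assert isinstance(out, Tensor)


class TestSaliencyLoss:
    def test_identity_generators_equal_thresholds_zero(self, rng):
        cfg = LossConfig(threshold_A=0.4, threshold_B=0.4)
        a = rng.random((2, 1, 4, 4))
        b = rng.random((2, 1, 4, 4))
        assert saliency_loss(a, a.copy(), b, b.copy(), cfg).item() == pytest.approx(0.0)

    def test_binary_images_with_preserved_level_sets(self, rng):
        cfg = LossConfig(threshold_A=0.5, threshold_B=0.5)
        a = (rng.random((1, 1, 8, 8)) > 0.5).astype(float)
        ga = a * 0.9 + 0.05  # still on the same side of 0.5 everywhere
        val = saliency_loss(a, ga, a.copy(), ga.copy(), cfg).item()
        assert val < 1e-10

    def test_matches_brute_force_oracle(self, rng):
        cfg = LossConfig(threshold_A=0.35, threshold_B=0.6)
        a, ga = rng.random((2, 1, 4, 4)), rng.random((2, 1, 4, 4))
        b, gb = rng.random((2, 1, 4, 4)), rng.random((2, 1, 4, 4))
        assert saliency_loss(a, ga, b, gb, cfg).item() == pytest.approx(
            brute_force_saliency(a, ga, b, gb, cfg), rel=1e-9)

    def test_symmetric_under_joint_side_swap(self, rng):
        cfg = LossConfig(threshold_A=0.5, threshold_B=0.5)
        a, ga = rng.random((1, 1, 4, 4)), rng.random((1, 1, 4, 4))
        b, gb = rng.random((1, 1, 4, 4)), rng.random((1, 1, 4, 4))
        assert saliency_loss(a, ga, b, gb, cfg).item() == pytest.approx(
            saliency_loss(b, gb, a, ga, cfg).item(), rel=1e-12)


class TestTotal:
    def test_zero_weights_collapse_to_adversarial_terms(self):
        cfg = LossConfig(lambda_cyc=0, xi_ssim=0, rho_saliency=0)
        bd = total_loss(0.7, 0.3, 5.0, 5.0, 5.0, cfg)
        assert bd.total == pytest.approx(1.0)

    def test_weighted_arithmetic(self):
        cfg = LossConfig(lambda_cyc=10, xi_ssim=5, rho_saliency=0.5)
        bd = total_loss(1.0, 1.0, 2.0, 3.0, 4.0, cfg)
        assert bd.total == pytest.approx(1 + 1 + 20 + 15 + 2)

    def test_monotone_in_each_weight(self):
        base = dict(gan_forward=1, gan_backward=1, cycle=2, ssim=3, saliency=4)
        lo = total_loss(**base, config=LossConfig(lambda_cyc=1, xi_ssim=1, rho_saliency=1))
        hi = total_loss(**base, config=LossConfig(lambda_cyc=2, xi_ssim=1, rho_saliency=1))
        assert hi.total >= lo.total

    def test_nonfinite_component_is_named(self):
        with pytest.raises(ValueError, match="ssim"):
            total_loss(1.0, 1.0, 1.0, float("nan"), 1.0, LossConfig())

    def test_breakdown_identity_holds(self, rng):
        cfg = LossConfig(lambda_cyc=3.0, xi_ssim=0.5, rho_saliency=2.0)
        parts = rng.random(5)
        bd = total_loss(*parts, cfg)
        recomputed = (bd.gan_forward + bd.gan_backward + cfg.lambda_cyc * bd.cycle
                      + cfg.xi_ssim * bd.ssim + cfg.rho_saliency * bd.saliency)
        assert bd.total == pytest.approx(recomputed, rel=1e-12)


class TestConfig:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(lambda_cyc=-1.0)

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(threshold_A=1.5)

    def test_otsu_threshold_separates_bimodal_tiles(self, rng):
        lo = rng.normal(0.1, 0.02, size=(4, 16, 16)).clip(0, 1)
        hi = rng.normal(0.8, 0.02, size=(4, 16, 16)).clip(0, 1)
        tiles = list(np.concatenate([lo, hi]))
        t = otsu_threshold(tiles)
        # separates the two intensity modes almost perfectly
        assert (lo < t).mean() > 0.99
        assert (hi > t).mean() == 1.0
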