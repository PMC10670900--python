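"""Loss terms against brute-force oracles and hand-computed fixtures."""

import numpy as np
import pytest

from cbctsynth.losses import (
    LossConfig,
    combined_loss,
    combined_loss_grad,
    gradient_difference_loss,
    gradient_difference_loss_grad,
    ms_ssim,
    ms_ssim_loss,
    ms_ssim_loss_grad,
    ssim,
    ssim_grad,
    ssim_loss,
    weighted_mae,
    weighted_mae_grad,
)

UNIT_CFG = LossConfig(data_range=1.0, region_threshold=0.6)


# ---------------------------------------------------------------------------
# Brute-force oracles (naive loops, independent of the vectorised code)
# ---------------------------------------------------------------------------

def oracle_weighted_mae(pred, target, threshold, omega):
    hi_sum = hi_n = lo_sum = lo_n = 0.0
    for i in range(target.shape[0]):
        for j in range(target.shape[1]):
            d = abs(target[i, j] - pred[i, j])
            if target[i, j] > threshold:
                hi_sum += d
                hi_n += 1
            else:
                lo_sum += d
                lo_n += 1
    out = 0.0
    if hi_n:
        out += hi_sum / hi_n
    if lo_n:
        out += omega * lo_sum / lo_n
    return out


def _gauss_window(n=11, sigma=1.5):
    x = np.arange(n) - (n - 1) / 2.0
    k = np.exp(-(x**2) / (2 * sigma**2))
    k = k / k.sum()
    return np.outer(k, k)


def oracle_ssim(x, y, data_range):
    """Per-window double loop over all valid 11x11 window positions."""
    w = _gauss_window()
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, wd = x.shape
    vals = []
    for i in range(h - 10):
        for j in range(wd - 10):
            px = x[i : i + 11, j : j + 11]
            py = y[i : i + 11, j : j + 11]
            mx = (w * px).sum()
            my = (w * py).sum()
            vx = (w * px * px).sum() - mx**2
            vy = (w * py * py).sum() - my**2
            cov = (w * px * py).sum() - mx * my
            lum = (2 * mx * my + c1) / (mx**2 + my**2 + c1)
            cs = (2 * cov + c2) / (vx + vy + c2)
            vals.append(lum * cs)
    return float(np.mean(vals))


def oracle_gdl(pred, target):
    dxs, dys = [], []
    for i in range(target.shape[0]):
        for j in range(target.shape[1] - 1):
            gt = target[i, j + 1] - target[i, j]
            gp = pred[i, j + 1] - pred[i, j]
            dxs.append((gt - gp) ** 2)
    for i in range(target.shape[0] - 1):
        for j in range(target.shape[1]):
            gt = target[i + 1, j] - target[i, j]
            gp = pred[i + 1, j] - pred[i, j]
            dys.append((gt - gp) ** 2)
    return float(np.mean(dxs) + np.mean(dys))


# ---------------------------------------------------------------------------
# Weighted MAE
# ---------------------------------------------------------------------------

class TestWeightedMAE:
    def test_hand_fixture(self):
        """Two bone pixels off by 10, two soft pixels off by 10 -> 10 + 5*10."""
        target = np.array([[600.0, 600.0], [0.0, 0.0]])
        pred = np.array([[610.0, 590.0], [10.0, -10.0]])
        cfg = LossConfig(region_threshold=500.0, omega=5.0)
        assert weighted_mae(pred, target, cfg) == pytest.approx(60.0)

    def test_identical_images_zero(self, rng):
        img = rng.random((16, 16))
        assert weighted_mae(img, img) == 0.0

    def test_single_region_omega_one_reduces_to_mae(self, rng):
        target = rng.random((8, 8))  # all below threshold 0.6? force it
        target = target * 0.5
        pred = rng.random((8, 8)) * 0.5
        cfg = LossConfig(omega=1.0, region_threshold=0.6, data_range=1.0)
        assert weighted_mae(pred, target, cfg) == pytest.approx(
            float(np.abs(pred - target).mean())
        )

    def test_oracle_equivalence(self, rng):
        cfg = UNIT_CFG
        for _ in range(25):
            t = rng.random((16, 16))
            p = rng.random((16, 16))
            assert weighted_mae(p, t, cfg) == pytest.approx(
                oracle_weighted_mae(p, t, cfg.region_threshold, cfg.omega), abs=1e-9
            )

    def test_not_symmetric(self):
        """Region membership comes from the target, so swapping args differs."""
        t = np.array([[0.9, 0.9], [0.1, 0.1]])
        p = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert weighted_mae(p, t, UNIT_CFG) != pytest.approx(
            weighted_mae(t, p, UNIT_CFG)
        )

    def test_empty_region_contributes_zero(self):
        t = np.zeros((4, 4))
        p = np.full((4, 4), 0.1)
        cfg = LossConfig(omega=5.0, region_threshold=0.6, data_range=1.0)
        assert weighted_mae(p, t, cfg) == pytest.approx(0.5)  # omega * 0.1

    def test_gradient_matches_finite_differences(self, rng):
        t = rng.random((8, 8))
        p = rng.random((8, 8))
        _, g = weighted_mae_grad(p, t, UNIT_CFG)
        eps = 1e-6
        for i, j in [(0, 0), (3, 5), (7, 7)]:
            pp, pm = p.copy(), p.copy()
            pp[i, j] += eps
            pm[i, j] -= eps
            fd = (weighted_mae(pp, t, UNIT_CFG) - weighted_mae(pm, t, UNIT_CFG)) / (2 * eps)
            assert g[i, j] == pytest.approx(fd, abs=1e-6)


# ---------------------------------------------------------------------------
# SSIM / MS-SSIM
# ---------------------------------------------------------------------------

class TestSSIM:
    def test_identical_images(self, rng):
        img = rng.random((16, 16))
        assert ssim(img, img, UNIT_CFG) == pytest.approx(1.0)
        assert ssim_loss(img, img, UNIT_CFG) == pytest.approx(0.0)

    def test_constant_images_closed_form(self):
        """Zero variance: per-window SSIM reduces to (2ab+C1)/(a^2+b^2+C1)."""
        a, b = 0.4, 0.7
        x = np.full((16, 16), a)
        y = np.full((16, 16), b)
        c1 = (0.01 * 1.0) ** 2
        expected = (2 * a * b + c1) / (a**2 + b**2 + c1)
        assert ssim(x, y, UNIT_CFG) == pytest.approx(expected, abs=1e-12)

    def test_oracle_equivalence(self, rng):
        for _ in range(10):
            x = rng.random((16, 16))
            y = rng.random((16, 16))
            assert ssim(x, y, UNIT_CFG) == pytest.approx(
                oracle_ssim(x, y, 1.0), abs=1e-6
            )

    def test_symmetric(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        assert ssim(x, y, UNIT_CFG) == pytest.approx(ssim(y, x, UNIT_CFG), abs=1e-12)

    def test_window_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.random((8, 8)), rng.random((8, 8)), UNIT_CFG)

    def test_gradient_matches_finite_differences(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        _, g = ssim_grad(x, y, UNIT_CFG)
        eps = 1e-6
        for i, j in [(0, 0), (8, 8), (15, 3)]:
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            fd = (ssim(xp, y, UNIT_CFG) - ssim(xm, y, UNIT_CFG)) / (2 * eps)
            assert g[i, j] == pytest.approx(fd, abs=1e-6)


class TestMSSSIM:
    def test_identical_images(self, rng):
        img = rng.random((64, 64))
        assert ms_ssim_loss(img, img, UNIT_CFG) == pytest.approx(0.0, abs=1e-12)

    def test_single_level_reduces_to_ssim(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        cfg = LossConfig(data_range=1.0, ms_ssim_levels=1)
        assert ms_ssim_loss(x, y, cfg) == ssim_loss(x, y, cfg)

    def test_levels_auto_reduced_for_small_images(self, rng):
        # 64 px supports only 3 levels with an 11-px window; must not raise
        x, y = rng.random((64, 64)), rng.random((64, 64))
        assert np.isfinite(ms_ssim(x, y, UNIT_CFG))

    def test_noise_monotonicity(self, rng):
        """Growing noise strictly increases the loss in expectation."""
        base = np.kron(rng.random((8, 8)), np.ones((8, 8)))
        sigmas = [0.02, 0.06, 0.12]
        means = []
        for s in sigmas:
            vals = [
                ms_ssim_loss(base, base + np.random.default_rng(k).normal(0, s, base.shape), UNIT_CFG)
                for k in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_gradient_matches_finite_differences(self, rng):
        base = np.kron(rng.random((8, 8)), np.ones((8, 8)))
        x = base + 0.05 * rng.random((64, 64))
        y = base + 0.05 * rng.random((64, 64))
        _, g = ms_ssim_loss_grad(x, y, UNIT_CFG)
        eps = 1e-6
        for i, j in [(5, 5), (32, 40), (63, 0)]:
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            fd = (ms_ssim_loss(xp, y, UNIT_CFG) - ms_ssim_loss(xm, y, UNIT_CFG)) / (2 * eps)
            assert g[i, j] == pytest.approx(fd, abs=1e-6)


# ---------------------------------------------------------------------------
# Gradient difference loss
# ---------------------------------------------------------------------------

class TestGDL:
    def test_hand_fixture(self):
        """Vertical edge of unit steps: x-term mean 1, y-term 0."""
        target = np.array([[0.0, 1.0], [0.0, 1.0]])
        pred = np.zeros((2, 2))
        assert gradient_difference_loss(pred, target) == pytest.approx(1.0)

    def test_identical_and_constant_offset(self, rng):
        img = rng.random((16, 16))
        assert gradient_difference_loss(img, img) == 0.0
        # distinct constants have identical (zero) gradients
        assert gradient_difference_loss(
            np.full((8, 8), 0.3), np.full((8, 8), 0.9)
        ) == 0.0

    def test_oracle_equivalence(self, rng):
        for _ in range(25):
            p, t = rng.random((16, 16)), rng.random((16, 16))
            assert gradient_difference_loss(p, t) == pytest.approx(
                oracle_gdl(p, t), abs=1e-9
            )

    def test_gradient_matches_finite_differences(self, rng):
        p, t = rng.random((8, 8)), rng.random((8, 8))
        _, g = gradient_difference_loss_grad(p, t)
        eps = 1e-6
        for i, j in [(0, 0), (4, 4), (7, 2)]:
            pp, pm = p.copy(), p.copy()
            pp[i, j] += eps
            pm[i, j] -= eps
            fd = (gradient_difference_loss(pp, t) - gradient_difference_loss(pm, t)) / (2 * eps)
            assert g[i, j] == pytest.approx(fd, abs=1e-6)


# ---------------------------------------------------------------------------
# Combined loss
# ---------------------------------------------------------------------------

class TestCombined:
    def test_identical_images_all_terms_zero(self, rng):
        img = rng.random((16, 16))
        total, terms = combined_loss(img, img, UNIT_CFG)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in terms.values())

    def test_mae_only_ablation_reduces_to_weighted_mae(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        cfg = LossConfig(lambdas=(1.0, 0.0, 0.0), data_range=1.0, region_threshold=0.6)
        total, _ = combined_loss(x, y, cfg)
        assert total == pytest.approx(weighted_mae(x, y, cfg))

    def test_termwise_composition(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        total, terms = combined_loss(x, y, UNIT_CFG)
        expected = (
            1.0 * weighted_mae(x, y, UNIT_CFG)
            + 3.0 * ms_ssim_loss(x, y, UNIT_CFG)
            + 2.0 * gradient_difference_loss(x, y)
        )
        assert total == pytest.approx(expected, abs=1e-12)
        assert terms["weighted_mae"] == pytest.approx(weighted_mae(x, y, UNIT_CFG))

    def test_grad_variant_matches_value_variant(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        v1, terms1 = combined_loss(x, y, UNIT_CFG)
        v2, terms2, g = combined_loss_grad(x, y, UNIT_CFG)
        assert v1 == pytest.approx(v2, abs=1e-12)
        assert g.shape == x.shape

    def test_nonnegative_terms(self, rng):
        for _ in range(5):
            x, y = rng.random((16, 16)), rng.random((16, 16))
            _, terms = combined_loss(x, y, UNIT_CFG)
            assert terms["weighted_mae"] >= 0
            assert terms["gradient_difference_loss"] >= 0
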