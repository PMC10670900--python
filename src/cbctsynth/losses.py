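"""Composite training loss: weighted MAE + MS-SSIM loss + gradient difference.

The three terms target complementary failure modes of CBCT-to-CT synthesis:

* **weighted MAE** — plain mean absolute error computed separately for the
  high-intensity region (bone, above a 500 HU threshold on the ground truth)
  and the remnant region, with the low-intensity term up-weighted by
  ``omega`` so soft tissue is not neglected in favour of bone;
* **MS-SSIM loss** — ``1 -`` multi-scale structural similarity, which
  counteracts the blurring tendency of pixel-wise losses;
* **gradient difference loss** — squared mismatch of forward-difference
  image gradients, sharpening tissue edges.

The combination is ``lambda1*wMAE + lambda2*(1-MS-SSIM) + lambda3*GDL`` with
default weights (1, 3, 2).

Every term comes in two flavours: a value-only function and a ``*_grad``
variant returning the analytic derivative with respect to the prediction,
used by the NumPy training loop.  All functions accept a single 2D image or
a batch with a leading axis; batch results are averaged per image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import correlate1d

__all__ = [
    "LossConfig",
    "weighted_mae",
    "weighted_mae_grad",
    "ssim",
    "ssim_loss",
    "ssim_grad",
    "ms_ssim",
    "ms_ssim_loss",
    "ms_ssim_loss_grad",
    "gradient_difference_loss",
    "gradient_difference_loss_grad",
    "combined_loss",
    "combined_loss_grad",
]

#: Canonical five-level MS-SSIM weights (contrast/structure per level,
#: luminance only at the coarsest); renormalised when fewer levels fit.
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass(frozen=True)
class LossConfig:
    """Tunables of the composite loss.

    ``region_threshold`` and ``data_range`` are expressed in the same units
    as the images the loss is applied to: 500 HU / 2500 HU when operating on
    Hounsfield images, or their affinely mapped equivalents in the network's
    normalised attenuation space (see :meth:`in_network_space`).
    """

    omega: float = 5.0
    region_threshold: float = 500.0
    lambdas: tuple[float, float, float] = (1.0, 3.0, 2.0)
    data_range: float = 2500.0
    k1: float = 0.01
    k2: float = 0.03
    ms_ssim_levels: int = 5
    ssim_window: int = 11
    ssim_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambdas must be non-negative")
        if self.data_range <= 0:
            raise ValueError("data_range must be positive")
        if self.ms_ssim_levels < 1:
            raise ValueError("ms_ssim_levels must be >= 1")

    def in_network_space(self, hu_lo: float = -1000.0, hu_hi: float = 1500.0) -> "LossConfig":
        """Map HU-domain threshold/data_range into the [0, 1] network space.

        The network input is ``(HU - hu_lo) / (hu_hi - hu_lo)``, an affine
        map, so the region threshold moves with it and the data range
        becomes 1.
        """
        span = hu_hi - hu_lo
        return replace(
            self,
            region_threshold=(self.region_threshold - hu_lo) / span,
            data_range=self.data_range / span,
        )


def _batched(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None]
    if x.ndim == 3:
        return x
    raise ValueError(f"expected 2D image or 3D batch, got shape {x.shape}")


def _check_shapes(pred: np.ndarray, target: np.ndarray) -> None:
    if np.shape(pred) != np.shape(target):
        raise ValueError(
            f"shape mismatch: pred {np.shape(pred)} vs target {np.shape(target)}"
        )


# ---------------------------------------------------------------------------
# Weighted MAE
# ---------------------------------------------------------------------------

def weighted_mae(pred, target, cfg: LossConfig | None = None) -> float:
    """Region-weighted mean absolute error.

    Region membership comes from the *ground truth*: pixels with
    ``target > region_threshold`` form the high-intensity (bone) region, the
    rest the remnant region whose MAE is multiplied by ``omega``.  An empty
    region contributes zero rather than raising, so all-air slices remain
    trainable.
    """
    value, _ = _wmae_impl(pred, target, cfg or LossConfig(), want_grad=False)
    return value


def weighted_mae_grad(pred, target, cfg: LossConfig | None = None):
    """Weighted MAE and its derivative with respect to ``pred``."""
    return _wmae_impl(pred, target, cfg or LossConfig(), want_grad=True)


def _wmae_impl(pred, target, cfg: LossConfig, want_grad: bool):
    _check_shapes(pred, target)
    p, t = _batched(pred), _batched(target)
    B = p.shape[0]
    diff = p - t
    high = t > cfg.region_threshold
    n_high = high.sum(axis=(1, 2))
    n_low = (~high).sum(axis=(1, 2))
    abs_diff = np.abs(diff)
    s_high = np.where(high, abs_diff, 0.0).sum(axis=(1, 2))
    s_low = np.where(high, 0.0, abs_diff).sum(axis=(1, 2))
    per_image = (
        np.divide(s_high, n_high, out=np.zeros(B), where=n_high > 0)
        + cfg.omega * np.divide(s_low, n_low, out=np.zeros(B), where=n_low > 0)
    )
    value = float(per_image.mean())
    if not want_grad:
        return value, None
    sign = np.sign(diff)
    w_high = np.divide(1.0, n_high, out=np.zeros(B), where=n_high > 0)
    w_low = np.divide(cfg.omega, n_low, out=np.zeros(B), where=n_low > 0)
    grad = sign * np.where(high, w_high[:, None, None], w_low[:, None, None]) / B
    return value, grad.reshape(np.shape(pred))


# ---------------------------------------------------------------------------
# SSIM / MS-SSIM
# ---------------------------------------------------------------------------

def _gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    r = (window - 1) / 2.0
    x = np.arange(window) - r
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _win_corr_valid(img: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Separable windowed correlation, valid region only (batch, H', W')."""
    r = len(k) // 2
    out = correlate1d(img, k, axis=-1, mode="constant")
    out = correlate1d(out, k, axis=-2, mode="constant")
    return out[..., r:-r, r:-r]


def _win_corr_adjoint(g: np.ndarray, k: np.ndarray, shape) -> np.ndarray:
    """Adjoint of :func:`_win_corr_valid` (full convolution of the grad map)."""
    r = len(k) // 2
    pad = [(0, 0)] * (g.ndim - 2) + [(r, r), (r, r)]
    gp = np.pad(g, pad)
    out = correlate1d(gp, k[::-1], axis=-1, mode="constant")
    out = correlate1d(out, k[::-1], axis=-2, mode="constant")
    assert out.shape == shape
    return out


def _ssim_stats(x, y, k):
    mu_x = _win_corr_valid(x, k)
    mu_y = _win_corr_valid(y, k)
    xx = _win_corr_valid(x * x, k)
    yy = _win_corr_valid(y * y, k)
    xy = _win_corr_valid(x * y, k)
    vx = xx - mu_x**2
    vy = yy - mu_y**2
    cov = xy - mu_x * mu_y
    return mu_x, mu_y, vx, vy, cov


def _ssim_maps(x, y, cfg: LossConfig):
    k = _gaussian_kernel(cfg.ssim_window, cfg.ssim_sigma)
    c1 = (cfg.k1 * cfg.data_range) ** 2
    c2 = (cfg.k2 * cfg.data_range) ** 2
    mu_x, mu_y, vx, vy, cov = _ssim_stats(x, y, k)
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    cs = (2 * cov + c2) / (vx + vy + c2)
    return lum, cs


def ssim(x, y, cfg: LossConfig | None = None) -> float:
    """Mean structural similarity over an 11-px Gaussian sliding window.

    Follows the standard two-constant form: luminance term
    ``(2 mu_x mu_y + C1)/(mu_x^2 + mu_y^2 + C1)`` times contrast/structure
    term ``(2 cov + C2)/(var_x + var_y + C2)`` with ``C1 = (K1 R)^2``,
    ``C2 = (K2 R)^2`` for data range ``R``; the map is averaged over the
    valid window positions.
    """
    cfg = cfg or LossConfig()
    _check_shapes(x, y)
    xb, yb = _batched(x), _batched(y)
    _require_window_fit(xb.shape, cfg.ssim_window)
    lum, cs = _ssim_maps(xb, yb, cfg)
    return float((lum * cs).mean())


def ssim_loss(x, y, cfg: LossConfig | None = None) -> float:
    """``1 - ssim(x, y)``."""
    return 1.0 - ssim(x, y, cfg)


def _require_window_fit(shape, window: int) -> None:
    if shape[-1] < window or shape[-2] < window:
        raise ValueError(
            f"image sides {shape[-2:]} smaller than the SSIM window {window}"
        )


def ssim_grad(x, y, cfg: LossConfig | None = None):
    """Mean SSIM and its derivative with respect to ``x``.

    The statistics are convolutions of x, x^2 and x*y with the window, so
    the chain rule backpropagates through the windowing operator's adjoint.
    """
    cfg = cfg or LossConfig()
    _check_shapes(x, y)
    xb, yb = _batched(x), _batched(y)
    _require_window_fit(xb.shape, cfg.ssim_window)
    k = _gaussian_kernel(cfg.ssim_window, cfg.ssim_sigma)
    c1 = (cfg.k1 * cfg.data_range) ** 2
    c2 = (cfg.k2 * cfg.data_range) ** 2
    mu_x, mu_y, vx, vy, cov = _ssim_stats(xb, yb, k)
    b1 = mu_x**2 + mu_y**2 + c1
    lum = (2 * mu_x * mu_y + c1) / b1
    b2 = vx + vy + c2
    cs = (2 * cov + c2) / b2
    value = float((lum * cs).mean())
    npos = lum[0].size * xb.shape[0]
    # d(mean S)/d(stat maps), each divided by the number of averaged windows
    g_mu = cs * 2 * (mu_y - lum * mu_x) / b1 / npos
    g_v = -lum * cs / b2 / npos
    g_c = lum * 2.0 / b2 / npos
    grad = _ssim_backprop_stats(xb, yb, k, mu_x, mu_y, g_mu, g_v, g_c)
    return value, grad.reshape(np.shape(x))


def _ssim_backprop_stats(xb, yb, k, mu_x, mu_y, g_mu, g_v, g_c):
    shape = xb.shape
    grad = _win_corr_adjoint(g_mu - 2 * mu_x * g_v - mu_y * g_c, k, shape)
    grad += 2 * xb * _win_corr_adjoint(g_v, k, shape)
    grad += yb * _win_corr_adjoint(g_c, k, shape)
    return grad


def _downsample2(x: np.ndarray) -> np.ndarray:
    """2x2 average pooling; odd trailing row/column dropped."""
    h, w = x.shape[-2] // 2 * 2, x.shape[-1] // 2 * 2
    x = x[..., :h, :w]
    s = x.shape
    return x.reshape(*s[:-2], h // 2, 2, w // 2, 2).mean(axis=(-3, -1))


def _downsample2_adjoint(g: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=g.dtype)
    up = np.repeat(np.repeat(g, 2, axis=-2), 2, axis=-1) / 4.0
    out[..., : up.shape[-2], : up.shape[-1]] = up
    return out


def _effective_levels(shape, cfg: LossConfig) -> int:
    side = min(shape[-2], shape[-1])
    levels = 1
    while levels < cfg.ms_ssim_levels and side // 2 >= cfg.ssim_window:
        side //= 2
        levels += 1
    return levels


def _ms_weights(levels: int) -> np.ndarray:
    w = np.asarray(MS_SSIM_WEIGHTS[:levels], dtype=np.float64)
    return w / w.sum()


def ms_ssim(x, y, cfg: LossConfig | None = None) -> float:
    """Multi-scale SSIM: contrast/structure at every level of a dyadic
    pyramid, luminance at the coarsest, combined as a weighted product.

    The number of levels is reduced automatically (weights renormalised)
    when the image is too small for the window at the coarsest scale; with a
    single level the value equals plain :func:`ssim` exactly.
    """
    cfg = cfg or LossConfig()
    _check_shapes(x, y)
    xb, yb = _batched(x), _batched(y)
    _require_window_fit(xb.shape, cfg.ssim_window)
    levels = _effective_levels(xb.shape, cfg)
    if levels == 1:
        # no geometric combination: exactly plain SSIM (sign preserved)
        lum, cs = _ssim_maps(xb, yb, cfg)
        return float((lum * cs).mean())
    weights = _ms_weights(levels)
    eps = 1e-8
    value = 1.0
    for j in range(levels):
        lum, cs = _ssim_maps(xb, yb, cfg)
        m = float((lum * cs).mean()) if j == levels - 1 else float(cs.mean())
        value *= max(m, eps) ** weights[j]
        if j < levels - 1:
            xb, yb = _downsample2(xb), _downsample2(yb)
    return float(value)


def ms_ssim_loss(x, y, cfg: LossConfig | None = None) -> float:
    """``1 - ms_ssim(x, y)``."""
    return 1.0 - ms_ssim(x, y, cfg)


def ms_ssim_loss_grad(x, y, cfg: LossConfig | None = None):
    """MS-SSIM loss and its derivative with respect to ``x``."""
    cfg = cfg or LossConfig()
    _check_shapes(x, y)
    xb, yb = _batched(x), _batched(y)
    _require_window_fit(xb.shape, cfg.ssim_window)
    levels = _effective_levels(xb.shape, cfg)
    if levels == 1:
        value, grad = ssim_grad(x, y, cfg)
        return 1.0 - value, -grad
    weights = _ms_weights(levels)
    k = _gaussian_kernel(cfg.ssim_window, cfg.ssim_sigma)
    c1 = (cfg.k1 * cfg.data_range) ** 2
    c2 = (cfg.k2 * cfg.data_range) ** 2
    eps = 1e-8

    xs, ys, caches, means = [xb], [yb], [], []
    for j in range(levels):
        xj, yj = xs[-1], ys[-1]
        mu_x, mu_y, vx, vy, cov = _ssim_stats(xj, yj, k)
        b1 = mu_x**2 + mu_y**2 + c1
        lum = (2 * mu_x * mu_y + c1) / b1
        b2 = vx + vy + c2
        cs = (2 * cov + c2) / b2
        m = float((lum * cs).mean()) if j == levels - 1 else float(cs.mean())
        caches.append((xj, yj, mu_x, mu_y, lum, cs, b1, b2))
        means.append(m)
        if j < levels - 1:
            xs.append(_downsample2(xj))
            ys.append(_downsample2(yj))

    clamped = np.maximum(means, eps)
    value = float(np.prod(clamped**weights))

    grad = np.zeros_like(xb)
    for j in reversed(range(levels)):
        xj, yj, mu_x, mu_y, lum, cs, b1, b2 = caches[j]
        if means[j] <= eps:
            continue
        dV_dm = value * weights[j] / clamped[j]
        npos = cs[0].size * cs.shape[0]
        if j == levels - 1:
            g_mu = cs * 2 * (mu_y - lum * mu_x) / b1 * (dV_dm / npos)
            g_v = -lum * cs / b2 * (dV_dm / npos)
            g_c = lum * 2.0 / b2 * (dV_dm / npos)
        else:
            g_mu = np.zeros_like(cs)
            g_v = -cs / b2 * (dV_dm / npos)
            g_c = (2.0 / b2) * (dV_dm / npos)
        gj = _ssim_backprop_stats(xj, yj, k, mu_x, mu_y, g_mu, g_v, g_c)
        for lev in reversed(range(j)):
            gj = _downsample2_adjoint(gj, xs[lev].shape)
        grad += gj
    # loss = 1 - value
    return 1.0 - value, (-grad).reshape(np.shape(x))


# ---------------------------------------------------------------------------
# Gradient difference loss
# ---------------------------------------------------------------------------

def gradient_difference_loss(pred, target) -> float:
    """Mean squared mismatch of forward-difference gradients along each axis.

    Invariant to constant intensity offsets; zero iff the two images have
    identical gradients.
    """
    value, _ = _gdl_impl(pred, target, want_grad=False)
    return value


def gradient_difference_loss_grad(pred, target):
    """GDL and its derivative with respect to ``pred``."""
    return _gdl_impl(pred, target, want_grad=True)


def _gdl_impl(pred, target, want_grad: bool):
    _check_shapes(pred, target)
    p, t = _batched(pred), _batched(target)
    if p.shape[-1] < 2 or p.shape[-2] < 2:
        raise ValueError("gradient difference loss needs images of side >= 2")
    dx = (t[..., :, 1:] - t[..., :, :-1]) - (p[..., :, 1:] - p[..., :, :-1])
    dy = (t[..., 1:, :] - t[..., :-1, :]) - (p[..., 1:, :] - p[..., :-1, :])
    value = float((dx**2).mean() + (dy**2).mean())
    if not want_grad:
        return value, None
    grad = np.zeros_like(p)
    gx = 2.0 * dx / dx.size
    gy = 2.0 * dy / dy.size
    # d/d pred of (grad(t) - grad(p)): minus sign on the forward position
    grad[..., :, 1:] -= gx
    grad[..., :, :-1] += gx
    grad[..., 1:, :] -= gy
    grad[..., :-1, :] += gy
    return value, grad.reshape(np.shape(pred))


# ---------------------------------------------------------------------------
# Combined loss
# ---------------------------------------------------------------------------

def combined_loss(pred, target, cfg: LossConfig | None = None):
    """Composite loss value plus a per-term breakdown for logging/ablation."""
    cfg = cfg or LossConfig()
    l1, l2, l3 = cfg.lambdas
    terms = {
        "weighted_mae": weighted_mae(pred, target, cfg) if l1 else 0.0,
        "ms_ssim_loss": ms_ssim_loss(pred, target, cfg) if l2 else 0.0,
        "gradient_difference_loss": (
            gradient_difference_loss(pred, target) if l3 else 0.0
        ),
    }
    total = (
        l1 * terms["weighted_mae"]
        + l2 * terms["ms_ssim_loss"]
        + l3 * terms["gradient_difference_loss"]
    )
    return float(total), terms


def combined_loss_grad(pred, target, cfg: LossConfig | None = None):
    """Composite loss, breakdown, and derivative with respect to ``pred``."""
    cfg = cfg or LossConfig()
    l1, l2, l3 = cfg.lambdas
    grad = np.zeros(np.shape(pred), dtype=np.float64)
    terms = {"weighted_mae": 0.0, "ms_ssim_loss": 0.0, "gradient_difference_loss": 0.0}
    if l1:
        v, g = weighted_mae_grad(pred, target, cfg)
        terms["weighted_mae"] = v
        grad += l1 * g
    if l2:
        v, g = ms_ssim_loss_grad(pred, target, cfg)
        terms["ms_ssim_loss"] = v
        grad += l2 * g
    if l3:
        v, g = gradient_difference_loss_grad(pred, target)
        terms["gradient_difference_loss"] = v
        grad += l3 * g
    total = (
        l1 * terms["weighted_mae"]
        + l2 * terms["ms_ssim_loss"]
        + l3 * terms["gradient_difference_loss"]
    )
    return float(total), terms, grad
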