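"""Training objective of the saliency-constrained cycle GAN.

Five terms make up the full objective:

* least-squares adversarial losses for the forward (A->B) and backward
  (B->A) GANs — the discriminator regresses real scores to 1 and fake scores
  to 0, the generator drives its fakes toward 1;
* cycle-consistency: L1 between each image and its round-trip reconstruction;
* an SSIM term ``E[1 - SSIM(x, roundtrip(x))]`` in both directions,
  preserving structural similarity through the cycle;
* a saliency term: the soft threshold mask ``sigmoid((x - T) * gain)`` of an
  input and of its translation must agree (L1), pinning the content layout
  of the translation to the input — the explainability constraint;

and the weighted total ``gan_fwd + gan_bwd + lambda*cycle + xi*ssim + rho*saliency``.

An identity term is deliberately absent: it does not help content
preservation in this setting and is dropped from the objective.

All loss functions operate on autodiff :class:`~staincycle.nn.Tensor` batches
(NCHW) and return scalar Tensors, so they serve both as training objectives
and, via ``.item()``, as plain evaluations; numpy arrays are accepted and
wrapped automatically. L1 norms are normalised per pixel, making every term
resolution-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .nn import Tensor

__all__ = ["LossConfig", "LossBreakdown", "lsgan_losses", "cycle_loss",
           "ssim_loss", "saliency_mask", "saliency_loss", "total_loss",
           "otsu_threshold", "SSIMLossParams"]


@dataclass
class LossConfig:
    """Weights and thresholds of the full objective.

    ``lambda_cyc`` follows the cycle-GAN convention (10); the SSIM and
    saliency weights default to 1. Thresholds live in the [0, 1] image range
    and are typically set by Otsu's method over training tiles
    (:func:`otsu_threshold`), with manual override supported.
    """

    lambda_cyc: float = 10.0
    xi_ssim: float = 1.0
    rho_saliency: float = 1.0
    threshold_A: float = 0.5
    threshold_B: float = 0.5
    sigmoid_gain: float = 100.0
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if min(self.lambda_cyc, self.xi_ssim, self.rho_saliency) < 0:
            raise ValueError("loss weights must be nonnegative")
        lo, hi = self.value_range
        for name, t in (("threshold_A", self.threshold_A), ("threshold_B", self.threshold_B)):
            if not (lo <= t <= hi):
                raise ValueError(f"{name}={t} outside value range [{lo}, {hi}]")


@dataclass
class LossBreakdown:
    """Per-batch record of every term plus the assembled total."""

    gan_forward: float
    gan_backward: float
    cycle: float
    ssim: float
    saliency: float
    total: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("gan_forward", "gan_backward", "cycle", "ssim", "saliency", "total")}


def _lift(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    return Tensor(arr if arr.dtype.kind == "f" else arr.astype(np.float64))


def _check_shapes(x: Tensor, y: Tensor, what: str) -> None:
    if x.shape != y.shape:
        raise ValueError(f"{what}: shape mismatch {x.shape} vs {y.shape}")


# ---------------------------------------------------------------------------
# adversarial
# ---------------------------------------------------------------------------

def lsgan_losses(d_real_scores, d_fake_scores):
    """Least-squares GAN losses from discriminator scores.

    Returns ``(discriminator_loss, generator_loss)``:
    ``mean((D_real - 1)^2) + mean(D_fake^2)`` and ``mean((D_fake - 1)^2)``.
    """
    real = _lift(d_real_scores)
    fake = _lift(d_fake_scores)
    if real.data.size == 0 or fake.data.size == 0:
        raise ValueError("score collections must be non-empty")
    d_loss = ((real - 1.0) ** 2).mean() + (fake ** 2).mean()
    g_loss = ((fake - 1.0) ** 2).mean()
    return d_loss, g_loss


# ---------------------------------------------------------------------------
# cycle consistency
# ---------------------------------------------------------------------------

def cycle_loss(a_batch, reconstructed_a, b_batch, reconstructed_b) -> Tensor:
    """Per-pixel L1 round-trip error, both directions, averaged over batch."""
    a, ra = _lift(a_batch), _lift(reconstructed_a)
    b, rb = _lift(b_batch), _lift(reconstructed_b)
    _check_shapes(a, ra, "cycle_loss A-side")
    _check_shapes(b, rb, "cycle_loss B-side")
    return (ra - a).abs().mean() + (rb - b).abs().mean()


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

@dataclass
class SSIMLossParams:
    """Differentiable SSIM configuration (mirrors the metric-side constants)."""

    dynamic_range: float = 1.0
    mode: str = "global"
    window_size: int = 11
    window_sigma: float = 1.5

    @property
    def c1(self) -> float:
        return (0.01 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (0.03 * self.dynamic_range) ** 2


def _ssim_tensor(x: Tensor, y: Tensor, params: SSIMLossParams) -> Tensor:
    """Mean SSIM of a batch (NCHW), differentiable."""
    c1, c2 = params.c1, params.c2
    if params.mode == "global":
        mu_x = x.mean(axis=(2, 3), keepdims=True)
        mu_y = y.mean(axis=(2, 3), keepdims=True)
        dx, dy = x - mu_x, y - mu_y
        var_x = (dx * dx).mean(axis=(2, 3), keepdims=True)
        var_y = (dy * dy).mean(axis=(2, 3), keepdims=True)
        cov = (dx * dy).mean(axis=(2, 3), keepdims=True)
        num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
        den = (mu_x * mu_x + mu_y * mu_y + c1) * (var_x + var_y + c2)
        return (num / den).mean()
    if params.mode != "windowed":
        raise ValueError(f"unknown SSIM mode {params.mode!r}")
    # depthwise Gaussian windowing via a grouped reshape to (N*C, 1, H, W)
    n, c, h, w = x.shape
    win, sig = params.window_size, params.window_sigma
    half = (win - 1) / 2.0
    g = np.exp(-((np.arange(win) - half) ** 2) / (2.0 * sig ** 2))
    k2 = np.outer(g, g)
    kernel = Tensor((k2 / k2.sum())[None, None].astype(np.float64))
    xf = x.reshape(n * c, 1, h, w)
    yf = y.reshape(n * c, 1, h, w)
    mu_x = xf.conv2d(kernel)
    mu_y = yf.conv2d(kernel)
    var_x = (xf * xf).conv2d(kernel) - mu_x * mu_x
    var_y = (yf * yf).conv2d(kernel) - mu_y * mu_y
    cov = (xf * yf).conv2d(kernel) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x * mu_x + mu_y * mu_y + c1) * (var_x + var_y + c2)
    return (num / den).mean()


def ssim_loss(a_batch, reconstructed_a, b_batch, reconstructed_b,
              ssim_params: SSIMLossParams | None = None) -> Tensor:
    """``E[1 - SSIM(a, roundtrip(a))] + E[1 - SSIM(b, roundtrip(b))]``.

    Inputs are expected in [0, 1] (remapped from the network range before
    the call). Bounded in [0, 4] since each SSIM lies in [-1, 1].
    """
    params = ssim_params or SSIMLossParams()
    a, ra = _lift(a_batch), _lift(reconstructed_a)
    b, rb = _lift(b_batch), _lift(reconstructed_b)
    _check_shapes(a, ra, "ssim_loss A-side")
    _check_shapes(b, rb, "ssim_loss B-side")
    return (1.0 - _ssim_tensor(a, ra, params)) + (1.0 - _ssim_tensor(b, rb, params))


# ---------------------------------------------------------------------------
# saliency
# ---------------------------------------------------------------------------

def saliency_mask(x, threshold: float, gain: float = 100.0):
    """Soft content mask ``sigmoid((x - T) * gain)``.

    Smooth and monotone in the pixel value; at high gain it approaches the
    hard indicator ``x > T``. Returns the same container kind as the input
    (Tensor in, Tensor out; array in, array out).
    """
    if isinstance(x, Tensor):
        return ((x - threshold) * gain).sigmoid()
    arr = (np.asarray(x, dtype=np.float64) - threshold) * gain
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    ex = np.exp(arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def saliency_loss(a_batch, g_a_outputs, b_batch, g_b_outputs,
                  config: LossConfig) -> Tensor:
    """L1 distance between input and translation soft masks, both directions.

    The A-side mask uses threshold ``T_A`` on the input and ``T_B`` on the
    translation (the translation lives in domain B), and symmetrically for
    the B side.
    """
    a, ga = _lift(a_batch), _lift(g_a_outputs)
    b, gb = _lift(b_batch), _lift(g_b_outputs)
    _check_shapes(a, ga, "saliency_loss A-side")
    _check_shapes(b, gb, "saliency_loss B-side")
    gain = config.sigmoid_gain
    term_a = (saliency_mask(a, config.threshold_A, gain)
              - saliency_mask(ga, config.threshold_B, gain)).abs().mean()
    term_b = (saliency_mask(b, config.threshold_B, gain)
              - saliency_mask(gb, config.threshold_A, gain)).abs().mean()
    return term_a + term_b


# ---------------------------------------------------------------------------
# total
# ---------------------------------------------------------------------------

def total_loss(gan_forward, gan_backward, cycle, ssim, saliency,
               config: LossConfig) -> LossBreakdown:
    """Assemble the weighted sum and keep the per-term breakdown for logging."""
    parts = {"gan_forward": gan_forward, "gan_backward": gan_backward,
             "cycle": cycle, "ssim": ssim, "saliency": saliency}
    vals = {}
    for name, v in parts.items():
        f = v.item() if isinstance(v, Tensor) else float(v)
        if not math.isfinite(f):
            raise ValueError(f"non-finite loss component: {name} = {f}")
        vals[name] = f
    tot = (vals["gan_forward"] + vals["gan_backward"]
           + config.lambda_cyc * vals["cycle"]
           + config.xi_ssim * vals["ssim"]
           + config.rho_saliency * vals["saliency"])
    return LossBreakdown(total=tot, **vals)


def otsu_threshold(tiles, n_sample: int | None = None) -> float:
    """Otsu threshold over a sample of [0, 1] training tiles (mask default)."""
    from skimage.filters import threshold_otsu
    arrs = [t.pixels if hasattr(t, "pixels") else np.asarray(t) for t in tiles]
    if n_sample is not None:
        arrs = arrs[:n_sample]
    stacked = np.concatenate([a.ravel() for a in arrs])
    if stacked.max() <= stacked.min():
        return float(stacked.mean())
    return float(threshold_otsu(stacked))
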