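"""Image-quality evaluation: PSNR, Pearson correlation, SSIM, FID and KID.

Paired metrics (PSNR/PCC/SSIM) score generated images against their ground
truth one pair at a time and are reported as mean +- sd over pairs. Set-level
metrics (FID/KID) compare feature-embedding distributions of the generated
and reference sets and need no pairing.

The feature embedding is pluggable. The default shipped embedding is a
deterministic seeded random projection of average-pooled patches — fully
offline and reproducible; FID/KID values are only comparable within one
embedding, and every report names the embedding used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import linalg as sla
from scipy.ndimage import correlate

from .imaging_io import DomainDataset, ImageTile

__all__ = ["SSIMParams", "FeatureEmbedding", "MetricReport", "psnr", "pcc",
           "ssim_index", "fid", "kid", "random_projection_embedding", "evaluate_sets"]


def _pixels(x) -> np.ndarray:
    return x.pixels if isinstance(x, ImageTile) else np.asarray(x)


@dataclass
class SSIMParams:
    """Constants and windowing for the structural similarity index.

    ``mode='global'`` evaluates the index once over the whole image (the
    literal mean/variance/cross-covariance form); ``mode='windowed'`` averages
    the index over 11x11 Gaussian-weighted sliding windows (sigma 1.5), the
    standard reference configuration. ``c1``/``c2`` default to ``(0.01 L)^2``
    and ``(0.03 L)^2`` for dynamic range ``L``.
    """

    dynamic_range: float = 1.0
    c1: float | None = None
    c2: float | None = None
    mode: str = "windowed"
    window_size: int = 11
    window_sigma: float = 1.5

    def resolved(self) -> tuple[float, float]:
        L = self.dynamic_range
        c1 = (0.01 * L) ** 2 if self.c1 is None else self.c1
        c2 = (0.03 * L) ** 2 if self.c2 is None else self.c2
        if c1 <= 0 or c2 <= 0:
            raise ValueError("SSIM stabilising constants must be positive")
        return c1, c2


@dataclass
class FeatureEmbedding:
    """A deterministic map from an image to a d-dimensional feature vector."""

    embed: Callable[[np.ndarray], np.ndarray]
    d: int
    name: str

    def __call__(self, image) -> np.ndarray:
        v = np.asarray(self.embed(_pixels(image)), dtype=np.float64)
        if v.shape != (self.d,):
            raise ValueError(f"embedding {self.name} returned shape {v.shape}, expected ({self.d},)")
        return v


@dataclass
class MetricReport:
    psnr_db_mean: float
    psnr_db_sd: float
    pcc_mean: float
    pcc_sd: float
    ssim_mean: float
    ssim_sd: float
    fid: float
    kid: float
    n_pairs: int
    n_images: int
    embedding: str
    per_pair: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("psnr_db_mean", "psnr_db_sd", "pcc_mean", "pcc_sd", "ssim_mean",
              "ssim_sd", "fid", "kid", "n_pairs", "n_images", "embedding")}
        return d


# ---------------------------------------------------------------------------
# paired metrics
# ---------------------------------------------------------------------------

def psnr(reference, test, max_value: float = 1.0, raw_ratio: bool = False) -> float:
    """Peak signal-to-noise ratio in decibels.

    ``10 * log10(MAX^2 / MSE)`` with the mean square error taken over all
    pixels (and channels). Identical images have zero MSE and return ``inf``.
    ``raw_ratio`` returns the unlogged ratio ``10 * MAX^2 / MSE`` instead.
    """
    a, b = _pixels(reference), _pixels(test)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    mse = float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))
    if mse == 0.0:
        return float("inf")
    if raw_ratio:
        return 10.0 * max_value ** 2 / mse
    return 10.0 * np.log10(max_value ** 2 / mse)


def pcc(a, b) -> float:
    """Pearson correlation over all pixels: cross-covariance / (sd_a * sd_b)."""
    x = _pixels(a).astype(np.float64).ravel()
    y = _pixels(b).astype(np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("PCC undefined for a constant image (zero variance)")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    half = (size - 1) / 2.0
    g = np.exp(-((np.arange(size) - half) ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim_index(a, b, params: SSIMParams | None = None) -> float:
    """Structural similarity index between two images.

    Global mode computes the single-term form
    ``(2 mu_a mu_b + c1)(2 sigma_ab + c2) / ((mu_a^2 + mu_b^2 + c1)(sigma_a^2 + sigma_b^2 + c2))``
    over the whole image; windowed mode averages that expression over
    Gaussian-weighted sliding windows, using only fully valid windows.
    Multi-channel images are averaged over channels.
    """
    params = params or SSIMParams()
    x, y = _pixels(a).astype(np.float64), _pixels(b).astype(np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim == 2:
        x, y = x[:, :, None], y[:, :, None]
    c1, c2 = params.resolved()
    vals = [_ssim_channel(x[:, :, c], y[:, :, c], c1, c2, params)
            for c in range(x.shape[2])]
    return float(np.mean(vals))


def _ssim_channel(x, y, c1, c2, params: SSIMParams) -> float:
    if params.mode == "global":
        mu_x, mu_y = x.mean(), y.mean()
        sig_x = x.var()
        sig_y = y.var()
        sig_xy = ((x - mu_x) * (y - mu_y)).mean()
        return ((2 * mu_x * mu_y + c1) * (2 * sig_xy + c2)
                / ((mu_x ** 2 + mu_y ** 2 + c1) * (sig_x + sig_y + c2)))
    if params.mode != "windowed":
        raise ValueError(f"unknown SSIM mode {params.mode!r}")
    win = params.window_size
    if min(x.shape) < win:
        raise ValueError(f"image smaller than SSIM window ({win})")
    w = _gaussian_window(win, params.window_sigma)
    mu_x = correlate(x, w, mode="constant")
    mu_y = correlate(y, w, mode="constant")
    sig_x = correlate(x * x, w, mode="constant") - mu_x ** 2
    sig_y = correlate(y * y, w, mode="constant") - mu_y ** 2
    sig_xy = correlate(x * y, w, mode="constant") - mu_x * mu_y
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * sig_xy + c2)
                / ((mu_x ** 2 + mu_y ** 2 + c1) * (sig_x + sig_y + c2)))
    pad = (win - 1) // 2
    core = ssim_map[pad:x.shape[0] - pad, pad:x.shape[1] - pad]
    return float(core.mean())


# ---------------------------------------------------------------------------
# set-level metrics
# ---------------------------------------------------------------------------

def fid(features_x: np.ndarray, features_y: np.ndarray, eps: float = 1e-6) -> float:
    """Frechet distance between Gaussian fits of two feature sets.

    ``||mu_x - mu_y||^2 + Tr(S_x + S_y - 2 (S_x S_y)^{1/2})`` from the sample
    means and covariances. Near-singular covariance products are regularised
    by ``eps * I`` before the matrix square root; the real part is taken.
    """
    X = np.atleast_2d(np.asarray(features_x, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(features_y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimension mismatch")
    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    cov_x = np.cov(X, rowvar=False).reshape(X.shape[1], X.shape[1])
    cov_y = np.cov(Y, rowvar=False).reshape(Y.shape[1], Y.shape[1])
    return fid_from_moments(mu_x, cov_x, mu_y, cov_y, eps=eps)


def fid_from_moments(mu_x, cov_x, mu_y, cov_y, eps: float = 1e-6) -> float:
    """FID evaluated directly from (mean, covariance) pairs."""
    mu_x, mu_y = np.atleast_1d(mu_x), np.atleast_1d(mu_y)
    cov_x = np.atleast_2d(cov_x)
    cov_y = np.atleast_2d(cov_y)
    diff = mu_x - mu_y
    prod = cov_x @ cov_y

    def _sqrtm(mat):
        res = sla.sqrtm(mat)
        return res[0] if isinstance(res, tuple) else res

    sqrt_prod = _sqrtm(prod)
    if not np.isfinite(sqrt_prod).all():
        sqrt_prod = _sqrtm(prod + eps * np.eye(prod.shape[0]))
    sqrt_prod = np.real(sqrt_prod)
    val = float(diff @ diff + np.trace(cov_x) + np.trace(cov_y) - 2.0 * np.trace(sqrt_prod))
    return max(val, 0.0) if abs(val) < 1e-8 else val


def _poly_kernel(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Cubic polynomial kernel k(x, y) = (x.y / d + 1)^3."""
    d = X.shape[1]
    return (X @ Y.T / d + 1.0) ** 3


def kid(features_x: np.ndarray, features_y: np.ndarray,
        n_subsets: int | None = None, subset_size: int | None = None,
        rng: np.random.Generator | None = None) -> float:
    """Unbiased squared maximum mean discrepancy with the cubic polynomial kernel.

    The plain estimator uses all samples; passing ``n_subsets``/``subset_size``
    averages the estimator over random subsets (the common reporting practice
    for large sets). Can be slightly negative by construction (unbiasedness).
    """
    X = np.atleast_2d(np.asarray(features_x, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(features_y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimension mismatch")
    if len(X) < 2 or len(Y) < 2:
        raise ValueError("KID needs at least 2 samples per set")
    if n_subsets:
        rng = rng or np.random.default_rng(0)
        size = subset_size or min(len(X), len(Y))
        vals = []
        for _ in range(n_subsets):
            xi = rng.choice(len(X), size=min(size, len(X)), replace=False)
            yi = rng.choice(len(Y), size=min(size, len(Y)), replace=False)
            vals.append(_mmd2_unbiased(X[xi], Y[yi]))
        return float(np.mean(vals))
    return _mmd2_unbiased(X, Y)


def _mmd2_unbiased(X: np.ndarray, Y: np.ndarray) -> float:
    m, n = len(X), len(Y)
    kxx = _poly_kernel(X, X)
    kyy = _poly_kernel(Y, Y)
    kxy = _poly_kernel(X, Y)
    sum_xx = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
    sum_yy = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    sum_xy = kxy.mean()
    return float(sum_xx + sum_yy - 2.0 * sum_xy)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def random_projection_embedding(d: int = 64, pool: int = 8, seed: int = 1234,
                                n_channels: int = 3) -> FeatureEmbedding:
    """Deterministic offline embedding: average-pool to ``pool x pool`` per
    channel, flatten, and project through a fixed seeded Gaussian matrix."""
    rng = np.random.default_rng(seed)
    in_dim = pool * pool * n_channels
    proj = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, d))

    def embed(pixels: np.ndarray) -> np.ndarray:
        px = np.asarray(pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.shape[2] < n_channels:  # replicate gray / pad stain2 to 3
            reps = [px[:, :, i % px.shape[2]] for i in range(n_channels)]
            px = np.stack(reps, axis=-1)
        elif px.shape[2] > n_channels:
            px = px[:, :, :n_channels]
        h, w, _ = px.shape
        ys = np.linspace(0, h, pool + 1).astype(int)
        xs = np.linspace(0, w, pool + 1).astype(int)
        pooled = np.empty((pool, pool, n_channels))
        for i in range(pool):
            for j in range(pool):
                pooled[i, j] = px[ys[i]:ys[i + 1], xs[j]:xs[j + 1]].mean(axis=(0, 1))
        return pooled.ravel() @ proj

    return FeatureEmbedding(embed=embed, d=d, name=f"randproj{d}-pool{pool}-seed{seed}")


# ---------------------------------------------------------------------------
# set evaluation
# ---------------------------------------------------------------------------

def evaluate_sets(generated: DomainDataset | Sequence, reference: DomainDataset | Sequence,
                  pairing: Optional[np.ndarray] = None,
                  embedding: FeatureEmbedding | None = None,
                  ssim_params: SSIMParams | None = None,
                  max_value: float = 1.0) -> MetricReport:
    """Full evaluation of a generated image set against a reference set.

    ``pairing[i]`` gives the reference index matching generated tile ``i``;
    it is required for the paired metrics and never touched by training. FID
    and KID are computed on the (unpaired) embedded sets regardless.
    """
    gen = list(generated.tiles if isinstance(generated, DomainDataset) else generated)
    ref = list(reference.tiles if isinstance(reference, DomainDataset) else reference)
    embedding = embedding or random_projection_embedding()
    ssim_params = ssim_params or SSIMParams(dynamic_range=max_value)

    psnrs, pccs, ssims = [], [], []
    if pairing is not None:
        pairing = np.asarray(pairing)
        if len(pairing) != len(gen):
            raise ValueError("pairing length must equal the generated set size")
        for i, j in enumerate(pairing):
            g, r = gen[i], ref[int(j)]
            psnrs.append(psnr(r, g, max_value=max_value))
            pccs.append(pcc(r, g))
            ssims.append(ssim_index(r, g, ssim_params))

    feats_g = np.array([embedding(t) for t in gen])
    feats_r = np.array([embedding(t) for t in ref])
    fid_val = fid(feats_g, feats_r)
    kid_val = kid(feats_g, feats_r)

    def _ms(vals):
        if not vals:
            return float("nan"), float("nan")
        arr = np.asarray(vals, dtype=np.float64)
        return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0

    pm, ps = _ms(psnrs)
    cm, cs = _ms(pccs)
    sm, ss = _ms(ssims)
    return MetricReport(
        psnr_db_mean=pm, psnr_db_sd=ps, pcc_mean=cm, pcc_sd=cs,
        ssim_mean=sm, ssim_sd=ss, fid=fid_val, kid=kid_val,
        n_pairs=0 if pairing is None else len(pairing),
        n_images=len(gen), embedding=embedding.name,
        per_pair={"psnr_db": psnrs, "pcc": pccs, "ssim": ssims})
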