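"""Synthetic two-channel fluorescence scenes and their label-free renderings.

Every downstream stage of the package (training, evaluation, morphometrics)
is exercisable on parametric cell scenes that mimic cultured fibroblast
morphology: oval nuclei (blue / Hoechst-analog channel) and curvilinear
F-actin filaments (green / FITC-analog channel). From one scene three images
are rendered:

* ``hr_stained``   — high-resolution two-channel stained tile,
* ``hr_unlabeled`` — a nonnegative channel mixture emulating a label-free
  intensity image at the same resolution (nuclei dominate the signal),
* ``lr_unlabeled`` — the unlabeled image degraded by a Gaussian optical blur
  whose FWHM models the physical lateral resolution limit (~6.6 um against a
  0.31 um/pixel grid) plus additive Gaussian noise.

The degradation is an optical-blur surrogate only; no photoacoustic forward
model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .imaging_io import DomainDataset, ImageTile

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2*sqrt(2 ln 2) * sigma

DEFAULT_PSF_FWHM_UM = 6.6      # lateral resolution of the low-resolution modality
DEFAULT_PIXEL_SIZE_UM = 0.31   # high-resolution sampling


@dataclass
class SceneParams:
    """Sampling ranges for a synthetic cell scene.

    Defaults describe a 256-px field at 0.31 um/pixel: nuclei with semi-axes
    of 10-24 px (6-15 um diameter) and a handful of actin filaments a few
    pixels wide, over a faint background.
    """

    field_size_px: int = 256
    n_nuclei: int = 6
    nucleus_axes_px: tuple[float, float] = (10.0, 24.0)
    n_filaments: int = 8
    filament_width_px: float = 3.0
    filament_n_control: int = 4
    background_level: float = 0.05
    noise_sd: float = 0.01
    no_overlap: bool = False

    def __post_init__(self):
        lo, hi = self.nucleus_axes_px
        if not (0 < lo <= hi):
            raise ValueError("nucleus_axes_px must be a nondegenerate positive range")
        if self.filament_width_px < 1:
            raise ValueError("filament width must be >= 1 px")
        if self.field_size_px < 8:
            raise ValueError("field_size_px too small")


@dataclass
class SceneSpec:
    """A fully materialised scene: every coordinate needed to re-render it."""

    seed: int
    field_size_px: int
    n_nuclei: int
    nucleus_axes_px: np.ndarray        # (n, 2) semi-axes (a, b), a >= b
    nucleus_orientations: np.ndarray   # (n,) radians
    nucleus_centers: np.ndarray        # (n, 2) (row, col)
    n_filaments: int
    filament_control_points: list      # list of (m, 2) arrays
    filament_width_px: float
    background_level: float
    noise_sd: float

    def __post_init__(self):
        if self.n_nuclei:
            if np.any(self.nucleus_axes_px <= 0):
                raise ValueError("semi-axes must be positive")
            c = self.nucleus_centers
            if np.any(c < 0) or np.any(c >= self.field_size_px):
                raise ValueError("nucleus centers must lie within the field")
        if self.filament_width_px < 1:
            raise ValueError("filament width must be >= 1 px")


@dataclass
class RenderedTriplet:
    hr_stained: ImageTile
    hr_unlabeled: ImageTile
    lr_unlabeled: ImageTile
    scene: SceneSpec


def sample_scene(seed: int, params: SceneParams | None = None) -> SceneSpec:
    """Draw a reproducible scene; same seed and parameters give identical output.

    With ``params.no_overlap`` the nuclei are placed by rejection sampling so
    that their bounding circles (radius = major semi-axis) are pairwise
    disjoint; if placement fails after a bounded number of attempts a
    ``RuntimeError`` names the density limit.
    """
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    n = params.n_nuclei
    lo, hi = params.nucleus_axes_px
    axes = np.zeros((n, 2))
    centers = np.zeros((n, 2))
    margin = hi if params.no_overlap else 0.0
    max_attempts = 200 * max(n, 1)
    attempts = 0
    placed = 0
    while placed < n:
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, min(a, hi))
        c = rng.uniform(margin, params.field_size_px - margin, size=2) \
            if params.field_size_px > 2 * margin else rng.uniform(0, params.field_size_px, size=2)
        if params.no_overlap and placed:
            radii = axes[:placed, 0] + a
            if np.any(np.linalg.norm(centers[:placed] - c, axis=1) < radii):
                attempts += 1
                if attempts > max_attempts:
                    raise RuntimeError(
                        f"could not place {n} non-overlapping nuclei of max radius {hi:.1f} px "
                        f"in a {params.field_size_px}-px field after {max_attempts} attempts; "
                        "reduce density or nucleus size")
                continue
        axes[placed] = (a, b)
        centers[placed] = c
        placed += 1
    orientations = rng.uniform(0.0, np.pi, size=n)
    filaments = []
    for _ in range(params.n_filaments):
        pts = rng.uniform(0, params.field_size_px, size=(params.filament_n_control, 2))
        filaments.append(pts)
    return SceneSpec(
        seed=seed, field_size_px=params.field_size_px, n_nuclei=n,
        nucleus_axes_px=axes, nucleus_orientations=orientations, nucleus_centers=centers,
        n_filaments=params.n_filaments, filament_control_points=filaments,
        filament_width_px=params.filament_width_px,
        background_level=params.background_level, noise_sd=params.noise_sd)


def _catmull_rom(points: np.ndarray, samples_per_segment: int = 32) -> np.ndarray:
    """Centripetal-free (uniform) Catmull-Rom curve through the control points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts
    ext = np.vstack([2 * pts[0] - pts[1], pts, 2 * pts[-1] - pts[-2]])
    out = []
    t = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)[:, None]
    for i in range(len(pts) - 1):
        p0, p1, p2, p3 = ext[i], ext[i + 1], ext[i + 2], ext[i + 3]
        out.append(0.5 * ((2 * p1) + (-p0 + p2) * t
                          + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t ** 2
                          + (-p0 + 3 * p1 - 3 * p2 + p3) * t ** 3))
    out.append(pts[-1][None])
    return np.vstack(out)


def _render_nuclei(scene: SceneSpec) -> np.ndarray:
    size = scene.field_size_px
    img = np.zeros((size, size), dtype=np.float64)
    if scene.n_nuclei == 0:
        return img.astype(np.float32)
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    for (a, b), theta, (cy, cx) in zip(scene.nucleus_axes_px, scene.nucleus_orientations,
                                       scene.nucleus_centers):
        dy, dx = rows - cy, cols - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        q = (u / a) ** 2 + (v / b) ** 2
        img = np.maximum(img, (q <= 1.0).astype(float))
    # sub-pixel feather so a 0.5 threshold recovers the analytic boundary
    return np.clip(gaussian_filter(img, 0.7, mode="reflect"), 0.0, 1.0).astype(np.float32)


def _render_filaments(scene: SceneSpec) -> np.ndarray:
    size = scene.field_size_px
    mask = np.zeros((size, size), dtype=bool)
    for pts in scene.filament_control_points:
        curve = _catmull_rom(pts)
        ij = np.round(curve).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < size) & (ij[:, 1] >= 0) & (ij[:, 1] < size)
        ij = ij[keep]
        if len(ij):
            mask[ij[:, 0], ij[:, 1]] = True
    if not mask.any():
        return np.zeros((size, size), dtype=np.float32)
    dist = distance_transform_edt(~mask)
    ribbon = (dist <= scene.filament_width_px / 2.0).astype(float)
    return np.clip(gaussian_filter(ribbon, 1.0, mode="reflect"), 0.0, 1.0).astype(np.float32)


def render_triplet(scene: SceneSpec,
                   psf_fwhm_um: float = DEFAULT_PSF_FWHM_UM,
                   pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                   unlabeled_mix: tuple[float, float] = (0.6, 0.4)) -> RenderedTriplet:
    """Render the stained / unlabeled / blurred-unlabeled triplet of a scene.

    The blur standard deviation follows the FWHM identity
    ``sigma_px = psf_fwhm_um / (2 sqrt(2 ln 2) * pixel_size_um)``; boundary
    handling is reflective so the blur conserves total intensity exactly.
    The unlabeled mixture weights (blue, green) default to (0.6, 0.4) —
    nuclei dominate the label-free signal.
    """
    if psf_fwhm_um <= 0:
        raise ValueError("psf_fwhm_um must be positive")
    if psf_fwhm_um <= pixel_size_um:
        raise ValueError("psf_fwhm_um must exceed pixel_size_um for a meaningful blur")
    blue = _render_nuclei(scene)
    green = _render_filaments(scene)
    hr_stained = np.stack([blue, green], axis=-1)
    wb, wg = unlabeled_mix
    if wb < 0 or wg < 0:
        raise ValueError("unlabeled mixture weights must be nonnegative")
    hr_unlabeled = np.clip(wb * blue + wg * green + scene.background_level, 0.0, 1.0)
    sigma_px = psf_fwhm_um / (FWHM_TO_SIGMA * pixel_size_um)
    lr = gaussian_filter(hr_unlabeled.astype(np.float64), sigma_px, mode="reflect")
    if scene.noise_sd > 0:
        noise_rng = np.random.default_rng((scene.seed ^ 0x5EED) & 0x7FFFFFFF)
        lr = lr + noise_rng.normal(0.0, scene.noise_sd, size=lr.shape)
    lr_unlabeled = np.clip(lr, 0.0, 1.0).astype(np.float32)
    mk = lambda px, ch: ImageTile(px, channels=ch, value_range=(0.0, 1.0),
                                  pixel_size_um=pixel_size_um)
    return RenderedTriplet(
        hr_stained=mk(hr_stained, "stain2"),
        hr_unlabeled=mk(hr_unlabeled.astype(np.float32), "gray1"),
        lr_unlabeled=mk(lr_unlabeled, "gray1"),
        scene=scene)


def psf_sigma_px(psf_fwhm_um: float, pixel_size_um: float) -> float:
    """Gaussian sigma (pixels) equivalent to an optical FWHM in micrometres."""
    return psf_fwhm_um / (FWHM_TO_SIGMA * pixel_size_um)


def _derive_seed(master_seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([master_seed, *tags]).generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(n_scenes: int, seed: int, paired: bool = False,
                     params: SceneParams | None = None,
                     psf_fwhm_um: float = DEFAULT_PSF_FWHM_UM,
                     pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                     ) -> tuple[DomainDataset, DomainDataset, Optional[np.ndarray]]:
    """Build the two training domains from independent (or shared) scenes.

    Domain A collects the low-resolution unlabeled tiles and domain B the
    high-resolution stained tiles. Unpaired mode (the training condition)
    renders A and B from disjoint scene seeds; paired mode reuses one scene
    per index and returns the identity pairing, for evaluation only.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    params = params or SceneParams()
    a_tiles, b_tiles = [], []
    for i in range(n_scenes):
        seed_a = _derive_seed(seed, 0, i)
        seed_b = seed_a if paired else _derive_seed(seed, 1, i)
        trip_a = render_triplet(sample_scene(seed_a, params), psf_fwhm_um, pixel_size_um)
        trip_b = trip_a if paired else render_triplet(sample_scene(seed_b, params),
                                                      psf_fwhm_um, pixel_size_um)
        a_tiles.append(trip_a.lr_unlabeled)
        b_tiles.append(trip_b.hr_stained)
    slides_a = [f"sceneA{i}" for i in range(n_scenes)]
    slides_b = [f"sceneB{i}" for i in range(n_scenes)]
    pairing = np.arange(n_scenes) if paired else None
    return (DomainDataset(a_tiles, "A", slides_a),
            DomainDataset(b_tiles, "B", slides_b),
            pairing)


def toy_dataset(n_scenes: int, seed: int, field_size_px: int = 64,
                paired: bool = False):
    """Small-field study condition: 64-px tiles at 4x-binned sampling.

    The physical point-spread function is kept (6.6 um FWHM) while the pixel
    size is coarsened to 1.24 um/pixel so one tile spans ~80 um and holds a
    few nuclei — the same structure as the full-size condition at a fraction
    of the compute.
    """
    scale = field_size_px / 256.0
    params = SceneParams(
        field_size_px=field_size_px,
        n_nuclei=max(2, round(6 * scale)),
        nucleus_axes_px=(max(3.0, 10.0 * scale * 2), max(4.0, 24.0 * scale * 2)),
        n_filaments=max(2, round(8 * scale)),
        filament_width_px=2.0,
        background_level=0.05,
        noise_sd=0.01)
    return generate_dataset(n_scenes, seed, paired=paired, params=params,
                            psf_fwhm_um=DEFAULT_PSF_FWHM_UM, pixel_size_um=1.24)
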