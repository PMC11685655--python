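"""Image containers, I/O, tiling, augmentation and cross-validation folds.

The package works on two unpaired image domains: domain A holds low-resolution
label-free intensity tiles (grayscale) and domain B holds high-resolution
stained tiles (two fluorescence channels: blue = nuclei, green = F-actin).
Intensities are kept in a canonical [0, 1] range at the I/O boundary; the
mapping to the [-1, 1] network range happens only at training/inference time.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

log = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_UM = 0.31  # confocal sampling at 20x magnification
CHANNEL_LAYOUTS = ("gray1", "rgb3", "stain2")


@dataclass
class ImageTile:
    """A single 2-D image with channel semantics and physical pixel size.

    ``pixels`` is (H, W, C) float; ``channels`` is one of ``gray1`` (C=1),
    ``rgb3`` (C=3) or ``stain2`` (C=2, ordered blue then green).
    """

    pixels: np.ndarray
    channels: str = "gray1"
    value_range: tuple[float, float] = (0.0, 1.0)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValueError(f"pixels must be 2-D or (H, W, C); got shape {px.shape}")
        self.pixels = px.astype(np.float32, copy=False)
        expected = {"gray1": 1, "rgb3": 3, "stain2": 2}
        if self.channels not in expected:
            raise ValueError(f"unknown channel layout {self.channels!r}; expected one of {CHANNEL_LAYOUTS}")
        if px.shape[2] != expected[self.channels]:
            raise ValueError(f"layout {self.channels} expects {expected[self.channels]} channels, "
                             f"got {px.shape[2]}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.value_range
        if not (np.all(self.pixels >= lo - 1e-6) and np.all(self.pixels <= hi + 1e-6)):
            raise ValueError(f"intensities outside declared value_range [{lo}, {hi}]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def with_pixels(self, pixels: np.ndarray) -> "ImageTile":
        return replace(self, pixels=pixels)


@dataclass
class DomainDataset:
    """An ordered set of tiles from one domain, tagged with source slides."""

    tiles: list[ImageTile]
    domain_label: str  # "A" or "B"
    source_slide_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.domain_label not in ("A", "B"):
            raise ValueError("domain_label must be 'A' or 'B'")
        if not self.source_slide_ids:
            self.source_slide_ids = ["slide0"] * len(self.tiles)
        if len(self.source_slide_ids) != len(self.tiles):
            raise ValueError("one source_slide_id per tile required")
        if self.tiles:
            first = self.tiles[0]
            for t in self.tiles:
                if t.pixels.shape != first.pixels.shape or t.channels != first.channels:
                    raise ValueError("all tiles in a domain must share shape and channel layout")

    def __len__(self) -> int:
        return len(self.tiles)

    def subset(self, indices) -> "DomainDataset":
        return DomainDataset([self.tiles[i] for i in indices], self.domain_label,
                             [self.source_slide_ids[i] for i in indices])


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_slide_ids: frozenset
    val_slide_ids: frozenset

    def __post_init__(self):
        if self.train_slide_ids & self.val_slide_ids:
            raise ValueError("train and validation slides must be disjoint")


# ---------------------------------------------------------------------------
# tiling / augmentation / normalisation / folds
# ---------------------------------------------------------------------------

def tile_image(image: ImageTile, tile_size: int, stride: int | None = None,
               random_offset: bool = False, rng: np.random.Generator | None = None) -> list[ImageTile]:
    """Cut a whole-slide image into a row-major grid of square tiles.

    With ``random_offset`` the grid origin is jittered (seeded via ``rng``),
    mimicking random tile placement; the default is the deterministic grid.
    Returns an empty list (with a warning) if the image is smaller than
    ``tile_size`` in either dimension.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    stride = tile_size if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.height, image.width
    if h < tile_size or w < tile_size:
        log.warning("image of size %dx%d smaller than tile_size %d; no tiles produced",
                    h, w, tile_size)
        return []
    off_y = off_x = 0
    if random_offset:
        rng = rng or np.random.default_rng()
        max_y = (h - tile_size) % stride
        max_x = (w - tile_size) % stride
        off_y = int(rng.integers(0, max_y + 1))
        off_x = int(rng.integers(0, max_x + 1))
    tiles = []
    for y in range(off_y, h - tile_size + 1, stride):
        for x in range(off_x, w - tile_size + 1, stride):
            tiles.append(image.with_pixels(image.pixels[y:y + tile_size, x:x + tile_size].copy()))
    return tiles


def stitch_tiles(tiles: list[ImageTile], n_rows: int, n_cols: int) -> ImageTile:
    """Reassemble a non-overlapping row-major grid of equally sized tiles."""
    if len(tiles) != n_rows * n_cols:
        raise ValueError("tile count does not match grid")
    rows = [np.concatenate([t.pixels for t in tiles[r * n_cols:(r + 1) * n_cols]], axis=1)
            for r in range(n_rows)]
    return tiles[0].with_pixels(np.concatenate(rows, axis=0))


_AUG_OPS = {
    "hflip": lambda p: p[:, ::-1],
    "vflip": lambda p: p[::-1, :],
    "rot90": lambda p: np.rot90(p, 1),
    "rot180": lambda p: np.rot90(p, 2),
    "rot270": lambda p: np.rot90(p, 3),
}


def apply_augmentation(tile: ImageTile, op: str) -> ImageTile:
    if op not in _AUG_OPS:
        raise ValueError(f"unknown augmentation {op!r}; valid: {sorted(_AUG_OPS)}")
    if op in ("rot90", "rot270") and tile.height != tile.width:
        raise ValueError(f"{op} on a non-square tile would change its shape")
    return tile.with_pixels(np.ascontiguousarray(_AUG_OPS[op](tile.pixels)))


def augment_tiles(tiles: list[ImageTile], ops=("hflip", "vflip", "rot90", "rot180", "rot270")) -> list[ImageTile]:
    """Return the originals plus each requested exact (lossless) transform.

    All transforms are pixel permutations from the dihedral group of the
    square grid; no interpolation is involved, so a transform composed with
    its inverse is bit-exact.
    """
    if not tiles:
        raise ValueError("augment_tiles requires a non-empty tile collection")
    out = list(tiles)
    for op in ops:
        out.extend(apply_augmentation(t, op) for t in tiles)
    return out


def normalize_image(image: ImageTile, lo_percentile: float = 0.0, hi_percentile: float = 1.0) -> ImageTile:
    """Percentile-stretch intensities onto [0, 1] with clipping.

    The lo/hi percentile values (fractions in [0, 1]) map to 0 and 1; values
    outside are clipped. A constant image has no dynamic range: it maps to
    all zeros and a warning is logged.
    """
    if not (0.0 <= lo_percentile < hi_percentile <= 1.0):
        raise ValueError("need 0 <= lo_percentile < hi_percentile <= 1")
    px = image.pixels.astype(np.float64)
    lo = np.quantile(px, lo_percentile)
    hi = np.quantile(px, hi_percentile)
    if hi <= lo:
        log.warning("image has zero dynamic range between the given percentiles; returning zeros")
        out = np.zeros_like(px, dtype=np.float32)
    else:
        out = np.clip((px - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)
    return replace(image, pixels=out, value_range=(0.0, 1.0))


def median_denoise(image: ImageTile, size: int = 3) -> ImageTile:
    """Optional pre-processing noise filter (median, off by default upstream)."""
    from scipy.ndimage import median_filter
    out = np.stack([median_filter(image.pixels[:, :, c], size=size)
                    for c in range(image.n_channels)], axis=-1)
    return image.with_pixels(out)


def make_cv_folds(slide_ids, k: int) -> list[FoldSplit]:
    """Deterministic k-fold partition of slides (input order preserved).

    Each fold holds out one contiguous chunk of slides for validation; the
    validation sets are disjoint and together cover every slide exactly once.
    For four slides and k=4 this is the 3-train / 1-validation rotation.
    """
    slide_ids = list(slide_ids)
    if len(set(slide_ids)) != len(slide_ids):
        raise ValueError("slide_ids must be unique")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(slide_ids):
        raise ValueError(f"k={k} exceeds number of slides ({len(slide_ids)})")
    chunks = np.array_split(np.arange(len(slide_ids)), k)
    folds = []
    for i, chunk in enumerate(chunks):
        val = frozenset(slide_ids[j] for j in chunk)
        train = frozenset(s for s in slide_ids if s not in val)
        folds.append(FoldSplit(fold_index=i, train_slide_ids=train, val_slide_ids=val))
    return folds


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path, channels: str | None = None,
               pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> ImageTile:
    """Read a TIFF or PNG image into a [0, 1]-scaled :class:`ImageTile`.

    Integer images are scaled by their dtype maximum (so 16-bit TIFFs keep
    their full dynamic range before any percentile normalisation).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[0] in (1, 2, 3) and arr.shape[0] < arr.shape[2]:
        arr = np.moveaxis(arr, 0, -1)  # planar TIFF -> (H, W, C)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if channels is None:
        channels = {1: "gray1", 2: "stain2", 3: "rgb3"}[arr.shape[2]]
    if channels == "stain2" and arr.shape[2] == 3:
        # stained images exported as RGB carry (blue, green) in B and G
        arr = arr[:, :, [2, 1]]
    if channels == "gray1" and arr.shape[2] == 3:
        arr = arr.mean(axis=2, keepdims=True)
    arr = np.clip(arr, 0.0, 1.0)
    return ImageTile(arr, channels=channels, value_range=(0.0, 1.0), pixel_size_um=pixel_size_um)


def write_image(path: str | Path, tile: ImageTile, dtype: str = "uint16") -> None:
    """Write a tile to TIFF (16-bit preserved) or PNG (8-bit).

    Two-channel stained tiles are exported as RGB with blue and green in the
    B and G positions and the red plane zeroed.
    """
    path = Path(path)
    lo, hi = tile.value_range
    px = (tile.pixels - lo) / (hi - lo) if hi > lo else tile.pixels
    px = np.clip(px, 0.0, 1.0)
    if tile.channels == "stain2":
        rgb = np.zeros(px.shape[:2] + (3,), dtype=px.dtype)
        rgb[:, :, 2] = px[:, :, 0]  # blue = nuclei
        rgb[:, :, 1] = px[:, :, 1]  # green = F-actin
        px = rgb
    if px.shape[2] == 1:
        px = px[:, :, 0]
    if path.suffix.lower() in (".tif", ".tiff"):
        if dtype == "uint16":
            tifffile.imwrite(path, (px * 65535.0 + 0.5).astype(np.uint16))
        else:
            tifffile.imwrite(path, (px * 255.0 + 0.5).astype(np.uint8))
    else:
        Image.fromarray((px * 255.0 + 0.5).astype(np.uint8)).save(path)


def write_manifest(path: str | Path, entries: list[dict]) -> None:
    """Write a dataset manifest: one record per file with domain and slide id."""
    for e in entries:
        missing = {"path", "domain", "slide_id"} - set(e)
        if missing:
            raise ValueError(f"manifest entry missing keys {sorted(missing)}")
    Path(path).write_text(json.dumps(entries, indent=2))


def read_manifest(path: str | Path) -> list[dict]:
    entries = json.loads(Path(path).read_text())
    if not isinstance(entries, list):
        raise ValueError("manifest must be a JSON list of records")
    return entries


def load_domain(manifest_path: str | Path, domain: str,
                pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> DomainDataset:
    """Load every manifest entry of one domain into a :class:`DomainDataset`."""
    root = Path(manifest_path).parent
    tiles, slides = [], []
    for e in read_manifest(manifest_path):
        if e["domain"] != domain:
            continue
        p = Path(e["path"])
        if not p.is_absolute():
            p = root / p
        tiles.append(read_image(p, channels=e.get("channels"), pixel_size_um=pixel_size_um))
        slides.append(str(e["slide_id"]))
    return DomainDataset(tiles, domain, slides)
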