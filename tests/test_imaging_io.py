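"""Tiling, augmentation, normalisation, folds and file I/O."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from staincycle.imaging_io import (DomainDataset, FoldSplit, ImageTile,
                                   apply_augmentation, augment_tiles,
                                   make_cv_folds, normalize_image, read_image,
                                   read_manifest, stitch_tiles, tile_image,
                                   write_image, write_manifest)


def _tile(arr, **kw):
    return ImageTile(np.asarray(arr, dtype=np.float32), **kw)


def _ramp(h, w):
    return (np.arange(h * w, dtype=np.float32).reshape(h, w) / (h * w - 1))


class TestTiling:
    @pytest.mark.parametrize("size,tile,stride,expected", [
        (512, 256, 256, 4),
        (512, 256, 128, 9),
        (256, 256, 256, 1),
        (300, 256, 40, 4),   # floor((300-256)/40+1)^2 = 2^2
    ])
    def test_grid_count_matches_closed_form(self, size, tile, stride, expected):
        img = _tile(_ramp(size, size))
        tiles = tile_image(img, tile, stride)
        per_axis = (size - tile) // stride + 1
        assert len(tiles) == per_axis ** 2 == expected

    def test_small_image_yields_empty_with_warning(self, caplog):
        img = _tile(_ramp(200, 200))
        with caplog.at_level(logging.WARNING):
            tiles = tile_image(img, 256, 256)
        assert tiles == []
        assert any("no tiles" in r.message for r in caplog.records)

    def test_tiles_inherit_metadata(self):
        img = _tile(_ramp(512, 512), pixel_size_um=0.62)
        t = tile_image(img, 256, 256)[0]
        assert t.pixel_size_um == 0.62
        assert t.value_range == img.value_range

    def test_tile_then_stitch_reconstructs_bit_exactly(self):
        img = _tile(_ramp(512, 512))
        tiles = tile_image(img, 128, 128)
        rebuilt = stitch_tiles(tiles, 4, 4)
        assert np.array_equal(rebuilt.pixels, img.pixels)

    def test_random_offset_mode_is_seeded(self):
        img = _tile(_ramp(300, 300))
        a = tile_image(img, 128, 64, random_offset=True, rng=np.random.default_rng(5))
        b = tile_image(img, 128, 64, random_offset=True, rng=np.random.default_rng(5))
        assert len(a) == len(b)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))


class TestAugmentation:
    def test_all_ops_multiply_count_by_six(self):
        tiles = [_tile(_ramp(8, 8)) for _ in range(10)]
        assert len(augment_tiles(tiles)) == 60

    def test_constant_tile_is_fixed_point(self):
        t = _tile(np.full((6, 6), 0.25))
        for op in ("hflip", "vflip", "rot90", "rot180", "rot270"):
            assert np.array_equal(apply_augmentation(t, op).pixels, t.pixels)

    @pytest.mark.parametrize("op,inverse", [
        ("hflip", "hflip"), ("vflip", "vflip"), ("rot180", "rot180"),
        ("rot90", "rot270"), ("rot270", "rot90"),
    ])
    def test_dihedral_involutions_are_bit_exact(self, op, inverse, rng):
        t = _tile(rng.random((16, 16, 2), dtype=np.float32), channels="stain2")
        back = apply_augmentation(apply_augmentation(t, op), inverse)
        assert np.array_equal(back.pixels, t.pixels)

    def test_rot90_on_nonsquare_raises(self):
        t = _tile(_ramp(4, 8))
        with pytest.raises(ValueError, match="non-square"):
            apply_augmentation(t, "rot90")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment_tiles([])


class TestNormalization:
    def test_minmax_endpoints(self):
        img = ImageTile(np.array([[10.0, 100.0], [150.0, 200.0]], dtype=np.float32),
                        value_range=(0.0, 255.0))
        out = normalize_image(img, 0.0, 1.0)
        assert out.pixels.min() == 0.0 and out.pixels.max() == 1.0
        assert out.value_range == (0.0, 1.0)

    def test_idempotent_on_normalized_image(self, rng):
        img = _tile(rng.random((8, 8), dtype=np.float32))
        once = normalize_image(img, 0.0, 1.0)
        twice = normalize_image(once, 0.0, 1.0)
        assert np.allclose(once.pixels, twice.pixels, atol=1e-6)

    def test_percentile_clipping_matches_per_pixel_oracle(self):
        vals = np.arange(0, 251, 50, dtype=np.float32)  # 0, 50, ..., 250
        img = ImageTile(np.tile(vals, (6, 1)), value_range=(0.0, 255.0))
        out = normalize_image(img, 0.1, 0.9)
        lo = np.quantile(img.pixels, 0.1)
        hi = np.quantile(img.pixels, 0.9)
        oracle = np.clip((img.pixels.astype(np.float64) - lo) / (hi - lo), 0, 1)
        assert np.allclose(out.pixels, oracle, atol=1e-6)
        assert (out.pixels == 0).any() and (out.pixels == 1).any()

    def test_constant_image_returns_zeros_and_warns(self, caplog):
        img = _tile(np.full((4, 4), 0.3))
        with caplog.at_level(logging.WARNING):
            out = normalize_image(img)
        assert np.array_equal(out.pixels, np.zeros_like(out.pixels))
        assert any("dynamic range" in r.message for r in caplog.records)


class TestFolds:
    def test_four_slides_four_folds_is_three_train_one_val(self):
        folds = make_cv_folds(["s1", "s2", "s3", "s4"], 4)
        assert len(folds) == 4
        for f in folds:
            assert len(f.val_slide_ids) == 1
            assert len(f.train_slide_ids) == 3

    @pytest.mark.parametrize("n,k", [(4, 4), (5, 5), (7, 3), (10, 4)])
    def test_validation_sets_partition_the_slides(self, n, k):
        slides = [f"wsi{i}" for i in range(n)]
        folds = make_cv_folds(slides, k)
        all_val = [s for f in folds for s in f.val_slide_ids]
        assert sorted(all_val) == sorted(slides)  # coverage, no repeats
        for f in folds:
            assert f.train_slide_ids | f.val_slide_ids == set(slides)

    def test_too_many_folds_raises(self):
        with pytest.raises(ValueError):
            make_cv_folds(["a", "b"], 3)

    def test_deterministic_given_order(self):
        slides = ["a", "b", "c", "d", "e"]
        assert make_cv_folds(slides, 5) == make_cv_folds(slides, 5)


class TestIO:
    def test_tiff_16bit_roundtrip(self, tmp_path, rng):
        px = rng.random((32, 32), dtype=np.float32)
        tile = _tile(px)
        path = tmp_path / "t.tif"
        write_image(path, tile)
        back = read_image(path)
        assert back.pixels.shape == (32, 32, 1)
        assert np.allclose(back.pixels[:, :, 0], px, atol=1.0 / 65535 + 1e-6)

    def test_stain2_exports_blue_green_with_zero_red(self, tmp_path, rng):
        px = rng.random((16, 16, 2), dtype=np.float32)
        path = tmp_path / "s.tif"
        write_image(path, _tile(px, channels="stain2"))
        import tifffile
        raw = tifffile.imread(path)
        assert raw.shape == (16, 16, 3)
        assert raw[:, :, 0].max() == 0  # red plane zeroed
        back = read_image(path, channels="stain2")
        assert np.allclose(back.pixels, px, atol=1.0 / 65535 + 1e-6)

    def test_manifest_roundtrip_and_validation(self, tmp_path):
        entries = [{"path": "a.tif", "domain": "A", "slide_id": "s1"}]
        write_manifest(tmp_path / "m.json", entries)
        assert read_manifest(tmp_path / "m.json") == entries
        with pytest.raises(ValueError):
            write_manifest(tmp_path / "bad.json", [{"path": "x"}])


class TestDomainTypes:
    def test_tile_invariants_enforced(self):
        with pytest.raises(ValueError):
            ImageTile(np.ones((4, 4, 2)), channels="gray1")
        with pytest.raises(ValueError):
            ImageTile(np.ones((4, 4)), pixel_size_um=-1.0)
        with pytest.raises(ValueError):
            ImageTile(np.full((4, 4), 2.0), value_range=(0.0, 1.0))

    def test_dataset_requires_homogeneous_tiles(self):
        a = _tile(np.zeros((4, 4)))
        b = _tile(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            DomainDataset([a, b], "A")

    def test_fold_disjointness_enforced(self):
        with pytest.raises(ValueError):
            FoldSplit(0, frozenset({"a"}), frozenset({"a"}))


@given(st.integers(64, 300), st.integers(16, 64), st.integers(8, 64))
@settings(max_examples=25, deadline=None)
def test_tiling_count_formula_property(size, tile, stride):
    img = ImageTile(np.zeros((size, size, 1), dtype=np.float32))
    tiles = tile_image(img, tile, stride)
    per_axis = (size - tile) // stride + 1 if size >= tile else 0
    assert len(tiles) == max(per_axis, 0) ** 2
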