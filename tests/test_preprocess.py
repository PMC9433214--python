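"""Grayscale conversion, clip-limited equalization, hair removal."""

import dataclasses

import numpy as np
import pytest

from swarmseg.phantoms import PhantomSpec, generate_phantom
from swarmseg.preprocess import (
    EnhanceParams,
    FormatError,
    average_pixels,
    enhance,
    remove_hair,
    to_grayscale,
)


class TestToGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((255, 0, 0), 77)],
    )
    def test_luminance_weights(self, rgb, expected):
        img = np.tile(np.array(rgb, dtype=np.uint8), (4, 4, 1))
        out = to_grayscale(img)
        assert out.shape == (4, 4)
        assert np.all(out == expected)

    def test_idempotent_on_grayscale(self, rng):
        gray = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        np.testing.assert_array_equal(to_grayscale(gray), gray)

    def test_rejects_bad_channel_count(self):
        with pytest.raises(FormatError):
            to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))


class TestAveragePixels:
    def test_known_region_occupancies(self):
        single = EnhanceParams(tile_rows=1, tile_cols=1, n_bins=256)
        assert average_pixels(np.zeros((64, 64), np.uint8), single) == 16.0
        assert average_pixels(np.zeros((256, 256), np.uint8), single) == 256.0

    def test_one_bin_degenerates_to_pixel_count(self):
        params = EnhanceParams(tile_rows=1, tile_cols=1, n_bins=1)
        assert average_pixels(np.zeros((10, 10), np.uint8), params) == 100.0

    def test_tiled_grid_shape(self):
        params = EnhanceParams(tile_rows=4, tile_cols=2)
        out = average_pixels(np.zeros((64, 64), np.uint8), params)
        assert out.shape == (4, 2)
        assert np.allclose(out, (16 * 32) / 256)  # tile pixels / bins


def _textbook_hist_eq(img: np.ndarray) -> np.ndarray:
    """Independent plain histogram equalization (cumulative-histogram form)."""
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    cdf = hist.cumsum()
    cdf_min = cdf[cdf > 0][0]
    lut = np.floor(255.0 * (cdf - cdf_min) / (cdf[-1] - cdf_min) + 0.5)
    return lut[img].astype(np.uint8)


class TestEnhance:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 97, dtype=np.uint8)
        np.testing.assert_array_equal(enhance(img, EnhanceParams()), img)

    def test_unclipped_single_region_equals_plain_equalization(self, rng):
        img = rng.integers(30, 200, size=(40, 40)).astype(np.uint8)
        params = EnhanceParams(
            clip_limit_multiplier=np.inf, tile_rows=1, tile_cols=1, n_bins=256
        )
        np.testing.assert_array_equal(enhance(img, params), _textbook_hist_eq(img))

    def test_two_level_contrast_expands(self, two_level_spec):
        # mild-contrast variant so the expansion is unambiguous
        spec = dataclasses.replace(
            two_level_spec, blob_intensity_mean=140.0, background_intensity_mean=100.0
        )
        img = generate_phantom(spec).image
        out = enhance(img, EnhanceParams(tile_rows=1, tile_cols=1))
        in_gap = 140 - 100
        lo = np.unique(out[img == 100]).item()
        hi = np.unique(out[img == 140]).item()
        assert hi - lo > in_gap

    def test_shape_bounds_and_monotone_mapping(self, rng):
        img = rng.integers(0, 256, size=(50, 70)).astype(np.uint8)
        out = enhance(img, EnhanceParams(tile_rows=1, tile_cols=1))
        assert out.shape == img.shape
        # single-region mapping must be monotone non-decreasing in input
        order = np.argsort(img.ravel(), kind="stable")
        mapped = out.ravel()[order]
        assert np.all(np.diff(mapped.astype(int))[np.diff(img.ravel()[order]) > 0] >= 0)

    def test_tiled_output_in_range(self, noisy_spec):
        img = generate_phantom(noisy_spec).image
        out = enhance(img, EnhanceParams(tile_rows=4, tile_cols=4))
        assert out.shape == img.shape and out.dtype == np.uint8


class TestRemoveHair:
    def test_near_noop_without_hair(self):
        spec = PhantomSpec(width=128, height=128, noise_sigma=8.0, hair_count=0, seed=3)
        img = generate_phantom(spec).image
        out = remove_hair(img)
        assert np.mean(out != img) < 0.01

    def test_restores_hairless_render(self):
        hairy_spec = PhantomSpec(
            width=128, height=128, noise_sigma=8.0, hair_count=5, seed=4
        )
        clean_spec = dataclasses.replace(hairy_spec, hair_count=0)
        hairy = generate_phantom(hairy_spec).image.astype(float)
        clean = generate_phantom(clean_spec).image.astype(float)
        cleaned = remove_hair(hairy.astype(np.uint8)).astype(float)
        mae_before = np.abs(hairy - clean).mean()
        mae_after = np.abs(cleaned - clean).mean()
        assert mae_after < mae_before

    def test_all_black_unchanged(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        np.testing.assert_array_equal(remove_hair(img), img)

    def test_color_roundtrip_shape(self):
        spec = PhantomSpec(width=64, height=64, noise_sigma=5.0, hair_count=2, seed=5)
        gray = generate_phantom(spec).image
        color = np.dstack([gray, gray, gray])
        out = remove_hair(color)
        assert out.shape == color.shape
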