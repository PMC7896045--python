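"""Tiling, padding, background filtering and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wsiweak.synthdata import SyntheticSlideSpec, generate_slide
from wsiweak.tiling import (
    AugmentationParams,
    augment,
    downscale,
    downscale_um,
    filter_tiles,
    is_background,
    pad_to_square,
    tile_slide,
)


class TestDownscale:
    def test_point_two_rule(self):
        img = np.zeros((1000, 800, 3), dtype=np.uint8)
        out = downscale(img, 0.2)
        assert out.shape == (200, 160, 3)

    def test_identity_factor(self):
        img = np.random.default_rng(0).integers(
            0, 256, (64, 64, 3), dtype=np.uint8
        )
        np.testing.assert_array_equal(downscale(img, 1.0), img)

    def test_pixel_spacing_rule(self):
        assert downscale_um(0.46, 0.2) == pytest.approx(2.3)

    def test_too_small_output_rejected(self):
        with pytest.raises(ValueError):
            downscale(np.zeros((3, 3, 3), dtype=np.uint8), 0.1)

    def test_factor_above_one_rejected(self):
        with pytest.raises(ValueError):
            downscale(np.zeros((8, 8, 3), dtype=np.uint8), 1.5)


class TestPadToSquare:
    def test_white_padding_outside_content(self):
        img = np.zeros((100, 80, 3), dtype=np.uint8)
        p = pad_to_square(img, 128)
        assert p.image.shape == (128, 128, 3)
        assert np.all(p.image[:100, :80] == 0)
        assert np.all(p.image[100:, :] == 255)
        assert np.all(p.image[:, 80:] == 255)

    def test_already_square_unchanged(self):
        img = np.random.default_rng(1).integers(
            0, 256, (64, 64, 3), dtype=np.uint8
        )
        p = pad_to_square(img, 64)
        np.testing.assert_array_equal(p.image, img)

    def test_content_preserved_exactly(self):
        img = np.random.default_rng(2).integers(
            0, 256, (50, 70, 3), dtype=np.uint8
        )
        p = pad_to_square(img, 96)
        np.testing.assert_array_equal(p.image[:50, :70], img)

    def test_no_cropping_allowed(self):
        with pytest.raises(ValueError, match="crop"):
            pad_to_square(np.zeros((100, 80, 3), dtype=np.uint8), 90)


class TestTiling:
    def test_448_square_gives_four_tiles(self):
        tiles = tile_slide(np.zeros((448, 448, 3), dtype=np.uint8))
        assert len(tiles) == 4

    def test_rectangular_grid(self):
        tiles = tile_slide(np.zeros((448, 672, 3), dtype=np.uint8))
        assert len(tiles) == 6
        assert max(t.grid_row for t in tiles) == 1
        assert max(t.grid_col for t in tiles) == 2

    def test_reassembly_reproduces_padded_image(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (300, 500, 3), dtype=np.uint8)
        tiles = tile_slide(img)
        rows = max(t.grid_row for t in tiles) + 1
        cols = max(t.grid_col for t in tiles) + 1
        canvas = np.zeros((rows * 224, cols * 224, 3), dtype=np.uint8)
        for t in tiles:
            r0, c0 = t.origin
            canvas[r0:r0 + 224, c0:c0 + 224] = t.pixels
        np.testing.assert_array_equal(canvas[:300, :500], img)
        assert np.all(canvas[300:, :] == 255)
        assert np.all(canvas[:, 500:] == 255)


class TestBackgroundFilter:
    def test_all_white_is_background(self):
        assert is_background(np.full((224, 224, 3), 255, dtype=np.uint8))

    def test_221_everywhere_is_background(self):
        assert is_background(np.full((224, 224, 3), 221, dtype=np.uint8))

    def test_single_220_pixel_is_foreground(self):
        t = np.full((224, 224, 3), 255, dtype=np.uint8)
        t[100, 100, 1] = 220
        assert not is_background(t)

    @given(st.integers(0, 255), st.integers(0, 34))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_pixel_values(self, base, bump):
        t = np.full((8, 8, 3), base, dtype=np.uint8)
        brighter = np.clip(t.astype(int) + bump, 0, 255).astype(np.uint8)
        if is_background(t):
            assert is_background(brighter)

    def test_filter_counts_and_fraction(self):
        bg = np.full((224, 224, 3), 255, dtype=np.uint8)
        fg = np.full((224, 224, 3), 128, dtype=np.uint8)
        tiles = tile_slide(
            np.concatenate(
                [np.concatenate([bg] * 4 + [fg], axis=1)] * 2, axis=0
            )
        )
        kept, frac = filter_tiles(tiles)
        assert len(kept) == 2
        assert frac == pytest.approx(0.8)

    def test_no_background_gives_zero_fraction(self):
        tiles = tile_slide(np.full((224, 448, 3), 100, dtype=np.uint8))
        kept, frac = filter_tiles(tiles)
        assert len(kept) == 2 and frac == 0.0

    def test_all_background_warns(self):
        tiles = tile_slide(np.full((224, 224, 3), 255, dtype=np.uint8))
        with pytest.warns(UserWarning, match="background"):
            kept, frac = filter_tiles(tiles)
        assert kept == [] and frac == 1.0

    def test_removed_fraction_tracks_tissue_fraction(self):
        """~80% of tiles are glass on a 20%-tissue slide.

        Measured on a tile grid fine enough that tiles straddling the
        tissue boundary are a small minority; at desk-scale slide sizes a
        224-px grid is boundary-dominated and understates the removal."""
        slide = generate_slide(
            SyntheticSlideSpec(
                label="NC", tissue_fraction=0.2, width_px=1792,
                height_px=1792, seed=13,
            )
        )
        _, frac = filter_tiles(tile_slide(slide.image, tile_size=56))
        assert frac == pytest.approx(0.8, abs=0.1)


class TestAugment:
    @pytest.fixture()
    def img(self):
        return np.random.default_rng(5).integers(
            0, 256, (64, 64, 3), dtype=np.uint8
        )

    def test_identity_params_are_noop(self, img):
        np.testing.assert_array_equal(augment(img, AugmentationParams()), img)

    def test_double_horizontal_flip_is_identity(self, img):
        p = AugmentationParams(flip_h=True)
        np.testing.assert_array_equal(augment(augment(img, p), p), img)

    def test_deterministic_given_params(self, img):
        rng = np.random.default_rng(9)
        p = AugmentationParams.random(rng)
        np.testing.assert_array_equal(augment(img, p), augment(img, p))

    def test_shape_and_dtype_preserved(self, img):
        p = AugmentationParams.random(np.random.default_rng(2))
        out = augment(img, p)
        assert out.shape == img.shape and out.dtype == img.dtype

    def test_translation_fills_white(self, img):
        out = augment(
            img, AugmentationParams(translation_px=(10, 0))
        )
        assert np.all(out[:, :10] == 255)

    def test_rotation_fills_white_corners(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        out = augment(img, AugmentationParams(rotation_deg=45.0))
        assert out[0, 0].tolist() == [255, 255, 255]

    def test_hue_wraps_modulo_256(self):
        # a pure-red image shifted by +32 then -32 returns to itself
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[..., 0] = 200
        fwd = augment(img, AugmentationParams(hue_shift=32))
        back = augment(fwd, AugmentationParams(hue_shift=-32))
        assert np.abs(back.astype(int) - img.astype(int)).max() <= 2

    def test_value_shift_clips(self):
        img = np.full((8, 8, 3), 250, dtype=np.uint8)
        out = augment(img, AugmentationParams(value_shift=32))
        assert out.max() == 255

    def test_contrast_about_mean(self):
        img = np.full((8, 8, 3), 100, dtype=np.uint8)
        img[0, 0] = 140
        out = augment(img, AugmentationParams(contrast=1.5))
        assert out[4, 4, 0] < 100 + 3      # near-mean pixels barely move
        assert out[0, 0, 0] > 140          # deviations amplified

    @pytest.mark.parametrize(
        "bad",
        [
            {"contrast": 0.4},
            {"contrast": 1.6},
            {"brightness": 0.5},
            {"hue_shift": 40},
            {"value_shift": -40},
        ],
    )
    def test_out_of_range_params_rejected(self, bad):
        with pytest.raises(ValueError):
            AugmentationParams(**bad)

    def test_sampled_params_respect_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = AugmentationParams.random(rng)
            assert 0.5 <= p.contrast <= 1.5
            assert 0.65 <= p.brightness <= 1.35
            assert -32 <= p.hue_shift <= 32
            assert -32 <= p.value_shift <= 32
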