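"""Slide preparation: downscaling, white padding, tiling, background
filtering and the training-time augmentation pipeline.

Slides are processed at a reduced magnification (bilinear downscale), padded
with white (255) to a common square size, and — for the instance-based
methods — cut into nonoverlapping 224x224 tiles on a row-major grid.  Tiles
whose every pixel exceeds 220 on all three channels are background (glass)
and are dropped before any instance model sees them; on real slides this
removes roughly 80% of tiles.

Augmentation mirrors the study protocol: flips, translation, rotation, and
colour jitter — contrast multiplied by 0.5-1.5 (about the per-image mean),
brightness multiplied by 0.65-1.35 (on HSV value), hue shifted by -32..32
(wrapping, hue being circular on the 0-255 scale) and value shifted by
-32..32 (clipped).  Geometric operations fill exposed area with white so the
background filter stays consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor

__all__ = [
    "TILE_SIZE",
    "BACKGROUND_THRESHOLD",
    "Tile",
    "AugmentationParams",
    "PaddedSlide",
    "read_image",
    "downscale",
    "downscale_um",
    "pad_to_square",
    "tile_slide",
    "is_background",
    "filter_tiles",
    "augment",
]

TILE_SIZE = 224
BACKGROUND_THRESHOLD = 220
WHITE = 255


@dataclass
class Tile:
    pixels: np.ndarray          # (tile, tile, 3) uint8
    grid_row: int
    grid_col: int
    slide_id: str = ""

    @property
    def origin(self) -> Tuple[int, int]:
        side = self.pixels.shape[0]
        return self.grid_row * side, self.grid_col * side


@dataclass(frozen=True)
class AugmentationParams:
    flip_h: bool = False
    flip_v: bool = False
    translation_px: Tuple[int, int] = (0, 0)
    rotation_deg: float = 0.0
    contrast: float = 1.0
    brightness: float = 1.0
    hue_shift: int = 0
    value_shift: int = 0

    def __post_init__(self):
        if not (0.5 <= self.contrast <= 1.5):
            raise ValueError("contrast must lie in [0.5, 1.5]")
        if not (0.65 <= self.brightness <= 1.35):
            raise ValueError("brightness must lie in [0.65, 1.35]")
        if not (-32 <= self.hue_shift <= 32):
            raise ValueError("hue_shift must lie in [-32, 32]")
        if not (-32 <= self.value_shift <= 32):
            raise ValueError("value_shift must lie in [-32, 32]")

    @classmethod
    def random(cls, rng: np.random.Generator,
               max_translation: int = 16,
               max_rotation: float = 180.0) -> "AugmentationParams":
        """Draw one augmentation from the study's stated ranges."""
        return cls(
            flip_h=bool(rng.integers(2)),
            flip_v=bool(rng.integers(2)),
            translation_px=(
                int(rng.integers(-max_translation, max_translation + 1)),
                int(rng.integers(-max_translation, max_translation + 1)),
            ),
            rotation_deg=float(rng.uniform(-max_rotation, max_rotation)),
            contrast=float(rng.uniform(0.5, 1.5)),
            brightness=float(rng.uniform(0.65, 1.35)),
            hue_shift=int(rng.integers(-32, 33)),
            value_shift=int(rng.integers(-32, 33)),
        )

    @classmethod
    def random_light(cls, rng: np.random.Generator) -> "AugmentationParams":
        """Flips plus colour jitter only (no resampling) — cheap variant."""
        return cls(
            flip_h=bool(rng.integers(2)),
            flip_v=bool(rng.integers(2)),
            contrast=float(rng.uniform(0.8, 1.2)),
            brightness=float(rng.uniform(0.85, 1.15)),
            hue_shift=int(rng.integers(-12, 13)),
            value_shift=int(rng.integers(-12, 13)),
        )


@dataclass
class PaddedSlide:
    image: np.ndarray            # (S, S, 3) uint8
    original_shape: Tuple[int, int]
    fill_value: int = WHITE
    content_origin: Tuple[int, int] = (0, 0)


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB slide image from PNG or plain (non-pyramidal) TIFF."""
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        img = np.asarray(Image.open(path).convert("RGB"))
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError(
            f"{path.name}: expected 8-bit 3-channel RGB, got "
            f"{img.dtype} array of shape {img.shape}"
        )
    return img


def downscale(image: np.ndarray, factor: float) -> np.ndarray:
    """Bilinear downscale by ``factor`` in (0, 1]; dims become round(dim*f)."""
    if factor <= 0 or factor > 1:
        raise ValueError("factor must lie in (0, 1]")
    if factor == 1.0:
        return image.copy()
    h, w = image.shape[:2]
    out_w, out_h = round(w * factor), round(h * factor)
    if out_w < 1 or out_h < 1:
        raise ValueError("downscaled image would be smaller than 1x1")
    pil = Image.fromarray(image)
    return np.asarray(pil.resize((out_w, out_h), Image.BILINEAR))


def downscale_um(um_per_px: float, factor: float) -> float:
    """Pixel spacing after downscaling: spacing grows as size shrinks."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return um_per_px / factor


def pad_to_square(image: np.ndarray, target_side: int) -> PaddedSlide:
    """Pad with white to ``target_side`` square, content at the top-left."""
    h, w = image.shape[:2]
    if target_side < max(h, w):
        raise ValueError(
            f"target_side {target_side} smaller than content {h}x{w}; "
            "padding never crops"
        )
    out = np.full((target_side, target_side, 3), WHITE, dtype=np.uint8)
    out[:h, :w] = image
    return PaddedSlide(out, original_shape=(h, w))


def tile_slide(image: np.ndarray, tile_size: int = TILE_SIZE,
               slide_id: str = "") -> List[Tile]:
    """Cut into nonoverlapping tiles, white-padding ragged edges first."""
    h, w = image.shape[:2]
    ph = -h % tile_size
    pw = -w % tile_size
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)),
                       constant_values=WHITE)
    rows, cols = image.shape[0] // tile_size, image.shape[1] // tile_size
    tiles = []
    for r in range(rows):
        for c in range(cols):
            tiles.append(
                Tile(
                    pixels=image[
                        r * tile_size : (r + 1) * tile_size,
                        c * tile_size : (c + 1) * tile_size,
                    ],
                    grid_row=r,
                    grid_col=c,
                    slide_id=slide_id,
                )
            )
    return tiles


def is_background(tile) -> bool:
    """True iff every pixel of every channel is strictly above 220."""
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    return bool(np.all(pixels > BACKGROUND_THRESHOLD))


def filter_tiles(tiles: Sequence[Tile]) -> Tuple[List[Tile], float]:
    """Drop background tiles; return survivors and the removed fraction."""
    if len(tiles) == 0:
        raise ValueError("no tiles to filter")
    kept = [t for t in tiles if not is_background(t)]
    removed_fraction = 1.0 - len(kept) / len(tiles)
    if not kept:
        warnings.warn("all tiles are background; downstream bag is empty")
    return kept, removed_fraction


def _hsv_jitter(img: np.ndarray, params: AugmentationParams) -> np.ndarray:
    hsv = skcolor.rgb2hsv(img / 255.0)
    if params.hue_shift:
        hsv[..., 0] = np.mod(hsv[..., 0] + params.hue_shift / 256.0, 1.0)
    v = hsv[..., 2] * params.brightness + params.value_shift / 255.0
    hsv[..., 2] = np.clip(v, 0.0, 1.0)
    rgb = skcolor.hsv2rgb(hsv) * 255.0
    return rgb


def augment(image: np.ndarray, params: AugmentationParams) -> np.ndarray:
    """Apply one deterministic augmentation; output matches input shape/dtype.

    Order: flips -> rotation -> translation -> contrast (RGB, about the
    per-image mean) -> HSV hue/brightness/value.  Exposed geometry is filled
    white.
    """
    img = np.asarray(image)
    out = img.astype(np.float64)
    if params.flip_h:
        out = out[:, ::-1]
    if params.flip_v:
        out = out[::-1, :]
    if params.rotation_deg:
        out = ndimage.rotate(
            out, params.rotation_deg, axes=(1, 0), reshape=False,
            order=1, mode="constant", cval=WHITE,
        )
    dx, dy = params.translation_px
    if dx or dy:
        out = ndimage.shift(
            out, shift=(dy, dx, 0), order=0, mode="constant", cval=WHITE
        )
    if params.contrast != 1.0:
        mean = out.mean()
        out = np.clip(mean + (out - mean) * params.contrast, 0, 255)
    if (params.hue_shift or params.value_shift
            or params.brightness != 1.0):
        out = _hsv_jitter(out, params)
    return np.clip(np.round(out), 0, 255).astype(img.dtype)
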