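"""Synthetic whole-slide-like images with planted lesions.

Real H&E slides are mostly white glass with irregular tissue regions;
cancerous slides additionally contain lesion regions whose texture differs
from benign parenchyma, sometimes occupying less than 10% of the tissue
("small-lesion" slides — the hard cases for weakly supervised training).
This module emulates exactly that statistical skeleton:

* background is pure white (255 on every channel), so the standard
  ">220 on all channels" background-tile filter applies unambiguously;
* tissue is a smoothly shaped blob region carrying a benign texture that is
  identical across classes;
* for ADC/SqCC slides a compact lesion region inside the tissue carries a
  class-specific texture (distinct base colour + colored noise blobs) whose
  mean-channel distance from benign tissue exceeds the noise scale, which
  makes tiles linearly separable — by design, so the desk-scale training
  runs probe the *training machinery*, not the feature extractor;
* every slide (benign ones included) additionally carries a few small
  *distractor* blobs whose colour sits roughly halfway between benign
  tissue and a cancer palette.  These emulate benign mimics (hyperplasia,
  necrosis-adjacent tissue) that produce intermediate-looking regions on
  real slides: they give average-pooled slide features a noise floor, and
  they are exactly the structures that mislead instance selection in
  weakly supervised training when a true lesion is small or absent.

Lesion area is planted to an exact pixel count (the nearest-``n`` tissue
pixels around a seeded interior centre), so the measured
lesion/tissue ratio matches the requested ``lesion_fraction`` up to mask
rounding.  Everything is reproducible from integer seeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "CLASSES",
    "DEFAULT_TEXTURES",
    "SyntheticSlideSpec",
    "LabeledSlide",
    "DatasetSplit",
    "generate_slide",
    "generate_corpus",
    "stratified_split",
    "split_slides",
    "is_small_lesion",
    "save_slide",
    "load_slide",
    "save_corpus",
    "load_corpus",
]

CLASSES = ("NC", "ADC", "SqCC")

SMALL_LESION_THRESHOLD = 0.10

# Base colours sit well below the 220 background threshold; the lesion
# palettes differ from benign tissue by ~40-60 mean-channel units, an order
# of magnitude above the fine-noise sigma.
DEFAULT_TEXTURES = {
    "tissue": {"base": (196, 160, 188), "noise_scale": 8.0, "blob_size": 24},
    "ADC": {"base": (138, 96, 168), "noise_scale": 8.0, "blob_size": 16},
    "SqCC": {"base": (186, 104, 96), "noise_scale": 8.0, "blob_size": 16},
}


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one synthetic slide."""

    width_px: int = 512
    height_px: int = 512
    um_per_px: float = 2.3
    label: str = "NC"
    tissue_fraction: float = 0.3
    lesion_fraction: float = 0.0
    texture_params: dict = field(default_factory=lambda: DEFAULT_TEXTURES)
    distractor_fraction: float = 0.02  # benign-mimic area / tissue area
    speckle_fraction: float = 0.03    # micro-mimic (full-palette dot) area
    seed: int = 0

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}")
        if self.width_px < 448 or self.height_px < 448:
            raise ValueError("slides must be at least 448x448 (two tiles)")
        if not (0 < self.tissue_fraction <= 1):
            raise ValueError("tissue_fraction must lie in (0, 1]")
        if not (0 <= self.lesion_fraction < 1):
            raise ValueError("lesion_fraction must lie in [0, 1)")
        if (self.label == "NC") != (self.lesion_fraction == 0):
            raise ValueError(
                "lesion_fraction must be 0 for NC slides and positive for "
                "cancerous slides"
            )
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not (0 <= self.distractor_fraction < 0.2):
            raise ValueError("distractor_fraction must lie in [0, 0.2)")
        if not (0 <= self.speckle_fraction < 0.2):
            raise ValueError("speckle_fraction must lie in [0, 0.2)")


@dataclass
class LabeledSlide:
    """An RGB slide image with slide-level label and reference masks."""

    image: np.ndarray            # (H, W, 3) uint8
    label: str
    tissue_mask: np.ndarray      # (H, W) bool
    lesion_mask: np.ndarray      # (H, W) bool; empty for NC
    um_per_px: float
    slide_id: str

    @property
    def lesion_fraction(self) -> float:
        tissue = int(self.tissue_mask.sum())
        if tissue == 0:
            raise ValueError(f"slide {self.slide_id} has an empty tissue mask")
        return float(self.lesion_mask.sum()) / tissue


@dataclass
class DatasetSplit:
    train_ids: list
    val_ids: list
    test_ids: list
    stratify_key: str = "label"

    @property
    def all_ids(self) -> list:
        return self.train_ids + self.val_ids + self.test_ids


# ---------------------------------------------------------------------------
# generation


def _smooth_field(rng, shape, sigma):
    # Low-frequency noise: draw on a coarse grid (one cell per ~sigma px)
    # and upsample with a cubic spline — equivalent smoothness to a
    # large-sigma Gaussian blur at a fraction of the cost.
    if sigma <= 2:
        return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    coarse_shape = tuple(max(4, int(np.ceil(s / sigma)) + 3) for s in shape)
    coarse = rng.standard_normal(coarse_shape)
    zoom = [s / c for s, c in zip(shape, coarse_shape)]
    f = ndimage.zoom(coarse, zoom, order=1)
    return f[: shape[0], : shape[1]]


def _texture(rng, shape, params):
    base = np.asarray(params["base"], dtype=float)
    blob = np.stack(
        [_smooth_field(rng, shape, params["blob_size"] / 4) for _ in range(3)],
        axis=-1,
    )
    blob *= 3.0 * params["noise_scale"] / max(blob.std(), 1e-9)
    fine = rng.standard_normal(shape + (3,)) * params["noise_scale"]
    return base + blob + fine


def _compact_region(allowed: np.ndarray, centre, target: int) -> np.ndarray:
    """The ``target`` allowed pixels nearest to ``centre`` (compact blob)."""
    yy, xx = np.nonzero(allowed)
    d2 = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2
    order = np.argsort(d2, kind="stable")[:target]
    region = np.zeros_like(allowed)
    region[yy[order], xx[order]] = True
    return region


def generate_slide(spec: SyntheticSlideSpec) -> LabeledSlide:
    """Render one slide deterministically from its spec."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    # Tissue: one compact, organically shaped section (real slides carry a
    # small number of contiguous tissue pieces, not scattered speckle).
    # A smoothed noise field minus a radial penalty from a random interior
    # centre is thresholded at the exact area quantile.
    field_ = _smooth_field(rng, (h, w), sigma=min(h, w) / 8)
    field_ = (field_ - field_.mean()) / max(field_.std(), 1e-9)
    cy = rng.uniform(0.35, 0.65) * h
    cx = rng.uniform(0.35, 0.65) * w
    yy, xx = np.ogrid[:h, :w]
    d2 = ((yy - cy) / (0.5 * h)) ** 2 + ((xx - cx) / (0.5 * w)) ** 2
    field_ = field_ - 4.0 * d2
    thresh = np.quantile(field_, 1.0 - spec.tissue_fraction)
    tissue = field_ >= thresh

    lesion = np.zeros((h, w), dtype=bool)
    if spec.label != "NC":
        target = int(round(spec.lesion_fraction * tissue.sum()))
        target = max(target, 1)
        # Centre the lesion deep inside the tissue: pick among the top
        # interior-score pixels at random, then grow to the nearest-n
        # tissue pixels so the planted area is exact and compact.
        interior = ndimage.distance_transform_edt(tissue)
        flat = interior.ravel()
        candidates = np.argsort(flat)[::-1][: max(50, target // 50)]
        centre = np.unravel_index(rng.choice(candidates), (h, w))
        lesion = _compact_region(tissue, centre, target)

    img = np.full((h, w, 3), 255.0)
    tex_t = spec.texture_params.get("tissue", DEFAULT_TEXTURES["tissue"])
    img[tissue] = _texture(rng, (h, w), tex_t)[tissue]
    if spec.label != "NC":
        tex_l = spec.texture_params.get(spec.label,
                                        DEFAULT_TEXTURES[spec.label])
        # Render the lesion texture only inside its bounding box.
        ys, xs = np.nonzero(lesion)
        y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
        local = lesion[y0:y1, x0:x1]
        patch = _texture(rng, (y1 - y0, x1 - x0), tex_l)
        img[y0:y1, x0:x1][local] = patch[local]

    # Benign-mimic distractor blobs on every slide: compact regions whose
    # base colour sits between benign tissue and a cancer palette.
    if spec.distractor_fraction > 0:
        total = int(round(spec.distractor_fraction * tissue.sum()))
        n_blobs = int(rng.integers(2, 5))
        free = tissue & ~lesion
        tex_t_base = np.asarray(tex_t["base"], dtype=float)
        for blob_i in range(n_blobs):
            blob_target = max(total // n_blobs, 1)
            yy, xx = np.nonzero(free)
            if yy.size == 0:
                break
            centre_idx = rng.integers(0, yy.size)
            blob = _compact_region(free, (yy[centre_idx], xx[centre_idx]),
                                   blob_target)
            # Peak colour stays well below the lesion palette (a trained
            # max-pooled detector can threshold it out) while the blob area
            # is large enough that the *integrated* colour shift overlaps
            # the signal of a small lesion — the regime where averaging
            # evidence over the slide becomes unreliable.  Mimic classes
            # alternate so every slide carries both colour directions.
            mimic_of = ("ADC", "SqCC")[blob_i % 2]
            weight = float(rng.uniform(0.35, 0.50))
            palette = np.asarray(
                spec.texture_params.get(mimic_of,
                                        DEFAULT_TEXTURES[mimic_of])["base"],
                dtype=float,
            )
            base = tex_t_base + weight * (palette - tex_t_base)
            noise = rng.standard_normal((int(blob.sum()), 3)) * \
                tex_t["noise_scale"]
            img[blob] = base + noise
            free &= ~blob
    # Micro-mimic speckles: tiny dots carrying the *full* lesion palette,
    # scattered through benign tissue on every slide.  Individually they
    # cover a small fraction of any receptive field (so a max-pooled
    # detector's peak response stays far below a true lesion's), but their
    # summed area rivals a small lesion, confounding averaged evidence.
    if spec.speckle_fraction > 0:
        speckle_target = int(round(spec.speckle_fraction * tissue.sum()))
        free = tissue & ~lesion
        yy, xx = np.nonzero(free)
        placed = 0
        i = 0
        while placed < speckle_target and yy.size:
            r = int(rng.integers(1, 4))
            c_idx = rng.integers(0, yy.size)
            cy_, cx_ = yy[c_idx], xx[c_idx]
            y0s, y1s = max(0, cy_ - r), min(h, cy_ + r + 1)
            x0s, x1s = max(0, cx_ - r), min(w, cx_ + r + 1)
            gy, gx = np.ogrid[y0s:y1s, x0s:x1s]
            disk = ((gy - cy_) ** 2 + (gx - cx_) ** 2 <= r * r) & \
                free[y0s:y1s, x0s:x1s]
            n_px = int(disk.sum())
            if n_px == 0:
                i += 1
                continue
            palette = DEFAULT_TEXTURES[("ADC", "SqCC")[i % 2]]["base"]
            palette = np.asarray(
                spec.texture_params.get(("ADC", "SqCC")[i % 2],
                                        {"base": palette})["base"],
                dtype=float,
            )
            # per-dot colour offset matches the blob-noise swing of real
            # lesion texture, so no pixel-level colour threshold separates
            # a speckle from a lesion pixel — only spatial extent does
            offset = rng.standard_normal(3) * 12.0
            vals = palette + offset + rng.standard_normal((n_px, 3)) * \
                tex_t["noise_scale"]
            img[y0s:y1s, x0s:x1s][disk] = vals
            placed += n_px
            i += 1

    # Tissue pixels stay at or below 219 so no tissue tile passes the
    # all-channels->220 background test; background remains exactly 255.
    content = tissue
    img[content] = np.clip(img[content], 0, 219)

    return LabeledSlide(
        image=img.astype(np.uint8),
        label=spec.label,
        tissue_mask=tissue,
        lesion_mask=lesion,
        um_per_px=spec.um_per_px,
        slide_id=f"{spec.label}_{spec.seed:08d}",
    )


def generate_corpus(
    n_per_class: int,
    lesion_fraction_range: tuple = (0.02, 0.40),
    small_lesion_quota: float = 0.3,
    size_px: int = 512,
    seed: int = 0,
    um_per_px: float = 2.3,
    tissue_fraction_range: tuple = (0.2, 0.4),
    distractor_fraction_range: tuple = (0.08, 0.18),
    speckle_fraction_range: tuple = (0.02, 0.06),
    textures: Optional[dict] = None,
) -> list:
    """Generate a balanced three-class corpus of synthetic slides.

    Exactly ``round(small_lesion_quota * n_per_class)`` slides of each
    cancer class receive a lesion fraction below 10% of tissue area (the
    small-lesion regime); the remainder draw from the upper part of
    ``lesion_fraction_range``.  Per-slide seeds derive from ``seed`` so the
    corpus is reproducible slide by slide.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not (0 <= small_lesion_quota <= 1):
        raise ValueError("small_lesion_quota must lie in [0, 1]")
    lo, hi = lesion_fraction_range
    if not (0 < lo < hi < 1):
        raise ValueError("lesion_fraction_range must satisfy 0 < lo < hi < 1")
    textures = textures or DEFAULT_TEXTURES

    rng = np.random.default_rng(seed)
    slides = []
    for label in CLASSES:
        n_small = 0
        if label != "NC":
            n_small = int(round(small_lesion_quota * n_per_class))
        for i in range(n_per_class):
            slide_seed = int(rng.integers(0, 2**31 - 1))
            tissue_fraction = float(rng.uniform(*tissue_fraction_range))
            if label == "NC":
                lesion_fraction = 0.0
            elif i < n_small:
                small_hi = min(hi, SMALL_LESION_THRESHOLD)
                lesion_fraction = float(
                    rng.uniform(lo, small_hi * 0.999)
                )
            else:
                large_lo = max(lo, SMALL_LESION_THRESHOLD)
                lesion_fraction = float(rng.uniform(large_lo * 1.001, hi))
            spec = SyntheticSlideSpec(
                width_px=size_px,
                height_px=size_px,
                um_per_px=um_per_px,
                label=label,
                tissue_fraction=tissue_fraction,
                lesion_fraction=lesion_fraction,
                texture_params=textures,
                distractor_fraction=float(
                    rng.uniform(*distractor_fraction_range)
                ),
                speckle_fraction=float(
                    rng.uniform(*speckle_fraction_range)
                ),
                seed=slide_seed,
            )
            slide = generate_slide(spec)
            slide.slide_id = f"{label}_{i:04d}_{slide_seed:08d}"
            slides.append(slide)
    return slides


# ---------------------------------------------------------------------------
# splitting and subsetting


def _largest_remainder(n: int, fractions: Sequence[float]) -> list:
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - base[i], -i), reverse=True
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def stratified_split(
    ids: Sequence[str],
    labels: Sequence[str],
    fractions: tuple,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified train/val/test split with largest-remainder rounding.

    Within each label stratum, ids are shuffled (seeded) and allocated so
    each split's class proportions match the global ones within one item.
    Strata smaller than the number of non-empty splits go entirely to train
    with a warning.
    """
    if len(ids) != len(labels):
        raise ValueError("ids and labels must have the same length")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    buckets = ([], [], [])
    for label in sorted(set(labels)):
        members = [i for i, l in zip(ids, labels) if l == label]
        n_splits_needed = sum(f > 0 for f in fractions)
        if len(members) < n_splits_needed:
            warnings.warn(
                f"stratum {label!r} has only {len(members)} item(s); "
                "assigning all to train"
            )
            buckets[0].extend(members)
            continue
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        counts = _largest_remainder(len(members), fractions)
        start = 0
        for b, c in zip(buckets, counts):
            b.extend(shuffled[start : start + c])
            start += c
    return DatasetSplit(*[sorted(b) for b in buckets])


def split_slides(slides: Sequence[LabeledSlide], fractions: tuple,
                 seed: int = 0) -> DatasetSplit:
    return stratified_split(
        [s.slide_id for s in slides], [s.label for s in slides],
        fractions, seed,
    )


def is_small_lesion(slide: LabeledSlide) -> bool:
    """True iff the slide is cancerous with lesion area < 10% of tissue.

    Benign slides return False here; the evaluation subset built around the
    small-lesion regime includes benign slides unconditionally instead (the
    subset consists of small-lesion cancers plus all benign slides).
    """
    if slide.tissue_mask.sum() == 0:
        raise ValueError(f"slide {slide.slide_id} has an empty tissue mask")
    if slide.label == "NC":
        return False
    return slide.lesion_fraction < SMALL_LESION_THRESHOLD


# ---------------------------------------------------------------------------
# IO: PNG image + PNG mask + JSON sidecar per slide, CSV manifest per corpus


def save_slide(directory, slide: LabeledSlide) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    Image.fromarray(slide.image).save(directory / f"{slide.slide_id}.png")
    masks = (
        slide.tissue_mask.astype(np.uint8) + slide.lesion_mask.astype(np.uint8)
    ) * 127  # 0 background, 127 tissue, 254 lesion
    Image.fromarray(masks).save(directory / f"{slide.slide_id}_mask.png")
    sidecar = {
        "slide_id": slide.slide_id,
        "label": slide.label,
        "um_per_px": slide.um_per_px,
        "lesion_fraction": slide.lesion_fraction,
    }
    (directory / f"{slide.slide_id}.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_slide(directory, slide_id: str) -> LabeledSlide:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{slide_id}.json").read_text())
    image = np.asarray(Image.open(directory / f"{slide_id}.png"))
    masks = np.asarray(Image.open(directory / f"{slide_id}_mask.png"))
    return LabeledSlide(
        image=image,
        label=sidecar["label"],
        tissue_mask=masks >= 127,
        lesion_mask=masks >= 254,
        um_per_px=sidecar["um_per_px"],
        slide_id=slide_id,
    )


def save_corpus(directory, slides: Sequence[LabeledSlide],
                split: Optional[DatasetSplit] = None) -> pd.DataFrame:
    directory = Path(directory)
    assignment = {}
    if split is not None:
        for name, ids in zip(
            ("train", "val", "test"),
            (split.train_ids, split.val_ids, split.test_ids),
        ):
            for sid in ids:
                assignment[sid] = name
    rows = []
    for slide in slides:
        save_slide(directory, slide)
        rows.append(
            {
                "slide_id": slide.slide_id,
                "label": slide.label,
                "split": assignment.get(slide.slide_id, ""),
                "lesion_fraction": slide.lesion_fraction,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def load_corpus(directory) -> list:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    return [load_slide(directory, sid) for sid in manifest["slide_id"]]
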