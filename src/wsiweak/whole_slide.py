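"""End-to-end whole-slide training and lesion localization.

Instead of decomposing a slide into instances, the whole (downscaled,
white-padded) image is fed through the convolutional backbone in a single
forward pass; the final feature map is reduced by global max pooling and a
linear layer yields the slide-level softmax.  Because max pooling keeps the
strongest activation per channel, a single receptive field covering a small
lesion suffices to drive the slide logit — the property that average
pooling lacks when the input grows far beyond the receptive field.

Localization comes from class activation mapping (CAM): the final feature
map is contracted against the dense-layer weight row of the class of
interest, min-max normalised and bicubically upscaled to the slide extent.
The same formula is applied under both pooling heads (CAM was derived for
average pooling; with a max-pooling head the map still scores how strongly
each location drives the class logit).  For comparison, MIL tile
prediction maps are upscaled the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize as sk_resize
from sklearn.base import BaseEstimator, ClassifierMixin

from .arch import receptive_field
from .nn import SmallConvNet, CLASSES, CLASS_INDEX
from .synthdata import LabeledSlide
from .tiling import downscale, pad_to_square, PaddedSlide
from .train import TrainConfig, train
from .mil import PredictionMap

__all__ = [
    "Heatmap",
    "FeatureMapInfo",
    "prepare_slide_input",
    "forward_whole",
    "train_whole",
    "WholeSlideClassifier",
    "cam",
    "mil_heatmap",
    "localization_overlap",
]


@dataclass
class Heatmap:
    values: np.ndarray            # (H, W) in [0, 1]
    target_class: str
    source: str                   # "CAM" or "MIL"


@dataclass
class FeatureMapInfo:
    values: np.ndarray            # (h, w, C)
    receptive_field_px: int
    jump_px: int


def prepare_slide_input(slide: LabeledSlide, factor: float = 1.0,
                        target_side: int = 512) -> PaddedSlide:
    """Downscale then white-pad to the common square input side."""
    small = downscale(slide.image, factor)
    return pad_to_square(small, target_side)


def forward_whole(model: SmallConvNet, slide) -> Tuple[np.ndarray,
                                                       FeatureMapInfo]:
    """Single forward pass over a whole padded slide (no tiling).

    Returns the 3-class probabilities and the final feature map annotated
    with its receptive field and jump in (downscaled) input pixels.
    """
    image = slide.image if isinstance(slide, PaddedSlide) else np.asarray(slide)
    x = image.astype(np.float32)[None] / 255.0
    probs, fm = model.forward(x)
    rf, jump = receptive_field(model.arch_spec())
    return probs[0], FeatureMapInfo(values=fm[0], receptive_field_px=rf,
                                    jump_px=jump)


def _slide_arrays(slides: Sequence[LabeledSlide], factor: float,
                  target_side: int):
    xs = np.stack(
        [prepare_slide_input(s, factor, target_side).image for s in slides]
    ).astype(np.float32) / 255.0
    ys = np.zeros((len(slides), 3), dtype=np.float32)
    for i, s in enumerate(slides):
        ys[i, CLASS_INDEX[s.label]] = 1.0
    return xs, ys


def train_whole(
    train_slides: Sequence[LabeledSlide],
    val_slides: Sequence[LabeledSlide],
    head: str = "gmp",
    cfg: Optional[TrainConfig] = None,
    channels: Tuple[int, ...] = (8, 16, 32),
    factor: float = 1.0,
    target_side: int = 512,
    augment_flips: bool = True,
):
    """Train a whole-slide model; returns (model, learning_curves)."""
    cfg = cfg or TrainConfig(lr_initial=1e-3, lr_decayed=1e-4,
                             patience_epochs=5, steps_per_epoch=50,
                             max_epochs=10)
    xt, yt = _slide_arrays(train_slides, factor, target_side)
    xv, yv = _slide_arrays(val_slides, factor, target_side)
    model = SmallConvNet(channels=channels, head=head, seed=cfg.seed)

    def sample_batch(rng, batch_size):
        idx = rng.integers(0, len(xt), size=batch_size)
        xb = xt[idx]
        if augment_flips:
            if rng.integers(2):
                xb = xb[:, :, ::-1]
            if rng.integers(2):
                xb = xb[:, ::-1, :]
            xb = np.ascontiguousarray(xb)
        return xb, yt[idx]

    return train(model, sample_batch, (xv, yv), cfg)


class WholeSlideClassifier(BaseEstimator, ClassifierMixin):
    """Whole-slide CNN classifier with a selectable pooling head.

    Fitted attributes: ``model_``, ``curves_`` (per-epoch learning curves).
    """

    def __init__(self, head: str = "gmp", channels: Tuple[int, ...] = (8, 16, 32),
                 factor: float = 1.0, target_side: int = 512,
                 lr: float = 1e-3, steps_per_epoch: int = 50,
                 max_epochs: int = 10, patience_epochs: int = 5,
                 batch_size: int = 8, seed: int = 0,
                 augment_flips: bool = True):
        self.head = head
        self.channels = channels
        self.factor = factor
        self.target_side = target_side
        self.lr = lr
        self.steps_per_epoch = steps_per_epoch
        self.max_epochs = max_epochs
        self.patience_epochs = patience_epochs
        self.batch_size = batch_size
        self.seed = seed
        self.augment_flips = augment_flips

    def fit(self, slides: Sequence[LabeledSlide], y=None,
            val_slides: Optional[Sequence[LabeledSlide]] = None):
        if val_slides is None:
            val_slides = slides
        cfg = TrainConfig(
            batch_size=self.batch_size, lr_initial=self.lr,
            lr_decayed=self.lr / 10, patience_epochs=self.patience_epochs,
            steps_per_epoch=self.steps_per_epoch, max_epochs=self.max_epochs,
            seed=self.seed,
        )
        self.model_, self.curves_ = train_whole(
            slides, val_slides, head=self.head, cfg=cfg,
            channels=self.channels, factor=self.factor,
            target_side=self.target_side, augment_flips=self.augment_flips,
        )
        return self

    def _inputs(self, slides):
        return np.stack(
            [prepare_slide_input(s, self.factor, self.target_side).image
             for s in slides]
        ).astype(np.float32) / 255.0

    def predict_proba(self, slides: Sequence[LabeledSlide]) -> np.ndarray:
        return self.model_.predict_proba(self._inputs(slides))

    def predict(self, slides: Sequence[LabeledSlide]) -> np.ndarray:
        idx = self.predict_proba(slides).argmax(axis=1)
        return np.array([CLASSES[i] for i in idx])

    def cam_heatmap(self, slide: LabeledSlide, target_class: str) -> Heatmap:
        padded = prepare_slide_input(slide, self.factor, self.target_side)
        _, fm = forward_whole(self.model_, padded)
        side = round(self.target_side / self.factor)
        return cam(fm.values, self.model_.params["Wd"], target_class,
                   out_shape=(side, side))


def cam(feature_map: np.ndarray, dense_weights: np.ndarray, target_class,
        out_shape: Tuple[int, int]) -> Heatmap:
    """Class activation map, min-max normalised and bicubic-upscaled.

    ``heat[i, j] = sum_c W[c, class] * fm[i, j, c]`` — the contribution of
    each feature-map cell to the class logit under the linear head.
    """
    dense_weights = np.asarray(dense_weights)
    if dense_weights.ndim != 2:
        raise ValueError("dense head must be a linear (C x n_classes) map")
    ci = CLASS_INDEX[target_class] if isinstance(target_class, str) \
        else int(target_class)
    heat = feature_map @ dense_weights[:, ci]
    lo, hi = heat.min(), heat.max()
    if hi > lo:
        heat = (heat - lo) / (hi - lo)
    else:
        heat = np.zeros_like(heat)
    up = sk_resize(heat, out_shape, order=3, mode="edge",
                   anti_aliasing=False)
    return Heatmap(values=np.clip(up, 0.0, 1.0),
                   target_class=CLASSES[ci] if isinstance(ci, int) else ci,
                   source="CAM")


def mil_heatmap(pmap: PredictionMap, target_class,
                out_shape: Tuple[int, int]) -> Heatmap:
    """Tile prediction map upscaled bicubically; background cells are 0."""
    ci = CLASS_INDEX[target_class] if isinstance(target_class, str) \
        else int(target_class)
    grid = pmap.probs[:, :, ci] * pmap.mask
    up = sk_resize(grid.astype(float), out_shape, order=3, mode="edge",
                   anti_aliasing=False)
    return Heatmap(values=np.clip(up, 0.0, 1.0),
                   target_class=CLASSES[ci], source="MIL")


def localization_overlap(hm: Heatmap, lesion_mask: np.ndarray,
                         threshold: float,
                         tissue_mask: Optional[np.ndarray] = None) -> Tuple[
                             float, float]:
    """Pixel precision/recall of the thresholded heatmap vs the lesion mask.

    Evaluation is restricted to tissue when a tissue mask is given.  An
    empty lesion mask is an error; precision over an empty prediction is
    defined as 0.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.sum() == 0:
        raise ValueError("empty lesion mask")
    pred = hm.values > threshold
    if pred.shape != lesion_mask.shape:
        raise ValueError("heatmap and mask extents differ")
    if tissue_mask is not None:
        sel = np.asarray(tissue_mask, dtype=bool)
        pred = pred & sel
        lesion = lesion_mask & sel
    else:
        lesion = lesion_mask
    tp = float(np.sum(pred & lesion))
    precision = tp / pred.sum() if pred.sum() else 0.0
    recall = tp / lesion.sum() if lesion.sum() else 0.0
    return precision, recall
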