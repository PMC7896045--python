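"""Minimal convolutional network with hand-written backpropagation.

The package trains small from-scratch CNNs on synthetic slides, so the
network core is deliberately compact: stride-2 'same'-padded 3x3
convolutions with ReLU, a global pooling head (average or max), and a
linear classifier producing a 3-way softmax.  Everything is plain numpy in
float32; gradients are derived analytically and verified against finite
differences in the test suite.

The global pooling head is the scientifically load-bearing choice: with
global average pooling (GAP) the evidence from a small lesion is diluted by
every other feature-map cell, while global max pooling (GMP) keeps the
strongest activation per channel, so one receptive field covering the
lesion suffices to drive the slide-level logit.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .arch import ArchitectureSpec, LayerSpec

__all__ = [
    "gap",
    "gmp",
    "softmax",
    "cross_entropy",
    "SmallConvNet",
    "Adam",
]

EPS_LOG = 1e-12

CLASSES = ("NC", "ADC", "SqCC")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


# ---------------------------------------------------------------------------
# pooling + loss primitives


def gap(fm: np.ndarray) -> np.ndarray:
    """Global average pooling over the spatial axes.

    ``fm`` is ``(h, w, C)`` or ``(N, h, w, C)``; returns ``(C,)`` / ``(N, C)``.
    """
    fm = np.asarray(fm)
    if fm.ndim == 3:
        return fm.mean(axis=(0, 1))
    return fm.mean(axis=(1, 2))


def gmp(fm: np.ndarray) -> np.ndarray:
    """Global max pooling over the spatial axes (same shapes as :func:`gap`)."""
    fm = np.asarray(fm)
    if fm.ndim == 3:
        return fm.max(axis=(0, 1))
    return fm.max(axis=(1, 2))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """3-class categorical cross entropy for a one-hot label.

    ``L = -sum_c y_c ln(y_hat_c)`` with predictions clipped to
    ``[1e-12, 1]`` so a saturated wrong prediction yields a large finite
    loss instead of infinity.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("label and prediction shapes differ")
    one_hot = np.all((y == 0) | (y == 1), axis=-1) & (y.sum(axis=-1) == 1)
    if not np.all(one_hot):
        raise ValueError("y must be one-hot")
    p = np.clip(y_hat, EPS_LOG, 1.0)
    return float(np.mean(-(y * np.log(p)).sum(axis=-1)))


# ---------------------------------------------------------------------------
# conv plumbing


def _same_pad(side: int, k: int, s: int) -> tuple:
    out = math.ceil(side / s)
    total = max((out - 1) * s + k - side, 0)
    lo = total // 2
    return lo, total - lo


def _conv_forward(x, W, b, stride):
    # x: (N, H, W, Cin) float32; W: (k, k, Cin, Cout)
    k = W.shape[0]
    n, h, w, cin = x.shape
    pt, pb = _same_pad(h, k, stride)
    pl, pr = _same_pad(w, k, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]              # (N, oh, ow, Cin, k, k)
    oh, ow = win.shape[1], win.shape[2]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, oh, ow, k * k * cin)
    out = cols @ W.transpose(0, 1, 2, 3).reshape(k * k * cin, -1) + b
    cache = (xp.shape, (pt, pl), cols, x.shape)
    return out.astype(np.float32), cache


def _conv_backward(dout, W, stride, cache):
    xp_shape, (pt, pl), cols, x_shape = cache
    k = W.shape[0]
    n, oh, ow, cout = dout.shape
    cin = x_shape[3]
    Wmat = W.reshape(k * k * cin, cout)
    flat = dout.reshape(-1, cout)
    dW = (cols.reshape(-1, k * k * cin).T @ flat).reshape(W.shape)
    db = flat.sum(axis=0)
    dcols = (flat @ Wmat.T).reshape(n, oh, ow, k, k, cin)
    dxp = np.zeros(xp_shape, dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + oh * stride : stride,
                j : j + ow * stride : stride, :] += dcols[:, :, :, i, j, :]
    h, w = x_shape[1], x_shape[2]
    dx = dxp[:, pt : pt + h, pl : pl + w, :]
    return dx, dW.astype(np.float32), db.astype(np.float32)


# ---------------------------------------------------------------------------
# the network


class SmallConvNet:
    """Stack of stride-2 ReLU convolutions + global pooling + linear head.

    Parameters
    ----------
    channels : sequence of int
        Output channels per stride-2 conv stage.  The final entry is the
        embedding width C fed to the pooling head.
    head : {"gmp", "gap"}
        Global pooling flavour.
    seed : int
        Seeds the He-style weight initialisation.
    """

    def __init__(
        self,
        channels: Sequence[int] = (8, 16, 32),
        kernel: int = 3,
        stride: int = 2,
        n_classes: int = 3,
        head: str = "gmp",
        seed: int = 0,
        in_channels: int = 3,
    ):
        if head not in ("gmp", "gap"):
            raise ValueError("head must be 'gmp' or 'gap'")
        self.channels = tuple(int(c) for c in channels)
        self.kernel = int(kernel)
        self.stride = int(stride)
        self.n_classes = int(n_classes)
        self.head = head
        self.seed = int(seed)
        self.in_channels = int(in_channels)

        rng = np.random.default_rng(seed)
        self.params = {}
        cin = in_channels
        for i, cout in enumerate(self.channels):
            fan_in = kernel * kernel * cin
            self.params[f"W{i}"] = (
                rng.standard_normal((kernel, kernel, cin, cout))
                * math.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"b{i}"] = np.zeros(cout, dtype=np.float32)
            cin = cout
        self.params["Wd"] = (
            rng.standard_normal((cin, n_classes)) * math.sqrt(1.0 / cin)
        ).astype(np.float32)
        self.params["bd"] = np.zeros(n_classes, dtype=np.float32)

    # -- architecture bridge ------------------------------------------------

    def arch_spec(self) -> ArchitectureSpec:
        layers = tuple(
            LayerSpec("conv", self.kernel, self.stride, name=f"conv{i + 1}")
            for i in range(len(self.channels))
        )
        return ArchitectureSpec(layers, final_channels=self.channels[-1],
                                name="desk")

    # -- forward ------------------------------------------------------------

    def _backbone(self, x, want_cache=False):
        caches = []
        a = np.ascontiguousarray(x, dtype=np.float32)
        for i in range(len(self.channels)):
            z, cache = _conv_forward(
                a, self.params[f"W{i}"], self.params[f"b{i}"], self.stride
            )
            a = np.maximum(z, 0.0)
            if want_cache:
                caches.append((cache, z))
        return a, caches

    def feature_map(self, x: np.ndarray) -> np.ndarray:
        """Final spatial feature map ``(N, h, w, C)`` for input ``(N,H,W,3)``."""
        fm, _ = self._backbone(x)
        return fm

    def _pool(self, fm):
        if self.head == "gmp":
            return gmp(fm)
        return gap(fm)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Pooled pre-head embedding ``(N, C)``."""
        return self._pool(self.feature_map(x))

    def forward(self, x: np.ndarray):
        """Class probabilities ``(N, 3)`` and the final feature map."""
        fm, _ = self._backbone(x)
        v = self._pool(fm)
        logits = v @ self.params["Wd"] + self.params["bd"]
        return softmax(logits), fm

    def predict_proba(self, x: np.ndarray, batch: int = 32) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch):
            probs, _ = self.forward(x[i : i + batch])
            out.append(probs)
        return np.concatenate(out, axis=0)

    # -- backward -----------------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y_onehot: np.ndarray):
        n = x.shape[0]
        fm, caches = self._backbone(x, want_cache=True)
        nn_, h, w, c = fm.shape
        if self.head == "gmp":
            flat = fm.reshape(n, h * w, c)
            amax = flat.argmax(axis=1)                       # (N, C)
            v = np.take_along_axis(flat, amax[:, None, :], axis=1)[:, 0, :]
        else:
            v = fm.mean(axis=(1, 2))
        logits = v @ self.params["Wd"] + self.params["bd"]
        probs = softmax(logits)
        p = np.clip(probs, EPS_LOG, 1.0)
        loss = float(-(y_onehot * np.log(p)).sum(axis=1).mean())

        grads = {}
        dlogits = (probs - y_onehot).astype(np.float32) / n
        grads["Wd"] = v.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dv = dlogits @ self.params["Wd"].T                   # (N, C)
        if self.head == "gmp":
            dflat = np.zeros((n, h * w, c), dtype=np.float32)
            np.put_along_axis(dflat, amax[:, None, :], dv[:, None, :], axis=1)
            dfm = dflat.reshape(n, h, w, c)
        else:
            dfm = np.broadcast_to(
                dv[:, None, None, :] / (h * w), fm.shape
            ).astype(np.float32)

        da = dfm
        for i in reversed(range(len(self.channels))):
            cache, z = caches[i]
            dz = da * (z > 0)
            da, dW, db = _conv_backward(dz, self.params[f"W{i}"],
                                        self.stride, cache)
            grads[f"W{i}"] = dW
            grads[f"b{i}"] = db
        return loss, grads, probs

    # -- state --------------------------------------------------------------

    def get_weights(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict) -> None:
        for k, v in weights.items():
            self.params[k] = np.asarray(v, dtype=np.float32).copy()

    def save(self, path) -> None:
        np.savez(path, **self.params,
                 _meta=np.array([self.kernel, self.stride, self.seed]),
                 _channels=np.array(self.channels),
                 _head=np.array(self.head))

    @classmethod
    def load(cls, path) -> "SmallConvNet":
        with np.load(path, allow_pickle=False) as z:
            channels = tuple(int(c) for c in z["_channels"])
            kernel, stride, seed = (int(v) for v in z["_meta"])
            head = str(z["_head"])
            net = cls(channels=channels, kernel=kernel, stride=stride,
                      head=head, seed=seed)
            net.set_weights({k: z[k] for k in z.files
                             if not k.startswith("_")})
        return net


class Adam:
    """Adam optimiser over a dict of numpy parameters."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1 ** self.t)
            vh = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)
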