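"""Layer-sequence calculus: receptive fields, jumps, and output shapes.

A convolutional backbone is described by the ordered list of sliding-window
layers along its single downsampling path.  Two quantities propagate through
that list:

* the receptive field ``r`` — the side length (in input pixels) of the input
  region that can influence one cell of the current feature map, and
* the jump ``j`` — the spacing (in input pixels) between the centres of
  adjacent feature-map cells.

Starting from ``r = j = 1`` at the input, a layer with kernel ``k``,
stride ``s`` and dilation ``d`` updates them as::

    r <- r + (k - 1) * d * j
    j <- j * s

Residual blocks contribute through their longest branch: the shortcut is a
1x1 (or identity) projection and never widens coverage, so the receptive
field of a block is the max over its parallel branches.

The reference backbone here is ResNet-50 in its original (v1) form, where
the stride-2 downsampling of stages conv3-conv5 sits on the *first 1x1*
convolution of the leading bottleneck.  Under that convention the recurrence
yields a 483 px receptive field for the final feature map and a 7-cell side
for a 224 px input ('same' padding, out = ceil(in / s)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import yaml

__all__ = [
    "LayerSpec",
    "ResidualSpec",
    "ArchitectureSpec",
    "receptive_field",
    "output_spatial_size",
    "physical_receptive_field",
    "resnet50_spec",
    "desk_spec",
]

_KINDS = frozenset({"conv", "pool", "identity"})


@dataclass(frozen=True)
class LayerSpec:
    """One sliding-window layer: kernel ``k``, stride ``s``, dilation ``d``.

    ``padding`` is ``"same"`` (shape rule ``ceil(in/s)``), ``"valid"``, or a
    non-negative int for explicit symmetric padding.
    """

    kind: str = "conv"
    kernel: int = 3
    stride: int = 1
    dilation: int = 1
    padding: Union[str, int] = "same"
    name: str = ""

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel < 1 or self.stride < 1 or self.dilation < 1:
            raise ValueError("kernel, stride and dilation must be >= 1")
        if isinstance(self.padding, int) and self.padding < 0:
            raise ValueError("explicit padding must be >= 0")


@dataclass(frozen=True)
class ResidualSpec:
    """Parallel branches that merge by addition; coverage = longest branch.

    Every branch must apply the same total stride, otherwise the merge is
    shape-inconsistent.
    """

    branches: tuple = ()
    name: str = ""

    def __post_init__(self):
        if not self.branches:
            raise ValueError("residual block needs at least one branch")


Layer = Union[LayerSpec, ResidualSpec]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layers along the downsampling path plus the channel width."""

    layers: tuple = ()
    final_channels: int = 2048
    name: str = ""

    def __post_init__(self):
        if not self.layers:
            raise ValueError("architecture must contain at least one layer")

    @property
    def total_stride(self) -> int:
        _, j = receptive_field(self)
        return j

    def to_yaml(self) -> str:
        def enc(layer):
            if isinstance(layer, ResidualSpec):
                return {
                    "residual": [[enc(l) for l in br] for br in layer.branches],
                    "name": layer.name,
                }
            return {
                "kind": layer.kind,
                "kernel": layer.kernel,
                "stride": layer.stride,
                "dilation": layer.dilation,
                "padding": layer.padding,
                "name": layer.name,
            }

        return yaml.safe_dump(
            {
                "name": self.name,
                "final_channels": self.final_channels,
                "layers": [enc(l) for l in self.layers],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        doc = yaml.safe_load(text)

        def dec(obj):
            if "residual" in obj:
                return ResidualSpec(
                    branches=tuple(
                        tuple(dec(l) for l in br) for br in obj["residual"]
                    ),
                    name=obj.get("name", ""),
                )
            return LayerSpec(
                kind=obj.get("kind", "conv"),
                kernel=obj["kernel"],
                stride=obj.get("stride", 1),
                dilation=obj.get("dilation", 1),
                padding=obj.get("padding", "same"),
                name=obj.get("name", ""),
            )

        return cls(
            layers=tuple(dec(l) for l in doc["layers"]),
            final_channels=doc.get("final_channels", 2048),
            name=doc.get("name", ""),
        )


def _propagate(layers: Iterable[Layer], r: int, j: int) -> tuple:
    for layer in layers:
        if isinstance(layer, ResidualSpec):
            results = [_propagate(br, r, j) for br in layer.branches]
            jumps = {jj for _, jj in results}
            if len(jumps) > 1:
                raise ValueError(
                    f"residual branches of {layer.name or 'block'} disagree "
                    f"on total stride: {sorted(jumps)}"
                )
            r = max(rr for rr, _ in results)
            j = jumps.pop()
        else:
            r = r + (layer.kernel - 1) * layer.dilation * j
            j = j * layer.stride
    return r, j


def receptive_field(arch: ArchitectureSpec) -> tuple:
    """Receptive-field side and jump (both in input pixels) of the final map."""
    return _propagate(arch.layers, 1, 1)


def _layer_out(side: int, layer: LayerSpec) -> int:
    k, s, d = layer.kernel, layer.stride, layer.dilation
    eff = d * (k - 1) + 1
    if layer.padding == "same":
        out = math.ceil(side / s)
    elif layer.padding == "valid":
        out = (side - eff) // s + 1
    else:
        out = (side + 2 * layer.padding - eff) // s + 1
    return out


def output_spatial_size(arch: ArchitectureSpec, input_side: int) -> int:
    """Final feature-map side for a square ``input_side`` input."""
    if input_side < 1:
        raise ValueError("input_side must be >= 1")
    side = input_side
    for layer in arch.layers:
        if isinstance(layer, ResidualSpec):
            sides = set()
            for br in layer.branches:
                s = side
                for l in br:
                    s = _layer_out(s, l)
                sides.add(s)
            if len(sides) > 1:
                raise ValueError("residual branches disagree on output size")
            side = sides.pop()
        else:
            side = _layer_out(side, layer)
        if side < 1:
            raise ValueError(
                f"spatial size collapsed to {side} at layer "
                f"{layer.name or layer!r}"
            )
    return side


def physical_receptive_field(rf_px: int, um_per_px: float) -> int:
    """Physical receptive-field side in µm, rounded to the nearest micron.

    At the scanner's native x20 (0.46 µm/px) a 483 px field covers 222 µm;
    downscaled to x4 (2.3 µm/px) it covers 1111 µm, and at x2, 2222 µm.
    """
    if rf_px <= 0 or um_per_px <= 0:
        raise ValueError("rf_px and um_per_px must be positive")
    return round(rf_px * um_per_px)


def _bottleneck(stride: int, stage: str, block: int) -> ResidualSpec:
    # v1 convention: the stage's downsampling stride sits on the first 1x1.
    main = (
        LayerSpec("conv", 1, stride, name=f"{stage}.{block}.conv1"),
        LayerSpec("conv", 3, 1, name=f"{stage}.{block}.conv2"),
        LayerSpec("conv", 1, 1, name=f"{stage}.{block}.conv3"),
    )
    shortcut = (LayerSpec("conv", 1, stride, name=f"{stage}.{block}.down"),)
    return ResidualSpec(branches=(main, shortcut), name=f"{stage}.{block}")


def resnet50_spec() -> ArchitectureSpec:
    """The reference ResNet-50 downsampling path (2048 final channels)."""
    layers = [
        LayerSpec("conv", 7, 2, name="conv1"),
        LayerSpec("pool", 3, 2, name="maxpool"),
    ]
    for stage, (n_blocks, first_stride) in {
        "conv2": (3, 1),
        "conv3": (4, 2),
        "conv4": (6, 2),
        "conv5": (3, 2),
    }.items():
        for b in range(n_blocks):
            layers.append(_bottleneck(first_stride if b == 0 else 1, stage, b))
    return ArchitectureSpec(tuple(layers), final_channels=2048, name="resnet50")


def desk_spec(channels: Sequence[int] = (8, 16, 32)) -> ArchitectureSpec:
    """Small desk-scale backbone: one 3x3 stride-2 conv per stage."""
    layers = tuple(
        LayerSpec("conv", 3, 2, name=f"conv{i + 1}")
        for i in range(len(channels))
    )
    return ArchitectureSpec(layers, final_channels=channels[-1], name="desk")
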