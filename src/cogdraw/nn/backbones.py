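"""Convolutional backbones producing the last feature map X (H x L x C).

Two backbones are provided:

* ``vgg16`` — the 13-conv-layer / 5-maxpool VGG16 feature extractor
  configuration.  Five stride-2 pools reduce a 256x256 input to an
  8x8x512 feature map.  Weights are He-initialized from the supplied
  generator; loading externally trained weights is possible through
  ``state`` round-tripping but never required.
* ``toy`` — a 4-block desk-scale CNN (conv3x3 + ReLU + maxpool per block)
  for fast experiments and tests; a 64x64 input yields a 4x4 map.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .layers import Conv2d, Module

__all__ = ["ToyBackbone", "VGG16Backbone", "build_backbone", "BACKBONES"]

_VGG16_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M"]


class _ConvStack(Module):
    def __init__(self, cfg: list, in_channels: int, rng: np.random.Generator):
        self.convs: list[Conv2d] = []
        self.cfg = cfg
        c = in_channels
        for item in cfg:
            if item == "M":
                continue
            self.convs.append(Conv2d(c, item, 3, rng, padding=1))
            c = item
        self.out_channels = c

    def __call__(self, x: Tensor) -> Tensor:
        i = 0
        for item in self.cfg:
            if item == "M":
                x = x.maxpool2x2()
            else:
                x = self.convs[i](x).relu()
                i += 1
        return x


class VGG16Backbone(_ConvStack):
    name = "vgg16"
    n_pools = 5

    def __init__(self, rng: np.random.Generator, in_channels: int = 3):
        super().__init__(_VGG16_CFG, in_channels, rng)


class ToyBackbone(_ConvStack):
    """Small 4-block backbone: channels (8, 16, 32, 32), four 2x2 pools."""

    name = "toy"
    n_pools = 4

    def __init__(self, rng: np.random.Generator, in_channels: int = 3,
                 channels: tuple[int, ...] = (8, 16, 32, 32)):
        cfg: list = []
        for c in channels:
            cfg.extend([c, "M"])
        super().__init__(cfg, in_channels, rng)


BACKBONES = {"vgg16": VGG16Backbone, "toy": ToyBackbone}


def build_backbone(name: str, rng: np.random.Generator,
                   in_channels: int = 3) -> _ConvStack:
    try:
        cls = BACKBONES[name]
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; valid: {sorted(BACKBONES)}") from None
    return cls(rng, in_channels=in_channels)
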