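"""Encoder-decoder segmentation network (BianqueNet layout).

The architecture is a deeplabv3+-style encoder-decoder with three
additions:

* **DFE** (depth feature extraction) between the backbone and the decoder:
  pyramid pooling doubles the bottom-level channels with multi-scale
  context (2048 → 4096 on the full preset), then an atrous spatial pyramid
  pooling (ASPP) block condenses them to a dense 256-channel semantic map;
* **ST-SC** — Swin-transformer skip connections (see
  :mod:`ivdquant.network.swin`) on the 1/4- and 1/8-resolution skip paths,
  with output channels reduced to 1/8 of the tapped feature map;
* **MFF** — feature-pyramid-style multi-scale feature fusion in the
  decoder: each ×2 transpose-convolution upsampling step splices the
  ST-SC features of the matching resolution, followed by a 3×3
  double-convolution refinement, ending in further ×2 transpose
  convolutions back to input resolution.

The backbone downsamples 16×: a strided stem, two strided residual stages,
one strided stage, and a final dilation-2 stage with atrous separable
convolutions at stride 1.  The ``tiny`` preset mirrors the full topology
layer for layer at a width and depth that runs on a CPU; the ``full``
preset is a resnet101-style bottleneck backbone.

Per-pixel class probabilities come from a final SoftMax, the form assumed
by the weighted dice loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, resize_nearest, softmax
from .layers import (BatchNorm2d, Conv2d, ConvBNReLU, ConvTranspose2d,
                     Module, SeparableConv2d, adaptive_avg_pool2d)
from .swin import STSC

__all__ = ["NetConfig", "ConfigError", "BianqueNet", "build_bianquenet",
           "save_checkpoint", "load_checkpoint"]


class ConfigError(ValueError):
    """Invalid network configuration (e.g. input size not divisible by 16)."""


@dataclass(frozen=True)
class NetConfig:
    """Configuration of the segmentation network.

    ``preset`` selects depth/width: ``tiny`` (basic residual blocks, 32
    base channels — every architectural path exercised at CPU-test scale)
    or ``full`` (bottleneck backbone with 256..2048-channel stages).
    """

    input_size: tuple[int, int] = (64, 64)
    n_classes: int = 14
    preset: str = "tiny"
    base_channels: int = 32
    st_sc_window: int = 2
    st_sc_heads: int = 2
    channel_reduction: float = 1 / 8
    xi: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ConfigError(f"input size {h}x{w} must be divisible by 16")
        if not 0 < self.channel_reduction <= 1:
            raise ConfigError("channel_reduction must be in (0, 1]")
        if self.preset not in ("tiny", "full"):
            raise ConfigError(f"unknown preset {self.preset!r}")

    @classmethod
    def full(cls, input_size=(512, 512), **kw) -> "NetConfig":
        kw.setdefault("base_channels", 64)
        kw.setdefault("st_sc_window", 8)
        kw.setdefault("st_sc_heads", 4)
        return cls(input_size=input_size, preset="full", **kw)


class BasicBlock(Module):
    def __init__(self, rng, c_in, c_out, stride=1, dilation=1, separable=False):
        conv = SeparableConv2d if separable else None
        if separable:
            self.conv1 = SeparableConv2d(rng, c_in, c_out, stride=stride,
                                         dilation=dilation)
        else:
            self.conv1 = Conv2d(rng, c_in, c_out, 3, stride,
                                dilation=dilation, bias=False)
        self.bn1 = BatchNorm2d(c_out)
        if separable:
            self.conv2 = SeparableConv2d(rng, c_out, c_out, dilation=dilation)
        else:
            self.conv2 = Conv2d(rng, c_out, c_out, 3, dilation=dilation,
                                bias=False)
        self.bn2 = BatchNorm2d(c_out)
        self.down = (Conv2d(rng, c_in, c_out, 1, stride, bias=False)
                     if (stride != 1 or c_in != c_out) else None)
        self.down_bn = BatchNorm2d(c_out) if self.down is not None else None

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        skip = self.down_bn(self.down(x)) if self.down is not None else x
        return (y + skip).relu()


class Bottleneck(Module):
    def __init__(self, rng, c_in, c_out, stride=1, dilation=1, separable=False):
        mid = c_out // 4
        self.conv1 = Conv2d(rng, c_in, mid, 1, bias=False)
        self.bn1 = BatchNorm2d(mid)
        if separable:
            self.conv2 = SeparableConv2d(rng, mid, mid, stride=stride,
                                         dilation=dilation)
        else:
            self.conv2 = Conv2d(rng, mid, mid, 3, stride, dilation=dilation,
                                bias=False)
        self.bn2 = BatchNorm2d(mid)
        self.conv3 = Conv2d(rng, mid, c_out, 1, bias=False)
        self.bn3 = BatchNorm2d(c_out)
        self.down = (Conv2d(rng, c_in, c_out, 1, stride, bias=False)
                     if (stride != 1 or c_in != c_out) else None)
        self.down_bn = BatchNorm2d(c_out) if self.down is not None else None

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        skip = self.down_bn(self.down(x)) if self.down is not None else x
        return (y + skip).relu()


class Stage(Module):
    def __init__(self, rng, block, c_in, c_out, n_units, stride, dilation=1,
                 separable=False):
        units = [block(rng, c_in, c_out, stride, dilation, separable)]
        for _ in range(n_units - 1):
            units.append(block(rng, c_out, c_out, 1, dilation, separable))
        self.units = units

    def forward(self, x):
        for u in self.units:
            x = u(x)
        return x


class Backbone(Module):
    """16×-downsampling residual backbone with a dilated last stage."""

    def __init__(self, rng, cfg: NetConfig):
        b = cfg.base_channels
        if cfg.preset == "tiny":
            block, units = BasicBlock, (1, 1, 1, 1)
            chans = (2 * b, 4 * b, 8 * b, 8 * b)       # 64,128,256,256
        else:
            block, units = Bottleneck, (3, 4, 23, 3)
            chans = (4 * b, 8 * b, 16 * b, 32 * b)     # 256,...,2048
        self.stem = ConvBNReLU(rng, 1, b, k=3, stride=2)            # /2
        self.stage1 = Stage(rng, block, b, chans[0], units[0], 2)   # /4
        self.stage2 = Stage(rng, block, chans[0], chans[1], units[1], 2)  # /8
        self.stage3 = Stage(rng, block, chans[1], chans[2], units[2], 2)  # /16
        # atrous separable convolution in the last stage, stride kept at 1
        self.stage4 = Stage(rng, block, chans[2], chans[3], units[3], 1,
                            dilation=2, separable=True)             # /16
        self.out_channels = chans[3]
        self.skip_channels = (chans[0], chans[1])       # /4, /8 taps

    def forward(self, x):
        x = self.stem(x)
        s4 = self.stage1(x)
        s8 = self.stage2(s4)
        s16 = self.stage3(s8)
        bottom = self.stage4(s16)
        return s4, s8, bottom


class PyramidPooling(Module):
    """Multi-bin average pooling; doubles the channel count (C → 2C)."""

    def __init__(self, rng, c_in, bins=(1, 2, 4, 8)):
        self.bins = bins
        c_branch = c_in // len(bins)
        # last branch absorbs the remainder so channels exactly double
        sizes = [c_branch] * (len(bins) - 1) + [c_in - c_branch * (len(bins) - 1)]
        self.convs = [Conv2d(rng, c_in, c, 1) for c in sizes]

    def forward(self, x):
        N, C, H, W = x.shape
        outs = [x]
        for bin_, conv in zip(self.bins, self.convs):
            p = conv(adaptive_avg_pool2d(x, bin_))
            outs.append(resize_nearest(p, H, W))
        return concat(outs, axis=1)


class ASPP(Module):
    """Atrous spatial pyramid pooling condensing context to a dense map."""

    def __init__(self, rng, c_in, c_out, rates=(2, 3, 4)):
        c_mid = c_out
        self.branch1 = ConvBNReLU(rng, c_in, c_mid, k=1)
        self.atrous = [ConvBNReLU(rng, c_in, c_mid, k=3, dilation=r)
                       for r in rates]
        self.pool_conv = Conv2d(rng, c_in, c_mid, 1)
        self.project = ConvBNReLU(rng, c_mid * (2 + len(rates)), c_out, k=1)

    def forward(self, x):
        N, C, H, W = x.shape
        outs = [self.branch1(x)] + [a(x) for a in self.atrous]
        pooled = self.pool_conv(adaptive_avg_pool2d(x, 1))
        outs.append(resize_nearest(pooled, H, W))
        return self.project(concat(outs, axis=1))


class DFE(Module):
    """Depth feature extraction: pyramid pooling then ASPP."""

    def __init__(self, rng, c_in, c_out, bins, rates):
        self.ppm = PyramidPooling(rng, c_in, bins)
        self.aspp = ASPP(rng, 2 * c_in, c_out, rates)

    def forward(self, x):
        return self.aspp(self.ppm(x))


class DoubleConv(Module):
    def __init__(self, rng, c_in, c_out):
        self.a = ConvBNReLU(rng, c_in, c_out)
        self.b = ConvBNReLU(rng, c_out, c_out)

    def forward(self, x):
        return self.b(self.a(x))


class BianqueNet(Module):
    """Full segmentation model; forward returns per-pixel SoftMax maps."""

    def __init__(self, config: NetConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        cfg = config
        self.backbone = Backbone(rng, cfg)
        c4, c8 = self.backbone.skip_channels
        cb = self.backbone.out_channels
        if cfg.preset == "tiny":
            bins, rates = (1, 2, 4), (1, 2, 3)
            c_dfe, dec1, dec2 = 4 * cfg.base_channels, 2 * cfg.base_channels, cfg.base_channels
        else:
            bins, rates = (1, 2, 4, 8), (6, 12, 18)
            c_dfe, dec1, dec2 = 256, 128, 64
        self.dfe = DFE(rng, cb, c_dfe, bins, rates)
        self.stsc8 = STSC(rng, c8, cfg.st_sc_window, cfg.st_sc_heads,
                          channel_reduction=cfg.channel_reduction)
        self.stsc4 = STSC(rng, c4, cfg.st_sc_window, cfg.st_sc_heads,
                          channel_reduction=cfg.channel_reduction)
        self.up1 = ConvTranspose2d(rng, c_dfe, dec1)                 # /16→/8
        self.fuse1 = DoubleConv(rng, dec1 + self.stsc8.c_out, dec1)
        self.up2 = ConvTranspose2d(rng, dec1, dec2)                  # /8→/4
        self.fuse2 = DoubleConv(rng, dec2 + self.stsc4.c_out, dec2)
        self.up3 = ConvTranspose2d(rng, dec2, dec2)                  # /4→/2
        self.up3_bn = BatchNorm2d(dec2)
        self.up4 = ConvTranspose2d(rng, dec2, cfg.n_classes)         # /2→/1

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ConfigError(f"input {h}x{w} must be divisible by 16")
        s4, s8, bottom = self.backbone(x)
        y = self.dfe(bottom)
        y = self.up1(y)
        y = self.fuse1(concat([y, self.stsc8(s8)], axis=1))
        y = self.up2(y)
        y = self.fuse2(concat([y, self.stsc4(s4)], axis=1))
        y = self.up3_bn(self.up3(y)).relu()
        logits = self.up4(y)
        return softmax(logits, axis=1)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """Hard label map (argmax over the SoftMax output)."""
        probs = self.forward(image)
        return np.argmax(probs.data, axis=1).squeeze()


def build_bianquenet(config: NetConfig) -> BianqueNet:
    """Construct the network for the given configuration."""
    return BianqueNet(config)


def save_checkpoint(model: BianqueNet, path) -> None:
    np.savez_compressed(path, **model.state_dict())


def load_checkpoint(model: BianqueNet, path) -> BianqueNet:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
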