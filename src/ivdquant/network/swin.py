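"""Swin-transformer skip-connection (ST-SC) module.

Two successive Swin transformer blocks — window-based multi-head
self-attention (W-MSA) followed by its shifted-window counterpart (SW-MSA),
each block being LN → attention → residual, LN → 2-layer GELU MLP →
residual:

    SC̄₀ = W-MSA(LN(X)) + X
    SC₀  = MLP(LN(SC̄₀)) + SC̄₀
    SC̄₁ = SW-MSA(LN(SC₀)) + SC₀
    SC₁  = MLP(LN(SC̄₁)) + SC̄₁
    Y    = fuse(X̂, SC₁)

where X̂ is the skip feature passed through a 1×1 convolution and the
fusion splices (concatenates) the two branches along channels.  To avoid
swamping the dense decoder features, the module's output channel count is
reduced to ``channel_reduction`` (default 1/8) times the input channels.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, softmax
from .layers import Conv2d, LayerNorm, Linear, Module

__all__ = ["WindowAttention", "SwinBlock", "STSC"]


def _window_partition(x: Tensor, win: int) -> Tensor:
    """(B, H, W, D) → (B·nWin, win², D) token windows."""
    B, H, W, D = x.shape
    x = x.reshape(B, H // win, win, W // win, win, D)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B * (H // win) * (W // win), win * win, D)


def _window_reverse(x: Tensor, win: int, B: int, H: int, W: int) -> Tensor:
    D = x.shape[-1]
    x = x.reshape(B, H // win, W // win, win, win, D)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B, H, W, D)


class WindowAttention(Module):
    """Multi-head self-attention within non-overlapping windows."""

    def __init__(self, rng, dim, heads, window):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.window = dim, heads, window
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)

    def forward(self, x: Tensor) -> Tensor:
        # x: (nW, L, D) windows of L = window² tokens
        nW, L, D = x.shape
        h, hd = self.heads, self.dim // self.heads
        qkv = self.qkv(x).reshape(nW, L, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]        # (nW, h, L, hd)
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * (hd ** -0.5), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(nW, L, D)
        return self.proj(out)


class SwinBlock(Module):
    """One Swin block: (S)W-MSA with pre-LN residual, then MLP residual."""

    def __init__(self, rng, dim, heads, window, shift, mlp_ratio=4):
        self.window, self.shift = window, shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(rng, dim, heads, window)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(rng, dim, dim * mlp_ratio)
        self.fc2 = Linear(rng, dim * mlp_ratio, dim)

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, H, W, D)
        B, H, W, D = x.shape
        if H % self.window or W % self.window:
            raise ValueError(
                f"feature map {H}x{W} not divisible by window {self.window}")
        y = self.norm1(x)
        if self.shift:
            y = y.roll((-self.shift, -self.shift), axis=(1, 2))
        y = _window_partition(y, self.window)
        y = self.attn(y)
        y = _window_reverse(y, self.window, B, H, W)
        if self.shift:
            y = y.roll((self.shift, self.shift), axis=(1, 2))
        x = x + y
        z = self.norm2(x)
        z = self.fc2(self.fc1(z).gelu())
        return x + z


class STSC(Module):
    """Swin-transformer skip connection with channel reduction and fusion.

    Input (N, C, H, W); output (N, round(C·channel_reduction), H, W),
    the channel-wise splice of a 1×1-convolved copy of the input with the
    output of two successive Swin blocks (W-MSA, then SW-MSA with shift
    window/2).
    """

    def __init__(self, rng, c_in, window=8, heads=4, mlp_ratio=4,
                 channel_reduction=1 / 8):
        if not 0 < channel_reduction <= 1:
            raise ValueError("channel_reduction must be in (0, 1]")
        c_out = max(2, round(c_in * channel_reduction))
        self.c_out = c_out
        c_conv = c_out // 2
        c_swin = c_out - c_conv
        heads = min(heads, c_swin)
        while c_swin % heads:
            heads -= 1
        self.window = window
        self.embed = Linear(rng, c_in, c_swin)
        self.block1 = SwinBlock(rng, c_swin, heads, window, shift=0,
                                mlp_ratio=mlp_ratio)
        self.block2 = SwinBlock(rng, c_swin, heads, window,
                                shift=window // 2, mlp_ratio=mlp_ratio)
        self.conv1x1 = Conv2d(rng, c_in, c_conv, k=1)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        tokens = x.transpose(0, 2, 3, 1)            # (N, H, W, C)
        tokens = self.embed(tokens)
        tokens = self.block2(self.block1(tokens))
        swin_map = tokens.transpose(0, 3, 1, 2)     # (N, c_swin, H, W)
        conv_map = self.conv1x1(x)
        return concat([conv_map, swin_map], axis=1)
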