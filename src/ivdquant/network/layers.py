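"""Neural-network layers built on the autodiff engine (NCHW layout)."""

from __future__ import annotations

import numpy as np

from .autodiff import (Tensor, adaptive_avg_pool2d, conv2d, conv_transpose2d,
                       depthwise_conv2d)

__all__ = ["Module", "Conv2d", "DepthwiseConv2d", "SeparableConv2d",
           "ConvTranspose2d", "BatchNorm2d", "LayerNorm", "Linear",
           "ConvBNReLU", "adaptive_avg_pool2d", "Adam"]


class Module:
    """Base class: parameter collection and state-dict (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v.data
            elif isinstance(v, Module):
                out.update(v.state_dict(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray],
                        prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[key], dtype=np.float64).reshape(v.shape)
            elif isinstance(v, Module):
                v.load_state_dict(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        item.data = np.asarray(state[f"{key}.{i}"],
                                               dtype=np.float64).reshape(item.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, k=3, stride=1, padding=None,
                 dilation=1, bias=True):
        self.stride, self.dilation = stride, dilation
        self.padding = padding if padding is not None else dilation * (k // 2)
        self.weight = _he(rng, (c_out, c_in, k, k), c_in * k * k)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, rng, c, k=3, stride=1, padding=None, dilation=1):
        self.stride, self.dilation = stride, dilation
        self.padding = padding if padding is not None else dilation * (k // 2)
        self.weight = _he(rng, (c, k, k), k * k)

    def forward(self, x):
        return depthwise_conv2d(x, self.weight, None, self.stride,
                                self.padding, self.dilation)


class SeparableConv2d(Module):
    """Atrous separable convolution: dilated depthwise then pointwise 1×1."""

    def __init__(self, rng, c_in, c_out, k=3, stride=1, dilation=1):
        self.depthwise = DepthwiseConv2d(rng, c_in, k, stride, dilation=dilation)
        self.pointwise = Conv2d(rng, c_in, c_out, k=1)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class ConvTranspose2d(Module):
    def __init__(self, rng, c_in, c_out, k=2, stride=2, padding=0, bias=True):
        self.stride, self.padding = stride, padding
        self.weight = _he(rng, (c_in, c_out, k, k), c_in * k * k)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride,
                                self.padding)


class BatchNorm2d(Module):
    """Batch normalisation using batch statistics (train-mode).

    No running statistics are tracked: the models here are trained and
    evaluated on the same small batches, and shipped checkpoints always
    carry their own inputs.
    """

    def __init__(self, c, eps=1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)

    def forward(self, x):
        m = x.mean(axis=(0, 2, 3), keepdims=True)
        xc = x - m
        var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
        xhat = xc * (var + self.eps) ** (-0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Layer normalisation over the last axis (token feature dimension)."""

    def __init__(self, d, eps=1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def forward(self, x):
        m = x.mean(axis=-1, keepdims=True)
        xc = x - m
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** (-0.5) * self.gamma + self.beta


class Linear(Module):
    def __init__(self, rng, d_in, d_out, bias=True):
        self.weight = _he(rng, (d_in, d_out), d_in)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class ConvBNReLU(Module):
    def __init__(self, rng, c_in, c_out, k=3, stride=1, dilation=1):
        self.conv = Conv2d(rng, c_in, c_out, k, stride, dilation=dilation,
                           bias=False)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
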