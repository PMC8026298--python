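"""Neural-network layers on top of :mod:`vesselseg.autodiff`.

Modules hold named :class:`Parameter` tensors and optional numpy buffers
(batch-norm running statistics).  Weight initialization is He-normal and is
driven entirely by an explicit ``numpy.random.Generator``, so two builds from
the same seed produce bit-identical parameters.
"""

from __future__ import annotations

import json

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: parameter/buffer traversal, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict:
        state = {f"param.{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r} in checkpoint")
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: checkpoint {value.shape}, model {params[name].data.shape}")
                params[name].data = np.asarray(value, dtype=params[name].data.dtype)
            elif kind == "buffer":
                if name not in buffers:
                    raise KeyError(f"unknown buffer {name!r} in checkpoint")
                buffers[name][...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def save_checkpoint(path, module: Module, config: dict | None = None, version: str = "1"):
    """Write a named-tensor checkpoint (.npz) with a JSON config/version header."""
    header = json.dumps({"version": version, "config": config or {}})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **module.state_dict())


def load_checkpoint(path):
    """Return (state_dict, header_dict) from a checkpoint file."""
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files if k != "__header__"}
        header = json.loads(bytes(archive["__header__"]).decode())
    if "version" not in header:
        raise ValueError("checkpoint missing version field")
    return state, header


class Conv2d(Module):
    """Stride-1 2-D convolution, 'same' padding by default."""

    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 dilation=1, padding=None, bias=True, gain=2.0):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(gain / fan_in)   # gain 2 for ReLU-followed convs, 1 for linear
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias,
                         dilation=self.dilation, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x):
        return ad.batchnorm2d(x, self.gamma, self.beta,
                              self.running_mean, self.running_var,
                              training=self.training,
                              momentum=self.momentum, eps=self.eps)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C): spatial mean per channel."""
    return ad.tmean(x, axis=(2, 3))
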