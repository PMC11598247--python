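"""Neural-network layers built on the autograd engine.

Modules follow the familiar container pattern: parameters are
:class:`~aernet.nn.autograd.Tensor` objects with ``requires_grad=True``,
child modules are discovered from instance attributes, and ``train()`` /
``eval()`` toggle batch-norm behaviour.  Weight initialization is He-normal
from an explicit ``numpy.random.Generator`` so models are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    batchnorm2d,
    concat,
    conv2d,
    maxpool2x2,
    upsample_nearest2x,
)

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "UpsampleNearest2x",
    "Sequential",
    "ChannelAttention",
    "SpatialAttention",
    "AttentionBlock",
]


class Module:
    """Base class: parameter discovery, mode switching, state dicts."""

    training = True

    def parameters(self) -> list[Tensor]:
        params = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # flat state dict keyed by attribute path, for checkpointing
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                state[key] = value.data.copy()
            elif isinstance(value, np.ndarray):  # running stats
                state[key] = value.copy()
            elif isinstance(value, Module):
                state.update(value.state_dict(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{key}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                value.data[...] = state[key]
            elif isinstance(value, np.ndarray):
                value[...] = state[key]
            elif isinstance(value, Module):
                value.load_state_dict(state, f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{key}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in, c_out, ksize, rng, stride=1, bias=True):
        fan_in = c_in * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, ksize, ksize)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
            if bias
            else None
        )
        self.stride = stride

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, c):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        return batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
        )


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class MaxPool2x2(Module):
    def forward(self, x):
        return maxpool2x2(x)


class UpsampleNearest2x(Module):
    def forward(self, x):
        return upsample_nearest2x(x)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ChannelAttention(Module):
    """CBAM-style channel gate.

    Global average- and max-pooled descriptors pass through a shared
    two-layer 1x1-conv bottleneck (reduction ratio ``r``); the summed logits
    are squashed by a sigmoid and multiply the input per channel.
    """

    def __init__(self, channels, rng, reduction=16):
        hidden = max(channels // reduction, 1)
        self.fc1 = Conv2d(channels, hidden, 1, rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng)

    def gate(self, x) -> Tensor:
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.max(axis=(2, 3), keepdims=True)
        logits = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return logits.sigmoid()

    def forward(self, x):
        return x * self.gate(x)

    def set_identity(self):
        """Test hook: force the gate to ~1 so the block is ~identity."""
        self.fc2.weight.data[...] = 0.0
        self.fc2.bias.data[...] = 30.0


class SpatialAttention(Module):
    """CBAM-style spatial gate: channel-pooled mean/max -> 7x7 conv -> sigmoid."""

    def __init__(self, rng, ksize=7):
        self.conv = Conv2d(2, 1, ksize, rng)

    def gate(self, x) -> Tensor:
        pooled = concat([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)], axis=1)
        return self.conv(pooled).sigmoid()

    def forward(self, x):
        return x * self.gate(x)

    def set_identity(self):
        self.conv.weight.data[...] = 0.0
        self.conv.bias.data[...] = 30.0


class AttentionBlock(Module):
    """Channel attention followed by spatial attention (shape preserving)."""

    def __init__(self, channels, rng, reduction=16):
        self.channel = ChannelAttention(channels, rng, reduction)
        self.spatial = SpatialAttention(rng)

    def forward(self, x):
        return self.spatial(self.channel(x))

    def set_identity(self):
        self.channel.set_identity()
        self.spatial.set_identity()
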