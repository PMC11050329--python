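"""Neural-network layers on top of the autodiff engine.

Layout convention: feature maps are (batch, channels, length).  For the
log-Mel input the 80 Mel bands are the channels and the 301 frames the
length.  The attention modules implement elementwise reweighting of the
feature map: channel attention multiplies every channel m_i by a learned
scalar weight in (0, 1); time attention does the same per time step.
"""

from __future__ import annotations

import logging

import numpy as np

from .autodiff import Tensor, conv1d, maxpool1d

__all__ = [
    "Module",
    "Parameter",
    "Conv1d",
    "BatchNorm1d",
    "Sigmoid",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Linear",
    "Sequential",
    "ChannelAttention",
    "TimeAttention",
    "RMAM",
]

logger = logging.getLogger(__name__)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}[{i}]")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def _children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                yield from (v for v in value if isinstance(v, Module))

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Module):
                yield from value.named_buffers(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}[{i}]")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        self._collect_buffer_owners(buffers, "")
        for name, array in state.items():
            if name in params:
                if params[name].data.shape != array.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: expected {params[name].data.shape}, "
                        f"got {array.shape}"
                    )
                params[name].data = np.asarray(array, dtype=np.float32)
            elif name in buffers:
                owner, attr = buffers[name]
                setattr(owner, attr, np.asarray(array, dtype=np.float64))
            else:
                raise ValueError(f"unexpected key {name!r} in state dict")

    def _collect_buffer_owners(self, out: dict, prefix: str) -> None:
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Module):
                value._collect_buffer_owners(out, full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item._collect_buffer_owners(out, f"{full}[{i}]")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                out[full] = (self, name)


def _glorot(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: str | int = "same", bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(
            _glorot((out_channels, in_channels, kernel_size),
                    in_channels * kernel_size, out_channels * kernel_size, rng)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm1d(Module):
    """Per-channel batch normalisation over (batch, length).

    Training mode normalises with batch statistics and updates exponential
    running averages; evaluation mode uses the running averages.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_channels = num_channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_channels, dtype=np.float32))
        self.running_mean = np.zeros(num_channels, dtype=np.float64)
        self.running_var = np.ones(num_channels, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        C = self.num_channels
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(C)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.reshape(C)
            )
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1))
            std_inv = Tensor((self.running_var.reshape(1, C, 1) + self.eps) ** -0.5)
            xhat = (x - mu) * std_inv
        return xhat * self.gamma.reshape(1, C, 1) + self.beta.reshape(1, C, 1)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool1d(Module):
    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.kernel)


class GlobalAvgPool1d(Module):
    """Average each channel over time: (B, C, L) -> (B, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=2)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_glorot((in_features, out_features), in_features, out_features, rng))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ChannelAttention(Module):
    """Squeeze-excitation-style per-channel reweighting.

    Global average pooling over time gives a channel descriptor z (one
    scalar per channel); a two-layer 1x1-convolution bottleneck
    (C -> max(1, C // r) -> C) with a ReLU between and a sigmoid after maps
    it to weights in (0, 1); each channel of the input is multiplied by its
    weight.  Output shape equals input shape.
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, channels // reduction)
        if channels % reduction != 0:
            logger.info(
                "channel count %d not divisible by reduction %d; bottleneck width %d",
                channels, reduction, hidden,
            )
        self.fc1 = Conv1d(channels, hidden, 1, rng=rng)
        self.fc2 = Conv1d(hidden, channels, 1, rng=rng)

    def weights(self, m: Tensor) -> Tensor:
        z = m.mean(axis=2, keepdims=True)  # (B, C, 1)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, m: Tensor) -> Tensor:
        return m * self.weights(m)


class TimeAttention(Module):
    """Per-time-step reweighting.

    A 1x1 convolution collapses the C channels to a single length-L
    descriptor q; two 1x1 nonlinear layers (shared across positions) and a
    sigmoid map it to weights in (0, 1); each time step of the input is
    multiplied by its weight.  Output shape equals input shape.
    """

    def __init__(self, channels: int, hidden: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.squeeze = Conv1d(channels, 1, 1, rng=rng)
        self.fc1 = Conv1d(1, hidden, 1, rng=rng)
        self.fc2 = Conv1d(hidden, 1, 1, rng=rng)

    def weights(self, m: Tensor) -> Tensor:
        q = self.squeeze(m)  # (B, 1, L)
        return self.fc2(self.fc1(q).relu()).sigmoid()

    def forward(self, m: Tensor) -> Tensor:
        return m * self.weights(m)


class RMAM(Module):
    """Residual mixed-domain attention module.

    Two convolution modules (1-D conv, batch norm, sigmoid activation)
    produce a feature map M; channel attention and time attention each
    reweight M; the branches are combined (elementwise sum by default) and
    a residual skip of the input (1x1 projection when the channel counts
    differ) is added:  y = combine(Nz, Nt) + x.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 reduction: int = 4, combine: str = "sum", activation: str = "sigmoid",
                 use_channel_att: bool = True, use_time_att: bool = True,
                 use_skip: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if combine not in ("sum", "mean"):
            raise ValueError(f"unknown combine mode {combine!r}")
        act = Sigmoid if activation == "sigmoid" else ReLU
        self.combine = combine
        self.use_channel_att = use_channel_att
        self.use_time_att = use_time_att
        self.use_skip = use_skip
        self.conv_module1 = Sequential(
            Conv1d(in_channels, out_channels, kernel_size, rng=rng),
            BatchNorm1d(out_channels), act(),
        )
        self.conv_module2 = Sequential(
            Conv1d(out_channels, out_channels, kernel_size, rng=rng),
            BatchNorm1d(out_channels), act(),
        )
        if use_channel_att:
            self.channel_att = ChannelAttention(out_channels, reduction, rng=rng)
        if use_time_att:
            self.time_att = TimeAttention(out_channels, rng=rng)
        if use_skip:
            self.projection = (
                Conv1d(in_channels, out_channels, 1, bias=False, rng=rng)
                if in_channels != out_channels
                else None
            )

    def forward(self, x: Tensor) -> Tensor:
        m = self.conv_module2(self.conv_module1(x))
        branches = []
        if self.use_channel_att:
            branches.append(self.channel_att(m))
        if self.use_time_att:
            branches.append(self.time_att(m))
        if branches:
            out = branches[0]
            for b in branches[1:]:
                out = out + b
            if self.combine == "mean" and len(branches) > 1:
                out = out * (1.0 / len(branches))
        else:
            out = m
        if self.use_skip:
            skip = self.projection(x) if self.projection is not None else x
            assert skip.shape == out.shape, (
                f"residual shape mismatch: skip {skip.shape} vs branch {out.shape}"
            )
            out = out + skip
        return out
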