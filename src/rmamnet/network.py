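"""Declarative network specification and the default 10-layer stack.

The default architecture stacks four residual mixed-domain attention
modules with widening kernels and max-pooling, one plain convolution
module, global average pooling and a 4-class softmax classifier:

    RMAM(k=12, 128) -> pool 4 -> RMAM(k=6, 256) -> pool 4
    -> RMAM(k=3, 256) -> pool 2 -> RMAM(k=3, 256) -> pool 2
    -> Conv(k=3, 256) + BN + act -> pool 2 -> GAP -> FC softmax(4)

Channel progression on an 80-channel input: 80 -> 128 -> 256 -> 256 ->
256 -> 256; the global-average-pooled feature vector has 256 dimensions.
Spatial lengths are recomputed from kernel/stride/pool settings rather
than hard-coded.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor
from .nn import (
    RMAM,
    BatchNorm1d,
    Conv1d,
    GlobalAvgPool1d,
    Linear,
    MaxPool1d,
    Module,
    ReLU,
    Sequential,
    Sigmoid,
)

__all__ = ["RMAMSpec", "NetworkSpec", "RMAMNet", "build_network", "default_network_spec"]


@dataclass(frozen=True)
class RMAMSpec:
    """One attention block: kernel size, output width, following pool stride."""

    kernel_size: int
    out_channels: int
    pool: int
    reduction: int = 4

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.out_channels < 1 or self.pool < 1:
            raise ValueError("kernel_size, out_channels and pool must be >= 1")


@dataclass(frozen=True)
class NetworkSpec:
    """Full architecture description (defaults mirror the published table)."""

    in_channels: int = 80
    blocks: tuple[RMAMSpec, ...] = (
        RMAMSpec(12, 128, 4),
        RMAMSpec(6, 256, 4),
        RMAMSpec(3, 256, 2),
        RMAMSpec(3, 256, 2),
    )
    final_conv_kernel: int = 3
    final_conv_channels: int = 256
    final_pool: int = 2
    n_classes: int = 4
    combine: str = "sum"
    activation: str = "sigmoid"
    use_channel_att: bool = True
    use_time_att: bool = True
    use_skip: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocks"] = [asdict(b) for b in self.blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["blocks"] = tuple(RMAMSpec(**b) for b in d.get("blocks", ()))
        return cls(**d)


def default_network_spec() -> NetworkSpec:
    return NetworkSpec()


class RMAMNet(Module):
    """The assembled classifier: returns logits; see :meth:`predict_proba`."""

    def __init__(self, spec: NetworkSpec = NetworkSpec(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        act = Sigmoid if spec.activation == "sigmoid" else ReLU
        layers: list[Module] = []
        channels = spec.in_channels
        for block in spec.blocks:
            layers.append(
                RMAM(
                    channels,
                    block.out_channels,
                    block.kernel_size,
                    reduction=block.reduction,
                    combine=spec.combine,
                    activation=spec.activation,
                    use_channel_att=spec.use_channel_att,
                    use_time_att=spec.use_time_att,
                    use_skip=spec.use_skip,
                    rng=rng,
                )
            )
            layers.append(MaxPool1d(block.pool))
            channels = block.out_channels
        layers.append(
            Sequential(
                Conv1d(channels, spec.final_conv_channels, spec.final_conv_kernel, rng=rng),
                BatchNorm1d(spec.final_conv_channels),
                act(),
            )
        )
        layers.append(MaxPool1d(spec.final_pool))
        self.backbone = Sequential(*layers)
        self.gap = GlobalAvgPool1d()
        self.classifier = Linear(spec.final_conv_channels, spec.n_classes, rng=rng)

    def features(self, x: Tensor) -> Tensor:
        """Global-average-pooled feature vector, shape (B, final_conv_channels)."""
        if x.ndim != 3 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected input of shape (batch, {self.spec.in_channels}, length), "
                f"got {tuple(x.shape)}"
            )
        return self.gap(self.backbone(x))

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.features(x))

    def predict_proba(self, x: Tensor) -> np.ndarray:
        logits = self.forward(x).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def summary(self, input_length: int = 301) -> str:
        """Layer table analogous to the published architecture table."""
        buf = io.StringIO()
        print(f"{'Layer':<6}{'Type':<24}{'Kernel/Channel':<18}{'Stride':<8}Output", file=buf)
        length = input_length
        idx = 1
        for block in self.spec.blocks:
            print(f"{idx:<6}{'RMAM':<24}{f'{block.kernel_size} x 1/{block.out_channels}':<18}"
                  f"{'1':<8}{length} x {block.out_channels}", file=buf)
            idx += 1
            length //= block.pool
            print(f"{idx:<6}{'MaxPooling':<24}{'-':<18}{block.pool:<8}"
                  f"{length} x {block.out_channels}", file=buf)
            idx += 1
        print(f"{idx:<6}{'Convolution':<24}"
              f"{f'{self.spec.final_conv_kernel} x 1/{self.spec.final_conv_channels}':<18}"
              f"{'1':<8}{length} x {self.spec.final_conv_channels}", file=buf)
        idx += 1
        length //= self.spec.final_pool
        print(f"{idx:<6}{'MaxPooling':<24}{'-':<18}{self.spec.final_pool:<8}"
              f"{length} x {self.spec.final_conv_channels}", file=buf)
        idx += 1
        print(f"{idx:<6}{'Global Average Pooling':<24}{'-':<18}{'-':<8}"
              f"{self.spec.final_conv_channels}", file=buf)
        idx += 1
        print(f"{idx:<6}{'Softmax':<24}{'-':<18}{'-':<8}{self.spec.n_classes}", file=buf)
        return buf.getvalue()


def build_network(spec: NetworkSpec = NetworkSpec(),
                  rng: np.random.Generator | None = None) -> RMAMNet:
    return RMAMNet(spec, rng=rng)
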