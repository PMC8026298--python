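"""Encoder-decoder segmentation network with attention skip connections.

Architecture (depth ``d``, base width ``c``):

* encoder — an RFU stage at full resolution, then ``d`` rounds of 2x2 max
  pooling followed by an RFU stage; stage ``k`` has ``c * 2**k`` channels.
* bottleneck — SEPP pyramid on the deepest features, then a 1x1 convolution
  + batch norm reducing the concatenation back to the deepest width.
* decoder — ``d`` SCA fusions pairing the running decoder map with the
  encoder skip of matching resolution, a BN(conv1x1) refinement after the
  first fusion, and a final 1x1 convolution to class logits with a softmax
  over classes.

Depth 4 suits CTA-style axial slices; depth 3 suits retina-style images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .blocks import RFU, SCAFusion, SEPP


@dataclass
class NetworkConfig:
    depth: int = 4
    base_channels: int = 32
    in_channels: int = 1
    n_classes: int = 2
    dilation_rates: tuple = (1, 6, 12, 12)
    se_ratio: int = 16
    attention_budget: int = 4096
    double_rfu: bool = True          # two conv-BN-ReLU units per encoder stage
    se_order: str = "conv_se"

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1 or self.in_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid channel configuration")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilation_rates"] = list(self.dilation_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "dilation_rates" in d:
            d["dilation_rates"] = tuple(d["dilation_rates"])
        return cls(**d)


@dataclass
class SegmentationOutput:
    """Per-pixel class logits and the vessel-class probability map."""
    logits: np.ndarray          # (n_classes, H, W)
    probabilities: np.ndarray   # (H, W), vessel class, in [0, 1]


@dataclass
class ArchitectureRow:
    name: str
    output_shape: tuple
    n_params: int


@dataclass
class ArchitectureTable:
    rows: list = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(r.n_params for r in self.rows)

    def to_tsv(self) -> str:
        lines = ["layer\toutput_shape\tn_params"]
        for r in self.rows:
            lines.append(f"{r.name}\t{'x'.join(map(str, r.output_shape))}\t{r.n_params}")
        lines.append(f"TOTAL\t-\t{self.total_params}")
        return "\n".join(lines)


class EncoderStage(nn.Module):
    def __init__(self, in_channels, out_channels, rng, double):
        super().__init__()
        units = [RFU(in_channels, out_channels, rng)]
        if double:
            units.append(RFU(out_channels, out_channels, rng))
        self.units = units

    def forward(self, x):
        for u in self.units:
            x = u(x)
        return x


class SCANet(nn.Module):
    """The full self- and channel-attention segmentation network."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c, d = config.base_channels, config.depth
        widths = [c * 2 ** k for k in range(d + 1)]

        self.enc_stages = [
            EncoderStage(config.in_channels if k == 0 else widths[k - 1],
                         widths[k], rng, config.double_rfu)
            for k in range(d + 1)
        ]
        deepest = widths[-1]
        self.sepp = SEPP(deepest, deepest // 2, rng,
                         rates=config.dilation_rates, se_ratio=config.se_ratio,
                         se_order=config.se_order)
        self.bottleneck_reduce = nn.Conv2d(self.sepp.out_channels, deepest, 1, rng)
        self.bottleneck_bn = nn.BatchNorm2d(deepest)

        # decoder: fuse deepest-with-skip upward; skip k pairs widths[k]
        self.sca_stages = [
            SCAFusion(widths[k], widths[k + 1], rng,
                      attention_budget=config.attention_budget)
            for k in reversed(range(d))
        ]
        self.refine_conv = nn.Conv2d(widths[d - 1], widths[d - 1], 1, rng)
        self.refine_bn = nn.BatchNorm2d(widths[d - 1])
        self.head = nn.Conv2d(widths[0], config.n_classes, 1, rng, gain=1.0)

    # -- forward -------------------------------------------------------------
    def _check(self, x: Tensor, name: str):
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError(f"non-finite activations after layer {name!r}")
        return x

    def forward(self, x: Tensor, record=None) -> Tensor:
        """Return class logits (N, n_classes, H, W) for a (N, C, H, W) batch."""
        d = self.config.depth
        h, w = x.shape[2], x.shape[3]
        div = 2 ** d
        if h % div or w % div:
            ph, pw = (div - h % div) % div, (div - w % div) % div
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth={div}; pad by "
                f"({ph}, {pw}) pixels (e.g. reflection) and crop the output back")
        skips = []
        for k, stage in enumerate(self.enc_stages):
            if k > 0:
                x = ad.maxpool2x2(x)
            x = self._check(stage(x), f"encoder{k}")
            skips.append(x)
            if record is not None:
                record.append((f"encoder{k} (RFU)", x.shape, _stage_params(stage)))

        x = self._check(self.sepp(x), "sepp")
        if record is not None:
            record.append(("bottleneck (SEPP)", x.shape, _stage_params(self.sepp)))
        x = self._check(self.bottleneck_bn(self.bottleneck_reduce(x)), "bottleneck_reduce")
        if record is not None:
            record.append(("bottleneck reduce (BN Conv1x1)", x.shape,
                           _stage_params(self.bottleneck_reduce) + _stage_params(self.bottleneck_bn)))

        for j, sca in enumerate(self.sca_stages):
            skip = skips[d - 1 - j]
            x = self._check(sca(skip, x), f"sca{j}")
            if record is not None:
                record.append((f"decoder{j} (SCA)", x.shape, _stage_params(sca)))
            if j == 0:
                x = self._check(self.refine_bn(self.refine_conv(x)), "refine")
                if record is not None:
                    record.append(("decoder refine (BN Conv1x1)", x.shape,
                                   _stage_params(self.refine_conv) + _stage_params(self.refine_bn)))

        logits = self._check(self.head(x), "head")
        if record is not None:
            record.append(("head (Conv1x1)", logits.shape, _stage_params(self.head)))
        return logits


def _stage_params(module: nn.Module) -> int:
    return module.n_parameters()


def build_network(config: NetworkConfig, seed: int = 0) -> SCANet:
    """Build a network with deterministic He-normal initialization."""
    return SCANet(config, seed=seed)


def forward(net: SCANet, image: np.ndarray) -> SegmentationOutput:
    """Run one image through the network in inference mode.

    ``image`` is (H, W) or (C, H, W), values in [0, 1]. Returns per-pixel
    logits and the vessel-class probability map.
    """
    arr = np.asarray(image, dtype=nn.DTYPE)
    if arr.ndim == 2:
        arr = arr[None]
    was_training = net.training
    net.eval()
    try:
        with ad.no_grad():
            logits = net(Tensor(arr[None]))
            probs = ad.softmax(logits, axis=1)
    finally:
        net.train(was_training)
    return SegmentationOutput(
        logits=logits.data[0],
        probabilities=probs.data[0, 1].astype(np.float64),
    )


def forward_batch(net: SCANet, images: np.ndarray) -> np.ndarray:
    """Inference-mode vessel probabilities for an (N, C, H, W) batch."""
    was_training = net.training
    net.eval()
    try:
        with ad.no_grad():
            logits = net(Tensor(np.asarray(images, dtype=nn.DTYPE)))
            probs = ad.softmax(logits, axis=1)
    finally:
        net.train(was_training)
    return probs.data[:, 1].astype(np.float64)


def summarize(net: SCANet, input_size=(64, 64)) -> ArchitectureTable:
    """Dry-run the network on a zero image and tabulate layer shapes/params."""
    record = []
    with ad.no_grad():
        was_training = net.training
        net.eval()
        try:
            net(Tensor(np.zeros((1, net.config.in_channels, *input_size), dtype=nn.DTYPE)),
                record=record)
        finally:
            net.train(was_training)
    return ArchitectureTable(
        rows=[ArchitectureRow(name, tuple(shape[1:]), n) for name, shape, n in record])


def save(path, net: SCANet, version: str = "1"):
    nn.save_checkpoint(path, net, config=net.config.to_dict(), version=version)


def load(path) -> SCANet:
    state, header = nn.load_checkpoint(path)
    net = SCANet(NetworkConfig.from_dict(header["config"]))
    net.load_state_dict(state)
    return net
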