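"""Configurable encoder-decoder segmentation network with extended skips.

The architecture family is described entirely by :class:`NetConfig`:

* a VGG-style contracting encoder (per stage: repeated 3x3 conv -> batch norm
  -> ReLU, 2x2 max pool between stages),
* a tail of large-kernel blocks at the deepest resolution to widen the
  receptive field, optionally with separable (kx1 then 1xk) kernels,
* skip connections from every pre-pool encoder stage to the matching decoder
  level, in one of four modes: ``none``, ``fixed`` (identity copy+concat),
  ``single_scale`` (one learned large-kernel branch) or ``multiscale`` (a
  filter bank of learned large-kernel branches),
* an expanding decoder with a constant channel width, finished by a 1x1
  scoring convolution with no activation.

The extended (multiscale) skip concatenates a channel-preserving 1x1 path
with a merged multi-scale branch emitting ``skip_branch_channels`` feature
maps, so its output always has Cin + skip_branch_channels channels.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "NetConfig",
    "ExtendedSkip",
    "Encoder",
    "Decoder",
    "SegmentationNet",
    "build_encoder",
    "build_decoder",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

SKIP_MODES = ("none", "fixed", "single_scale", "multiscale")


@dataclass(frozen=True)
class NetConfig:
    """Declarative description of one network variant."""

    encoder_stages: tuple[tuple[int, int], ...] = ((2, 32), (2, 64), (2, 128), (2, 256))
    tail_blocks: int = 2
    tail_kernel: int = 15
    tail_separable: bool = True
    skip_mode: str = "multiscale"
    single_scale_k: int = 7
    multiscale_kernels: tuple[int, ...] = (7, 11, 15)
    skip_branch_channels: int = 12
    decoder_channels: int = 64
    n_classes: int = 2

    def validate(self):
        if not self.encoder_stages:
            raise ValueError("encoder_stages must be non-empty")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.skip_mode not in SKIP_MODES:
            raise ValueError(f"skip_mode must be one of {SKIP_MODES}")
        kernels = [self.tail_kernel, self.single_scale_k, *self.multiscale_kernels]
        for k in kernels:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")
        if self.skip_mode == "multiscale":
            if self.skip_branch_channels <= 0:
                raise ValueError("skip_branch_channels must be > 0 for multiscale skips")
            if not self.multiscale_kernels:
                raise ValueError("multiscale skips need at least one kernel size")

    @property
    def n_pools(self) -> int:
        return len(self.encoder_stages) - 1

    @property
    def pool_factor(self) -> int:
        return 2**self.n_pools

    def skip_channels(self, cin: int) -> int:
        """Channels a skip connection contributes at an encoder stage of width cin."""
        if self.skip_mode == "none":
            return 0
        if self.skip_mode == "fixed":
            return cin
        return cin + self.skip_branch_channels

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        if "encoder_stages" in d:
            d["encoder_stages"] = tuple(tuple(s) for s in d["encoder_stages"])
        if "multiscale_kernels" in d:
            d["multiscale_kernels"] = tuple(d["multiscale_kernels"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def replace(self, **kwargs) -> "NetConfig":
        return replace(self, **kwargs)


def _conv_bn_relu(cin, cout, kernel, rng, separable=False):
    conv = (
        nn.SeparableConv2d(cin, cout, kernel, rng)
        if separable
        else nn.Conv2d(cin, cout, kernel, rng)
    )
    return nn.Sequential([conv, nn.BatchNorm2d(cout), nn.ReLU()])


class Encoder(nn.Module):
    """Contracting path: VGG-style stages plus a large-kernel tail."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.stages = nn.ModuleList()
        cin = 3
        for n_convs, cout in config.encoder_stages:
            blocks = []
            for _ in range(n_convs):
                blocks.append(_conv_bn_relu(cin, cout, 3, rng))
                cin = cout
            self.stages.append(nn.Sequential(blocks))
        self.pool = nn.MaxPool2()
        self.tail = nn.Sequential(
            [
                _conv_bn_relu(cin, cin, config.tail_kernel, rng, separable=config.tail_separable)
                for _ in range(config.tail_blocks)
            ]
        )
        self.out_channels = cin

    def forward(self, x: Tensor):
        """Returns (per-stage pre-pool features, tail output)."""
        _, _, h, w = x.shape
        f = self.config.pool_factor
        if h % f or w % f:
            raise ValueError(
                f"input spatial size ({h}, {w}) must be divisible by {f} "
                f"(one 2x2 pool per encoder stage transition)"
            )
        features = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            features.append(x)
            if i < len(self.stages) - 1:
                x = self.pool(x)
        return features, self.tail(x)


class ExtendedSkip(nn.Module):
    """Learned skip: 1x1 channel-preserving path || summed multi-scale bank.

    Each branch is a separable large-kernel convolution emitting
    ``branch_channels`` maps; branches are merged by element-wise sum so the
    module output has cin + branch_channels channels regardless of how many
    scales are configured.
    """

    def __init__(self, cin: int, kernels, branch_channels: int, rng: np.random.Generator):
        super().__init__()
        self.pointwise = nn.Conv2d(cin, cin, 1, rng)
        self.branches = nn.ModuleList(
            [nn.SeparableConv2d(cin, branch_channels, k, rng) for k in kernels]
        )

    def forward(self, x: Tensor) -> Tensor:
        merged = None
        for branch in self.branches:
            out = branch(x)
            merged = out if merged is None else nn.functional.add(merged, out)
        return nn.functional.concat([self.pointwise(x), merged], axis=1)


class _Identity(nn.Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def _make_skip(config: NetConfig, cin: int, rng) -> nn.Module | None:
    if config.skip_mode == "none":
        return None
    if config.skip_mode == "fixed":
        return _Identity()
    kernels = (
        [config.single_scale_k]
        if config.skip_mode == "single_scale"
        else config.multiscale_kernels
    )
    return ExtendedSkip(cin, kernels, config.skip_branch_channels, rng)


class Decoder(nn.Module):
    """Expanding path: per level 2x up-sample, concat skip features, convs."""

    def __init__(self, config: NetConfig, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.upsample = nn.Upsample2()
        self.levels = nn.ModuleList()
        cin = in_channels
        # decoder levels pair with encoder stages n-2 .. 0
        for n_convs, stage_channels in reversed(config.encoder_stages[:-1]):
            cat = cin + config.skip_channels(stage_channels)
            blocks = []
            c = cat
            for _ in range(max(n_convs, 1)):
                blocks.append(_conv_bn_relu(c, config.decoder_channels, 3, rng))
                c = config.decoder_channels
            self.levels.append(nn.Sequential(blocks))
            cin = config.decoder_channels
        self.head = nn.Conv2d(cin, config.n_classes, 1, rng)

    def forward(self, x: Tensor, skips: list[Tensor | None]) -> Tensor:
        if len(skips) != len(self.levels):
            raise ValueError(
                f"decoder expects {len(self.levels)} skip entries, got {len(skips)}"
            )
        for level, skip in zip(self.levels, skips):
            x = self.upsample(x)
            if self.config.skip_mode != "none":
                if skip is None:
                    raise ValueError("skip features missing for a decoder level")
                x = nn.functional.concat([skip, x], axis=1)
            x = level(x)
        return self.head(x)


class SegmentationNet(nn.Module):
    """Full encoder-decoder with per-level skip modules; outputs class scores."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.encoder = Encoder(config, rng)
        self.skips = nn.ModuleList()
        for _, stage_channels in config.encoder_stages[:-1]:
            skip = _make_skip(config, stage_channels, rng)
            self.skips.append(skip if skip is not None else _Identity())
        self.decoder = Decoder(config, self.encoder.out_channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        features, deep = self.encoder(x)
        if self.config.skip_mode == "none":
            skips = [None] * (len(features) - 1)
        else:
            # deepest-first order to match decoder levels
            skips = [
                skip(feat) for skip, feat in zip(self.skips, features[:-1])
            ][::-1]
        return self.decoder(deep, skips)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Argmax class map for a batch of (N, 3, H, W) float images; eval mode."""
        was_training = self.training
        self.eval()
        scores = self.forward(Tensor(images))
        if was_training:
            self.train()
        return np.argmax(scores.data, axis=1)


def build_encoder(config: NetConfig, rng: np.random.Generator | int = 0) -> Encoder:
    return Encoder(config, _as_rng(rng))


def build_decoder(config: NetConfig, in_channels: int | None = None, rng: np.random.Generator | int = 0) -> Decoder:
    if in_channels is None:
        in_channels = config.encoder_stages[-1][1]
    return Decoder(config, in_channels, _as_rng(rng))


def build_model(config: NetConfig, rng: np.random.Generator | int = 0) -> SegmentationNet:
    return SegmentationNet(config, _as_rng(rng))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def count_parameters(model: nn.Module) -> int:
    """Exact number of trainable scalar weights."""
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: SegmentationNet, path):
    """Self-describing checkpoint: weights + embedded NetConfig (npz)."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    buf = io.BytesIO()
    np.savez(buf, **state)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path, rng: np.random.Generator | int = 0) -> SegmentationNet:
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    config = NetConfig.from_dict(json.loads(bytes(state.pop("__config__")).decode()))
    model = build_model(config, rng)
    model.load_state_dict(state)
    return model
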