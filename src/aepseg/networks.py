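"""Lightweight encoder-decoder networks.

Both networks share a U-Net-style trunk that is deliberately lighter than
the original U-Net: each encoder layer is a single convolution followed by
batch normalization, ReLU and dropout; the encoder is one input layer plus
six encoder layers (three blocks of two, the first layer of each block
downsampling by a stride-2 convolution), and the decoder is six decoder
layers (three blocks of a stride-2 transposed-convolution layer followed by
a convolution layer), with skip connections concatenated at each resolution.

The first network carries two output convolutions: the first emits the
penultimate feature maps used as translation filters (m*C channels), the
second maps them to the C class logits.  The second network carries a single
output convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    Module,
    ReLU,
    Sequential,
)

__all__ = [
    "NetworkConfig",
    "FirstNetwork",
    "SecondNetwork",
    "build_first_network",
    "build_second_network",
    "softmax",
]


@dataclass
class NetworkConfig:
    in_channels: int = 1
    num_classes: int = 3
    filter_multiplier: int = 1
    base_channels: int = 64
    dropout_rate: float = 0.2
    depth: int = 3  # number of downsampling blocks; 3 -> six encoder layers
    dtype: str = "float32"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.num_classes < 2:
            raise ValueError("need in_channels >= 1 and num_classes >= 2")
        if self.filter_multiplier < 1:
            raise ValueError("filter_multiplier must be >= 1")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def filter_channels(self) -> int:
        return self.filter_multiplier * self.num_classes

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "num_classes": self.num_classes,
            "filter_multiplier": self.filter_multiplier,
            "base_channels": self.base_channels,
            "dropout_rate": self.dropout_rate,
            "depth": self.depth,
            "dtype": self.dtype,
            "init_seed": self.init_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


def _encoder_layer(
    in_ch: int, out_ch: int, stride: int, cfg: NetworkConfig, rng, drop_rng
) -> Sequential:
    return Sequential(
        Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng, dtype=cfg.np_dtype),
        BatchNorm2d(out_ch, dtype=cfg.np_dtype),
        ReLU(),
        Dropout(cfg.dropout_rate, drop_rng),
    )


def _deconv_layer(in_ch: int, out_ch: int, cfg: NetworkConfig, rng, drop_rng) -> Sequential:
    return Sequential(
        ConvTranspose2d(in_ch, out_ch, rng=rng, dtype=cfg.np_dtype),
        BatchNorm2d(out_ch, dtype=cfg.np_dtype),
        ReLU(),
        Dropout(cfg.dropout_rate, drop_rng),
    )


class UNetTrunk(Module):
    """Shared encoder-decoder trunk; forward returns base-width features."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator, drop_rng: np.random.Generator):
        b = cfg.base_channels
        self.cfg = cfg
        self.input_layer = _encoder_layer(cfg.in_channels, b, 1, cfg, rng, drop_rng)
        self.enc_blocks: list[Sequential] = []
        ch = b
        for _ in range(cfg.depth):
            blk = Sequential(
                *_encoder_layer(ch, 2 * ch, 2, cfg, rng, drop_rng).modules,
                *_encoder_layer(2 * ch, 2 * ch, 1, cfg, rng, drop_rng).modules,
            )
            self.enc_blocks.append(blk)
            ch *= 2
        self.dec_up: list[Sequential] = []
        self.dec_conv: list[Sequential] = []
        for _ in range(cfg.depth):
            self.dec_up.append(_deconv_layer(ch, ch // 2, cfg, rng, drop_rng))
            # input doubles after skip concatenation
            self.dec_conv.append(_encoder_layer(ch, ch // 2, 1, cfg, rng, drop_rng))
            ch //= 2
        self.out_channels = ch  # == base_channels
        self._skip_channels: list[int] = []

    @property
    def encoder_layer_count(self) -> int:
        return 2 * self.cfg.depth

    @property
    def decoder_layer_count(self) -> int:
        return 2 * self.cfg.depth

    def check_spatial(self, h: int, w: int) -> None:
        d = 2**self.cfg.depth
        if h % d or w % d:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by {d}; pad the image to "
                f"a multiple of {d} (e.g. {-(-h // d) * d}x{-(-w // d) * d})"
            )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self.check_spatial(x.shape[2], x.shape[3])
        skips = []
        h = self.input_layer.forward(x, training)
        skips.append(h)
        for blk in self.enc_blocks:
            h = blk.forward(h, training)
            skips.append(h)
        h = skips.pop()  # bottom features
        self._skip_channels = []
        for up, conv in zip(self.dec_up, self.dec_conv):
            s = skips.pop()
            u = up.forward(h, training)
            if u.shape[2:] != s.shape[2:]:  # pragma: no cover - guarded by check_spatial
                raise ValueError("skip/upsample spatial mismatch")
            self._skip_channels.append(u.shape[1])
            h = conv.forward(np.concatenate([u, s], axis=1), training)
        return h

    def backward(self, gout: np.ndarray) -> np.ndarray:
        # mirror of forward: walk decoder blocks in reverse, routing the skip
        # half of each concat gradient back into the matching encoder stage
        skip_grads: list[np.ndarray] = []
        g = gout
        for up, conv, uch in zip(
            reversed(self.dec_up), reversed(self.dec_conv), reversed(self._skip_channels)
        ):
            gcat = conv.backward(g)
            gu, gs = gcat[:, :uch], gcat[:, uch:]
            skip_grads.append(gs)
            g = up.backward(gu)
        # g now holds the gradient at the bottom encoder output; skip_grads is
        # ordered shallowest-first: [input_layer, block1, ..., block(depth-1)]
        for blk in reversed(self.enc_blocks):
            g = blk.backward(g)
            g = g + skip_grads.pop()
        return self.input_layer.backward(g)


class FirstNetwork(Module):
    """Dual-head network: translation-filter preactivations + class logits."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.init_seed)
        self.drop_rng = np.random.default_rng(np.random.SeedSequence(cfg.init_seed).spawn(1)[0])
        self.cfg = cfg
        self.trunk = UNetTrunk(cfg, rng, self.drop_rng)
        self.out_conv_filters = Conv2d(
            cfg.base_channels, cfg.filter_channels, 3, rng=rng, dtype=cfg.np_dtype
        )
        self.out_conv_logits = Conv2d(
            cfg.filter_channels, cfg.num_classes, 3, rng=rng, dtype=cfg.np_dtype
        )

    @property
    def output_conv_count(self) -> int:
        return 2

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, np.ndarray]:
        feat = self.trunk.forward(x, training)
        preact = self.out_conv_filters.forward(feat, training)
        logits = self.out_conv_logits.forward(preact, training)
        return preact, logits

    def backward(self, g_preact: np.ndarray, g_logits: np.ndarray) -> np.ndarray:
        g = self.out_conv_logits.backward(g_logits) + g_preact
        g = self.out_conv_filters.backward(g)
        return self.trunk.backward(g)

    def param_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


class SecondNetwork(Module):
    """Single-head segmentation network sharing the trunk design."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.init_seed + 1)
        self.drop_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.init_seed + 1).spawn(1)[0]
        )
        self.cfg = cfg
        self.trunk = UNetTrunk(cfg, rng, self.drop_rng)
        self.out_conv = Conv2d(cfg.base_channels, cfg.num_classes, 3, rng=rng, dtype=cfg.np_dtype)

    @property
    def output_conv_count(self) -> int:
        return 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.out_conv.forward(self.trunk.forward(x, training), training)

    def backward(self, g_logits: np.ndarray) -> np.ndarray:
        return self.trunk.backward(self.out_conv.backward(g_logits))

    def param_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_first_network(cfg: NetworkConfig) -> FirstNetwork:
    return FirstNetwork(cfg)


def build_second_network(cfg: NetworkConfig) -> SecondNetwork:
    return SecondNetwork(cfg)


def softmax(logits: np.ndarray, axis: int = -3) -> np.ndarray:
    """Numerically stabilized softmax over the class axis.

    The default axis -3 is the class axis both for a single (C, H, W) map and
    for a batched (B, C, H, W) array.
    """
    logits = np.asarray(logits)
    if not np.isfinite(logits).all():
        raise ValueError("softmax requires finite logits")
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def describe_network(net: FirstNetwork | SecondNetwork) -> dict:
    """Layer-count and parameter summary (CLI `inspect-model`)."""
    return {
        "kind": type(net).__name__,
        "input_layers": 1,
        "encoder_layers": net.trunk.encoder_layer_count,
        "decoder_layers": net.trunk.decoder_layer_count,
        "output_convs": net.output_conv_count,
        "parameters": net.param_count(),
        "config": net.cfg.to_dict(),
    }
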