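"""Six-layer hierarchical transformer encoder.

Each encoder layer downsamples with an overlapping patch-merging
convolution (kernel larger than stride), then applies two repetitions of
a self-attention block and a Mix-FFN block.  The Mix-FFN embeds a 3×3
convolution in the feed-forward path, which injects local positional
cues, so the encoder carries no explicit positional-encoding parameters.
Layer *i* produces a feature map at 1/2^(i+1) of the input resolution
(scales 1/4, 1/8, …, 1/128); non-integer divisions resolve by ceiling via
padded convolutions, so every layer stays non-empty down to 1×1.

Self-attention cost is kept linear-ish by spatially reducing the key/value
token set with a strided convolution (per-layer reduction ratios are
config).  Channel depths, head counts and reduction ratios are not fixed
by the architecture; the ``tiny`` preset runs a 112×112 forward pass in
well under a second on one CPU, the ``base`` preset is a GPU-scale
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigError, DimensionError
from .nn import Tensor

__all__ = ["EncoderConfig", "FeaturePyramid", "OverlapPatchMerge",
           "AttentionBlock", "MixFFN", "MiTEncoder"]

N_LAYERS = 6
# merge stride per layer realises the 1/4, 1/8, ..., 1/128 ladder
LAYER_STRIDES = (4, 2, 2, 2, 2, 2)
LAYER_KERNELS = (7, 3, 3, 3, 3, 3)


@dataclass(frozen=True)
class EncoderConfig:
    channels: tuple[int, ...] = (8, 16, 24, 32, 40, 48)
    heads: tuple[int, ...] = (1, 1, 2, 2, 4, 4)
    reduction: tuple[int, ...] = (8, 4, 2, 1, 1, 1)
    blocks_per_layer: int = 2
    ffn_expansion: int = 4

    def validate(self):
        for name in ("channels", "heads", "reduction"):
            if len(getattr(self, name)) != N_LAYERS:
                raise ConfigError(f"encoder.{name} needs {N_LAYERS} entries")
        if any(c <= 0 for c in self.channels):
            raise ConfigError("encoder channel depths must be positive")
        for c, h in zip(self.channels, self.heads):
            if c % h != 0:
                raise ConfigError(f"channels {c} not divisible by heads {h}")

    @classmethod
    def tiny(cls) -> "EncoderConfig":
        return cls()

    @classmethod
    def base(cls) -> "EncoderConfig":
        return cls(channels=(64, 128, 192, 256, 288, 320),
                   heads=(1, 2, 4, 8, 8, 8))


@dataclass
class FeaturePyramid:
    """Six per-layer feature rasters, channels-last ``(Hi, Wi, Ci)``."""

    maps: list[np.ndarray] = field(default_factory=list)

    def __getitem__(self, layer: int) -> np.ndarray:
        """1-based layer access matching the architectural numbering."""
        if not 1 <= layer <= N_LAYERS:
            raise ConfigError(f"layer index must be 1..{N_LAYERS}, got {layer}")
        return self.maps[layer - 1]

    @property
    def shapes(self) -> list[tuple[int, int, int]]:
        return [m.shape for m in self.maps]


def pyramid_shape(h: int, w: int, layer: int) -> tuple[int, int]:
    """Spatial size of layer ``layer`` (1-based): repeated ceiling division."""
    for s in LAYER_STRIDES[:layer]:
        h = math.ceil(h / s)
        w = math.ceil(w / s)
    return h, w


class OverlapPatchMerge(nn.Module):
    """Strided convolution with kernel > stride: downsample while keeping
    neighbouring patches overlapping.  Symmetric padding gives ceiling
    division of the spatial dims."""

    def __init__(self, c_in: int, c_out: int, stride: int, kernel: int,
                 rng: np.random.Generator):
        if stride not in (2, 4):
            raise ConfigError(f"merge stride must be 2 or 4, got {stride}")
        self.conv = nn.Conv2d(c_in, c_out, kernel, stride=stride,
                              padding=kernel // 2, rng=rng)
        self.norm = nn.LayerNorm(c_out)
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        y = self.conv(x)
        # kernel 2p+stride-ish with symmetric padding: strided conv output
        # floor((H+2p-k)/s)+1 equals ceil(H/s) for these kernel/pad pairs
        assert y.shape[2:] == (math.ceil(H / self.stride), math.ceil(W / self.stride))
        return _norm_cl(y, self.norm)


def _norm_cl(x: Tensor, norm: nn.LayerNorm) -> Tensor:
    """Apply a channel LayerNorm to an NCHW tensor."""
    B, C, H, W = x.shape
    t = x.reshape(B, C, H * W).transpose(0, 2, 1)
    t = norm(t)
    return t.transpose(0, 2, 1).reshape(B, C, H, W)


class AttentionBlock(nn.Module):
    """Pre-norm multi-head self-attention over the spatial token grid.

    Keys/values may come from a spatially reduced token set (strided
    convolution by ``reduction``); attention weights per query are a
    softmax, i.e. non-negative and summing to one.  Output is input plus
    the attention residual.
    """

    def __init__(self, channels: int, heads: int, reduction: int,
                 rng: np.random.Generator):
        if channels % heads != 0:
            raise ConfigError(f"channels {channels} not divisible by heads {heads}")
        self.heads = heads
        self.reduction = reduction
        self.norm = nn.LayerNorm(channels)
        self.q = nn.Linear(channels, channels, rng)
        self.k = nn.Linear(channels, channels, rng)
        self.v = nn.Linear(channels, channels, rng)
        self.proj = nn.Linear(channels, channels, rng)
        if reduction > 1:
            self.sr = nn.Conv2d(channels, channels, reduction, stride=reduction,
                                rng=rng)
            self.sr_norm = nn.LayerNorm(channels)
        else:
            self.sr = None

    def _weights_and_values(self, x: Tensor):
        B, C, H, W = x.shape
        h = self.heads
        d = C // h
        tokens = x.reshape(B, C, H * W).transpose(0, 2, 1)     # (B, N, C)
        tn = self.norm(tokens)
        q = self.q(tn)                                         # (B, N, C)
        if self.sr is not None:
            sp = tn.transpose(0, 2, 1).reshape(B, C, H, W)
            # pad so the reduction conv tiles the map exactly
            r = self.reduction
            ph, pw = (-H) % r, (-W) % r
            if ph or pw:
                src = sp
                sp = Tensor(np.pad(sp.data, ((0, 0), (0, 0), (0, ph), (0, pw))),
                            _parents=(sp,))
                sp._backward = lambda g, src=src: src._accum(g[:, :, :H, :W])
            red = self.sr(sp)
            Hr, Wr = red.shape[2:]
            kv = self.sr_norm(red.reshape(B, C, Hr * Wr).transpose(0, 2, 1))
        else:
            kv = tn
        k = self.k(kv)
        v = self.v(kv)
        N, M = q.shape[1], k.shape[1]

        def split(t, n):
            return t.reshape(B, n, h, d).transpose(0, 2, 1, 3)  # (B, h, n, d)

        attn = (split(q, N) @ split(k, M).transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(d))
        attn = attn.softmax(axis=-1)
        return tokens, attn, split(v, M)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        tokens, attn, v = self._weights_and_values(x)
        out = attn @ v                                          # (B, h, N, d)
        out = out.transpose(0, 2, 1, 3).reshape(B, tokens.shape[1], C)
        out = self.proj(out)
        y = tokens + out
        return y.transpose(0, 2, 1).reshape(B, C, H, W)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """The (B, heads, N, M) attention weights for inspection/tests."""
        return self._weights_and_values(x)[1].data


class MixFFN(nn.Module):
    """Feed-forward block with an embedded 3×3 convolution.

    expansion 1×1 → 3×3 convolution → GELU → contraction 1×1, wrapped in a
    pre-norm residual.  The 3×3 kernel is what carries positional/local
    information through the encoder.
    """

    def __init__(self, channels: int, expansion: int, rng: np.random.Generator):
        hidden = channels * expansion
        self.norm = nn.LayerNorm(channels)
        self.expand = nn.Conv2d(channels, hidden, 1, rng=rng)
        self.dw = nn.Conv2d(hidden, hidden, 3, padding=1, rng=rng)
        self.contract = nn.Conv2d(hidden, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = _norm_cl(x, self.norm)
        y = self.expand(y)
        y = self.dw(y).gelu()
        y = self.contract(y)
        return x + y


class MiTEncoder(nn.Module):
    """The full six-layer hierarchical encoder."""

    def __init__(self, config: EncoderConfig | None = None, seed: int = 0):
        config = config or EncoderConfig.tiny()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers = []
        c_prev = 3
        for i in range(N_LAYERS):
            merge = OverlapPatchMerge(c_prev, config.channels[i],
                                      LAYER_STRIDES[i], LAYER_KERNELS[i], rng)
            blocks = []
            for _ in range(config.blocks_per_layer):
                blocks.append(AttentionBlock(config.channels[i], config.heads[i],
                                             config.reduction[i], rng))
                blocks.append(MixFFN(config.channels[i], config.ffn_expansion, rng))
            self.layers.append({"merge": merge, "blocks": blocks})
            c_prev = config.channels[i]

    def forward(self, x: Tensor) -> list[Tensor]:
        """NCHW float input → list of six NCHW feature tensors."""
        B, C, H, W = x.shape
        if H < 2 or W < 2:
            raise DimensionError(f"input {H}×{W} too small to encode")
        feats = []
        for layer in self.layers:
            x = layer["merge"](x)
            for block in layer["blocks"]:
                x = block(x)
            feats.append(x)
        return feats

    def encode(self, image: np.ndarray, mean: np.ndarray | None = None,
               std: np.ndarray | None = None) -> FeaturePyramid:
        """Convenience single-image forward: uint8 HWC in, pyramid out."""
        x = normalize_image(image, mean, std)[None]
        feats = self.forward(Tensor(x))
        return FeaturePyramid(
            maps=[f.data[0].transpose(1, 2, 0) for f in feats])


def normalize_image(image: np.ndarray, mean: np.ndarray | None = None,
                    std: np.ndarray | None = None) -> np.ndarray:
    """uint8 (H, W, 3) → normalized float32 (3, H, W)."""
    img = np.asarray(image, dtype=np.float32) / 255.0
    mean = np.array([0.5, 0.5, 0.5], np.float32) if mean is None else np.asarray(mean, np.float32)
    std = np.array([0.25, 0.25, 0.25], np.float32) if std is None else np.asarray(std, np.float32)
    img = (img - mean) / std
    return img.transpose(2, 0, 1)
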