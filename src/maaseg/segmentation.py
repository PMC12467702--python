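"""Segmentation stage: pyramid-pooling network trained on pseudo-labels
with online easy example mining (OEEM).

Pseudo-labels carry noise, concentrated at gland boundaries.  OEEM
re-weights the per-pixel cross-entropy so reliable (low-loss) pixels
dominate: w = softmax(−L) / mean(softmax(−L)) over the valid pixels of an
image, which has unit mean by construction and is treated as a constant
during backpropagation.  When a pseudo-label map contains a single class
the plain mean cross-entropy is used instead.  Pixels labelled 255
(uncertain) are excluded from the loss entirely.

The network is a small residual CNN with a pyramid pooling module
(average pooling to 1×1, 2×2, 3×3 and 6×6 grids, projected and
upsampled back, concatenated before the classifier), emitting two-class
logits at input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .encoder import normalize_image
from .errors import ConfigError, DimensionError, UndefinedLossError
from .nn import Tensor

__all__ = ["SegConfig", "PSPSegNet", "pixel_ce", "oeem_weights",
           "normalized_loss", "train_seg_stage", "predict_mask"]

IGNORE = 255
LOSS_CLAMP = 50.0
PPM_BINS = (1, 2, 3, 6)


@dataclass
class SegConfig:
    lr: float = 0.0005
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 32
    iterations: int = 10_000
    width: int = 32
    ppm_dim: int = 8
    oeem: bool = True
    oeem_scope: str = "image"     # "image" (default) or "batch"
    oeem_warmup: int = 100        # plain-CE iterations before mining starts
    max_grad_norm: float = 5.0
    flip_p: float = 0.5
    crop_ratio: tuple[float, float] = (1.0, 1.0)  # flips only by default
    seed: int = 0
    log_every: int = 50


def _norm_chw(x: Tensor, norm: nn.LayerNorm) -> Tensor:
    """Channel LayerNorm applied at every spatial position of NCHW."""
    B, C, H, W = x.shape
    t = x.reshape(B, C, H * W).transpose(0, 2, 1)
    return norm(t).transpose(0, 2, 1).reshape(B, C, H, W)


class _ResBlock(nn.Module):
    def __init__(self, c: int, rng):
        self.c1 = nn.Conv2d(c, c, 3, padding=1, rng=rng)
        self.n1 = nn.LayerNorm(c)
        self.c2 = nn.Conv2d(c, c, 3, padding=1, rng=rng)
        self.n2 = nn.LayerNorm(c)

    def forward(self, x: Tensor) -> Tensor:
        y = _norm_chw(self.c1(x), self.n1).relu()
        y = _norm_chw(self.c2(y), self.n2)
        return (x + y).relu()


class PSPSegNet(nn.Module):
    """Residual stem at 1/4 scale + pyramid pooling + 1×1 classifier,
    bilinearly upsampled back to input resolution.  Channel LayerNorms
    keep from-scratch SGD training stable at practical learning rates."""

    def __init__(self, config: SegConfig | None = None, n_classes: int = 2):
        config = config or SegConfig()
        rng = np.random.default_rng(config.seed)
        w = config.width
        self.stem1 = nn.Conv2d(3, w // 2, 3, stride=2, padding=1, rng=rng)
        self.sn1 = nn.LayerNorm(w // 2)
        self.stem2 = nn.Conv2d(w // 2, w, 3, stride=2, padding=1, rng=rng)
        self.sn2 = nn.LayerNorm(w)
        self.res = [_ResBlock(w, rng), _ResBlock(w, rng)]
        self.ppm = [nn.Conv2d(w, config.ppm_dim, 1, rng=rng) for _ in PPM_BINS]
        cat_dim = w + config.ppm_dim * len(PPM_BINS)
        self.fuse = nn.Conv2d(cat_dim, w, 3, padding=1, rng=rng)
        self.fn = nn.LayerNorm(w)
        self.classify = nn.Conv2d(w, n_classes, 1, rng=rng)
        self.config = config

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        y = _norm_chw(self.stem1(x), self.sn1).relu()
        y = _norm_chw(self.stem2(y), self.sn2).relu()
        for block in self.res:
            y = block(y)
        hw = y.shape[2:]
        pooled = [y]
        for conv, b in zip(self.ppm, PPM_BINS):
            p = conv(nn.adaptive_avg_pool2d(y, (b, b))).relu()
            pooled.append(nn.bilinear_resize(p, hw))
        y = nn.concat(pooled, axis=1)
        y = _norm_chw(self.fuse(y), self.fn).relu()
        logits = self.classify(y)
        return nn.bilinear_resize(logits, (H, W))

    def save(self, path: str | Path):
        np.savez(path, __version__=np.array([1]),
                 __mean__=self.mean, __std__=self.std, **self.state_dict())

    @classmethod
    def load(cls, path: str | Path, config: SegConfig | None = None) -> "PSPSegNet":
        blob = np.load(path)
        if int(blob["__version__"][0]) != 1:
            raise ConfigError(f"unsupported checkpoint version in {path}")
        model = cls(config)
        model.mean = blob["__mean__"]
        model.std = blob["__std__"]
        model.load_state_dict(
            {k: blob[k] for k in blob.files if not k.startswith("__")})
        return model

    mean = np.array([0.5, 0.5, 0.5], np.float32)
    std = np.array([0.25, 0.25, 0.25], np.float32)


def pixel_ce(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Per-pixel cross-entropy −log softmax(logits)[label] over valid
    (non-255) pixels, returned as a flat tensor of length n_valid.

    ``logits``: (B, K, H, W) or (K, H, W); ``mask``: matching {0..K−1, 255}.
    """
    if logits.ndim == 3:
        logits = logits.reshape(1, *logits.shape)
        mask = np.asarray(mask)[None]
    B, K, H, W = logits.shape
    mask = np.asarray(mask)
    if mask.shape != (B, H, W):
        raise DimensionError(f"mask shape {mask.shape} != {(B, H, W)}")
    flat_mask = mask.reshape(-1)
    valid = flat_mask != IGNORE
    if not valid.any():
        raise UndefinedLossError("all pixels are ignore-labelled")
    flat = logits.transpose(0, 2, 3, 1).reshape(B * H * W, K)
    sel = flat.take(np.flatnonzero(valid))
    lsm = sel.log_softmax(axis=-1)
    onehot = np.zeros((int(valid.sum()), K), dtype=lsm.data.dtype)
    onehot[np.arange(onehot.shape[0]), flat_mask[valid].astype(int)] = 1.0
    return -(lsm * Tensor(onehot)).sum(axis=-1)


def oeem_weights(loss_map: Tensor | np.ndarray) -> np.ndarray:
    """Unit-mean pixel weights w = softmax(−L) / mean(softmax(−L)).

    Detached from the graph: the weights re-scale supervision, they are
    not themselves optimised.  Losses are clamped at 50 before the
    softmax so extreme outliers cannot underflow every weight to zero.
    """
    losses = loss_map.data if isinstance(loss_map, Tensor) else np.asarray(loss_map)
    if losses.size == 0:
        raise UndefinedLossError("weight map needs at least one valid pixel")
    z = -np.clip(losses.astype(np.float64), 0.0, LOSS_CLAMP)
    z -= z.max()
    s = np.exp(z)
    s /= s.sum()
    return s / s.mean()


def normalized_loss(logits: Tensor, mask: np.ndarray,
                    oeem: bool = True) -> Tensor:
    """OEEM-normalised segmentation loss for one image.

    With more than one distinct class among the valid pixels, returns the
    mean of w·CE with the unit-mean OEEM weights; with a single class (or
    ``oeem=False``) returns the plain mean cross-entropy.
    """
    mask = np.asarray(mask)
    losses = pixel_ce(logits, mask)
    classes = np.unique(mask[mask != IGNORE])
    if not oeem or len(classes) <= 1:
        return losses.mean()
    w = oeem_weights(losses).astype(losses.data.dtype)
    return (losses * Tensor(w)).mean()


def _nearest_resize_mask(mask: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize for a label raster ({0,1,255} preserved)."""
    H, W = mask.shape
    Ho, Wo = out_hw
    ys = np.minimum((np.arange(Ho) + 0.5) * H / Ho, H - 1).astype(int)
    xs = np.minimum((np.arange(Wo) + 0.5) * W / Wo, W - 1).astype(int)
    return mask[ys[:, None], xs[None, :]]


def _augment_pair(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                  flip_p: float, crop_ratio: tuple[float, float]):
    """Joint flips and random crop of an image/label pair, resized back.

    Random cropping is essential with noisy pseudo-labels: it breaks the
    absolute-position shortcut by which a high-capacity network can
    memorise each patch's label layout instead of learning an
    appearance rule.  Labels are resized nearest-neighbour so
    {0, 1, 255} survive exactly.
    """
    if rng.random() < flip_p:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < flip_p:
        img, mask = img[::-1, :], mask[::-1, :]
    h, w = img.shape[:2]
    ratio = rng.uniform(*crop_ratio)
    ch, cw = max(1, round(h * ratio)), max(1, round(w * ratio))
    if (ch, cw) != (h, w):
        y0 = rng.integers(0, h - ch + 1)
        x0 = rng.integers(0, w - cw + 1)
        img = np.clip(np.rint(nn.bilinear_resize_np(
            img[y0:y0 + ch, x0:x0 + cw], (h, w))), 0, 255).astype(np.uint8)
        mask = _nearest_resize_mask(mask[y0:y0 + ch, x0:x0 + cw], (h, w))
    return np.ascontiguousarray(img), np.ascontiguousarray(mask)


def _batch_loss(logits: Tensor, masks: np.ndarray, config: SegConfig,
                oeem_active: bool | None = None) -> Tensor:
    oeem = config.oeem if oeem_active is None else (config.oeem and oeem_active)
    if config.oeem_scope == "batch":
        # single softmax over every valid pixel of the batch
        return normalized_loss(logits, masks, oeem=oeem)
    per_image = [normalized_loss(logits.take(np.array([i])), masks[i:i + 1],
                                 oeem=oeem)
                 for i in range(masks.shape[0])
                 if (masks[i] != IGNORE).any()]
    if not per_image:
        raise UndefinedLossError("no image in the batch has valid pixels")
    total = per_image[0]
    for t in per_image[1:]:
        total = total + t
    return total * (1.0 / len(per_image))


def train_seg_stage(images: list[np.ndarray], pseudo_masks: list[np.ndarray],
                    config: SegConfig | None = None,
                    model: PSPSegNet | None = None):
    """Train the segmentation network on pseudo-labelled patches.

    ``images``: (H, W, 3) uint8 patches; ``pseudo_masks``: matching
    {0, 1, 255} rasters.  SGD at a fixed learning rate; logs the loss
    trace.  Returns ``(model, log)``.
    """
    config = config or SegConfig()
    if len(images) == 0:
        raise ConfigError("empty pseudo-label manifest")
    if len(images) != len(pseudo_masks):
        raise ConfigError("images and pseudo masks differ in length")
    # drop patches whose pseudo-label map is entirely uncertain
    keep = [i for i, m in enumerate(pseudo_masks) if (np.asarray(m) != IGNORE).any()]
    if not keep:
        raise ConfigError("every pseudo-label map is fully ignore-labelled")
    images = [images[i] for i in keep]
    pseudo_masks = [pseudo_masks[i] for i in keep]
    if model is None:
        model = PSPSegNet(config)
    stack = np.stack(images).astype(np.float32) / 255.0
    model.mean = stack.mean(axis=(0, 1, 2))
    model.std = np.maximum(stack.std(axis=(0, 1, 2)), 1e-3)

    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay,
                 max_grad_norm=config.max_grad_norm)
    n = len(images)
    log = {"loss": []}
    for it in range(config.iterations):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        batch, masks = [], []
        for i in idx:
            img, m = _augment_pair(images[i], pseudo_masks[i], rng,
                                   config.flip_p, config.crop_ratio)
            batch.append(normalize_image(img, model.mean, model.std))
            masks.append(m)
        x = Tensor(np.stack(batch))
        logits = model(x)
        loss = _batch_loss(logits, np.stack(masks), config,
                           oeem_active=it >= config.oeem_warmup)
        opt.zero_grad()
        loss.backward()
        opt.step()
        log["loss"].append(float(loss.data))
    return model, log


def predict_mask(model: PSPSegNet, image: np.ndarray) -> np.ndarray:
    """Argmax class mask (uint8 {0,1}) for one image patch."""
    x = Tensor(normalize_image(image, model.mean, model.std)[None])
    logits = model(x)
    return logits.data[0].argmax(axis=0).astype(np.uint8)


def predict_proba(model: PSPSegNet, image: np.ndarray) -> np.ndarray:
    """Foreground (class-1) probability raster for one image patch."""
    x = Tensor(normalize_image(image, model.mean, model.std)[None])
    z = model(x).data[0]
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return (e[1] / e.sum(axis=0)).astype(np.float64)
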