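"""Multi-level attention fusion (MAF) and class activation maps.

The classifier is trained from image-level [gland, background] bits only.
Feature maps from encoder layers 3, 5 and 6 — coarse gland localisation,
structural completeness, boundary refinement — are aligned to a common
resolution S (the layer-3 resolution, 1/16 scale, by default) with
bilinear upsampling plus a learned 1×1 projection, summed element-wise,
and fed to a 1×1 classifier head.  Global average pooling of the head's
score raster gives the image logits; the multi-label loss is per-class
binary cross-entropy on those logits.

A class activation map is the head's score raster before pooling,
rectified at zero and min-max normalised per class to [0, 1] (a channel
with zero range maps to all zeros, so the downstream confidence
thresholds always see a well-defined [0, 1] scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .encoder import EncoderConfig, MiTEncoder, normalize_image
from .errors import ConfigError, DimensionError
from .nn import Tensor

__all__ = ["CAMTrainConfig", "ClassActivationMap", "MAFModel", "MAFEnsemble",
           "align_feature", "fuse", "train_cam_stage", "generate_cam",
           "bce_with_logits"]

CLASS_NAMES = ("gland", "background")
FUSE_LAYERS = (3, 5, 6)


@dataclass
class CAMTrainConfig:
    lr: float = 0.002
    min_lr: float = 0.0
    momentum: float = 0.9
    weight_decay: float = 1e-3
    max_grad_norm: float = 5.0
    batch_size: int = 16
    epochs: int = 200
    flip_p: float = 0.5
    crop_ratio: tuple[float, float] = (0.7, 1.0)
    augment: bool = True
    seed: int = 0
    n_models: int = 1            # >1 trains an ensemble of restarts
    fuse_dim: int = 32
    fuse_layers: tuple[int, ...] = FUSE_LAYERS


@dataclass
class ClassActivationMap:
    """Per-class score raster in [0, 1], channel order [gland, background].

    ``raster`` keeps the head's raw (unrectified, unnormalised) response:
    patch rasters can be stitched back to whole-image scale and
    re-normalised there, which keeps the scale of a patch that only
    clips a gland sliver consistent with its neighbours.
    """

    scores: np.ndarray           # (Sh, Sw, 2)
    logits: np.ndarray           # (2,)
    raster: np.ndarray | None = None   # (Sh, Sw, 2) raw head response
    classes: tuple[str, str] = CLASS_NAMES

    @property
    def gland(self) -> np.ndarray:
        return self.scores[..., 0]

    def foreground(self) -> np.ndarray:
        """Scores of the foreground classes only (here: the gland channel),
        shape (Sh, Sw, 1) — the input to confidence thresholding."""
        return self.scores[..., :1]


def align_feature(feature: Tensor, target_hw: tuple[int, int],
                  proj: nn.Conv2d) -> Tensor:
    """Bilinear-upsample an NCHW feature map to ``target_hw`` and project
    channels with a (learned) 1×1 convolution."""
    return proj(nn.bilinear_resize(feature, target_hw))


def fuse(aligned: list[Tensor]) -> Tensor:
    """Element-wise sum of aligned feature maps."""
    shapes = {t.shape for t in aligned}
    if len(shapes) != 1:
        raise DimensionError(f"aligned features disagree in shape: {shapes}")
    out = aligned[0]
    for t in aligned[1:]:
        out = out + t
    return out


class MAFModel(nn.Module):
    """Encoder + per-layer 1×1 alignment projections + 1×1 classifier head."""

    def __init__(self, encoder_config: EncoderConfig | None = None,
                 fuse_dim: int = 32, fuse_layers: tuple[int, ...] = FUSE_LAYERS,
                 seed: int = 0):
        encoder_config = encoder_config or EncoderConfig.tiny()
        self.encoder = MiTEncoder(encoder_config, seed=seed)
        rng = np.random.default_rng(seed + 1)
        self.fuse_layers = tuple(fuse_layers)
        if any(i < 1 or i > 6 for i in self.fuse_layers):
            raise ConfigError(f"fuse layers must be in 1..6, got {fuse_layers}")
        self.projs = {i: nn.Conv2d(encoder_config.channels[i - 1], fuse_dim, 1,
                                   rng=rng)
                      for i in self.fuse_layers}
        # zero-init head: initial logits are 0, so early training is
        # well-scaled regardless of the encoder's activation magnitudes
        self.head = nn.Conv2d(fuse_dim, len(CLASS_NAMES), 1, rng=rng,
                              zero_init=True)
        # per-channel normalisation statistics, set by the training stage
        self.mean = np.array([0.5, 0.5, 0.5], np.float32)
        self.std = np.array([0.25, 0.25, 0.25], np.float32)

    def forward(self, x: Tensor):
        """Returns (score raster (B,2,Sh,Sw), logits (B,2), fused (B,F,Sh,Sw))."""
        feats = self.encoder.forward(x)
        target = feats[self.fuse_layers[0] - 1].shape[2:]
        aligned = [align_feature(feats[i - 1], target, self.projs[i])
                   for i in self.fuse_layers]
        fused = fuse(aligned)
        raster = self.head(fused)
        logits = raster.mean(axis=(2, 3))
        return raster, logits, fused

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path):
        np.savez(path,
                 __version__=np.array([1]),
                 __mean__=self.mean, __std__=self.std,
                 **self.state_dict())

    @classmethod
    def load(cls, path: str | Path, encoder_config: EncoderConfig | None = None,
             fuse_dim: int = 32,
             fuse_layers: tuple[int, ...] = FUSE_LAYERS) -> "MAFModel":
        blob = np.load(path)
        if int(blob["__version__"][0]) != 1:
            raise ConfigError(f"unsupported checkpoint version in {path}")
        model = cls(encoder_config, fuse_dim=fuse_dim, fuse_layers=fuse_layers)
        model.mean = blob["__mean__"]
        model.std = blob["__std__"]
        model.load_state_dict(
            {k: blob[k] for k in blob.files if not k.startswith("__")})
        return model


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean per-class binary cross-entropy, numerically stable:
    BCE(z, y) = softplus(z) − z·y, with gradient σ(z) − y."""
    y = Tensor(np.asarray(targets, dtype=logits.data.dtype))
    return (logits.softplus() - logits * y).mean()


def _augment(img: np.ndarray, rng: np.random.Generator,
             flip_p: float, crop_ratio: tuple[float, float]) -> np.ndarray:
    """Random flips and random crop (ratio of side length) resized back."""
    if rng.random() < flip_p:
        img = img[:, ::-1]
    if rng.random() < flip_p:
        img = img[::-1, :]
    h, w = img.shape[:2]
    ratio = rng.uniform(*crop_ratio)
    ch, cw = max(1, round(h * ratio)), max(1, round(w * ratio))
    if (ch, cw) != (h, w):
        y0 = rng.integers(0, h - ch + 1)
        x0 = rng.integers(0, w - cw + 1)
        img = nn.bilinear_resize_np(img[y0:y0 + ch, x0:x0 + cw], (h, w))
        img = np.clip(np.rint(img), 0, 255)
    return np.ascontiguousarray(img, dtype=np.uint8)


def train_cam_stage(images: list[np.ndarray], labels: np.ndarray,
                    config: CAMTrainConfig | None = None,
                    encoder_config: EncoderConfig | None = None,
                    model: MAFModel | None = None):
    """Train the MAF classifier under image-level supervision.

    ``images``: list of (112, 112, 3) uint8 patches; ``labels``: (N, 2)
    bits [gland, background].  SGD with momentum and cosine-annealed
    learning rate; per-epoch mean loss is logged.  Returns
    ``(model, log)`` where ``log["loss"]`` is the per-epoch trajectory.
    With ``config.n_models > 1``, trains that many independent restarts
    (seeds ``seed + 1000·k``) and returns a :class:`MAFEnsemble`; the log
    then carries each member's trajectory under ``log["models"]``.
    """
    config = config or CAMTrainConfig()
    if config.n_models > 1 and model is None:
        from dataclasses import replace as _replace

        members, logs = [], []
        for k in range(config.n_models):
            member_cfg = _replace(config, n_models=1,
                                  seed=config.seed + 1000 * k)
            member, mlog = train_cam_stage(images, labels, member_cfg,
                                           encoder_config)
            members.append(member)
            logs.append(mlog)
        return MAFEnsemble(members), {"loss": logs[0]["loss"],
                                      "models": logs}
    if len(images) == 0:
        raise ConfigError("empty patch manifest: nothing to train on")
    labels = np.asarray(labels, dtype=np.float32)
    if labels.shape != (len(images), 2):
        raise ConfigError(f"labels must be (N, 2) bits, got {labels.shape}")

    if model is None:
        model = MAFModel(encoder_config, fuse_dim=config.fuse_dim,
                         fuse_layers=config.fuse_layers, seed=config.seed)
    stack = np.stack(images).astype(np.float32) / 255.0
    model.mean = stack.mean(axis=(0, 1, 2))
    model.std = np.maximum(stack.std(axis=(0, 1, 2)), 1e-3)

    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay,
                 max_grad_norm=config.max_grad_norm)
    n = len(images)
    steps_per_epoch = max(1, n // config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    log = {"loss": [], "lr": []}
    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            batch = []
            for i in idx:
                img = images[i]
                if config.augment:
                    img = _augment(img, rng, config.flip_p, config.crop_ratio)
                batch.append(normalize_image(img, model.mean, model.std))
            x = Tensor(np.stack(batch))
            _, logits, _ = model(x)
            loss = bce_with_logits(logits, labels[idx])
            opt.lr = nn.cosine_lr(config.lr, step, total_steps, config.min_lr)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            step += 1
        log["loss"].append(float(np.mean(epoch_losses)))
        log["lr"].append(opt.lr)
    return model, log


class MAFEnsemble:
    """Average of independently initialised MAF classifiers.

    Patch classification is near-perfect for every restart, but where a
    from-scratch run places its within-patch raster structure varies
    with the restart; averaging the raw rasters keeps the consistent
    class evidence and cancels restart-specific structure.  Fused
    features are concatenated along the channel axis.
    """

    def __init__(self, models: list[MAFModel]):
        if not models:
            raise ConfigError("an ensemble needs at least one model")
        self.models = list(models)

    def __len__(self):
        return len(self.models)


def _forward_patch(image: np.ndarray, model):
    """(raster (Sh,Sw,2), logits (2,), fused (Sh,Sw,F)) for one patch,
    averaged over the members when ``model`` is an ensemble."""
    models = model.models if isinstance(model, MAFEnsemble) else [model]
    rasters, logits, fused = [], [], []
    for m in models:
        x = Tensor(normalize_image(image, m.mean, m.std)[None])
        r, l, f = m(x)
        rasters.append(r.data[0].transpose(1, 2, 0))
        logits.append(l.data[0])
        fused.append(f.data[0].transpose(1, 2, 0))
    return (np.mean(rasters, axis=0), np.mean(logits, axis=0),
            np.concatenate(fused, axis=-1))


def classification_accuracy(model, images: list[np.ndarray],
                            labels: np.ndarray, class_index: int = 0) -> float:
    """Fraction of patches whose predicted bit (logit > 0) matches the label."""
    labels = np.asarray(labels)
    hits = 0
    for img, lab in zip(images, labels):
        _, logits, _ = _forward_patch(img, model)
        hits += int((logits[class_index] > 0) == bool(lab[class_index]))
    return hits / len(images)


def generate_cam(image: np.ndarray, model,
                 out_size: tuple[int, int] | None = None):
    """Emit the class activation map (and fused features) for one patch.

    ``model`` is a :class:`MAFModel` or :class:`MAFEnsemble`.  Scores are
    the classifier-head responses before pooling, rectified at zero and
    min-max normalised per class; ``out_size`` optionally bilinearly
    upsamples the score raster (e.g. to the patch resolution).  Returns
    ``(ClassActivationMap, fused_features (Sh, Sw, F))``.
    """
    raster, logits, fused = _forward_patch(image, model)
    scores = np.maximum(raster, 0.0)
    lo = scores.min(axis=(0, 1), keepdims=True)
    hi = scores.max(axis=(0, 1), keepdims=True)
    rng_ = hi - lo
    norm = np.where(rng_ > 0, (scores - lo) / np.where(rng_ > 0, rng_, 1.0), 0.0)
    if out_size is not None:
        norm = np.clip(nn.bilinear_resize_np(norm, out_size), 0.0, 1.0)
    cam = ClassActivationMap(scores=norm, logits=logits.copy(),
                             raster=raster.copy())
    return cam, fused
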