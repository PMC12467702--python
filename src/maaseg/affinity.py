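"""Affinity-guided refinement of initial CAM pseudo-labels.

The initial class activation maps are noisy and coarse.  This module
refines them in four steps:

1. **Confidence labels** — per-pixel thresholding of the foreground CAM
   scores into {class, background 0, uncertain 255}: a pixel is labelled
   with the argmax foreground class when its top score ≥ β_h, background
   when it is ≤ β_l, uncertain otherwise (defaults β_l = 0.3, β_h = 0.6).
2. **Pair supervision** — unordered pixel pairs within Euclidean radius
   r (default 8) whose confidence labels are both certain form a positive
   set R+ (equal labels) and a negative set R− (different labels).
3. **Learned affinity** — a three-layer perceptron scores each pair from
   the concatenation of the two pixels' descriptors (fused multi-level
   features ++ an 8-dim embedding of the confidence label); the score is
   symmetrised over the pair order.  The loss drives sigmoid(A) → 1 on
   R+ and → 0 on R−.
4. **Propagation** — pixel-adaptive refinement (PAR: iterative local
   smoothing with RGB/position kernels) and a random walk with the
   row-stochastic transition T = row-normalise(A∘β + I) spread confident
   scores along high-affinity links; re-thresholding yields the final
   pseudo-labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import nn
from .cam import ClassActivationMap
from .errors import ConfigError, DimensionError, UndefinedLossError
from .nn import Tensor

__all__ = ["ConfidenceLabelMap", "PairSets", "AffinityScores", "AffinityMLP",
           "AffinityConfig", "confidence_labels", "build_pair_sets",
           "affinity_loss", "par_refine", "build_transition", "random_walk",
           "finalize_pseudo_labels", "train_affinity", "AffinityRefiner"]

IGNORE = 255


@dataclass
class ConfidenceLabelMap:
    """Raster of {1..K (foreground class index + 1), 0 (background),
    255 (uncertain)} plus the thresholds that produced it."""

    labels: np.ndarray           # (H, W) uint8
    beta_low: float
    beta_high: float


@dataclass
class PairSets:
    """Unordered in-radius pixel pairs, as flat-index columns (N, 2)."""

    positives: np.ndarray
    negatives: np.ndarray
    radius: float
    shape: tuple[int, int]

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)


@dataclass
class AffinityScores:
    """Predicted pair scores, split by supervision set."""

    positive: Tensor
    negative: Tensor


def _score_raster(cam, background_channel: int | None):
    """(H, W, K) score raster plus the background channel index (or None).

    A :class:`ClassActivationMap` carries [gland, background] channels, so
    its background sits at channel 1 unless overridden; a bare array is
    treated as foreground-only by default.
    """
    if isinstance(cam, ClassActivationMap):
        arr = np.asarray(cam.scores, dtype=np.float64)
        if background_channel is None:
            background_channel = 1
    else:
        arr = np.asarray(cam, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[..., None]
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ConfigError("CAM scores must lie in [0, 1]")
    return arr, background_channel


def confidence_labels(cam, beta_low: float = 0.3, beta_high: float = 0.6,
                      background_channel: int | None = None) -> ConfidenceLabelMap:
    """Threshold CAM scores into {foreground class, 0, 255}.

    Per pixel: the argmax class when the top score is ≥ β_h (the
    background channel, when present, competes and maps to label 0), 0
    when the top score is ≤ β_l, 255 (uncertain) otherwise.  Boundary
    values are inclusive on both branches.  Foreground classes are
    numbered 1..K in channel order (here: 1 = gland).
    """
    if not 0.0 < beta_low < beta_high < 1.0:
        raise ConfigError(
            f"need 0 < beta_low < beta_high < 1, got {beta_low}, {beta_high}")
    scores, bg = _score_raster(cam, background_channel)
    top = scores.max(axis=-1)
    arg = scores.argmax(axis=-1)
    # map channel index → label: foreground channels 1..K, background → 0
    channel_label = np.arange(scores.shape[-1]) + 1
    if bg is not None:
        channel_label[bg] = 0
        channel_label[bg + 1:] -= 1
    labels = np.full(top.shape, IGNORE, dtype=np.uint8)
    labels[top <= beta_low] = 0
    confident = top >= beta_high
    labels[confident] = channel_label[arg[confident]].astype(np.uint8)
    return ConfidenceLabelMap(labels=labels, beta_low=beta_low, beta_high=beta_high)


def _radius_offsets(r: float) -> list[tuple[int, int]]:
    """Half-plane offsets (dy, dx) with 0 < dy²+dx² ≤ r², each unordered
    pair enumerated exactly once."""
    out = []
    ri = int(np.floor(r))
    for dy in range(0, ri + 1):
        for dx in range(-ri, ri + 1):
            if dy == 0 and dx <= 0:
                continue
            if dy * dy + dx * dx <= r * r:
                out.append((dy, dx))
    return out


def build_pair_sets(labels: ConfidenceLabelMap | np.ndarray, r: float = 8) -> PairSets:
    """Enumerate supervised pixel pairs within Euclidean radius ``r``.

    A pair joins R+ when both labels are certain and equal, R− when both
    are certain and different; pairs touching an uncertain (255) pixel
    are discarded.
    """
    if r < 1:
        raise ConfigError(f"pair radius must be ≥ 1, got {r}")
    lab = labels.labels if isinstance(labels, ConfidenceLabelMap) else np.asarray(labels)
    H, W = lab.shape
    flat = np.arange(H * W, dtype=np.int64).reshape(H, W)
    pos_chunks, neg_chunks = [], []
    for dy, dx in _radius_offsets(r):
        if dy >= H or abs(dx) >= W:   # offset falls off the raster entirely
            continue
        ys = slice(0, H - dy)
        yt = slice(dy, H)
        if dx >= 0:
            xs, xt = slice(0, W - dx), slice(dx, W)
        else:
            xs, xt = slice(-dx, W), slice(0, W + dx)
        a = lab[ys, xs]
        b = lab[yt, xt]
        ia = flat[ys, xs]
        ib = flat[yt, xt]
        certain = (a != IGNORE) & (b != IGNORE)
        same = certain & (a == b)
        diff = certain & (a != b)
        if same.any():
            pos_chunks.append(np.stack([ia[same], ib[same]], axis=1))
        if diff.any():
            neg_chunks.append(np.stack([ia[diff], ib[diff]], axis=1))
    empty = np.empty((0, 2), dtype=np.int64)
    return PairSets(
        positives=np.concatenate(pos_chunks) if pos_chunks else empty,
        negatives=np.concatenate(neg_chunks) if neg_chunks else empty,
        radius=r, shape=(H, W))


@dataclass
class AffinityConfig:
    r: float = 8
    emb_dim: int = 8
    hidden: int = 32
    lr: float = 0.01
    momentum: float = 0.9
    max_grad_norm: float = 5.0
    iters: int = 300
    pairs_per_step: int = 2048
    beta_low: float = 0.3
    beta_high: float = 0.6
    walk_beta: float = 2.0
    walk_iters: int = 16
    par_iters: int = 10
    par_dilations: tuple[int, ...] = (1, 2, 4, 8)
    par_rgb_bw: float = 0.1
    par_pos_bw: float = 6.0
    seed: int = 0


class AffinityMLP(nn.Module):
    """Three fully connected layers mapping a concatenated pair descriptor
    to one scalar affinity; symmetric by averaging both pair orders."""

    def __init__(self, feat_dim: int, emb_dim: int = 8, hidden: int = 32,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.embed = nn.Embedding(3, emb_dim, rng)   # labels {0, fg, 255}
        d = 2 * (feat_dim + emb_dim)
        self.fc1 = nn.Linear(d, hidden, rng)
        self.fc2 = nn.Linear(hidden, hidden, rng)
        self.fc3 = nn.Linear(hidden, 1, rng)
        self.feat_dim = feat_dim
        self.emb_dim = emb_dim

    def descriptors(self, features: np.ndarray, labels: np.ndarray) -> Tensor:
        """Per-pixel descriptor: features ++ label embedding, flattened (N, D)."""
        H, W, F = features.shape
        if F != self.feat_dim:
            raise DimensionError(f"feature depth {F} != model's {self.feat_dim}")
        idx = np.where(labels == IGNORE, 2, np.minimum(labels, 1)).reshape(-1)
        emb = self.embed(idx)
        feat = Tensor(features.reshape(-1, F).astype(np.float32))
        return nn.concat([feat, emb], axis=-1)

    def _mlp(self, d: Tensor) -> Tensor:
        h = self.fc1(d).relu()
        h = self.fc2(h).relu()
        return self.fc3(h)

    def score_pairs(self, desc: Tensor, pairs: np.ndarray) -> Tensor:
        """Affinity scores for flat-index ``pairs`` (M, 2); symmetric in
        the pair order by construction."""
        if len(pairs) == 0:
            return Tensor(np.zeros((0,), dtype=np.float32))
        di = desc.take(pairs[:, 0])
        dj = desc.take(pairs[:, 1])
        fwd = self._mlp(nn.concat([di, dj], axis=-1))
        rev = self._mlp(nn.concat([dj, di], axis=-1))
        return ((fwd + rev) * 0.5).reshape(-1)


def pair_affinity(mlp: AffinityMLP, desc: Tensor, i: int, j: int) -> float:
    """Scalar affinity of one pixel pair."""
    return float(mlp.score_pairs(desc, np.array([[i, j]])).data[0])


def affinity_loss(scores: AffinityScores) -> Tensor:
    """Pair-supervision loss: mean sigmoid(A) over R− plus mean
    (1 − sigmoid(A)) over R+, so minimisation pushes positive-pair
    affinities up and negative-pair affinities down.  An empty set
    contributes 0; both sets empty is undefined."""
    n_pos = scores.positive.data.size
    n_neg = scores.negative.data.size
    if n_pos == 0 and n_neg == 0:
        raise UndefinedLossError("affinity loss needs at least one pair")
    total = Tensor(np.zeros((), dtype=np.float32))
    if n_pos:
        total = total + (1.0 - scores.positive.sigmoid()).mean()
    if n_neg:
        total = total + scores.negative.sigmoid().mean()
    return total


# ---------------------------------------------------------------------------
# pixel-adaptive refinement (PAR)
# ---------------------------------------------------------------------------

def par_refine(image: np.ndarray, scores: np.ndarray, iterations: int = 10,
               dilations: tuple[int, ...] = (1, 2, 4, 8),
               rgb_bw: float = 0.1, pos_bw: float = 6.0) -> np.ndarray:
    """Iterative local smoothing guided by RGB similarity and proximity.

    Each pixel's score becomes a convex combination of its 8-neighbours
    at the given dilations, weighted by a normalised
    exp(−‖ΔRGB‖²/2σ_rgb² − d²/2σ_pos²) kernel (RGB on a [0, 1] scale).
    Convexity keeps every class channel inside its input range.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    if img.max() > 1.5:
        img = img / 255.0
    s = np.asarray(scores, dtype=np.float64)
    squeeze = s.ndim == 2
    if squeeze:
        s = s[..., None]
    if img.shape[:2] != s.shape[:2]:
        raise DimensionError(
            f"image {img.shape[:2]} and scores {s.shape[:2]} must align")
    H, W = s.shape[:2]

    offsets = [(dy * d, dx * d)
               for d in dilations
               for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if not (dy == 0 and dx == 0)]
    pad = max(max(abs(dy), abs(dx)) for dy, dx in offsets)
    imgp = np.pad(img, ((pad, pad), (pad, pad), (0, 0)), mode="edge")

    weights = np.empty((len(offsets), H, W))
    for k, (dy, dx) in enumerate(offsets):
        nb = imgp[pad + dy:pad + dy + H, pad + dx:pad + dx + W]
        rgb_d2 = ((nb - img) ** 2).sum(axis=-1)
        pos_d2 = float(dy * dy + dx * dx)
        weights[k] = np.exp(-rgb_d2 / (2 * rgb_bw ** 2)
                            - pos_d2 / (2 * pos_bw ** 2))
    weights /= weights.sum(axis=0, keepdims=True)

    for _ in range(iterations):
        spad = np.pad(s, ((pad, pad), (pad, pad), (0, 0)), mode="edge")
        nxt = np.zeros_like(s)
        for k, (dy, dx) in enumerate(offsets):
            nxt += weights[k][..., None] * spad[pad + dy:pad + dy + H,
                                                pad + dx:pad + dx + W]
        s = nxt
    return s[..., 0] if squeeze else s


# ---------------------------------------------------------------------------
# random-walk propagation
# ---------------------------------------------------------------------------

def build_transition(pairs: np.ndarray, values: np.ndarray, n: int,
                     beta: float = 2.0) -> sp.csr_matrix:
    """Row-stochastic transition T = row-normalise(A∘β + I) over ``n``
    pixels, where A is the symmetric sparse affinity matrix given by
    ``pairs``/``values`` (values ≥ 0).  The identity term acts as a
    self-loop whose weight is one minus the normalised neighbour mass,
    so a pixel with no (or zero) affinities keeps its score."""
    if np.any(values < 0):
        raise ConfigError("affinity values must be non-negative")
    v = np.asarray(values, dtype=np.float64) ** beta
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    data = np.concatenate([v, v])
    a = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    a = a + sp.identity(n, format="csr")
    inv_rowsum = 1.0 / np.asarray(a.sum(axis=1)).ravel()
    return sp.diags(inv_rowsum) @ a


def random_walk(scores: np.ndarray, transition: sp.csr_matrix,
                t: int = 16) -> np.ndarray:
    """Iterate class scores through the transition operator ``t`` times.

    ``scores`` is (H, W) or (H, W, K); each class channel is propagated
    independently and the result is clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=np.float64)
    squeeze = s.ndim == 2
    if squeeze:
        s = s[..., None]
    H, W, K = s.shape
    if transition.shape != (H * W, H * W):
        raise DimensionError(
            f"transition is {transition.shape}, scores need {(H * W, H * W)}")
    flat = s.reshape(H * W, K)
    for _ in range(t):
        flat = transition @ flat
    out = np.clip(flat.reshape(H, W, K), 0.0, 1.0)
    return out[..., 0] if squeeze else out


def finalize_pseudo_labels(refined_scores: np.ndarray, beta_low: float = 0.3,
                           beta_high: float = 0.6,
                           out_size: tuple[int, int] | None = None,
                           background_channel: int | None = None) -> np.ndarray:
    """Re-threshold refined scores into a {0, 1, 255} mask, optionally
    after bilinear upsampling to ``out_size``."""
    s = np.asarray(refined_scores, dtype=np.float64)
    if out_size is not None:
        s = np.clip(nn.bilinear_resize_np(s, out_size), 0.0, 1.0)
    return confidence_labels(s, beta_low, beta_high,
                             background_channel=background_channel).labels


# ---------------------------------------------------------------------------
# training + orchestration
# ---------------------------------------------------------------------------

def train_affinity(features: list[np.ndarray], label_maps: list[np.ndarray],
                   config: AffinityConfig | None = None):
    """Fit the affinity perceptron on pair supervision from many rasters.

    ``features``: per-raster (H, W, F) fused features; ``label_maps``:
    matching {0, 1, 255} confidence labels.  Pairs are enumerated per
    raster and subsampled each step.  Returns ``(mlp, log)``.
    """
    config = config or AffinityConfig()
    if not features:
        raise ConfigError("no rasters to train the affinity model on")
    feat_dim = features[0].shape[-1]
    mlp = AffinityMLP(feat_dim, config.emb_dim, config.hidden, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)

    per_raster = []
    for feat, lab in zip(features, label_maps):
        pairs = build_pair_sets(lab, config.r)
        desc = mlp.descriptors(_standardize(feat), lab)
        per_raster.append((desc, pairs))

    opt = nn.SGD(mlp.parameters(), lr=config.lr, momentum=config.momentum,
                 max_grad_norm=config.max_grad_norm)
    log = {"loss": []}
    usable = [pr for pr in per_raster if pr[1].n_pos + pr[1].n_neg > 0]
    if not usable:
        raise UndefinedLossError("no certain pixel pairs in any raster")
    for step in range(config.iters):
        desc, pairs = usable[step % len(usable)]
        half = config.pairs_per_step // 2
        pos = _subsample(pairs.positives, half, rng)
        neg = _subsample(pairs.negatives, half, rng)
        scores = AffinityScores(positive=mlp.score_pairs(desc, pos),
                                negative=mlp.score_pairs(desc, neg))
        loss = affinity_loss(scores)
        opt.zero_grad()
        loss.backward()
        opt.step()
        log["loss"].append(float(loss.data))
    return mlp, log


def _subsample(pairs: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    if len(pairs) <= k:
        return pairs
    return pairs[rng.choice(len(pairs), size=k, replace=False)]


def _standardize(feat: np.ndarray) -> np.ndarray:
    mu = feat.mean(axis=(0, 1), keepdims=True)
    sd = feat.std(axis=(0, 1), keepdims=True)
    return (feat - mu) / np.maximum(sd, 1e-6)


def assemble_tile_cam(cams: list[ClassActivationMap],
                      fused_list: list[np.ndarray], grid,
                      scale: int = 16):
    """Merge per-patch CAM rasters back to whole-tile scale.

    Patch rasters (raw head responses) are bilinearly upsampled to patch
    resolution, averaged over overlaps by :func:`maaseg.tiling.stitch`,
    rectified and min-max normalised per class over the *tile*.  Fused
    features are stitched the same way and downsampled to the tile's CAM
    resolution (ceil(H/scale) × ceil(W/scale)) for affinity learning and
    the random walk.  Returns ``(tile_scores (H, W, K), tile_features
    (h, w, F), gland_present)``.
    """
    from .tiling import stitch   # local import to avoid a cycle

    P = grid.patch_size
    rasters = [nn.bilinear_resize_np(
        cam.raster if cam.raster is not None else cam.scores, (P, P))
        for cam in cams]
    feats = [nn.bilinear_resize_np(f, (P, P)) for f in fused_list]
    tile_raster = stitch(rasters, grid)
    tile_feat = stitch(feats, grid)
    tile_scores = renormalize_scores(np.maximum(tile_raster, 0.0))
    h = -(-grid.height // scale)
    w = -(-grid.width // scale)
    tile_feat = nn.bilinear_resize_np(tile_feat, (h, w))
    present = any(cam.logits[0] > 0 for cam in cams)
    return tile_scores, tile_feat, present


def renormalize_scores(scores: np.ndarray) -> np.ndarray:
    """Restore the CAM min-max contract after a smoothing operation.

    PAR and the random walk are averaging operators: they contract the
    score range, which would push true background above the β_l
    threshold.  A refined score map is still a CAM, so its per-class
    min-max normalisation to [0, 1] is re-established before any
    thresholding; a constant channel maps to all zeros.
    """
    s = np.asarray(scores, dtype=np.float64)
    squeeze = s.ndim == 2
    if squeeze:
        s = s[..., None]
    lo = s.min(axis=(0, 1), keepdims=True)
    hi = s.max(axis=(0, 1), keepdims=True)
    rng = hi - lo
    out = np.where(rng > 0, (s - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return out[..., 0] if squeeze else out


class AffinityRefiner:
    """End-to-end pseudo-label refinement for whole tiles.

    Inputs are tile-level foreground CAM scores (per-patch head rasters
    stitched and min-max normalised over the tile, see
    :func:`assemble_tile_cam`) plus fused features at the tile's CAM
    resolution.  For each tile: PAR-smooth the CAM at CAM resolution
    (against a downsampled copy of the image), renormalise and threshold
    to confidence labels, learn pair affinities across all tiles, then
    random-walk the smoothed scores, upsample, PAR-refine again at full
    resolution against the RGB image, renormalise, and re-threshold.
    A tile classified as gland-free gets an all-zero foreground map:
    CAMs are only meaningful for classes present in the image.
    """

    def __init__(self, config: AffinityConfig | None = None):
        self.config = config or AffinityConfig()
        self.mlp: AffinityMLP | None = None

    @staticmethod
    def _downsample_image(image: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
        return nn.bilinear_resize_np(np.asarray(image, np.float64) / 255.0, hw)

    @staticmethod
    def _fg(tile_scores: np.ndarray, present: bool) -> np.ndarray:
        fg = _score_raster(tile_scores, None)[0][..., :1]
        return fg if present else np.zeros_like(fg)

    def _smoothed(self, image: np.ndarray, fg: np.ndarray,
                  cam_hw: tuple[int, int]) -> np.ndarray:
        cfg = self.config
        small_img = self._downsample_image(image, cam_hw)
        small_fg = np.clip(nn.bilinear_resize_np(fg, cam_hw), 0.0, 1.0)
        # CAM-resolution PAR uses proportionally smaller dilations
        dil = tuple(sorted({max(1, d // 2) for d in cfg.par_dilations}))
        sm = par_refine(small_img, small_fg, iterations=cfg.par_iters,
                        dilations=dil, rgb_bw=cfg.par_rgb_bw,
                        pos_bw=cfg.par_pos_bw)
        return renormalize_scores(sm)

    def _labels(self, scores: np.ndarray) -> np.ndarray:
        return confidence_labels(scores, self.config.beta_low,
                                 self.config.beta_high).labels

    def fit(self, images: list[np.ndarray], tile_scores: list[np.ndarray],
            features: list[np.ndarray], present: list[bool] | None = None):
        """Train the affinity perceptron from the tiles' own CAM labels."""
        present = present or [True] * len(images)
        label_maps = []
        for img, sc, feat, pres in zip(images, tile_scores, features, present):
            sm = self._smoothed(img, self._fg(sc, pres), feat.shape[:2])
            label_maps.append(self._labels(sm))
        self.mlp, log = train_affinity(features, label_maps, self.config)
        return log

    def refine(self, image: np.ndarray, tile_scores: np.ndarray,
               features: np.ndarray, present: bool = True) -> dict:
        """Refine one tile; returns raw/refined scores and label masks."""
        if self.mlp is None:
            raise ConfigError("AffinityRefiner.fit must run before refine")
        cfg = self.config
        H, W = image.shape[:2]
        fg = self._fg(tile_scores, present)
        sm = self._smoothed(image, fg, features.shape[:2])
        lab = self._labels(sm)

        # The walk's transition must stay local relative to the raster:
        # the supervision radius r is sized for CAM rasters tens of
        # pixels across, and on a small raster it would connect every
        # pixel to every other, turning the walk into an attractor to
        # its global stationary distribution.
        walk_r = min(cfg.r, max(2.0, min(lab.shape) / 4.0))
        pairs_all = build_pair_sets(np.zeros_like(lab), walk_r)  # full support
        support = np.concatenate([pairs_all.positives, pairs_all.negatives]) \
            if (pairs_all.n_pos + pairs_all.n_neg) else np.empty((0, 2), np.int64)
        desc = self.mlp.descriptors(_standardize(features), lab)
        aff = self.mlp.score_pairs(desc, support).data
        aff = 1.0 / (1.0 + np.exp(-np.clip(aff, -60, 60)))
        T = build_transition(support, aff, lab.size, beta=cfg.walk_beta)
        walked = renormalize_scores(random_walk(sm, T, t=cfg.walk_iters))

        up = np.clip(nn.bilinear_resize_np(walked, (H, W)), 0.0, 1.0)
        full = par_refine(image, up, iterations=cfg.par_iters,
                          dilations=cfg.par_dilations, rgb_bw=cfg.par_rgb_bw,
                          pos_bw=cfg.par_pos_bw)
        full = renormalize_scores(full)
        final = finalize_pseudo_labels(full, cfg.beta_low, cfg.beta_high)
        raw = finalize_pseudo_labels(fg, cfg.beta_low, cfg.beta_high)
        return {"raw_labels": raw, "final_labels": final,
                "walked_scores": walked, "full_scores": full}
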