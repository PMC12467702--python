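"""Synthetic H&E-like gland tiles with ground-truth masks.

Colorectal gland tissue in H&E sections shows ring-shaped glands — an
epithelial border (hematoxylin purple) around a pale lumen — embedded in
eosin-pink stroma.  This module renders that geometry deterministically:
randomly rotated ellipses with an inner lumen ellipse, flat palette colors
per tissue class, optional per-channel Gaussian noise.  Every downstream
stage (tiling, CAM training, affinity refinement, segmentation) is
exercised on these tiles, so no external dataset download is ever needed.

With ``noise_sigma=0`` the three palette classes are exactly
linearly separable in RGB, which is what makes end-to-end recovery of the
gland mask from image-level labels a well-posed check.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse as _draw_ellipse

from .errors import ConfigError

__all__ = ["SyntheticSpec", "PlacedGland", "LabeledTile",
           "generate_tile", "generate_dataset", "DEFAULT_PALETTE"]

# flat H&E-ish palette: (stroma, epithelium, lumen)
DEFAULT_PALETTE = ((236, 180, 206), (118, 62, 151), (244, 240, 242))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic tile; identical spec ⇒ identical tile."""

    seed: int = 0
    width: int = 775
    height: int = 522
    n_glands: int = 6
    radius_range: tuple[int, int] = (30, 60)
    lumen_ratio: float = 0.45
    noise_sigma: float = 0.0
    palette: tuple = DEFAULT_PALETTE

    def validate(self) -> None:
        if self.width < 112 or self.height < 112:
            raise ConfigError(
                f"tile must be at least 112×112, got {self.width}×{self.height}")
        if not 0.0 < self.lumen_ratio < 1.0:
            raise ConfigError(f"lumen_ratio must be in (0,1), got {self.lumen_ratio}")
        if self.radius_range[0] < 4:
            raise ConfigError(f"minimum gland radius must be ≥ 4, got {self.radius_range[0]}")
        if self.radius_range[0] > self.radius_range[1]:
            raise ConfigError(f"radius_range min > max: {self.radius_range}")
        if self.n_glands < 0:
            raise ConfigError("n_glands must be non-negative")
        if len(self.palette) != 3 or any(len(c) != 3 for c in self.palette):
            raise ConfigError("palette must be three RGB triplets")


@dataclass(frozen=True)
class PlacedGland:
    """Geometry of one rendered gland (recorded for area oracles)."""

    cy: float
    cx: float
    r_major: float
    r_minor: float
    rotation: float  # radians


@dataclass
class LabeledTile:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) uint8, 1 = gland (epithelial ring + lumen)
    glands: list[PlacedGland] = field(default_factory=list)


def generate_tile(spec: SyntheticSpec) -> LabeledTile:
    """Render one tile.  Pure function of ``spec`` (bit-identical re-runs)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    shape = (H, W)
    stroma, epithelium, lumen = (np.array(c, dtype=np.float64) for c in spec.palette)

    image = np.empty((H, W, 3), dtype=np.float64)
    image[:] = stroma
    mask = np.zeros(shape, dtype=np.uint8)

    placed: list[PlacedGland] = []
    for _ in range(spec.n_glands):
        for _attempt in range(100):
            a = rng.uniform(*spec.radius_range)           # major radius
            b = a * rng.uniform(0.6, 1.0)                 # minor radius
            theta = rng.uniform(0.0, np.pi)
            cy = rng.uniform(a, H - a)
            cx = rng.uniform(a, W - a)
            # bounding-circle test keeps glands disjoint and unambiguous
            ok = all((cy - g.cy) ** 2 + (cx - g.cx) ** 2 > (a + g.r_major) ** 2
                     for g in placed)
            if ok:
                placed.append(PlacedGland(cy, cx, a, b, theta))
                break
        # after 100 rejected placements the gland is skipped

    for g in placed:
        rr, cc = _draw_ellipse(g.cy, g.cx, g.r_major, g.r_minor,
                               shape=shape, rotation=g.rotation)
        mask[rr, cc] = 1
        image[rr, cc] = epithelium
        lr, lc = _draw_ellipse(g.cy, g.cx, g.r_major * spec.lumen_ratio,
                               g.r_minor * spec.lumen_ratio,
                               shape=shape, rotation=g.rotation)
        image[lr, lc] = lumen

    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return LabeledTile(image=image, mask=mask, glands=placed)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a mask PNG stored with values {0, 255} back to {0, 1}."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def generate_dataset(spec_list: list[SyntheticSpec], out_dir: str | Path) -> list[dict]:
    """Write tiles as PNG image/mask pairs plus a CSV manifest.

    Masks are stored with values {0, 255} (mapped back to {0, 1} by
    :func:`read_mask`).  Returns the manifest records; an empty spec list
    yields an empty manifest and no image files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise _io_error(out_dir, exc)
    records: list[dict] = []
    for k, spec in enumerate(spec_list):
        tile = generate_tile(spec)
        img_path = out_dir / f"tile_{k:04d}.png"
        mask_path = out_dir / f"tile_{k:04d}_mask.png"
        try:
            Image.fromarray(tile.image).save(img_path)
            Image.fromarray(tile.mask * 255).save(mask_path)
        except OSError as exc:
            raise _io_error(img_path, exc)
        records.append({
            "image_path": str(img_path),
            "mask_path": str(mask_path),
            "width": spec.width,
            "height": spec.height,
            "seed": spec.seed,
        })
    manifest_path = out_dir / "manifest.csv"
    try:
        with open(manifest_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["image_path", "mask_path", "width", "height", "seed"])
            writer.writeheader()
            writer.writerows(records)
    except OSError as exc:
        raise _io_error(manifest_path, exc)
    return records


def _io_error(path, exc):
    from .errors import PipelineError
    return PipelineError(f"I/O failure at {path}: {exc}")


def sha256_file(path: str | Path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()
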