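"""Sliding-window tiling of whole-slide-like images and patch stitching.

Whole-slide gland images are cropped into 112×112 patches with a 56-pixel
stride (so adjacent patches overlap by half a patch).  Per-axis start
coordinates are the stride multiples that keep the window inside the
image, plus one clamped final start at ``dim − patch_size`` so the last
rows/columns are always covered.  For all axis lengths that are not
multiples of the patch size this yields exactly
``ceil((dim − patch_size)/stride) + 1`` windows, i.e. the published
per-axis patch count.

Per-patch image-level labels are the weak supervision of the whole
method: a two-bit vector [gland present, background present] derived from
the ground-truth mask of the patch.  Stitching inverts the crop by
averaging patch scores over overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError

__all__ = ["PatchGrid", "ImageLevelLabel", "Patch",
           "compute_patch_grid", "crop", "derive_image_labels", "stitch"]

PATCH_SIZE = 112
STRIDE = 56


def _axis_starts(dim: int, patch_size: int, stride: int) -> list[int]:
    starts = list(range(0, dim - patch_size + 1, stride))
    if starts[-1] != dim - patch_size:
        starts.append(dim - patch_size)
    return starts


@dataclass(frozen=True)
class PatchGrid:
    width: int
    height: int
    patch_size: int
    stride: int
    starts_x: tuple[int, ...]
    starts_y: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.starts_x) * len(self.starts_y)

    def positions(self) -> list[tuple[int, int]]:
        """Row-major (x, y) top-left corners; the canonical patch order."""
        return [(x, y) for y in self.starts_y for x in self.starts_x]


@dataclass(frozen=True)
class ImageLevelLabel:
    gland: int
    background: int

    def as_vector(self) -> np.ndarray:
        return np.array([self.gland, self.background], dtype=np.float32)


@dataclass(frozen=True)
class Patch:
    x: int
    y: int
    data: np.ndarray


def compute_patch_grid(width: int, height: int, patch_size: int = PATCH_SIZE,
                       stride: int = STRIDE) -> PatchGrid:
    """Sliding-window grid over a ``width``×``height`` image."""
    if width < patch_size or height < patch_size:
        raise DimensionError(
            f"image {width}×{height} smaller than patch size {patch_size}")
    return PatchGrid(width=width, height=height, patch_size=patch_size,
                     stride=stride,
                     starts_x=tuple(_axis_starts(width, patch_size, stride)),
                     starts_y=tuple(_axis_starts(height, patch_size, stride)))


def crop(image: np.ndarray, grid: PatchGrid) -> list[Patch]:
    """Extract every grid patch; patches are half-open windows [x, x+P)."""
    H, W = image.shape[:2]
    if (W, H) != (grid.width, grid.height):
        raise DimensionError(
            f"image is {W}×{H} but grid was built for {grid.width}×{grid.height}")
    P = grid.patch_size
    return [Patch(x=x, y=y, data=image[y:y + P, x:x + P])
            for x, y in grid.positions()]


def derive_image_labels(mask_patch: np.ndarray) -> ImageLevelLabel:
    """Two-bit weak label of a binary mask patch: [any gland, any background]."""
    mask_patch = np.asarray(mask_patch)
    values = np.unique(mask_patch)
    if not np.isin(values, (0, 1)).all():
        raise DimensionError(f"mask is not binary; found values {values}")
    return ImageLevelLabel(gland=int((mask_patch == 1).any()),
                           background=int((mask_patch == 0).any()))


def stitch(patch_scores: list[np.ndarray], grid: PatchGrid,
           width: int | None = None, height: int | None = None) -> np.ndarray:
    """Merge per-patch score rasters back to full size.

    ``patch_scores`` must follow :meth:`PatchGrid.positions` order.
    Overlapping pixels receive the arithmetic mean of all contributing
    patches.
    """
    width = grid.width if width is None else width
    height = grid.height if height is None else height
    if len(patch_scores) != grid.n:
        raise DimensionError(
            f"got {len(patch_scores)} patch scores for a grid of {grid.n}")
    P = grid.patch_size
    extra = patch_scores[0].shape[2:]
    acc = np.zeros((height, width) + extra, dtype=np.float64)
    cnt = np.zeros((height, width) + (1,) * len(extra), dtype=np.float64)
    for (x, y), score in zip(grid.positions(), patch_scores):
        if score.shape[:2] != (P, P):
            raise DimensionError(f"patch score shape {score.shape} != ({P},{P},...)")
        acc[y:y + P, x:x + P] += score
        cnt[y:y + P, x:x + P] += 1.0
    return acc / cnt
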