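"""Overlap metrics for binary gland segmentation.

IoU = |X∩Y| / |X∪Y| and Dice = 2|X∩Y| / (|X|+|Y|); the two are linked by
Dice = 2·IoU / (1 + IoU), which is useful both for converting published
IoU values and as an internal consistency identity.  Whole-slide
evaluation reports per-image foreground scores as mean ± standard
deviation in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, ConfigError

__all__ = ["iou", "dice", "dice_from_iou", "evaluate", "evaluate_pairs",
           "SegmentationReport"]


def _check_pair(pred: np.ndarray, true: np.ndarray):
    pred = np.asarray(pred).astype(bool)
    true = np.asarray(true).astype(bool)
    if pred.shape != true.shape:
        raise DimensionError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    return pred, true


def iou(pred_mask: np.ndarray, true_mask: np.ndarray,
        valid: np.ndarray | None = None) -> float:
    """Foreground intersection-over-union; 1.0 when both masks are empty.

    ``valid`` optionally restricts the comparison to a boolean pixel
    subset (used when pseudo-labels carry an uncertain/ignore region).
    """
    pred, true = _check_pair(pred_mask, true_mask)
    if valid is not None:
        valid = np.asarray(valid).astype(bool)
        pred, true = pred[valid], true[valid]
    inter = np.logical_and(pred, true).sum()
    union = np.logical_or(pred, true).sum()
    return 1.0 if union == 0 else float(inter) / float(union)


def dice(pred_mask: np.ndarray, true_mask: np.ndarray,
         valid: np.ndarray | None = None) -> float:
    """Sørensen–Dice coefficient; 1.0 when both masks are empty."""
    pred, true = _check_pair(pred_mask, true_mask)
    if valid is not None:
        valid = np.asarray(valid).astype(bool)
        pred, true = pred[valid], true[valid]
    inter = np.logical_and(pred, true).sum()
    total = pred.sum() + true.sum()
    return 1.0 if total == 0 else 2.0 * float(inter) / float(total)


def dice_from_iou(iou_value: float, percent_decimals: int | None = None) -> float:
    """Convert an IoU value to Dice via Dice = 2·IoU/(1+IoU).

    With ``percent_decimals`` set, returns a percentage rounded to that
    many decimals (e.g. ``dice_from_iou(0.8199, 2) == 90.1``).
    """
    if not 0.0 <= iou_value <= 1.0:
        raise ConfigError(f"IoU must be in [0,1], got {iou_value}")
    d = 2.0 * iou_value / (1.0 + iou_value)
    if percent_decimals is not None:
        return round(100.0 * d, percent_decimals)
    return d


@dataclass
class SegmentationReport:
    per_image: list[tuple[str, float, float]] = field(default_factory=list)
    mean_iou: float = 0.0   # percentages
    std_iou: float = 0.0
    mean_dice: float = 0.0
    std_dice: float = 0.0

    def to_json(self, path: str | Path):
        payload = {
            "mean_iou": self.mean_iou, "std_iou": self.std_iou,
            "mean_dice": self.mean_dice, "std_dice": self.std_dice,
            "per_image": [
                {"id": i, "iou": a, "dice": d} for i, a, d in self.per_image],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def evaluate_pairs(pairs: list[tuple[str, np.ndarray, np.ndarray]],
                   sample_std: bool = True) -> SegmentationReport:
    """Per-image foreground IoU/Dice, summarised as mean ± std in percent.

    ``sample_std`` selects the n−1 denominator (population std otherwise).
    """
    rows = [(img_id, iou(p, t), dice(p, t)) for img_id, p, t in pairs]
    ious = np.array([r[1] for r in rows], dtype=np.float64)
    dices = np.array([r[2] for r in rows], dtype=np.float64)
    ddof = 1 if (sample_std and len(rows) > 1) else 0
    return SegmentationReport(
        per_image=rows,
        mean_iou=float(100.0 * ious.mean()),
        std_iou=float(100.0 * ious.std(ddof=ddof)),
        mean_dice=float(100.0 * dices.mean()),
        std_dice=float(100.0 * dices.std(ddof=ddof)),
    )


def evaluate(pred_dir: str | Path, truth_dir: str | Path,
             sample_std: bool = True) -> SegmentationReport:
    """Evaluate stitched whole-image predictions against ground-truth masks.

    Masks are PNG files paired by stem; prediction ``foo.png`` matches
    truth ``foo.png`` (or ``foo_mask.png``).
    """
    from .synth import read_mask

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    preds = {p.stem: p for p in sorted(pred_dir.glob("*.png"))}
    truths = {}
    for p in sorted(truth_dir.glob("*.png")):
        stem = p.stem[:-5] if p.stem.endswith("_mask") else p.stem
        truths[stem] = p
    missing = sorted(set(preds) ^ set(truths))
    if missing:
        raise DimensionError(f"unpaired image ids: {missing}")
    pairs = [(stem, read_mask(preds[stem]), read_mask(truths[stem]))
             for stem in sorted(preds)]
    return evaluate_pairs(pairs, sample_std=sample_std)
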