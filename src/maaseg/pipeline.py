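"""Two-stage pipeline orchestration, configuration and run logging.

Stage 1 (CAM generation and refinement): tile whole images into 112×112
patches with stride 56, train the multi-level attention fusion classifier
on image-level labels, emit CAMs, refine them into pseudo-labels with the
affinity module.  Stage 2 (segmentation): train the pyramid-pooling
network on the pseudo-labels with the OEEM loss, infer on evaluation
tiles, stitch, and report IoU/Dice.

Every stage writes its artifacts plus a ``manifest.json`` (config hash,
wall time, outputs) into its own sub-directory; a stage whose manifest
exists with a matching config hash is skipped on resume, so deleting one
stage's directory recomputes exactly that stage.  One global seed fans
out as ``seed + stage_index`` to each stochastic stage.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields, is_dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .affinity import AffinityConfig, AffinityRefiner
from .cam import CAMTrainConfig, MAFEnsemble, MAFModel, \
    classification_accuracy, generate_cam, train_cam_stage
from .encoder import EncoderConfig
from .errors import ConfigError, PipelineError
from .metrics import evaluate
from .segmentation import PSPSegNet, SegConfig, predict_proba, train_seg_stage
from .synth import SyntheticSpec, generate_dataset, read_mask
from .tiling import compute_patch_grid, crop, derive_image_labels, stitch

__all__ = ["RunConfig", "SynthStageConfig", "TilingConfig", "EvalConfig",
           "validate_config", "run_pipeline", "desk_config", "desk_study"]

STAGES = ("synth", "tile", "train_cam", "make_cam", "refine",
          "train_seg", "infer", "eval")

# pseudo-label PNG palette: {0 → 0, gland 1 → 128, uncertain 255 → 255}
PSEUDO_ENCODE = {0: 0, 1: 128, 255: 255}


@dataclass
class SynthStageConfig:
    enabled: bool = True
    n_train: int = 24
    n_eval: int = 20
    train_width: int = 168
    train_height: int = 168
    eval_width: int = 112
    eval_height: int = 112
    glands_cycle: tuple[int, ...] = (0, 1, 2, 3)
    eval_glands_cycle: tuple[int, ...] = (1, 2)
    radius_range: tuple[int, int] = (20, 45)
    lumen_ratio: float = 0.45
    noise_sigma: float = 0.0


@dataclass
class TilingConfig:
    patch_size: int = 112
    stride: int = 56


@dataclass
class EvalConfig:
    sample_std: bool = True
    threshold: float = 0.5


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/maa"
    device: str = "cpu"
    train_images_dir: str | None = None   # external data; synthetic when None
    eval_images_dir: str | None = None
    synth: SynthStageConfig = field(default_factory=SynthStageConfig)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig.tiny)
    cam: CAMTrainConfig = field(default_factory=CAMTrainConfig)
    affinity: AffinityConfig = field(default_factory=AffinityConfig)
    segmentation: SegConfig = field(default_factory=SegConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def validate(self) -> "RunConfig":
        self.encoder.validate()
        if not 0.0 < self.affinity.beta_low < self.affinity.beta_high < 1.0:
            raise ConfigError(
                "affinity: need 0 < beta_low < beta_high < 1, got "
                f"{self.affinity.beta_low} / {self.affinity.beta_high}")
        if self.tiling.patch_size <= 0 or self.tiling.stride <= 0:
            raise ConfigError("tiling: patch_size and stride must be positive")
        if self.segmentation.oeem_scope not in ("image", "batch"):
            raise ConfigError(
                f"segmentation.oeem_scope must be image|batch, "
                f"got {self.segmentation.oeem_scope}")
        return self


def _from_mapping(cls, data: dict, path: str):
    """Build a (nested) dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s): "
                          + ", ".join(f"{path}.{k}".lstrip(".") for k in sorted(unknown)))
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = f.type if is_dataclass(f.type) else _DATACLASS_FIELDS.get((cls, name))
        if sub is not None:
            kwargs[name] = _from_mapping(sub, value, f"{path}.{name}".lstrip("."))
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_DATACLASS_FIELDS = {
    (RunConfig, "synth"): SynthStageConfig,
    (RunConfig, "tiling"): TilingConfig,
    (RunConfig, "encoder"): EncoderConfig,
    (RunConfig, "cam"): CAMTrainConfig,
    (RunConfig, "affinity"): AffinityConfig,
    (RunConfig, "segmentation"): SegConfig,
    (RunConfig, "eval"): EvalConfig,
}


def validate_config(path: str | Path | dict | None) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults.

    Unknown keys are rejected with their full key path; threshold and
    shape invariants are checked.
    """
    if path is None:
        data = {}
    elif isinstance(path, dict):
        data = path
    else:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    return _from_mapping(RunConfig, data, "").validate()


def desk_config(seed: int = 0, out_dir: str = "runs/desk") -> RunConfig:
    """The desk-scale study configuration: tiny presets and reduced
    schedules sized so the full pipeline runs in minutes on one CPU,
    with the synthetic generator in its noiseless separable setting.

    Training tiles are single patches (112×112) holding both tissue
    classes: a balanced patch gives the per-patch CAM normalisation
    reliable anchors on both sides of the thresholds, which is what the
    desk-scale refinement quality rests on (multi-patch stitching is
    exercised by the unit suite and by evaluation-time inference).
    """
    cfg = RunConfig(seed=seed, out_dir=out_dir)
    cfg.synth = SynthStageConfig(n_train=48, n_eval=20,
                                 train_width=112, train_height=112,
                                 eval_width=112, eval_height=112,
                                 glands_cycle=(0, 1, 2),
                                 eval_glands_cycle=(1, 2),
                                 radius_range=(20, 45))
    cfg.cam = CAMTrainConfig(epochs=30, batch_size=16, lr=0.002, n_models=3,
                             seed=seed)
    # walk propagation sized to the desk tiles' small CAM rasters:
    # t steps of a radius-limited walk should stay below the raster
    # diameter, or propagation stops being local
    cfg.affinity = AffinityConfig(walk_iters=2, seed=seed)
    cfg.segmentation = SegConfig(lr=0.05, batch_size=8, iterations=300,
                                 width=32, seed=seed)
    return cfg


# ---------------------------------------------------------------------------
# stage plumbing
# ---------------------------------------------------------------------------

def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Run:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.root = Path(cfg.out_dir)
        self.root.mkdir(parents=True, exist_ok=True)
        self.hash = _config_hash(cfg)
        self.log_path = self.root / "run.log"

    def log(self, **payload):
        payload.setdefault("ts", time.time())
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps(payload) + "\n")

    def stage_dir(self, stage: str) -> Path:
        return self.root / stage

    def done(self, stage: str) -> bool:
        mpath = self.stage_dir(stage) / "manifest.json"
        if not mpath.exists():
            return False
        try:
            manifest = json.loads(mpath.read_text())
        except json.JSONDecodeError:
            return False
        return manifest.get("config_hash") == self.hash and manifest.get("completed")

    def finish(self, stage: str, t0: float, **extra):
        d = self.stage_dir(stage)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {"stage": stage, "config_hash": self.hash,
                    "completed": True, "wall_time_s": time.time() - t0, **extra}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        self.log(stage=stage, wall_time_s=manifest["wall_time_s"], **extra)

    def seed_for(self, stage: str) -> int:
        return self.cfg.seed + STAGES.index(stage)


def _load_tiles(images_dir: Path) -> list[dict]:
    manifest = images_dir / "manifest.csv"
    if not manifest.exists():
        raise PipelineError(f"missing tile manifest {manifest}; run the "
                            "'synth' stage or point the config at real data")
    with open(manifest) as fh:
        return list(csv.DictReader(fh))


def _stage_synth(run: _Run):
    cfg, s = run.cfg, run.cfg.synth
    seed0 = run.seed_for("synth")
    def spec(i, width, height, glands, offset):
        return SyntheticSpec(
            seed=seed0 + offset + i, width=width, height=height,
            n_glands=glands[i % len(glands)],
            radius_range=s.radius_range, lumen_ratio=s.lumen_ratio,
            noise_sigma=s.noise_sigma)
    train_specs = [spec(i, s.train_width, s.train_height, s.glands_cycle, 0)
                   for i in range(s.n_train)]
    eval_specs = [spec(i, s.eval_width, s.eval_height, s.eval_glands_cycle, 10_000)
                  for i in range(s.n_eval)]
    d = run.stage_dir("synth")
    generate_dataset(train_specs, d / "train")
    generate_dataset(eval_specs, d / "eval")


def _stage_tile(run: _Run):
    cfg = run.cfg
    train_dir = Path(cfg.train_images_dir) if cfg.train_images_dir \
        else run.stage_dir("synth") / "train"
    records = _load_tiles(train_dir)
    d = run.stage_dir("tile")
    pdir = d / "patches"
    pdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        image = np.asarray(Image.open(rec["image_path"]).convert("RGB"))
        mask = read_mask(rec["mask_path"])
        grid = compute_patch_grid(int(rec["width"]), int(rec["height"]),
                                  cfg.tiling.patch_size, cfg.tiling.stride)
        img_patches = crop(image, grid)
        mask_patches = crop(mask, grid)
        stem = Path(rec["image_path"]).stem
        for ip, mp in zip(img_patches, mask_patches):
            label = derive_image_labels(mp.data)
            name = f"{stem}_x{ip.x}_y{ip.y}"
            Image.fromarray(ip.data).save(pdir / f"{name}.png")
            Image.fromarray(mp.data * 255).save(pdir / f"{name}_mask.png")
            rows.append({"patch": name, "image_path": str(pdir / f"{name}.png"),
                         "mask_path": str(pdir / f"{name}_mask.png"),
                         "source": stem, "x": ip.x, "y": ip.y,
                         "gland_bit": label.gland,
                         "background_bit": label.background})
    with open(d / "patches.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def _load_patches(run: _Run):
    path = run.stage_dir("tile") / "patches.csv"
    if not path.exists():
        raise PipelineError(f"missing {path}; run the 'tile' stage first")
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    images = [np.asarray(Image.open(r["image_path"]).convert("RGB")) for r in rows]
    labels = np.array([[int(r["gland_bit"]), int(r["background_bit"])]
                       for r in rows], dtype=np.float32)
    return rows, images, labels


def _stage_train_cam(run: _Run):
    cfg = run.cfg
    rows, images, labels = _load_patches(run)
    cam_cfg = replace(cfg.cam, seed=run.seed_for("train_cam"))
    model, log = train_cam_stage(images, labels, cam_cfg, cfg.encoder)
    acc = classification_accuracy(model, images, labels, class_index=0)
    d = run.stage_dir("train_cam")
    d.mkdir(parents=True, exist_ok=True)
    members = model.models if isinstance(model, MAFEnsemble) else [model]
    for k, member in enumerate(members):
        member.save(d / f"model_{k}.npz")
    (d / "train_log.json").write_text(json.dumps({**log, "gland_accuracy": acc}))
    return {"gland_accuracy": acc, "final_loss": log["loss"][-1]}


def _cam_model(run: _Run):
    d = run.stage_dir("train_cam")
    paths = sorted(d.glob("model_*.npz"))
    if not paths:
        raise PipelineError(
            f"missing {d}/model_*.npz; run the 'train_cam' stage first")
    members = [MAFModel.load(p, run.cfg.encoder, fuse_dim=run.cfg.cam.fuse_dim,
                             fuse_layers=run.cfg.cam.fuse_layers)
               for p in paths]
    return members[0] if len(members) == 1 else MAFEnsemble(members)


def _stage_make_cam(run: _Run):
    rows, images, _ = _load_patches(run)
    model = _cam_model(run)
    d = run.stage_dir("make_cam")
    d.mkdir(parents=True, exist_ok=True)
    bundle = {}
    for r, img in zip(rows, images):
        cam, fused = generate_cam(img, model)
        bundle[f"{r['patch']}::scores"] = cam.scores.astype(np.float32)
        bundle[f"{r['patch']}::raster"] = cam.raster.astype(np.float32)
        bundle[f"{r['patch']}::logits"] = cam.logits.astype(np.float32)
        bundle[f"{r['patch']}::fused"] = fused.astype(np.float32)
        preview = (np.clip(cam.scores[..., 0], 0, 1) * 255).astype(np.uint8)
        Image.fromarray(preview).save(d / f"{r['patch']}_gland.png")
    np.savez_compressed(d / "cams.npz", **bundle)


def _load_cams(run: _Run):
    path = run.stage_dir("make_cam") / "cams.npz"
    if not path.exists():
        raise PipelineError(f"missing {path}; run the 'make_cam' stage first")
    return np.load(path)


def _tile_groups(run: _Run, rows):
    """Group patch rows by source tile, in grid (row-major) order."""
    groups: dict[str, list[dict]] = {}
    for r in rows:
        groups.setdefault(r["source"], []).append(r)
    for recs in groups.values():
        recs.sort(key=lambda r: (int(r["y"]), int(r["x"])))
    return groups


def _assemble_train_tiles(run: _Run):
    """Rebuild per-tile CAM scores/features from the make_cam artifacts."""
    from .affinity import assemble_tile_cam
    from .cam import ClassActivationMap

    cfg = run.cfg
    rows, _, _ = _load_patches(run)
    blob = _load_cams(run)
    train_dir = Path(cfg.train_images_dir) if cfg.train_images_dir \
        else run.stage_dir("synth") / "train"
    tiles = []
    for source, recs in _tile_groups(run, rows).items():
        image = np.asarray(
            Image.open(train_dir / f"{source}.png").convert("RGB"))
        grid = compute_patch_grid(image.shape[1], image.shape[0],
                                  cfg.tiling.patch_size, cfg.tiling.stride)
        cams = [ClassActivationMap(scores=blob[f"{r['patch']}::scores"],
                                   logits=blob[f"{r['patch']}::logits"],
                                   raster=blob[f"{r['patch']}::raster"])
                for r in recs]
        fused = [blob[f"{r['patch']}::fused"].astype(np.float64) for r in recs]
        scores, feat, present = assemble_tile_cam(cams, fused, grid)
        tiles.append({"source": source, "recs": recs, "image": image,
                      "grid": grid, "scores": scores, "feat": feat,
                      "present": present})
    return tiles


def _fit_refiner(run: _Run):
    """Assemble the training tiles and fit the affinity refiner on them."""
    tiles = _assemble_train_tiles(run)
    aff_cfg = replace(run.cfg.affinity, seed=run.seed_for("refine"))
    refiner = AffinityRefiner(aff_cfg)
    refiner.fit([t["image"] for t in tiles], [t["scores"] for t in tiles],
                [t["feat"] for t in tiles], [t["present"] for t in tiles])
    return refiner, tiles


def _stage_refine(run: _Run):
    refiner, tiles = _fit_refiner(run)
    d = run.stage_dir("refine")
    d.mkdir(parents=True, exist_ok=True)
    scores_bundle = {}
    for t in tiles:
        out = refiner.refine(t["image"], t["scores"], t["feat"], t["present"])
        encoded = np.zeros_like(out["final_labels"])
        for value, code in PSEUDO_ENCODE.items():
            encoded[out["final_labels"] == value] = code
        Image.fromarray(encoded).save(d / f"{t['source']}_pseudo.png")
        # per-patch crops feed the segmentation stage
        for r, pp in zip(t["recs"], crop(out["final_labels"], t["grid"])):
            epp = np.zeros_like(pp.data)
            for value, code in PSEUDO_ENCODE.items():
                epp[pp.data == value] = code
            Image.fromarray(epp).save(d / f"{r['patch']}_pseudo.png")
        scores_bundle[f"{t['source']}::scores"] = \
            out["full_scores"].astype(np.float32)
    np.savez_compressed(d / "refined_scores.npz", **scores_bundle)


def _load_pseudo(run: _Run, rows):
    d = run.stage_dir("refine")
    masks = []
    for r in rows:
        path = d / f"{r['patch']}_pseudo.png"
        if not path.exists():
            raise PipelineError(f"missing {path}; run the 'refine' stage first")
        png = np.asarray(Image.open(path))
        decoded = np.full(png.shape, 255, dtype=np.uint8)
        decoded[png == 0] = 0
        decoded[png == 128] = 1
        masks.append(decoded)
    return masks


def _stage_train_seg(run: _Run):
    cfg = run.cfg
    rows, images, _ = _load_patches(run)
    pseudo = _load_pseudo(run, rows)
    seg_cfg = replace(cfg.segmentation, seed=run.seed_for("train_seg"))
    model, log = train_seg_stage(images, pseudo, seg_cfg)
    d = run.stage_dir("train_seg")
    d.mkdir(parents=True, exist_ok=True)
    model.save(d / "model.npz")
    (d / "train_log.json").write_text(json.dumps(log))
    return {"final_loss": log["loss"][-1]}


def _stage_infer(run: _Run):
    cfg = run.cfg
    seg_path = run.stage_dir("train_seg") / "model.npz"
    if not seg_path.exists():
        raise PipelineError(f"missing {seg_path}; run the 'train_seg' stage first")
    model = PSPSegNet.load(seg_path, cfg.segmentation)
    eval_dir = Path(cfg.eval_images_dir) if cfg.eval_images_dir \
        else run.stage_dir("synth") / "eval"
    records = _load_tiles(eval_dir)
    d = run.stage_dir("infer")
    d.mkdir(parents=True, exist_ok=True)
    for rec in records:
        image = np.asarray(Image.open(rec["image_path"]).convert("RGB"))
        grid = compute_patch_grid(int(rec["width"]), int(rec["height"]),
                                  cfg.tiling.patch_size, cfg.tiling.stride)
        probs = [predict_proba(model, p.data) for p in crop(image, grid)]
        full = stitch(probs, grid)
        mask = (full >= cfg.eval.threshold).astype(np.uint8)
        Image.fromarray(mask * 255).save(d / f"{Path(rec['image_path']).stem}.png")


def _stage_eval(run: _Run):
    cfg = run.cfg
    eval_dir = Path(cfg.eval_images_dir) if cfg.eval_images_dir \
        else run.stage_dir("synth") / "eval"
    pred_dir = run.stage_dir("infer")
    if not pred_dir.exists():
        raise PipelineError(f"missing {pred_dir}; run the 'infer' stage first")
    report = evaluate(pred_dir, eval_dir, sample_std=cfg.eval.sample_std)
    d = run.stage_dir("eval")
    d.mkdir(parents=True, exist_ok=True)
    report.to_json(d / "report.json")
    with open(d / "per_image.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "iou", "dice"])
        writer.writerows(report.per_image)
    return {"mean_iou": report.mean_iou, "mean_dice": report.mean_dice}


_STAGE_FN = {"synth": _stage_synth, "tile": _stage_tile,
             "train_cam": _stage_train_cam, "make_cam": _stage_make_cam,
             "refine": _stage_refine, "train_seg": _stage_train_seg,
             "infer": _stage_infer, "eval": _stage_eval}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES,
                 resume: bool = True) -> Path:
    """Execute the requested stages in order; returns the artifacts root.

    With ``resume=True`` a stage whose manifest matches the current
    config is skipped.  The eval tiles' truth masks live alongside the
    eval images, so the final report needs no extra inputs.
    """
    config.validate()
    run = _Run(config)
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "synth" and not config.synth.enabled:
            continue
        if resume and run.done(stage):
            run.log(stage=stage, skipped=True)
            continue
        t0 = time.time()
        extra = _STAGE_FN[stage](run) or {}
        run.finish(stage, t0, **extra)
    return run.root


def _label_iou(labels: np.ndarray, mask: np.ndarray) -> float:
    """Foreground IoU of a {0,1,255} label map against a binary mask,
    restricted to the certain (non-255) pixels."""
    from .metrics import iou as _iou

    valid = labels != 255
    if not valid.any():
        return 0.0
    return _iou(labels == 1, mask == 1,
                valid=None if valid.all() else valid)


def desk_study(seed: int = 0, out_dir: str = "runs/desk",
               resume: bool = True) -> dict:
    """Run the desk-scale recovery study and collect its headline numbers.

    Executes the full pipeline under :func:`desk_config`, then measures:
    stage-1 gland-bit training accuracy; the paired pseudo-label
    comparison on the evaluation tiles (foreground IoU of the refined
    pseudo-labels vs the raw thresholded CAM labels, certain pixels
    only); and the final stitched segmentation IoU/Dice.
    """
    from .affinity import assemble_tile_cam

    cfg = desk_config(seed, out_dir)
    root = run_pipeline(cfg, resume=resume)
    run = _Run(cfg)
    train_log = json.loads((root / "train_cam" / "train_log.json").read_text())

    refiner, _ = _fit_refiner(run)
    model = _cam_model(run)
    eval_dir = Path(cfg.eval_images_dir) if cfg.eval_images_dir \
        else root / "synth" / "eval"
    raw_ious, refined_ious, wins = [], [], 0
    for rec in _load_tiles(eval_dir):
        image = np.asarray(Image.open(rec["image_path"]).convert("RGB"))
        mask = read_mask(rec["mask_path"])
        grid = compute_patch_grid(int(rec["width"]), int(rec["height"]),
                                  cfg.tiling.patch_size, cfg.tiling.stride)
        cams, fused = [], []
        for p in crop(image, grid):
            c, f = generate_cam(p.data, model)
            cams.append(c)
            fused.append(f.astype(np.float64))
        scores, feat, present = assemble_tile_cam(cams, fused, grid)
        out = refiner.refine(image, scores, feat, present)
        ri = _label_iou(out["raw_labels"], mask)
        fi = _label_iou(out["final_labels"], mask)
        raw_ious.append(ri)
        refined_ious.append(fi)
        wins += int(fi >= ri)

    report = json.loads((root / "eval" / "report.json").read_text())
    return {
        "gland_accuracy": train_log["gland_accuracy"],
        "n_train_patches": len(_load_patches(run)[0]),
        "raw_pseudo_iou": float(np.mean(raw_ious)),
        "refined_pseudo_iou": float(np.mean(refined_ious)),
        "refinement_wins": wins,
        "n_eval_tiles": len(raw_ious),
        "mean_iou": report["mean_iou"],
        "std_iou": report["std_iou"],
        "mean_dice": report["mean_dice"],
        "std_dice": report["std_dice"],
    }
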