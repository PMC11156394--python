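"""Training loop, learning-rate schedule, checkpointing and evaluation.

The reference schedule is SGD with momentum 0.9, base learning rate 0.01,
weight decay 0.05, 100 epochs with a x0.1 step at epochs 80 and 90, and an
effective batch of 64 at 1280 px input.  Batches are realised as
gradient-accumulated micro-batches of one image, which preserves the
effective-batch semantics on a single CPU.  Everything (data order,
initialisation, augmentation, RoI sampling) is driven by one seed, so a
(config, seed) pair fully determines the loss trajectory.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentPolicy, online_augment
from .backbone import BackboneConfig, SwinBackbone
from .boxes import BoxSet, box_iou
from .coco_io import DetectionDataset
from .detector import CascadeConfig, PestDetector, training_losses
from .scf_fpn import SCFConfig, SCFNeck


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule; defaults follow the reference recipe."""

    base_lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.05
    epochs: int = 100
    batch_size: int = 64          # effective batch via gradient accumulation
    lr_milestones: tuple[int, ...] = (80, 90)
    lr_gamma: float = 0.1
    input_size: int = 1280
    seed: int = 0
    grad_clip: float = 10.0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if any(m >= self.epochs for m in self.lr_milestones):
            raise ValueError("lr_milestones must lie before the last epoch")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Stepped schedule: base_lr * gamma^(milestones passed)."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    steps = sum(1 for m in config.lr_milestones if m <= epoch)
    return config.base_lr * config.lr_gamma ** steps


@dataclass
class EvalResult:
    """Detection quality on a dataset at IoU-0.5 matching."""

    precision: float
    recall: float
    map50: float
    per_class_ap: np.ndarray

    def __post_init__(self):
        for v in (self.precision, self.recall, self.map50):
            if not 0.0 <= v <= 1.0:
                raise ValueError("metrics must lie in [0, 1]")


def build_detector(n_classes: int, profile: str = "tiny",
                   seed: int = 0, windows=None) -> PestDetector:
    """Assemble backbone + neck + cascade heads for a named profile.

    ``tiny`` is the CPU profile (embed 32, neck 64); ``full`` uses the
    reference widths (embed 128, neck 256, stage channels 256/512/1024).
    Per-level SCF windows are overridable for the window-size ablation.
    """
    if profile == "tiny":
        bb_cfg = BackboneConfig.tiny()
        neck_ch, hidden = 64, 128
    elif profile == "full":
        bb_cfg = BackboneConfig()
        neck_ch, hidden = 256, 256
    else:
        raise ValueError(f"unknown profile '{profile}'")
    scf_cfg = SCFConfig(neck_channels=neck_ch,
                        windows=windows or ((7, 7), (5, 5), (3, 3)))
    C = bb_cfg.embed_dim
    backbone = SwinBackbone(bb_cfg, seed=seed)
    neck = SCFNeck(in_channels=(2 * C, 4 * C, 8 * C), config=scf_cfg,
                   seed=seed + 1)
    model = PestDetector(n_classes, backbone, neck, head_hidden=hidden,
                         seed=seed + 2)
    model.profile = profile
    model.scf_windows = scf_cfg.windows
    return model


def save_checkpoint(model: PestDetector, path: str | Path) -> None:
    """Weights + a config echo sufficient to rebuild the model."""
    path = Path(path)
    meta = {"n_classes": model.n_classes,
            "profile": getattr(model, "profile", "tiny"),
            "windows": [list(w) for w in model.scf_windows]}
    state = model.state_dict()
    state["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path, seed: int = 0) -> PestDetector:
    path = Path(path)
    try:
        with np.load(path if path.suffix == ".npz" else f"{path}.npz") as f:
            state = {k: f[k] for k in f.files}
    except Exception as exc:
        raise ValueError(f"unreadable checkpoint {path}: {exc}") from exc
    if "__meta__" not in state:
        raise ValueError(f"checkpoint {path} lacks its config echo")
    meta = json.loads(state.pop("__meta__").tobytes().decode())
    model = build_detector(meta["n_classes"], meta["profile"], seed=seed,
                           windows=tuple(tuple(w) for w in meta["windows"]))
    model.load_state_dict(state)
    return model


def train(dataset: DetectionDataset, model: PestDetector, config: TrainConfig,
          *, augment_policy: AugmentPolicy | None = None,
          max_iterations: int | None = None, accum_steps: int | None = None,
          log_path: str | Path | None = None, checkpoint_path=None,
          checkpoint_every: int = 0, verbose: bool = False) -> list[dict]:
    """Optimise the detector; returns the per-iteration loss history.

    One iteration is one optimizer step over ``accum_steps`` accumulated
    single-image gradients (default: ``config.batch_size`` capped at the
    dataset size).
    """
    if dataset.n_classes != model.n_classes:
        raise ValueError(
            f"dataset has {dataset.n_classes} classes but the model head "
            f"expects {model.n_classes}")
    if len(dataset.images) == 0:
        raise ValueError("empty dataset")
    model.train()
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = nn.SGD(params, lr=config.base_lr, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    accum = accum_steps or min(config.batch_size, len(dataset.images))
    history: list[dict] = []
    log_file = open(log_path, "w") if log_path else None
    iteration = 0
    t0 = time.time()
    try:
        for epoch in range(config.epochs):
            opt.lr = lr_at_epoch(config, epoch)
            ids = list(dataset.images)
            rng.shuffle(ids)
            micro, loss_sum, parts_sum = 0, 0.0, {}
            for img_id in ids:
                image = dataset.images[img_id]
                gt_boxes, gt_labels = dataset.gt_arrays(img_id)
                if augment_policy is not None:
                    anns = dataset.annotations_for(img_id)
                    image, anns = online_augment(
                        image, anns, augment_policy,
                        rng_seed=int(rng.integers(2**31)))
                    if anns:
                        gt_boxes = np.array([a.bbox for a in anns])
                        gt_labels = np.array([a.class_id for a in anns])
                losses = training_losses(model, image, gt_boxes, gt_labels, rng)
                total = None
                for name, term in losses.items():
                    total = term if total is None else total + term
                    parts_sum[name] = parts_sum.get(name, 0.0) + float(term.data)
                total.backward()
                loss_sum += float(total.data)
                micro += 1
                if micro == accum:
                    for p in params:  # average accumulated gradients
                        if p.grad is not None:
                            p.grad /= accum
                    nn.clip_grad_norm(params, config.grad_clip)
                    opt.step()
                    opt.zero_grad()
                    rec = {"iteration": iteration, "epoch": epoch,
                           "lr": opt.lr, "loss": loss_sum / micro,
                           **{k: v / micro for k, v in parts_sum.items()}}
                    history.append(rec)
                    if log_file:
                        log_file.write(json.dumps(rec) + "\n")
                    if verbose and iteration % 10 == 0:
                        print(f"iter {iteration:5d} epoch {epoch:3d} "
                              f"loss {rec['loss']:.4f} "
                              f"({time.time() - t0:.0f}s)")
                    iteration += 1
                    micro, loss_sum, parts_sum = 0, 0.0, {}
                    if checkpoint_path and checkpoint_every \
                            and iteration % checkpoint_every == 0:
                        save_checkpoint(model, checkpoint_path)
                    if max_iterations and iteration >= max_iterations:
                        raise StopIteration
    except StopIteration:
        pass
    finally:
        if log_file:
            log_file.close()
    if checkpoint_path:
        save_checkpoint(model, checkpoint_path)
    return history


def overfit_benchmark(seed: int = 0, n_images: int = 20, n_classes: int = 3,
                      iterations: int = 200, image_size: int = 256,
                      verbose: bool = False):
    """Train the tiny profile to memorise a small synthetic set.

    Generates ``n_images`` scenes (3 instances each, balanced classes,
    40-120 px targets), trains for ``iterations`` optimizer steps
    (effective batch 2) and evaluates on the training set.  A working
    detector memorises this set to high mAP@0.5; a wiring defect anywhere
    in backbone/neck/heads/losses shows up as a low score.

    Returns (EvalResult, history, model, dataset).
    """
    from .synthetic import SceneSpec, build_dataset
    weights = tuple([1.0 / n_classes] * n_classes)
    spec = SceneSpec(width=image_size, height=image_size, n_instances=3,
                     class_weights=weights, size_range=(40, 120), seed=0)
    ds = build_dataset(n_images, spec, seed=seed)
    model = build_detector(n_classes, "tiny", seed=seed)
    cfg = TrainConfig(base_lr=0.01, weight_decay=0.0, epochs=100,
                      lr_milestones=(80, 90), batch_size=2,
                      input_size=image_size, seed=seed)
    history = train(ds, model, cfg, max_iterations=iterations,
                    accum_steps=2, verbose=verbose)
    return evaluate(ds, model), history, model, ds


# -- evaluation ------------------------------------------------------------


def _average_precision(scores: np.ndarray, is_tp: np.ndarray,
                       n_gt: int) -> float:
    """101-point interpolated AP from a scored TP/FP sequence."""
    if n_gt == 0:
        return float("nan")
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(is_tp[order])
    fp = np.cumsum(~is_tp[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        mask = recall >= r
        ap += precision[mask].max() if mask.any() else 0.0
    return ap / 101.0


def match_detections(dets: BoxSet, gt_boxes: np.ndarray,
                     iou_thr: float = 0.5) -> np.ndarray:
    """Greedy best-IoU matching in score order; each GT matched once."""
    matched_gt: set[int] = set()
    is_tp = np.zeros(len(dets), dtype=bool)
    if len(gt_boxes) == 0 or len(dets) == 0:
        return is_tp
    ious = box_iou(dets.boxes, gt_boxes)
    for i in range(len(dets)):
        free = [j for j in range(len(gt_boxes)) if j not in matched_gt]
        if not free:
            break
        j = free[int(np.argmax(ious[i, free]))]
        if ious[i, j] >= iou_thr:
            is_tp[i] = True
            matched_gt.add(j)
    return is_tp


def evaluate(dataset: DetectionDataset, model: PestDetector,
             iou_thr: float = 0.5, verbose: bool = False) -> EvalResult:
    """Precision / recall at the model's score floor and class-mean AP.

    Detections are ordered by score with a lexicographic box tie-break, so
    the result is invariant to detection ordering within equal scores.
    """
    per_class_scores: dict[int, list] = {c: [] for c in range(model.n_classes)}
    per_class_tp: dict[int, list] = {c: [] for c in range(model.n_classes)}
    n_gt = np.zeros(model.n_classes, dtype=np.int64)
    total_tp = total_det = 0
    for img_id, image in dataset.images.items():
        gt_boxes, gt_labels = dataset.gt_arrays(img_id)
        dets = model.detect(image).sorted_by_score()
        for c in range(model.n_classes):
            n_gt[c] += int((gt_labels == c).sum())
            mask = dets.labels == c
            sub = dets.select(mask)
            is_tp = match_detections(sub, gt_boxes[gt_labels == c], iou_thr)
            per_class_scores[c].extend(sub.scores)
            per_class_tp[c].extend(is_tp)
            total_tp += int(is_tp.sum())
            total_det += len(sub)
        if verbose:
            print(f"image {img_id}: {len(dets)} detections")
    aps = np.array([
        _average_precision(np.asarray(per_class_scores[c]),
                           np.asarray(per_class_tp[c], dtype=bool),
                           int(n_gt[c]))
        for c in range(model.n_classes)])
    valid = ~np.isnan(aps)
    map50 = float(aps[valid].mean()) if valid.any() else 0.0
    precision = total_tp / total_det if total_det else 0.0
    recall = total_tp / int(n_gt.sum()) if n_gt.sum() else 0.0
    return EvalResult(precision=precision, recall=recall, map50=map50,
                      per_class_ap=aps)
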