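"""Two-stage cascade detector over the SCF-FPN pyramid.

A region proposal network (RPN) scores anchors on P3-P6 and emits
class-agnostic candidate boxes.  Three refinement stages then re-classify
and re-regress the candidates at increasingly strict positive-assignment
IoU thresholds (0.5 / 0.6 / 0.7): each stage's refined boxes are the next
stage's input, so later stages train on progressively better-localised
samples.  At inference the per-class score of a final box is the average of
the three stage classifiers evaluated along the box trajectory, the final
coordinates are the stage-3 regression output (B3), and linear Soft-NMS
removes redundancy without deleting dense true positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import _tensor as T
from ._tensor import Tensor
from . import nn
from .backbone import FeatureMap
from .boxes import (BoxSet, box_iou, clip_boxes, decode_boxes, encode_boxes,
                    hard_nms, soft_nms)


@dataclass(frozen=True)
class CascadeConfig:
    """Cascade schedule and suppression settings."""

    iou_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7)
    soft_nms_nt: float = 0.5
    score_floor: float = 0.05
    stage_loss_weights: tuple[float, ...] = (1.0, 0.5, 0.25)
    score_mode: str = "trajectory"  # or "final_boxes"

    def __post_init__(self):
        t = self.iou_thresholds
        if any(not 0 < x < 1 for x in t) or any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError("iou_thresholds must be strictly increasing in (0,1)")
        if len(self.stage_loss_weights) != len(t):
            raise ValueError("one loss weight per stage required")
        if self.score_mode not in ("trajectory", "final_boxes"):
            raise ValueError("score_mode must be 'trajectory' or 'final_boxes'")

    @property
    def num_stages(self) -> int:
        return len(self.iou_thresholds)


@dataclass
class StageOutputs:
    """Per-stage classifier distributions and refined boxes."""

    C: list[np.ndarray]  # per stage: (N, K+1) probabilities
    B: list[np.ndarray]  # per stage: (N, 4) refined boxes

    def averaged_scores(self) -> np.ndarray:
        return np.mean(self.C, axis=0)


# -- anchors ---------------------------------------------------------------

ANCHOR_RATIOS = (0.5, 1.0, 2.0)
ANCHOR_SCALE = 4.0  # base anchor side = scale * stride


def generate_anchors(h: int, w: int, stride: int) -> np.ndarray:
    """(h*w*A, 4) anchors centred on the feature grid, A = len(ratios)."""
    base = ANCHOR_SCALE * stride
    ws = np.array([base / np.sqrt(r) for r in ANCHOR_RATIOS])
    hs = np.array([base * np.sqrt(r) for r in ANCHOR_RATIOS])
    cx = (np.arange(w) + 0.5) * stride
    cy = (np.arange(h) + 0.5) * stride
    cy, cx = np.meshgrid(cy, cx, indexing="ij")
    ctr = np.stack([cx, cy], axis=-1).reshape(-1, 1, 2)
    half = np.stack([ws, hs], axis=-1) / 2.0
    boxes = np.concatenate([ctr - half, ctr + half], axis=-1)
    return boxes.reshape(-1, 4)


# -- assignment ------------------------------------------------------------


def assign_stage_targets(proposals: np.ndarray, gt_boxes: np.ndarray,
                         gt_labels: np.ndarray, iou_threshold: float
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stage assignment: positive iff max IoU over GT >= threshold.

    Returns (labels, matched_gt_index, max_iou); background proposals get
    label -1 and match -1.
    """
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must lie in (0, 1)")
    n = len(proposals)
    labels = np.full(n, -1, dtype=np.int64)
    match = np.full(n, -1, dtype=np.int64)
    if len(gt_boxes) == 0 or n == 0:
        return labels, match, np.zeros(n)
    ious = box_iou(proposals, gt_boxes)
    best = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best]
    pos = best_iou >= iou_threshold
    labels[pos] = gt_labels[best[pos]]
    match[pos] = best[pos]
    return labels, match, best_iou


def assign_rpn_targets(anchors: np.ndarray, gt_boxes: np.ndarray,
                       pos_iou: float = 0.6, neg_iou: float = 0.3
                       ) -> tuple[np.ndarray, np.ndarray]:
    """RPN anchor assignment: 1 positive, 0 negative, -1 ignored.

    Anchors with IoU >= pos_iou are positive, the best anchor for every GT
    box is forced positive, IoU < neg_iou is negative.
    """
    n = len(anchors)
    labels = np.full(n, -1, dtype=np.int64)
    match = np.full(n, -1, dtype=np.int64)
    if len(gt_boxes) == 0:
        labels[:] = 0
        return labels, match
    ious = box_iou(anchors, gt_boxes)
    best = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best]
    labels[best_iou < neg_iou] = 0
    pos = best_iou >= pos_iou
    labels[pos] = 1
    match[pos] = best[pos]
    # guarantee every GT owns its best-overlap anchor
    forced = ious.argmax(axis=0)
    labels[forced] = 1
    match[forced] = np.arange(len(gt_boxes))
    return labels, match


# -- RoI feature extraction ------------------------------------------------


def roi_align(feat: Tensor, boxes: np.ndarray, stride: int,
              out_size: int = 7) -> Tensor:
    """Aligned 7x7 pooling: bilinear sampling at bin centres.

    One sample per bin; boxes are image-pixel coordinates.
    """
    H, W, C = feat.shape
    n = len(boxes)
    b = boxes / stride
    xs = np.linspace(0, 1, 2 * out_size + 1)[1::2]  # bin centres in [0,1]
    gx = b[:, 0:1] + (b[:, 2:3] - b[:, 0:1]) * xs[None, :]  # (n, S)
    gy = b[:, 1:2] + (b[:, 3:4] - b[:, 1:2]) * xs[None, :]
    gx = np.clip(gx - 0.5, 0, W - 1)
    gy = np.clip(gy - 0.5, 0, H - 1)
    x0 = np.floor(gx).astype(np.int64)
    y0 = np.floor(gy).astype(np.int64)
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    fx = (gx - x0).astype(np.float32)
    fy = (gy - y0).astype(np.float32)
    # broadcast to (n, S, S) index grids
    Y0 = np.broadcast_to(y0[:, :, None], (n, out_size, out_size))
    Y1 = np.broadcast_to(y1[:, :, None], (n, out_size, out_size))
    X0 = np.broadcast_to(x0[:, None, :], (n, out_size, out_size))
    X1 = np.broadcast_to(x1[:, None, :], (n, out_size, out_size))
    wy1 = np.broadcast_to(fy[:, :, None], (n, out_size, out_size))[..., None]
    wx1 = np.broadcast_to(fx[:, None, :], (n, out_size, out_size))[..., None]
    wy0, wx0 = 1.0 - wy1, 1.0 - wx1
    v00 = feat[Y0, X0] * Tensor(wy0 * wx0)
    v01 = feat[Y0, X1] * Tensor(wy0 * wx1)
    v10 = feat[Y1, X0] * Tensor(wy1 * wx0)
    v11 = feat[Y1, X1] * Tensor(wy1 * wx1)
    return v00 + v01 + v10 + v11  # (n, S, S, C)


def assign_levels(boxes: np.ndarray, num_levels: int = 4) -> np.ndarray:
    """Map each box to a pyramid level by scale (0 = stride-8 level)."""
    area = np.clip((boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]),
                   1e-6, None)
    k = np.floor(np.log2(np.sqrt(area) / 56.0))
    return np.clip(k, 0, num_levels - 1).astype(np.int64) + 0


def pool_pyramid(pyramid: tuple[FeatureMap, ...], boxes: np.ndarray,
                 out_size: int = 7) -> Tensor:
    """RoI-align every box on its scale-assigned level; order preserved."""
    levels = assign_levels(boxes, len(pyramid))
    C = pyramid[0].channels
    pieces, orders = [], []
    for lvl, fmap in enumerate(pyramid):
        idx = np.flatnonzero(levels == lvl)
        if idx.size == 0:
            continue
        pieces.append(roi_align(fmap.data, boxes[idx], fmap.stride, out_size))
        orders.append(idx)
    pooled = T.concatenate(pieces, axis=0) if len(pieces) > 1 else pieces[0]
    order = np.concatenate(orders)
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return pooled[inv].reshape(len(boxes), out_size * out_size * C)


# -- network heads ---------------------------------------------------------


class RPNHead(nn.Module):
    """Shared 3x3 conv tower + objectness / box-delta predictors."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        A = len(ANCHOR_RATIOS)
        self.conv = nn.Conv2d(channels, channels, 3, rng)
        self.cls = nn.Conv2d(channels, A, 1, rng)
        self.reg = nn.Conv2d(channels, 4 * A, 1, rng)

    def forward(self, fmap: Tensor) -> tuple[Tensor, Tensor]:
        h = T.relu(self.conv(fmap))
        return self.cls(h), self.reg(h)


class RoIHead(nn.Module):
    """Two-fc head with a (K+1)-way classifier and class-agnostic regressor."""

    def __init__(self, in_dim: int, hidden: int, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, hidden, rng)
        self.cls = nn.Linear(hidden, n_classes + 1, rng)
        self.reg = nn.Linear(hidden, 4, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = T.relu(self.fc2(T.relu(self.fc1(x))))
        return self.cls(h), self.reg(h)


# stage-wise delta normalisation tightens as boxes get better localised
STAGE_STDS = ((0.1, 0.1, 0.2, 0.2), (0.05, 0.05, 0.1, 0.1),
              (0.033, 0.033, 0.067, 0.067))


class PestDetector(nn.Module):
    """Backbone + SCF-FPN + RPN + cascade heads, end to end."""

    def __init__(self, n_classes: int, backbone, neck,
                 cascade: CascadeConfig = CascadeConfig(),
                 head_hidden: int = 256, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed + 101)
        self.n_classes = n_classes
        self.cascade = cascade
        self.backbone = backbone
        self.neck = neck
        C = neck.config.neck_channels
        self.rpn = RPNHead(C, rng)
        self.heads = [RoIHead(7 * 7 * C, head_hidden, n_classes, rng)
                      for _ in range(cascade.num_stages)]

    # -- shared forward pieces --------------------------------------------

    def pyramid(self, image: np.ndarray) -> tuple[FeatureMap, ...]:
        feats = self.backbone(image)
        return self.neck(feats)

    def rpn_outputs(self, pyramid) -> list[tuple[Tensor, Tensor, np.ndarray]]:
        """Per level: (objectness logits, deltas, anchors)."""
        outs = []
        for fmap in pyramid:
            logits, deltas = self.rpn(fmap.data)
            h, w = fmap.shape[:2]
            anchors = generate_anchors(h, w, fmap.stride)
            outs.append((logits.reshape(h * w * len(ANCHOR_RATIOS)),
                         deltas.reshape(h * w * len(ANCHOR_RATIOS), 4),
                         anchors))
        return outs

    def propose(self, rpn_outs, image_size: tuple[int, int],
                pre_nms: int = 400, post_nms: int = 100,
                nms_iou: float = 0.7, min_size: float = 2.0) -> np.ndarray:
        """Decode, clip and NMS-filter proposals (no gradient flows here)."""
        H, W = image_size
        all_boxes, all_scores = [], []
        for logits, deltas, anchors in rpn_outs:
            scores = expit(logits.data)
            k = min(pre_nms, len(scores))
            top = np.argpartition(-scores, k - 1)[:k]
            boxes = decode_boxes(anchors[top], deltas.data[top])
            boxes = clip_boxes(boxes, W, H)
            ok = ((boxes[:, 2] - boxes[:, 0] >= min_size)
                  & (boxes[:, 3] - boxes[:, 1] >= min_size))
            boxes, sc = boxes[ok], scores[top][ok]
            if len(boxes) == 0:
                continue
            keep = hard_nms(boxes, sc, nms_iou)[:post_nms]
            all_boxes.append(boxes[keep])
            all_scores.append(sc[keep])
        if not all_boxes:
            return np.zeros((0, 4))
        boxes = np.concatenate(all_boxes)
        scores = np.concatenate(all_scores)
        keep = np.argsort(-scores, kind="stable")[:post_nms]
        return boxes[keep]

    def rpn_propose(self, pyramid, image_size: tuple[int, int],
                    **kw) -> BoxSet:
        """Class-agnostic proposal boxes with objectness scores."""
        if not pyramid:
            raise ValueError("empty pyramid")
        outs = self.rpn_outputs(pyramid)
        boxes = self.propose(outs, image_size, **kw)
        return BoxSet(boxes, np.ones(len(boxes)),
                      np.zeros(len(boxes), dtype=np.int64))

    def cascade_forward(self, pyramid, proposals: np.ndarray,
                        image_size: tuple[int, int]
                        ) -> tuple[StageOutputs, BoxSet]:
        """Run the refinement cascade; final boxes are B3, final scores the
        C1..C3 average, assembled per class before suppression."""
        H, W = image_size
        boxes = proposals
        C_list, B_list = [], []
        for s, head in enumerate(self.heads):
            feats = pool_pyramid(pyramid, boxes)
            logits, deltas = head(feats)
            probs = T.softmax(logits, axis=-1).data
            refined = decode_boxes(boxes, deltas.data, stds=STAGE_STDS[s])
            refined = clip_boxes(refined, W, H)
            # guard against collapsed boxes from an untrained regressor
            refined[:, 2] = np.maximum(refined[:, 2], refined[:, 0] + 1e-3)
            refined[:, 3] = np.maximum(refined[:, 3], refined[:, 1] + 1e-3)
            C_list.append(probs)
            B_list.append(refined)
            boxes = refined
        if self.cascade.score_mode == "final_boxes":
            feats = pool_pyramid(pyramid, B_list[-1])
            C_list = []
            for head in self.heads:
                logits, _ = head(feats)
                C_list.append(T.softmax(logits, axis=-1).data)
        stage_out = StageOutputs(C=C_list, B=B_list)
        avg = stage_out.averaged_scores()          # (N, K+1)
        fg = avg[:, :-1]                           # background is last column
        n = len(proposals)
        labels = fg.argmax(axis=1) if n else np.zeros(0, dtype=np.int64)
        scores = fg.max(axis=1) if n else np.zeros(0)
        final = BoxSet(B_list[-1] if n else np.zeros((0, 4)), scores, labels)
        return stage_out, final

    def detect(self, image: np.ndarray) -> BoxSet:
        """Full pipeline on one image; deterministic in eval mode."""
        self.eval()
        H, W = image.shape[:2]
        with T.no_grad():
            pyr = self.pyramid(image)
            proposals = self.rpn_propose(pyr, (H, W)).boxes
            if len(proposals) == 0:
                return BoxSet.empty()
            _, final = self.cascade_forward(pyr, proposals, (H, W))
        return soft_nms(final, nt=self.cascade.soft_nms_nt,
                        score_floor=self.cascade.score_floor)


def detect(image: np.ndarray, model: PestDetector,
           config: CascadeConfig | None = None) -> BoxSet:
    """Functional entry point; optionally override the cascade config."""
    if config is not None:
        model.cascade = config
    return model.detect(image)


# -- losses ----------------------------------------------------------------


def _abs(x: Tensor) -> Tensor:
    return T.relu(x) + T.relu(-x)


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Huber-style box regression loss, mean over elements."""
    d = pred - Tensor(target)
    a = _abs(d)
    quad = (a.data < beta).astype(np.float32)
    loss = Tensor(quad) * (d * d) * (0.5 / beta) + Tensor(1 - quad) * (a - 0.5 * beta)
    return loss.mean()


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on raw logits, mean."""
    y = Tensor(targets.astype(np.float32))
    loss = T.relu(logits) - logits * y + T.log(T.exp(-_abs(logits)) + 1.0)
    return loss.mean()


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Softmax cross-entropy, mean over rows."""
    m = logits.max(axis=-1, keepdims=True)
    lse = T.log(T.exp(logits - m).sum(axis=-1, keepdims=True)) + m
    logp = logits - lse
    picked = logp[np.arange(len(targets)), targets.astype(np.int64)]
    return -picked.mean()


def _sample(idx_pos: np.ndarray, idx_neg: np.ndarray, total: int,
            pos_fraction: float, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray]:
    n_pos = min(len(idx_pos), int(total * pos_fraction))
    n_neg = min(len(idx_neg), total - n_pos)
    pos = rng.choice(idx_pos, n_pos, replace=False) if n_pos else idx_pos[:0]
    neg = rng.choice(idx_neg, n_neg, replace=False) if n_neg else idx_neg[:0]
    return pos, neg


def rpn_loss(rpn_outs, gt_boxes: np.ndarray, rng: np.random.Generator,
             batch: int = 128) -> Tensor:
    """Sampled objectness BCE + smooth-L1 on positive anchor deltas."""
    logits = T.concatenate([o[0] for o in rpn_outs], axis=0)
    deltas = T.concatenate([o[1] for o in rpn_outs], axis=0)
    anchors = np.concatenate([o[2] for o in rpn_outs], axis=0)
    labels, match = assign_rpn_targets(anchors, gt_boxes)
    pos, neg = _sample(np.flatnonzero(labels == 1),
                       np.flatnonzero(labels == 0), batch, 0.5, rng)
    sel = np.concatenate([pos, neg])
    cls_loss = bce_with_logits(logits[sel], (labels[sel] == 1))
    if len(pos):
        targets = encode_boxes(anchors[pos], gt_boxes[match[pos]])
        reg_loss = smooth_l1(deltas[pos], targets.astype(np.float32))
    else:
        reg_loss = Tensor(0.0)
    return cls_loss + reg_loss


def training_losses(model: PestDetector, image: np.ndarray,
                    gt_boxes: np.ndarray, gt_labels: np.ndarray,
                    rng: np.random.Generator, rois_per_stage: int = 32
                    ) -> dict[str, Tensor]:
    """All loss terms for one image (RPN + the three cascade stages).

    Ground-truth boxes are appended to the stage-1 proposals so positives
    exist from the first iteration on; each stage samples a class-balanced
    RoI batch at its own IoU threshold and re-feeds its refined boxes to
    the next stage.
    """
    H, W = image.shape[:2]
    pyr = model.pyramid(image)
    rpn_outs = model.rpn_outputs(pyr)
    losses = {"rpn": rpn_loss(rpn_outs, gt_boxes, rng)}
    boxes = model.propose(rpn_outs, (H, W))
    if len(gt_boxes):
        boxes = np.concatenate([boxes, gt_boxes], axis=0)
    for s, head in enumerate(model.heads):
        thr = model.cascade.iou_thresholds[s]
        labels, match, _ = assign_stage_targets(boxes, gt_boxes, gt_labels, thr)
        pos, neg = _sample(np.flatnonzero(labels >= 0),
                           np.flatnonzero(labels < 0), rois_per_stage,
                           0.5, rng)
        sel = np.concatenate([pos, neg])
        if len(sel) == 0:
            break
        feats = pool_pyramid(pyr, boxes[sel])
        logits, deltas = head(feats)
        # background class index = n_classes
        cls_targets = np.where(labels[sel] >= 0, labels[sel], model.n_classes)
        w = model.cascade.stage_loss_weights[s]
        losses[f"stage{s + 1}_cls"] = cross_entropy(logits, cls_targets) * w
        if len(pos):
            pos_in_sel = np.arange(len(pos))
            tgt = encode_boxes(boxes[pos], gt_boxes[match[pos]],
                               stds=STAGE_STDS[s]).astype(np.float32)
            losses[f"stage{s + 1}_reg"] = smooth_l1(deltas[pos_in_sel], tgt) * w
        # refine all boxes for the next stage without gradient flow
        with T.no_grad():
            feats_all = pool_pyramid(pyr, boxes)
            _, deltas_all = head(feats_all)
        refined = decode_boxes(boxes, deltas_all.data, stds=STAGE_STDS[s])
        refined = clip_boxes(refined, W, H)
        refined[:, 2] = np.maximum(refined[:, 2], refined[:, 0] + 1e-3)
        refined[:, 3] = np.maximum(refined[:, 3], refined[:, 1] + 1e-3)
        boxes = refined
        if len(gt_boxes):
            boxes = np.concatenate([boxes, gt_boxes], axis=0)
    return losses
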