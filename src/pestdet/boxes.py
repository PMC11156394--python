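"""Axis-aligned box arithmetic: IoU, NMS variants, anchor coding.

Boxes are (x1, y1, x2, y2) in continuous 0-based pixel coordinates with
x2 > x1, y2 > y1 (corner convention).  Conversion to the COCO (x, y, w, h)
dialect happens only at JSON serialisation, in :mod:`pestdet.coco_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BoxSet:
    """Scored, class-labelled boxes in image pixel coordinates.

    ``boxes`` is (N, 4) float, ``scores`` (N,) in [0, 1], ``labels`` (N,) int.
    """

    boxes: np.ndarray
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        n = len(self.boxes)
        if len(self.scores) != n or len(self.labels) != n:
            raise ValueError("boxes/scores/labels lengths differ")
        if n and (np.any(self.boxes[:, 2] <= self.boxes[:, 0])
                  or np.any(self.boxes[:, 3] <= self.boxes[:, 1])):
            raise ValueError("degenerate box (x2<=x1 or y2<=y1)")

    def __len__(self) -> int:
        return len(self.boxes)

    @classmethod
    def empty(cls) -> "BoxSet":
        return cls(np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=np.int64))

    def select(self, idx) -> "BoxSet":
        return BoxSet(self.boxes[idx], self.scores[idx], self.labels[idx])

    def sorted_by_score(self) -> "BoxSet":
        # deterministic tie-break: score desc, then box coords lexicographically
        order = np.lexsort((self.boxes[:, 3], self.boxes[:, 2],
                            self.boxes[:, 1], self.boxes[:, 0], -self.scores))
        return self.select(order)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return float(inter / union)


def box_iou(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU matrix, shape (len(a), len(b))."""
    boxes_a = np.asarray(boxes_a, dtype=np.float64).reshape(-1, 4)
    boxes_b = np.asarray(boxes_b, dtype=np.float64).reshape(-1, 4)
    iw = (np.minimum(boxes_a[:, None, 2], boxes_b[None, :, 2])
          - np.maximum(boxes_a[:, None, 0], boxes_b[None, :, 0]))
    ih = (np.minimum(boxes_a[:, None, 3], boxes_b[None, :, 3])
          - np.maximum(boxes_a[:, None, 1], boxes_b[None, :, 1]))
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = ((boxes_a[:, 2] - boxes_a[:, 0])
              * (boxes_a[:, 3] - boxes_a[:, 1]))[:, None]
    area_b = ((boxes_b[:, 2] - boxes_b[:, 0])
              * (boxes_b[:, 3] - boxes_b[:, 1]))[None, :]
    union = area_a + area_b - inter
    return np.where(union > 0, inter / union, 0.0)


def _soft_nms_single_class(boxes, scores, nt, score_floor):
    """Greedy linear-decay suppression on one class.

    Repeatedly freezes the current max-score box M and rescales every
    remaining score s_i to s_i * (1 - IoU(M, b_i)) when IoU(M, b_i) >= N_t,
    leaving it untouched otherwise.
    """
    boxes = boxes.copy()
    scores = scores.copy()
    keep_boxes, keep_scores = [], []
    alive = np.ones(len(boxes), dtype=bool)
    while alive.any():
        live_idx = np.flatnonzero(alive)
        m = live_idx[np.argmax(scores[live_idx])]
        keep_boxes.append(boxes[m])
        keep_scores.append(scores[m])
        alive[m] = False
        rest = np.flatnonzero(alive)
        if rest.size == 0:
            break
        ious = box_iou(boxes[m][None], boxes[rest])[0]
        decay = np.where(ious >= nt, 1.0 - ious, 1.0)
        scores[rest] *= decay
    keep_boxes = np.array(keep_boxes).reshape(-1, 4)
    keep_scores = np.array(keep_scores)
    mask = keep_scores >= score_floor
    return keep_boxes[mask], keep_scores[mask]


def soft_nms(dets: BoxSet, nt: float = 0.5, score_floor: float = 0.05) -> BoxSet:
    """Linear Soft-NMS, applied per class independently.

    Overlapping boxes are down-weighted rather than removed: a box whose
    overlap with the current best box reaches ``nt`` has its score multiplied
    by (1 - IoU), so dense true positives survive with reduced confidence.
    Boxes falling below ``score_floor`` are dropped at the end.  The result
    is sorted by descending score.
    """
    if len(dets) == 0:
        return BoxSet.empty()
    out_boxes, out_scores, out_labels = [], [], []
    for cls in np.unique(dets.labels):
        mask = dets.labels == cls
        kb, ks = _soft_nms_single_class(dets.boxes[mask], dets.scores[mask],
                                        nt, score_floor)
        out_boxes.append(kb)
        out_scores.append(ks)
        out_labels.append(np.full(len(kb), cls, dtype=np.int64))
    result = BoxSet(np.concatenate(out_boxes), np.concatenate(out_scores),
                    np.concatenate(out_labels)) if out_boxes else BoxSet.empty()
    return result.sorted_by_score()


def hard_nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Classic greedy NMS; returns kept indices sorted by descending score."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        m = order[0]
        keep.append(m)
        if order.size == 1:
            break
        ious = box_iou(boxes[m][None], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_threshold]
    return np.asarray(keep, dtype=np.int64)


def clip_boxes(boxes: np.ndarray, width: float, height: float) -> np.ndarray:
    out = boxes.copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0, width)
    out[:, 1::2] = np.clip(out[:, 1::2], 0, height)
    return out


# -- anchor delta coding (Faster R-CNN parameterisation) -------------------


def encode_boxes(anchors: np.ndarray, boxes: np.ndarray,
                 stds=(0.1, 0.1, 0.2, 0.2)) -> np.ndarray:
    """Encode target boxes as (dx, dy, dw, dh) deltas relative to anchors."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    bw = boxes[:, 2] - boxes[:, 0]
    bh = boxes[:, 3] - boxes[:, 1]
    bx = boxes[:, 0] + 0.5 * bw
    by = boxes[:, 1] + 0.5 * bh
    deltas = np.stack([(bx - ax) / aw, (by - ay) / ah,
                       np.log(bw / aw), np.log(bh / ah)], axis=1)
    return deltas / np.asarray(stds)


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray,
                 stds=(0.1, 0.1, 0.2, 0.2)) -> np.ndarray:
    """Invert :func:`encode_boxes`; zero deltas return the anchors exactly."""
    deltas = deltas * np.asarray(stds)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    # clamp log-scale deltas to avoid overflow from untrained heads
    dw = np.clip(deltas[:, 2], -4.0, 4.0)
    dh = np.clip(deltas[:, 3], -4.0, 4.0)
    cx = ax + deltas[:, 0] * aw
    cy = ay + deltas[:, 1] * ah
    w = aw * np.exp(dw)
    h = ah * np.exp(dh)
    return np.stack([cx - 0.5 * w, cy - 0.5 * h,
                     cx + 0.5 * w, cy + 0.5 * h], axis=1)
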