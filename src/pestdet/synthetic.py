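"""Synthetic pest-scene generation with exact ground truth.

Scenes emulate the data regime of small-object field photography: textured
soil/foliage backgrounds with multi-scale, multi-class "insect" blobs whose
class identity is encoded in hue, body aspect ratio and appendage count, so
that a small detector can genuinely learn to separate the classes.  Severe
class imbalance is modelled by :func:`make_imbalanced_counts`, which
interpolates a head-class count down to a tail-class count the way real
pest surveys skew (a few hundred instances of a common species against a
handful of a rare one).

Everything is a pure function of (spec, seed): identical inputs give
bitwise-identical images and boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import json

import numpy as np
from PIL import Image, ImageDraw
from scipy.ndimage import gaussian_filter

from .boxes import box_iou
from .coco_io import AnnotationRecord, DetectionDataset


class InfeasibleSceneError(RuntimeError):
    """Raised when instance placement fails within the retry budget."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``class_weights`` is the sampling distribution over classes;
    ``size_range`` bounds the instance box long side in pixels;
    ``density_mode`` permits overlapping clusters (otherwise pairwise box
    IoU is capped at 0.2).
    """

    width: int = 256
    height: int = 256
    n_instances: int = 3
    class_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    size_range: tuple[int, int] = (40, 120)
    density_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValueError("scene dimensions must be >= 64")
        if self.n_instances < 0:
            raise ValueError("n_instances must be >= 0")
        w = np.asarray(self.class_weights, dtype=np.float64)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("class_weights must be a probability vector")
        lo, hi = self.size_range
        if lo < 4 or hi < lo:
            raise ValueError("size_range must satisfy 4 <= min <= max")

    @property
    def n_classes(self) -> int:
        return len(self.class_weights)


# -- class appearance ------------------------------------------------------

_GOLDEN = 0.618033988749895


def class_style(class_id: int) -> dict:
    """Deterministic per-class appearance: hue, aspect and leg count."""
    hue = (0.05 + class_id * _GOLDEN) % 1.0
    aspect = 1.3 + 0.3 * (class_id % 5)          # body length / width
    legs = 2 + class_id % 4                      # leg pairs
    return {"hue": hue, "aspect": aspect, "legs": legs}


def _hsv_to_rgb(h: float, s: float, v: float) -> tuple[int, int, int]:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return tuple(int(round(255 * c)) for c in rgb)


def _render_insect(class_id: int, long_side: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw one insect blob as an RGBA tile whose long side == long_side."""
    style = class_style(class_id)
    scale = 6  # draw large, then shrink: crisper strokes at small sizes
    L = 48 * scale
    W = int(L / style["aspect"])
    margin = L // 3
    tile = Image.new("RGBA", (L + 2 * margin, W + 2 * margin), (0, 0, 0, 0))
    draw = ImageDraw.Draw(tile)
    cx, cy = tile.width // 2, tile.height // 2
    body = _hsv_to_rgb(style["hue"], 0.75, 0.8)
    dark = _hsv_to_rgb(style["hue"], 0.85, 0.45)
    # legs: strokes fanning out from the body
    n_legs = style["legs"]
    for k in range(n_legs):
        frac = (k + 0.5) / n_legs
        x = cx - L // 2 + int(frac * L)
        leg_len = W // 2 + margin // 2
        for side in (-1, 1):
            sway = int((rng.uniform(-0.2, 0.2)) * leg_len)
            draw.line([(x, cy), (x + sway, cy + side * (W // 2 + leg_len))],
                      fill=dark, width=3 * scale)
    # body ellipse + head
    draw.ellipse([cx - L // 2, cy - W // 2, cx + L // 2, cy + W // 2], fill=body)
    head_r = W // 3
    draw.ellipse([cx + L // 2 - head_r, cy - head_r,
                  cx + L // 2 + head_r, cy + head_r], fill=dark)
    # dorsal stripe, helps separate similar hues
    draw.ellipse([cx - L // 4, cy - W // 8, cx + L // 4, cy + W // 8], fill=dark)
    arr = np.asarray(tile)
    ys, xs = np.nonzero(arr[:, :, 3])
    arr = arr[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    # random in-plane orientation, then exact long-side resize
    angle = float(rng.uniform(0, 360))
    tile = Image.fromarray(arr).rotate(angle, expand=True, resample=Image.BILINEAR)
    arr = np.asarray(tile)
    ys, xs = np.nonzero(arr[:, :, 3] > 8)
    arr = arr[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    h, w = arr.shape[:2]
    if w >= h:
        new_w, new_h = long_side, max(3, round(h * long_side / w))
    else:
        new_h, new_w = long_side, max(3, round(w * long_side / h))
    tile = Image.fromarray(arr).resize((new_w, new_h), Image.BILINEAR)
    return np.asarray(tile)


def _render_background(width: int, height: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Soil/foliage-like texture: smoothed low-frequency noise + grain."""
    base = np.array([96, 110, 70], dtype=np.float64)  # muted green-brown
    coarse = rng.normal(0, 28, size=(height // 16 + 1, width // 16 + 1, 3))
    coarse = np.repeat(np.repeat(coarse, 16, axis=0), 16, axis=1)
    coarse = coarse[:height, :width]
    coarse = gaussian_filter(coarse, sigma=(8, 8, 0))
    grain = rng.normal(0, 6, size=(height, width, 3))
    img = base + coarse + grain
    return np.clip(img, 0, 255).astype(np.uint8)


def _paste_rgba(canvas: np.ndarray, tile: np.ndarray, x: int, y: int) -> None:
    h, w = tile.shape[:2]
    region = canvas[y:y + h, x:x + w].astype(np.float64)
    alpha = tile[:, :, 3:4].astype(np.float64) / 255.0
    blended = alpha * tile[:, :, :3].astype(np.float64) + (1 - alpha) * region
    canvas[y:y + h, x:x + w] = np.clip(np.round(blended), 0, 255).astype(np.uint8)


_RETRY_BUDGET = 100  # placement attempts per instance
_OVERLAP_CAP = 0.2   # pairwise box IoU cap outside density mode


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, list[AnnotationRecord]]:
    """Render one scene; returns (uint8 RGB image, annotations).

    The first RNG draw is the class-id vector
    ``rng.choice(n_classes, size=n_instances, p=class_weights)`` — a stable
    contract that lets callers replay the class composition independently.
    """
    rng = np.random.default_rng(spec.seed)
    class_ids = rng.choice(spec.n_classes, size=spec.n_instances,
                           p=np.asarray(spec.class_weights))
    image = _render_background(spec.width, spec.height, rng)
    annotations: list[AnnotationRecord] = []
    placed: list[tuple[float, float, float, float]] = []
    for idx, class_id in enumerate(class_ids):
        long_side = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
        tile = _render_insect(int(class_id), long_side, rng)
        h, w = tile.shape[:2]
        if w > spec.width or h > spec.height:
            raise InfeasibleSceneError(
                f"instance {idx} ({w}x{h}) larger than scene")
        for _ in range(_RETRY_BUDGET):
            x = int(rng.integers(0, spec.width - w + 1))
            y = int(rng.integers(0, spec.height - h + 1))
            box = (float(x), float(y), float(x + w), float(y + h))
            if spec.density_mode or not placed:
                break
            ious = box_iou(np.array([box]), np.array(placed))[0]
            if ious.max() <= _OVERLAP_CAP:
                break
        else:
            raise InfeasibleSceneError(
                f"could not place instance {idx} within {_RETRY_BUDGET} tries; "
                "reduce n_instances or enable density_mode")
        _paste_rgba(image, tile, x, y)
        placed.append(box)
        annotations.append(AnnotationRecord(image_id=0, class_id=int(class_id),
                                            bbox=box))
    return image, annotations


def dataset_seeds(seed: int, n_images: int) -> np.ndarray:
    """Per-image scene seeds derived from one master seed (replayable)."""
    return np.random.SeedSequence(seed).generate_state(n_images)


def build_dataset(n_images: int, spec_template: SceneSpec,
                  seed: int) -> DetectionDataset:
    """Generate an in-memory dataset of ``n_images`` scenes."""
    seeds = dataset_seeds(seed, n_images)
    ds = DetectionDataset(n_classes=spec_template.n_classes)
    for i in range(n_images):
        spec = replace(spec_template, seed=int(seeds[i]))
        image, anns = generate_scene(spec)
        ds.add_image(image, anns, image_id=i)
    return ds


def generate_dataset(n_images: int, spec_template: SceneSpec,
                     out_dir: str | Path, seed: int) -> DetectionDataset:
    """Generate scenes and write images + COCO JSON + a generation sidecar."""
    ds = build_dataset(n_images, spec_template, seed)
    out_dir = Path(out_dir)
    ds.save(out_dir)
    sidecar = {
        "n_images": n_images, "seed": seed,
        "spec": {
            "width": spec_template.width, "height": spec_template.height,
            "n_instances": spec_template.n_instances,
            "class_weights": list(spec_template.class_weights),
            "size_range": list(spec_template.size_range),
            "density_mode": spec_template.density_mode,
        },
    }
    (out_dir / "generation.json").write_text(json.dumps(sidecar, indent=2))
    return ds


def build_imbalanced_dataset(counts, *, image_size: int = 256,
                             size_range: tuple[int, int] = (20, 48),
                             instances_per_image: int = 8,
                             seed: int = 0) -> DetectionDataset:
    """Dataset whose per-class instance counts equal ``counts`` exactly.

    Images are filled with up to ``instances_per_image`` instances of a
    single class at a time (the class with the largest remaining need), so
    arbitrary count vectors — e.g. a long-tailed profile from
    :func:`make_imbalanced_counts` — are realised exactly.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_classes = len(counts)
    ds = DetectionDataset(n_classes=n_classes)
    rng = np.random.default_rng(seed)
    remaining = counts.copy()
    img_id = 0
    while remaining.sum() > 0:
        cls = int(remaining.argmax())
        k = int(min(instances_per_image, remaining[cls]))
        weights = np.zeros(n_classes)
        weights[cls] = 1.0
        spec = SceneSpec(width=image_size, height=image_size, n_instances=k,
                         class_weights=tuple(weights), size_range=size_range,
                         seed=int(rng.integers(2**31)))
        image, anns = generate_scene(spec)
        ds.add_image(image, anns, image_id=img_id)
        remaining[cls] -= k
        img_id += 1
    return ds


def make_imbalanced_counts(n_classes: int, head_count: int,
                           tail_count: int) -> np.ndarray:
    """Per-class instance counts interpolating linearly from head to tail.

    Emulates the long-tailed skew of field pest surveys, where a common
    species may have two orders of magnitude more labelled instances than a
    rare one (e.g. 242 against 3).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes for an imbalance profile")
    if not head_count >= tail_count >= 1:
        raise ValueError("require head_count >= tail_count >= 1")
    t = np.arange(n_classes) / (n_classes - 1)
    counts = np.round(head_count + (tail_count - head_count) * t).astype(np.int64)
    return counts
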