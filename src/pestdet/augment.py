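"""Copy-paste class balancing and online photometric augmentation.

The offline path cuts annotated instances out of their source images and
pastes them onto background images until every class reaches a target
instance count, leaving originals untouched.  Pasting is a hard rectangular
insertion (no blending), so a cut/paste round trip is pixel-exact; pasted
boxes keep pairwise IoU below an overlap cap so dense layouts stay
resolvable.  The online path applies colour dithering, random masking,
Gaussian noise and horizontal flips, all label-preserving and fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .boxes import box_iou
from .coco_io import AnnotationRecord, DetectionDataset


class PlacementError(RuntimeError):
    """Raised when a patch cannot be placed within the retry budget."""


@dataclass
class TargetPatch:
    """A rectangular crop of one annotated instance."""

    pixels: np.ndarray          # (h, w, 3) uint8
    class_id: int
    source_image_id: int

    def __post_init__(self):
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("patch must be at least 1x1")


@dataclass
class AugmentPolicy:
    """Online augmentation strengths; everything at 0 is the identity."""

    color_jitter: tuple[float, float, float, float] = (0.2, 0.2, 0.2, 0.05)
    mask_prob: float = 0.3
    mask_area_frac: float = 0.08
    noise_sigma: float = 4.0
    flip_prob: float = 0.5

    def __post_init__(self):
        for p in (self.mask_prob, self.flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(color_jitter=(0, 0, 0, 0), mask_prob=0.0,
                   mask_area_frac=0.0, noise_sigma=0.0, flip_prob=0.0)


# -- cut -------------------------------------------------------------------


def extract_targets(image: np.ndarray,
                    annotations: list[AnnotationRecord]) -> list[TargetPatch]:
    """Crop one patch per annotation; patch size is the rounded box size."""
    H, W = image.shape[:2]
    patches = []
    for i, ann in enumerate(annotations):
        x1, y1, x2, y2 = (int(round(v)) for v in ann.bbox)
        if not (0 <= x1 < x2 <= W and 0 <= y1 < y2 <= H):
            raise ValueError(f"annotation {i} box {ann.bbox} outside image "
                             f"bounds {W}x{H} or degenerate after rounding")
        patches.append(TargetPatch(pixels=image[y1:y2, x1:x2].copy(),
                                   class_id=ann.class_id,
                                   source_image_id=ann.image_id))
    return patches


# -- paste -----------------------------------------------------------------

_PASTE_RETRIES = 100


def _jitter_patch(patch: TargetPatch, rng: np.random.Generator,
                  scale_jitter: float, flip_prob: float) -> np.ndarray:
    px = patch.pixels
    if flip_prob > 0 and rng.random() < flip_prob:
        px = px[:, ::-1]
    if scale_jitter > 0:
        s = 1.0 + rng.uniform(-scale_jitter, scale_jitter)
        h = max(1, int(round(px.shape[0] * s)))
        w = max(1, int(round(px.shape[1] * s)))
        px = np.asarray(Image.fromarray(px).resize((w, h), Image.BILINEAR))
    return px


def paste_targets(background: np.ndarray, patches: list[TargetPatch],
                  rng_seed: int, *, existing_boxes: np.ndarray | None = None,
                  overlap_cap: float = 0.2, scale_jitter: float = 0.2,
                  flip_prob: float = 0.5,
                  ) -> tuple[np.ndarray, list[AnnotationRecord]]:
    """Paste patches at random non-conflicting locations on a background.

    Pasted boxes have pairwise IoU <= ``overlap_cap``, also against
    ``existing_boxes``.  Patches are optionally scale-jittered and flipped
    before pasting; the returned annotation exactly covers the pasted
    region.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    image = background.copy()
    H, W = image.shape[:2]
    taken = ([] if existing_boxes is None
             else [tuple(b) for b in np.asarray(existing_boxes)])
    annotations: list[AnnotationRecord] = []
    for idx, patch in enumerate(patches):
        px = _jitter_patch(patch, rng, scale_jitter, flip_prob)
        h, w = px.shape[:2]
        if h > H or w > W:
            raise PlacementError(f"patch {idx} ({w}x{h}) larger than "
                                 f"background {W}x{H}")
        for _ in range(_PASTE_RETRIES):
            x = int(rng.integers(0, W - w + 1))
            y = int(rng.integers(0, H - h + 1))
            box = (float(x), float(y), float(x + w), float(y + h))
            if not taken:
                break
            if box_iou(np.array([box]), np.array(taken))[0].max() <= overlap_cap:
                break
        else:
            raise PlacementError(
                f"patch {idx}: no placement with IoU <= {overlap_cap} after "
                f"{_PASTE_RETRIES} tries")
        image[y:y + h, x:x + w] = px
        taken.append(box)
        annotations.append(AnnotationRecord(image_id=-1,
                                            class_id=patch.class_id, bbox=box))
    return image, annotations


# -- offline balancing -----------------------------------------------------


def balance_classes(dataset: DetectionDataset, target_count: int,
                    backgrounds: list[np.ndarray], rng_seed: int, *,
                    overlap_cap: float = 0.2, scale_jitter: float = 0.2,
                    flip_prob: float = 0.5, patches_per_image: int = 8,
                    ) -> DetectionDataset:
    """Expand a dataset by copy-paste until every class reaches target_count.

    Classes already at or above the target are untouched; original images
    are never modified — new pasted images are appended with fresh ids.
    """
    if not backgrounds:
        raise ValueError("need at least one background image")
    counts = dataset.class_counts()
    deficits = {c: int(target_count - n) for c, n in enumerate(counts)
                if n < target_count}
    for c, n in enumerate(counts):
        if n == 0:
            raise ValueError(f"class {c} has zero source instances; "
                             "cannot balance it by copy-paste")
    # source patch pools per class, cut from the original images
    pools: dict[int, list[TargetPatch]] = {c: [] for c in range(len(counts))}
    for img_id, image in dataset.images.items():
        for patch in extract_targets(image, dataset.annotations_for(img_id)):
            pools[patch.class_id].append(patch)

    out = DetectionDataset(images=dict(dataset.images),
                           annotations=list(dataset.annotations),
                           n_classes=dataset.n_classes,
                           category_names=dataset.category_names)
    rng = np.random.default_rng(rng_seed)
    next_id = max(out.images, default=-1) + 1
    while any(d > 0 for d in deficits.values()):
        needy = [c for c, d in deficits.items() if d > 0]
        # fill one new image with patches from still-deficient classes
        k = min(patches_per_image, sum(deficits[c] for c in needy))
        chosen: list[TargetPatch] = []
        budget = dict(deficits)
        for _ in range(k):
            live = [c for c in needy if budget[c] > 0]
            if not live:
                break
            c = int(rng.choice(live))
            chosen.append(pools[c][int(rng.integers(len(pools[c])))])
            budget[c] -= 1
        bg = backgrounds[int(rng.integers(len(backgrounds)))]
        try:
            image, anns = paste_targets(
                bg, chosen, rng_seed=int(rng.integers(2**31)),
                overlap_cap=overlap_cap, scale_jitter=scale_jitter,
                flip_prob=flip_prob)
        except PlacementError:
            # crowded draw: retry with half as many patches
            image, anns = paste_targets(
                bg, chosen[:max(1, len(chosen) // 2)],
                rng_seed=int(rng.integers(2**31)), overlap_cap=overlap_cap,
                scale_jitter=scale_jitter, flip_prob=flip_prob)
        out.add_image(image, anns, image_id=next_id)
        for a in anns:
            deficits[a.class_id] -= 1
        next_id += 1
    return out


# -- online augmentation ---------------------------------------------------


def _hue_rotation_matrix(theta: float) -> np.ndarray:
    """Rotation about the gray axis in RGB space (hue shift)."""
    c, s = np.cos(theta), np.sin(theta)
    one3 = 1.0 / 3.0
    sq3 = np.sqrt(1.0 / 3.0)
    m = np.full((3, 3), one3 * (1.0 - c))
    m += np.eye(3) * c
    off = sq3 * s
    m += np.array([[0, -off, off], [off, 0, -off], [-off, off, 0]])
    return m


def online_augment(image: np.ndarray, annotations: list[AnnotationRecord],
                   policy: AugmentPolicy, rng_seed: int,
                   ) -> tuple[np.ndarray, list[AnnotationRecord]]:
    """Photometric + flip augmentation; boxes follow flips exactly.

    A fully zeroed policy returns bit-identical copies of the inputs.
    """
    rng = np.random.default_rng(rng_seed)
    img = image.copy()
    anns = list(annotations)
    H, W = img.shape[:2]
    b, c, s, hmax = policy.color_jitter

    if policy.flip_prob > 0 and rng.random() < policy.flip_prob:
        img = img[:, ::-1].copy()
        anns = [AnnotationRecord(a.image_id, a.class_id,
                                 (W - a.bbox[2], a.bbox[1],
                                  W - a.bbox[0], a.bbox[3]), a.iscrowd)
                for a in anns]

    if any(v > 0 for v in (b, c, s, hmax)):
        x = img.astype(np.float64)
        if b > 0:
            x *= 1.0 + rng.uniform(-b, b)
        if c > 0:
            mean = x.mean()
            x = (x - mean) * (1.0 + rng.uniform(-c, c)) + mean
        if s > 0:
            luma = x @ np.array([0.299, 0.587, 0.114])
            f = 1.0 + rng.uniform(-s, s)
            x = luma[..., None] + (x - luma[..., None]) * f
        if hmax > 0:
            theta = rng.uniform(-hmax, hmax) * 2.0 * np.pi
            x = x @ _hue_rotation_matrix(theta).T
        img = np.clip(np.round(x), 0, 255).astype(np.uint8)

    if policy.mask_prob > 0 and rng.random() < policy.mask_prob:
        area = H * W * rng.uniform(0.2, 1.0) * policy.mask_area_frac
        aspect = rng.uniform(0.5, 2.0)
        mh = min(H, max(1, int(round(np.sqrt(area * aspect)))))
        mw = min(W, max(1, int(round(np.sqrt(area / aspect)))))
        fill = img.reshape(-1, 3).mean(axis=0).round().astype(np.uint8)
        gt = np.array([a.bbox for a in anns]) if anns else np.zeros((0, 4))
        for _ in range(20):
            x0 = int(rng.integers(0, W - mw + 1))
            y0 = int(rng.integers(0, H - mh + 1))
            if len(gt) == 0:
                break
            # fraction of each GT box covered by the candidate mask
            iw = np.clip(np.minimum(gt[:, 2], x0 + mw) - np.maximum(gt[:, 0], x0),
                         0, None)
            ih = np.clip(np.minimum(gt[:, 3], y0 + mh) - np.maximum(gt[:, 1], y0),
                         0, None)
            cover = iw * ih / ((gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1]))
            if cover.max() <= 0.5:
                break
        else:
            x0 = None
        if x0 is not None:
            img[y0:y0 + mh, x0:x0 + mw] = fill

    if policy.noise_sigma > 0:
        noise = rng.normal(0.0, policy.noise_sigma, size=img.shape)
        img = np.clip(np.round(img.astype(np.float64) + noise),
                      0, 255).astype(np.uint8)

    return img, anns
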