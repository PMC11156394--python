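"""Copy-paste balancing and online augmentation contracts."""

import numpy as np
import pytest

from pestdet.augment import (AugmentPolicy, PlacementError, balance_classes,
                             extract_targets, online_augment, paste_targets)
from pestdet.boxes import box_iou
from pestdet.coco_io import AnnotationRecord, DetectionDataset
from pestdet.synthetic import SceneSpec, build_dataset, generate_scene


def _scene(seed=0, n=3):
    return generate_scene(SceneSpec(n_instances=n, size_range=(24, 48),
                                    class_weights=(0.4, 0.3, 0.3), seed=seed))


def test_extract_targets_shapes_and_classes():
    img, anns = _scene()
    patches = extract_targets(img, anns)
    assert len(patches) == len(anns)
    for p, a in zip(patches, anns):
        assert p.class_id == a.class_id
        x1, y1, x2, y2 = (int(round(v)) for v in a.bbox)
        assert p.pixels.shape == (y2 - y1, x2 - x1, 3)


def test_extract_targets_crop_arithmetic():
    img = np.arange(100 * 100 * 3, dtype=np.uint8).reshape(100, 100, 3)
    ann = AnnotationRecord(0, 0, (10, 10, 20, 30))
    (patch,) = extract_targets(img, [ann])
    assert patch.pixels.shape == (20, 10, 3)  # h=20, w=10


def test_extract_targets_rejects_out_of_bounds():
    img = np.zeros((50, 50, 3), dtype=np.uint8)
    with pytest.raises(ValueError, match="annotation 0"):
        extract_targets(img, [AnnotationRecord(0, 0, (40, 40, 60, 60))])


def test_cut_paste_roundtrip_is_pixel_exact():
    img, anns = _scene(seed=4)
    patches = extract_targets(img, anns)
    bg = np.zeros_like(img)
    out, new_anns = paste_targets(bg, patches, rng_seed=0,
                                  scale_jitter=0.0, flip_prob=0.0)
    for p, a in zip(patches, new_anns):
        x1, y1, x2, y2 = (int(v) for v in a.bbox)
        assert np.array_equal(out[y1:y2, x1:x2], p.pixels)


def test_paste_zero_patches_is_identity():
    bg = np.full((64, 64, 3), 7, dtype=np.uint8)
    out, anns = paste_targets(bg, [], rng_seed=0)
    assert np.array_equal(out, bg) and anns == []


def test_paste_overlap_cap_holds_exhaustively():
    img, anns = _scene(seed=2, n=4)
    patches = extract_targets(img, anns) * 3  # 12 patches
    bg = np.zeros((512, 512, 3), dtype=np.uint8)
    out, new_anns = paste_targets(bg, patches, rng_seed=5, overlap_cap=0.2)
    boxes = np.array([a.bbox for a in new_anns])
    ious = box_iou(boxes, boxes)
    np.fill_diagonal(ious, 0.0)
    assert ious.max() <= 0.2 + 1e-12
    # determinism
    out2, anns2 = paste_targets(bg, patches, rng_seed=5, overlap_cap=0.2)
    assert np.array_equal(out, out2) and anns2 == new_anns


def test_paste_infeasible_raises_with_patch_index():
    bg = np.zeros((64, 64, 3), dtype=np.uint8)
    big = np.zeros((60, 60, 3), dtype=np.uint8)
    from pestdet.augment import TargetPatch
    patches = [TargetPatch(big, 0, 0), TargetPatch(big, 0, 0)]
    with pytest.raises(PlacementError, match="patch 1"):
        paste_targets(bg, patches, rng_seed=0, scale_jitter=0.0, flip_prob=0.0,
                      overlap_cap=0.1)


def _imbalanced_dataset(counts, seed=0):
    """Build a dataset whose per-class instance counts equal `counts`."""
    n_classes = len(counts)
    ds = DetectionDataset(n_classes=n_classes)
    rng = np.random.default_rng(seed)
    img_id = 0
    remaining = list(counts)
    while any(remaining):
        cls = max(range(n_classes), key=lambda c: remaining[c])
        k = min(3, remaining[cls])
        w = [0.0] * n_classes
        w[cls] = 1.0
        img, anns = generate_scene(SceneSpec(
            n_instances=k, class_weights=tuple(w), size_range=(20, 40),
            seed=int(rng.integers(2**31))))
        ds.add_image(img, anns, image_id=img_id)
        remaining[cls] -= k
        img_id += 1
    return ds


def test_balance_classes_reaches_target_exactly():
    ds = _imbalanced_dataset([5, 100, 200])
    assert ds.class_counts().tolist() == [5, 100, 200]
    bgs = [generate_scene(SceneSpec(n_instances=0, seed=s))[0] for s in (1, 2)]
    out = balance_classes(ds, target_count=150, backgrounds=bgs, rng_seed=3)
    assert out.class_counts().tolist() == [150, 150, 200]
    # originals untouched
    for img_id in ds.images:
        assert np.array_equal(out.images[img_id], ds.images[img_id])
    assert all(a in out.annotations for a in ds.annotations)


def test_balance_classes_leaves_saturated_class_unchanged():
    """A class already above target keeps its count (242 -> 242 pattern)."""
    ds = _imbalanced_dataset([12, 30])
    bgs = [generate_scene(SceneSpec(n_instances=0, seed=9))[0]]
    out = balance_classes(ds, target_count=20, backgrounds=bgs, rng_seed=0)
    assert out.class_counts().tolist() == [20, 30]


def test_balance_classes_never_decreases_counts():
    ds = _imbalanced_dataset([4, 9, 15])
    bgs = [generate_scene(SceneSpec(n_instances=0, seed=1))[0]]
    out = balance_classes(ds, target_count=12, backgrounds=bgs, rng_seed=7)
    assert np.all(out.class_counts() >= ds.class_counts())


def test_balance_classes_rejects_empty_class():
    ds = _imbalanced_dataset([5, 5])
    ds.n_classes = 3  # class 2 has no instances
    bgs = [np.zeros((256, 256, 3), dtype=np.uint8)]
    with pytest.raises(ValueError, match="class 2"):
        balance_classes(ds, target_count=10, backgrounds=bgs, rng_seed=0)


def test_online_augment_identity_policy_is_bitwise():
    img, anns = _scene(seed=8)
    out, out_anns = online_augment(img, anns, AugmentPolicy.identity(), rng_seed=0)
    assert np.array_equal(out, img)
    assert out_anns == anns


def test_online_augment_flip_reflects_boxes():
    img = np.zeros((50, 100, 3), dtype=np.uint8)
    anns = [AnnotationRecord(0, 1, (10.0, 5.0, 20.0, 15.0))]
    policy = AugmentPolicy(color_jitter=(0, 0, 0, 0), mask_prob=0,
                           mask_area_frac=0, noise_sigma=0, flip_prob=1.0)
    out, out_anns = online_augment(img, anns, policy, rng_seed=0)
    assert out_anns[0].bbox == (80.0, 5.0, 90.0, 15.0)


def test_online_augment_deterministic_and_in_bounds():
    img, anns = _scene(seed=5)
    policy = AugmentPolicy(noise_sigma=5.0)
    a1 = online_augment(img, anns, policy, rng_seed=12)
    a2 = online_augment(img, anns, policy, rng_seed=12)
    assert np.array_equal(a1[0], a2[0]) and a1[1] == a2[1]
    H, W = img.shape[:2]
    for a in a1[1]:
        x1, y1, x2, y2 = a.bbox
        assert 0 <= x1 < x2 <= W and 0 <= y1 < y2 <= H
    assert a1[0].shape == img.shape
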