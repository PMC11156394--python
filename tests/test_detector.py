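"""Cascade detector: assignment monotonicity, RPN contracts, score fusion."""

import numpy as np
import pytest

from pestdet import _tensor as T
from pestdet._tensor import Tensor
from pestdet.boxes import box_iou
from pestdet.detector import (CascadeConfig, StageOutputs, assign_levels,
                              assign_rpn_targets, assign_stage_targets,
                              generate_anchors, pool_pyramid, roi_align,
                              training_losses)
from pestdet.synthetic import SceneSpec, generate_scene
from pestdet.train import build_detector


@pytest.fixture(scope="module")
def tiny_model():
    return build_detector(3, "tiny", seed=0)


@pytest.fixture(scope="module")
def scene():
    return generate_scene(SceneSpec(n_instances=3, size_range=(40, 100),
                                    class_weights=(0.4, 0.3, 0.3), seed=2))


def test_cascade_config_requires_increasing_thresholds():
    with pytest.raises(ValueError):
        CascadeConfig(iou_thresholds=(0.5, 0.5, 0.7))
    cfg = CascadeConfig()
    assert cfg.iou_thresholds == (0.5, 0.6, 0.7)
    assert cfg.num_stages == 3


def test_stage_assignment_threshold_semantics():
    """IoU 0.55 is positive at 0.5 but background at 0.6 and 0.7."""
    gt = np.array([[0.0, 0.0, 100.0, 100.0]])
    gt_labels = np.array([2])
    prop = np.array([[0.0, 0.0, 100.0, 55.0]])  # IoU exactly 0.55
    assert np.isclose(box_iou(prop, gt)[0, 0], 0.55)
    for thr, expect in [(0.5, 2), (0.6, -1), (0.7, -1)]:
        labels, match, _ = assign_stage_targets(prop, gt, gt_labels, thr)
        assert labels[0] == expect
    # a proposal identical to GT is positive at every stage
    labels, _, _ = assign_stage_targets(gt.copy(), gt, gt_labels, 0.7)
    assert labels[0] == 2


def test_stage_assignment_monotone_shrinkage():
    """Positives at a stricter threshold are a subset of a looser one."""
    rng = np.random.default_rng(0)
    n_trials = 1000
    violations = 0
    for _ in range(n_trials):
        xy = rng.uniform(0, 60, (8, 2))
        wh = rng.uniform(5, 50, (8, 2))
        props = np.concatenate([xy, xy + wh], axis=1)
        gxy = rng.uniform(0, 60, (3, 2))
        gwh = rng.uniform(5, 50, (3, 2))
        gts = np.concatenate([gxy, gxy + gwh], axis=1)
        glab = rng.integers(0, 3, 3)
        prev = None
        for thr in (0.5, 0.6, 0.7):
            labels, _, _ = assign_stage_targets(props, gts, glab, thr)
            pos = set(np.flatnonzero(labels >= 0))
            if prev is not None and not pos.issubset(prev):
                violations += 1
            prev = pos
    assert violations == 0


def test_rpn_assignment_forces_best_anchor_per_gt():
    anchors = generate_anchors(8, 8, 8)
    gt = np.array([[10.0, 10.0, 40.0, 40.0]])
    labels, match = assign_rpn_targets(anchors, gt)
    assert (labels == 1).sum() >= 1
    assert np.all(match[labels == 1] == 0)
    # no ground truth: everything is negative
    labels0, _ = assign_rpn_targets(anchors, np.zeros((0, 4)))
    assert np.all(labels0 == 0)


def test_anchor_grid_geometry():
    anchors = generate_anchors(4, 4, 16)
    assert anchors.shape == (4 * 4 * 3, 4)
    ctr = (anchors[:, :2] + anchors[:, 2:]) / 2
    assert np.allclose(ctr[0], [8.0, 8.0])  # first cell centre at stride/2
    # all three ratios share the same area
    areas = ((anchors[:3, 2] - anchors[:3, 0])
             * (anchors[:3, 3] - anchors[:3, 1]))
    assert np.allclose(areas, areas[0])


def test_rpn_proposals_clipped_and_nonempty(tiny_model, scene):
    image, _ = scene
    with T.no_grad():
        pyr = tiny_model.pyramid(image)
        props = tiny_model.rpn_propose(pyr, image.shape[:2])
    assert len(props) > 0
    assert props.boxes[:, 0].min() >= 0 and props.boxes[:, 1].min() >= 0
    assert props.boxes[:, 2].max() <= image.shape[1]
    assert props.boxes[:, 3].max() <= image.shape[0]
    with pytest.raises(ValueError):
        tiny_model.rpn_propose((), image.shape[:2])


def test_roi_align_constant_field_and_level_routing():
    const = Tensor(np.full((16, 16, 4), 2.5, dtype=np.float32))
    boxes = np.array([[8.0, 8.0, 64.0, 64.0]])
    pooled = roi_align(const, boxes, stride=8, out_size=7)
    assert pooled.shape == (1, 7, 7, 4)
    assert np.allclose(pooled.data, 2.5)
    # small boxes route to fine levels, large ones to coarse levels
    lv = assign_levels(np.array([[0, 0, 30, 30], [0, 0, 600, 600]]))
    assert lv[0] == 0 and lv[1] == 3


def test_pool_pyramid_preserves_box_order(tiny_model, scene):
    image, _ = scene
    with T.no_grad():
        pyr = tiny_model.pyramid(image)
        boxes = np.array([[0, 0, 500, 500], [10, 10, 40, 40],
                          [5, 5, 200, 200]], dtype=np.float64)
        pooled = pool_pyramid(pyr, boxes)
        assert pooled.shape[0] == 3
        single = pool_pyramid(pyr, boxes[1:2])
    assert np.allclose(pooled.data[1], single.data[0], atol=1e-5)


def test_cascade_scores_average_and_bounds(tiny_model, scene):
    image, _ = scene
    with T.no_grad():
        pyr = tiny_model.pyramid(image)
        props = tiny_model.rpn_propose(pyr, image.shape[:2]).boxes[:10]
        stage_out, final = tiny_model.cascade_forward(pyr, props,
                                                      image.shape[:2])
    assert len(stage_out.C) == 3 and len(stage_out.B) == 3
    for C in stage_out.C:
        assert np.allclose(C.sum(axis=1), 1.0, atol=1e-5)
    avg = stage_out.averaged_scores()
    stacked = np.stack(stage_out.C)
    assert np.all(avg >= stacked.min(axis=0) - 1e-9)
    assert np.all(avg <= stacked.max(axis=0) + 1e-9)
    # final boxes are the stage-3 output
    assert np.array_equal(final.boxes, stage_out.B[2])


def test_stage_outputs_mean_arithmetic():
    C = [np.array([[0.9, 0.1]]), np.array([[0.8, 0.2]]), np.array([[0.7, 0.3]])]
    out = StageOutputs(C=C, B=[np.zeros((1, 4))] * 3)
    assert np.isclose(out.averaged_scores()[0, 0], 0.8)


def test_detect_is_deterministic_and_labels_in_range(tiny_model, scene):
    image, _ = scene
    d1 = tiny_model.detect(image)
    d2 = tiny_model.detect(image)
    assert np.array_equal(d1.boxes, d2.boxes)
    assert np.array_equal(d1.scores, d2.scores)
    if len(d1):
        assert d1.labels.min() >= 0 and d1.labels.max() < 3


def test_training_losses_produce_gradients(tiny_model, scene):
    image, anns = scene
    gt_boxes = np.array([a.bbox for a in anns])
    gt_labels = np.array([a.class_id for a in anns])
    rng = np.random.default_rng(0)
    losses = training_losses(tiny_model, image, gt_boxes, gt_labels, rng)
    assert "rpn" in losses and "stage1_cls" in losses
    total = None
    for t in losses.values():
        total = t if total is None else total + t
    tiny_model.zero_grad()
    total.backward()
    grads = [p.grad for p in tiny_model.heads[0].parameters()]
    assert any(g is not None and np.abs(g).max() > 0 for g in grads)
    tiny_model.zero_grad()
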