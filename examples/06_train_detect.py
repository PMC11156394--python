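"""Train the tiny detector on a handful of scenes and run detection.

A short demonstration run (150 iterations on 6 images) — enough to watch
the loss fall and see detections appear; the full memorisation benchmark
(20 images, 200 iterations, mAP@0.5 >= 0.9) is
`pestdet.train.overfit_benchmark`.
"""

import numpy as np

from pestdet.synthetic import SceneSpec, build_dataset
from pestdet.train import TrainConfig, build_detector, evaluate, train

spec = SceneSpec(width=256, height=256, n_instances=3,
                 class_weights=(1 / 3, 1 / 3, 1 / 3), size_range=(40, 120),
                 seed=0)
ds = build_dataset(6, spec, seed=0)
model = build_detector(n_classes=3, profile="tiny", seed=0)

cfg = TrainConfig(base_lr=0.01, weight_decay=0.0, epochs=100,
                  lr_milestones=(80, 90), batch_size=2, input_size=256,
                  seed=0)
history = train(ds, model, cfg, max_iterations=150, accum_steps=2)
print(f"loss: {history[0]['loss']:.3f} (start) -> "
      f"{history[-1]['loss']:.3f} (iteration {history[-1]['iteration']})")

res = evaluate(ds, model)
print(f"train-set mAP@0.5 = {res.map50:.3f}, recall = {res.recall:.3f}")

dets = model.detect(ds.images[0]).sorted_by_score()
gt_boxes, gt_labels = ds.gt_arrays(0)
print(f"\nimage 0 has {len(gt_boxes)} ground-truth instances; "
      f"top detections:")
for box, score, label in list(zip(dets.boxes, dets.scores, dets.labels))[:5]:
    print(f"  class {label} score {score:.2f} box {np.round(box, 1).tolist()}")
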