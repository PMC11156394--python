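"""Linear Soft-NMS versus hard suppression on a dense cluster.

Two overlapping detections of densely packed targets: hard NMS deletes the
second box outright, Soft-NMS only decays its score by (1 - IoU), so a
true neighbour survives the final score floor.
"""

import numpy as np

from pestdet.boxes import BoxSet, hard_nms, iou, soft_nms

a = [0.0, 0.0, 10.0, 10.0]   # score 0.95
b = [0.0, 0.0, 10.0, 8.0]    # score 0.90, IoU 0.8 with a
print(f"IoU(a, b) = {iou(a, b):.2f}")

dets = BoxSet([a, b], [0.95, 0.90], [0, 0])
keep = hard_nms(dets.boxes, dets.scores, 0.5)
print(f"hard NMS keeps {len(keep)} box(es)")

out = soft_nms(dets, nt=0.5, score_floor=0.05)
print(f"soft NMS keeps {len(out)} boxes with scores "
      f"{np.round(out.scores, 3).tolist()}")
print("the second score is 0.9 * (1 - 0.8) = 0.18: decayed, not deleted.")
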