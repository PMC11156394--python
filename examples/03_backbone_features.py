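"""Run the shifted-window backbone and show the multi-scale feature maps.

The tiny CPU profile keeps the topology of the full model (four stages,
patch merging, alternating plain/shifted window attention) at reduced
width.  Stage s halves the resolution and doubles the channels of stage
s-1; the detector consumes stages 2-4.
"""

import numpy as np

from pestdet import _tensor as T
from pestdet.backbone import BackboneConfig, SwinBackbone
from pestdet.synthetic import SceneSpec, generate_scene

image, _ = generate_scene(SceneSpec(seed=5))
backbone = SwinBackbone(BackboneConfig.tiny(), seed=0)

with T.no_grad():
    feat1, feat2, feat3 = backbone(image)

print(f"input image: {image.shape}")
for name, f in [("feat1", feat1), ("feat2", feat2), ("feat3", feat3)]:
    h, w, c = f.shape
    print(f"  {name}: {h}x{w}x{c}  (stride {f.stride} -> one cell covers "
          f"{f.stride}x{f.stride} px)")
print("feat1 resolves small targets, feat3 summarises large ones;")
print("with the full profile (embed 128) the channels are 256/512/1024.")
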