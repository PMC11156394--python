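"""Balance a long-tailed dataset by copy-paste expansion.

Creates a 5-class dataset whose counts interpolate from 60 down to 3
instances, then pastes cut-out instances onto empty background scenes
until every class reaches 40.  Original images are never modified.
"""

from pestdet.augment import balance_classes
from pestdet.synthetic import (SceneSpec, build_imbalanced_dataset,
                               generate_scene, make_imbalanced_counts)

counts = make_imbalanced_counts(n_classes=5, head_count=60, tail_count=3)
print(f"long-tailed class profile: {counts.tolist()}")

ds = build_imbalanced_dataset(counts, seed=1)
print(f"dataset: {len(ds.images)} images, counts {ds.class_counts().tolist()}")

backgrounds = [generate_scene(SceneSpec(n_instances=0, seed=s))[0]
               for s in (100, 101)]
balanced = balance_classes(ds, target_count=40, backgrounds=backgrounds,
                           rng_seed=7)
print(f"after balancing to 40: {balanced.class_counts().tolist()}")
print(f"  ({len(balanced.images) - len(ds.images)} pasted images appended; "
      "classes already above 40 are untouched)")
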