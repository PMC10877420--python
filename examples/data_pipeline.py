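"""Dataset bookkeeping: 11x augmentation expansion, quality filter and the
per-class 6:2:2 split.

The numbers mirror the study setting: 417 originals expand to 4,587
images, and a class of 1,008 images splits 605/202/201 by per-class
largest-remainder apportionment.
"""

import numpy as np

from micropest import (AnnotatedImage, AugmentConfig, Box, GroundTruthBox,
                       apportion, expand_dataset, quality_filter, split_dataset)

rng = np.random.default_rng(0)
originals = [
    AnnotatedImage(rng.integers(0, 255, (24, 24, 3), dtype=np.uint8),
                   [GroundTruthBox(Box(4, 4, 18, 18), "ABCD"[i % 4])], f"img{i}")
    for i in range(417)
]
expanded = expand_dataset(originals, AugmentConfig(seed=0), factor=11)
print(f"{len(originals)} originals x 11 -> {len(expanded)} images")

kept, flagged = quality_filter(expanded, min_area_fraction=0.2)
print(f"quality filter (insects < 20% of image area): kept {len(kept)}, "
      f"flagged {len(flagged)}")

print("6:2:2 apportionment of 1008 images:", apportion(1008, (0.6, 0.2, 0.2)))
print("6:2:2 apportionment of 1033 images:", apportion(1033, (0.6, 0.2, 0.2)))

split = split_dataset(expanded, (0.6, 0.2, 0.2), seed=1)
sizes = {p: len(split.indices(p)) for p in split.PARTITIONS}
print(f"split of the expanded set: {sizes} (sum {sum(sizes.values())})")
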