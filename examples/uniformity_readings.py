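"""The uniformity index U and its prefactor variants.

U = 1 - c(P) * (within-class squared deviation) / (N * gray_range^2)
penalizes heterogeneous classes.  Published reports are ambiguous about
the prefactor c(P); this package implements three readings.  On an
8-pixel toy image the differences are exact and easy to follow.
"""

import numpy as np

from histmerge import UNIFORMITY_VARIANTS, apply_thresholds, uniformity

img = np.array([[0, 0, 1, 1], [2, 3, 3, 3]])
ts = [0, 1]  # three classes: {0,0} {1,1} {2,3,3,3}
labels = apply_thresholds(img, ts)

print(f"image grays: {sorted(img.ravel().tolist())}")
print(f"thresholds {ts} -> class sizes {np.bincount(labels.ravel()).tolist()}")
print("within-class squared deviation: 0 + 0 + 0.75 (last class mean 2.75)")
print()
for variant in UNIFORMITY_VARIANTS:
    u = uniformity(img, labels, ts, variant=variant)
    print(f"  variant {variant:7s}: U = {u:.6f}")
print()
print("All variants agree on the ranking of segmentations; only the")
print("absolute scale changes. The default 2(P-1) makes U degenerate to 1")
print("for single-threshold segmentations (P = 1 zeroes the prefactor).")
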