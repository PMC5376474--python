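"""Compare region merging with exhaustive Otsu on a synthetic MR-like image.

Draws a three-mode Gaussian-mixture image (the canonical fixture: modes
at 56/128/200, sd 12), segments it with two thresholds by both methods,
and scores each segmentation with the uniformity index U.
"""

import numpy as np

from histmerge import (
    THREE_MODE,
    apply_thresholds,
    build_histogram,
    merge_thresholds,
    otsu_exhaustive,
    synth_image,
    uniformity,
)

img, truth = synth_image(THREE_MODE, shape=(256, 256), seed=42)
h = build_histogram(img)

ts_merge, trace = merge_thresholds(h, 2, return_trace=True)
res_otsu = otsu_exhaustive(h, 2)
ts_otsu = list(res_otsu.thresholds)

u_merge = uniformity(img, apply_thresholds(img, ts_merge), ts_merge)
u_otsu = uniformity(img, apply_thresholds(img, ts_otsu), ts_otsu)

print(f"density valleys (ground truth): {truth}")
print(f"region merging : thresholds={ts_merge}  U={u_merge:.4f}  "
      f"({len(trace.steps)} merges, {trace.energy_evaluations} energy evaluations)")
print(f"exhaustive Otsu: thresholds={ts_otsu}  U={u_otsu:.4f}  "
      f"({res_otsu.candidates_evaluated} candidate tuples)")
print()
print("Otsu lands on the density valleys; the greedy merge places its")
print("boundaries at the edges of the low-mass valley regions, so its")
print("thresholds sit off-valley while costing only ~2x256 energy")
print("evaluations instead of a combinatorial search.")
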