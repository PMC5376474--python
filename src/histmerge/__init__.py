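"""histmerge: multithreshold segmentation by greedy histogram region merging.

The histogram of an 8-bit image starts as 256 singleton regions; each
iteration merges the region with minimum energy D = omega * sigma2 into
its smaller-energy neighbor, removing one threshold, until T thresholds
remain — linear work in the number of gray levels regardless of T.  An
exhaustive multilevel Otsu comparator, the uniformity index U, and a
Gaussian-mixture fixture generator complete the test bench.
"""

from __future__ import annotations

import numpy as np

from .histogram import (
    N_GRAY,
    GrayHistogram,
    Partition,
    Region,
    build_histogram,
    histogram_from_counts,
    region_stats,
)
from .merging import (
    MergeAuditError,
    MergeStep,
    MergeTrace,
    choose_merge_neighbor,
    initialize_partition,
    merge_once,
    merge_thresholds,
    run_merging,
    select_min_energy_region,
    thresholds_from_partition,
)
from .otsu import OtsuResult, between_class_variance, otsu_exhaustive
from .evaluation import (
    SegmentationResult,
    UNIFORMITY_VARIANTS,
    apply_thresholds,
    segment_with_thresholds,
    uniformity,
)
from .synthetic import (
    THREE_MODE,
    TWO_MODE,
    ModeSpec,
    mixture_density,
    synth_histogram,
    synth_image,
    valley_thresholds,
)
from .io import (
    load_gray_image,
    read_histogram_text,
    write_histogram_text,
    write_label_png,
)

__version__ = "0.1.0"

__all__ = [
    "N_GRAY",
    "GrayHistogram", "Region", "Partition",
    "build_histogram", "histogram_from_counts", "region_stats",
    "MergeTrace", "MergeStep", "MergeAuditError",
    "initialize_partition", "select_min_energy_region",
    "choose_merge_neighbor", "merge_once", "run_merging",
    "thresholds_from_partition", "merge_thresholds",
    "OtsuResult", "otsu_exhaustive", "between_class_variance",
    "SegmentationResult", "apply_thresholds", "uniformity",
    "segment_with_thresholds", "UNIFORMITY_VARIANTS",
    "ModeSpec", "TWO_MODE", "THREE_MODE",
    "mixture_density", "valley_thresholds", "synth_image", "synth_histogram",
    "load_gray_image", "read_histogram_text",
    "write_histogram_text", "write_label_png",
    "segment_image",
]


def segment_image(image, T: int, method: str = "merge",
                  variant: str = "2(P-1)") -> SegmentationResult:
    """One-call pipeline: image -> thresholds -> label map -> U score.

    Parameters
    ----------
    image
        2-D array of gray levels in [0, 255].
    T
        Number of thresholds (classes = T + 1).
    method
        ``"merge"`` for histogram region merging, ``"otsu"`` for the
        exhaustive multilevel Otsu search (T capped at 4).
    variant
        Uniformity-index prefactor variant (see :func:`uniformity`).
    """
    h = build_histogram(image)
    if method == "merge":
        ts = merge_thresholds(h, T)
    elif method == "otsu":
        ts = list(otsu_exhaustive(h, T).thresholds)
    else:
        raise ValueError(f"unknown method {method!r}: choose 'merge' or 'otsu'")
    return segment_with_thresholds(np.asarray(image), ts, variant=variant)
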