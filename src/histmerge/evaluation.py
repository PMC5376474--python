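"""Applying thresholds to images and scoring segmentations with U.

The uniformity index rewards segmentations whose classes are internally
homogeneous in gray level:

    U = 1 - c(P) * [sum_j sum_{i in R_j} (f_i - mu_j)^2] / [N * (f_max - f_min)^2]

where P is the number of thresholds, R_j the pixels of class j (all
P + 1 classes are summed), mu_j the mean gray of class j, N the pixel
count and f_max/f_min the image's gray extremes.  U <= 1, and U == 1
exactly when every class is internally constant.  The prefactor c(P) is
``2 * (P - 1)`` by default; the classical ``2 * sqrt(P)`` and the
literal ``2 * P - 1`` are available as variants since published reports
differ in which grouping they use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import N_GRAY

#: Supported prefactor variants for the uniformity index.
UNIFORMITY_VARIANTS = ("2(P-1)", "2sqrtP", "2P-1")


@dataclass(frozen=True)
class SegmentationResult:
    """Thresholds, the per-pixel label map they induce, and the U score
    (None when the input image is constant, where U is undefined)."""

    thresholds: tuple[int, ...]
    labels: np.ndarray
    uniformity: float | None


def _check_thresholds(thresholds) -> np.ndarray:
    ts = np.asarray(list(thresholds), dtype=np.int64)
    if ts.size == 0:
        raise ValueError("threshold list is empty")
    if (np.diff(ts) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    if ts[0] < 0 or ts[-1] > N_GRAY - 2:
        raise ValueError("thresholds must lie in [0, 254]")
    return ts


def apply_thresholds(image, thresholds) -> np.ndarray:
    """Label every pixel: class j holds grays thresholds[j-1] < g <= thresholds[j].

    Class 0 is ``g <= thresholds[0]``; class P is ``g > thresholds[-1]``.
    Returns an integer label map of the image's shape with values in
    ``0 .. len(thresholds)``.
    """
    ts = _check_thresholds(thresholds)
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty input")
    # side='left': g == t lands in the class t closes (inclusive-left rule)
    return np.searchsorted(ts, arr, side="left").astype(np.int64)


def uniformity(
    image, labels, thresholds, variant: str = "2(P-1)"
) -> float:
    """Uniformity index U of a labelled segmentation (closer to 1 is better).

    ``labels`` must be consistent with ``thresholds`` (as produced by
    :func:`apply_thresholds`, up to a permutation of the class indices —
    only the grouping of pixels matters).  Raises on a constant image,
    where the dynamic-range denominator vanishes.
    """
    ts = _check_thresholds(thresholds)
    arr = np.asarray(image, dtype=np.float64)
    lab = np.asarray(labels)
    if arr.shape != lab.shape:
        raise ValueError("image and label map shapes differ")
    f_min, f_max = float(arr.min()), float(arr.max())
    if f_max == f_min:
        raise ValueError("undefined uniformity (zero gray range)")
    P = int(ts.size)
    if variant == "2(P-1)":
        pref = 2.0 * (P - 1)
    elif variant == "2sqrtP":
        pref = 2.0 * np.sqrt(P)
    elif variant == "2P-1":
        pref = 2.0 * P - 1.0
    else:
        raise ValueError(f"unknown uniformity variant {variant!r}; "
                         f"choose from {UNIFORMITY_VARIANTS}")
    n = arr.size
    within = 0.0
    for cls in np.unique(lab):
        vals = arr[lab == cls]
        within += float(((vals - vals.mean()) ** 2).sum())
    return 1.0 - pref * within / (n * (f_max - f_min) ** 2)


def segment_with_thresholds(
    image, thresholds, variant: str = "2(P-1)"
) -> SegmentationResult:
    """Label an image with given thresholds and score it with U.

    U is reported as None for a constant image (undefined there).
    """
    labels = apply_thresholds(image, thresholds)
    arr = np.asarray(image)
    if arr.max() == arr.min():
        u = None
    else:
        u = uniformity(arr, labels, thresholds, variant=variant)
    return SegmentationResult(
        thresholds=tuple(int(t) for t in thresholds), labels=labels, uniformity=u
    )
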