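"""File I/O: 8-bit grayscale images and plain-text 256-bin histograms."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

from .histogram import N_GRAY, GrayHistogram

#: extensions treated as raw histogram text rather than images
HISTOGRAM_SUFFIXES = (".txt", ".csv", ".hist")


def load_gray_image(path) -> np.ndarray:
    """Read a single-channel 8-bit image (PNG/TIFF/PGM).

    Multi-channel inputs are rejected outright — no silent RGB-to-gray
    conversion — as are bit depths other than 8.
    """
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"not 8-bit gray: {path} has {arr.ndim} dimensions "
            "(multi-channel images are not converted)"
        )
    if arr.dtype != np.uint8:
        raise ValueError(f"not 8-bit gray: {path} has dtype {arr.dtype}")
    return arr


def write_label_png(path, labels: np.ndarray) -> None:
    """Write a label map as an 8-bit PNG, class index as pixel value."""
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() > N_GRAY - 1:
        raise ValueError("label values do not fit in 8 bits")
    iio.imwrite(path, lab.astype(np.uint8))


def read_histogram_text(path) -> GrayHistogram:
    """Read 256 whitespace/newline/comma-separated nonnegative integer counts."""
    with open(path) as fh:
        tokens = fh.read().replace(",", " ").split()
    if len(tokens) != N_GRAY:
        raise ValueError(
            f"histogram file must contain exactly {N_GRAY} values, got {len(tokens)}"
        )
    try:
        counts = np.array([int(t) for t in tokens], dtype=np.int64)
    except ValueError as exc:
        raise ValueError(f"non-integer value in histogram file: {exc}") from exc
    return GrayHistogram(counts)


def write_histogram_text(path, h: GrayHistogram) -> None:
    """Write counts as 256 newline-separated integers."""
    np.savetxt(path, h.counts, fmt="%d")
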