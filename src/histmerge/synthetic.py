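"""Synthetic MR-like grayscale fixtures with known ground-truth thresholds.

Brain MR intensity histograms are well approximated by a mixture of a
few Gaussian modes (CSF, gray matter, white matter, background).  This
module draws 8-bit images or histograms from a stated 2–5 mode Gaussian
mixture on [0, 255] and reports the ground-truth thresholds as the
*valleys* of the analytic mixture density between consecutive mode
means, located by scanning the density on integer gray levels.  Valleys
— not Bayes boundaries — are what histogram-shape methods can see; for
equal-spread modes the two coincide.

The module-level ``TWO_MODE`` and ``THREE_MODE`` specs are the canonical
study conditions used throughout the test-bench: modes separated by six
standard deviations, the tightest spacing at which the inter-mode valley
still carries pixel mass, rendered at 256x256 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import N_GRAY, GrayHistogram


@dataclass(frozen=True)
class ModeSpec:
    """One Gaussian mode: mean gray, spread (sd, gray levels), mixing weight."""

    mean: float
    sd: float
    weight: float


#: Canonical two-class fixture: equal modes six sd apart, valley at 128.
TWO_MODE = (ModeSpec(80.0, 16.0, 0.5), ModeSpec(176.0, 16.0, 0.5))

#: Canonical three-class fixture: modes six sd apart, MR-like weights.
THREE_MODE = (
    ModeSpec(56.0, 12.0, 0.4),
    ModeSpec(128.0, 12.0, 0.3),
    ModeSpec(200.0, 12.0, 0.3),
)


def _validate_modes(modes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    modes = list(modes)
    if len(modes) < 2:
        raise ValueError("at least 2 modes required (no threshold exists otherwise)")
    if len(modes) > 5:
        raise ValueError("at most 5 modes supported")
    means = np.array([m.mean for m in modes], dtype=np.float64)
    sds = np.array([m.sd for m in modes], dtype=np.float64)
    weights = np.array([m.weight for m in modes], dtype=np.float64)
    if (np.diff(means) <= 0).any():
        raise ValueError("mode means must be strictly increasing")
    if (sds <= 0).any():
        raise ValueError("mode sds must be positive")
    if abs(weights.sum() - 1.0) > 1e-9 or (weights < 0).any():
        raise ValueError("mode weights must be nonnegative and sum to 1")
    return means, sds, weights


def mixture_density(modes, x) -> np.ndarray:
    """Analytic mixture density at gray value(s) x (not renormalized to [0,255])."""
    means, sds, weights = _validate_modes(modes)
    x = np.asarray(x, dtype=np.float64)[..., None]
    comp = weights * np.exp(-0.5 * ((x - means) / sds) ** 2) / (sds * np.sqrt(2 * np.pi))
    return comp.sum(axis=-1)


def valley_thresholds(modes) -> list[int]:
    """Ground-truth thresholds: the density minimum (integer scan) between
    each pair of consecutive mode means.  Ties take the lowest gray."""
    means, _, _ = _validate_modes(modes)
    grid = np.arange(N_GRAY, dtype=np.float64)
    dens = mixture_density(modes, grid)
    out: list[int] = []
    for m0, m1 in zip(means, means[1:]):
        lo = int(np.ceil(m0))
        hi = int(np.floor(m1))
        seg = dens[lo : hi + 1]
        out.append(lo + int(np.argmin(seg)))
    return out


def _sample_values(modes, n: int, rng: np.random.Generator) -> np.ndarray:
    means, sds, weights = _validate_modes(modes)
    comp = rng.choice(len(means), size=n, p=weights)
    vals = rng.normal(means[comp], sds[comp])
    return np.clip(np.rint(vals), 0, N_GRAY - 1).astype(np.uint8)


def synth_image(
    modes, shape: tuple[int, int] = (256, 256), seed: int = 0
) -> tuple[np.ndarray, list[int]]:
    """Draw an 8-bit image from the mixture; return (image, true thresholds).

    Pixels are iid mixture draws, rounded and clipped to [0, 255]; there
    is no spatial structure, bias field or partial-volume blur.  The same
    seed always reproduces the same image.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError("image shape must be positive")
    rng = np.random.default_rng(seed)
    img = _sample_values(modes, rows * cols, rng).reshape(rows, cols)
    return img, valley_thresholds(modes)


def synth_histogram(
    modes, total_pixels: int = 65536, seed: int = 0
) -> tuple[GrayHistogram, list[int]]:
    """Sample histogram counts directly from the mixture (fast fixture).

    Equivalent to building the histogram of a ``total_pixels``-pixel
    :func:`synth_image` draw, without materializing the image.
    """
    if total_pixels <= 0:
        raise ValueError("total_pixels must be positive")
    rng = np.random.default_rng(seed)
    vals = _sample_values(modes, int(total_pixels), rng)
    counts = np.bincount(vals.astype(np.int64), minlength=N_GRAY)
    return GrayHistogram(counts), valley_thresholds(modes)
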