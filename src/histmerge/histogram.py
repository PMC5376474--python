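"""256-bin gray-level histograms and per-region statistics.

Everything in this package operates on the image histogram rather than
the pixel grid: an 8-bit image contributes only its 256 bin counts, from
which bin probabilities ``P_i = counts_i / (M*N)`` are derived.  A
*region* is a contiguous inclusive run of gray levels ``[lo, hi]``
carrying its probability mass ``omega``, mean gray ``mu``, gray variance
``sigma2`` and the merge energy ``D = omega * sigma2`` that drives the
region-merging segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_GRAY = 256


@dataclass(frozen=True, eq=False)
class GrayHistogram:
    """An 8-bit gray-level histogram: 256 nonnegative integer counts.

    Parameters
    ----------
    counts
        Sequence of exactly 256 nonnegative integers, ``counts[i]`` being
        the number of pixels with gray level ``i``.  The total must be
        positive.

    Attributes
    ----------
    total_pixels : int
        ``M*N``, the number of pixels the histogram was built from.
    probs : numpy.ndarray
        Bin probabilities ``P_i = counts_i / total_pixels``; sums to 1.
    """

    counts: np.ndarray
    probs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_GRAY,):
            raise ValueError(
                f"histogram must have exactly {N_GRAY} bins, got shape {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise ValueError("histogram counts must be integers")
            counts = rounded
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("histogram counts must be nonnegative")
        total = int(counts.sum())
        if total <= 0:
            raise ValueError("histogram is empty (zero total count)")
        counts.setflags(write=False)
        probs = counts / total
        probs.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "probs", probs)

    @property
    def total_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Region:
    """A contiguous gray-level interval ``[lo, hi]`` with its statistics.

    ``energy`` is the merge criterion ``D = omega * sigma2``: probability
    mass times within-region gray variance.  Low-energy regions carry
    little information and are merged first.
    """

    lo: int
    hi: int
    omega: float
    mu: float
    sigma2: float
    energy: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= N_GRAY - 1):
            raise ValueError(f"invalid interval [{self.lo}, {self.hi}]")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.lo, self.hi)


# gray-level axis, shared by every statistic computation
_LEVELS = np.arange(N_GRAY, dtype=np.float64)


def region_stats(h: GrayHistogram, lo: int, hi: int) -> Region:
    """Compute ``omega``, ``mu``, ``sigma2`` and ``D`` for gray levels [lo, hi].

    An empty region (``omega == 0``) gets ``mu`` at the interval midpoint
    and zero variance/energy, keeping it finite and maximally mergeable.
    A singleton region has exactly zero variance by construction.
    """
    if lo > hi:
        raise ValueError(f"invalid interval: lo={lo} > hi={hi}")
    if not (0 <= lo and hi <= N_GRAY - 1):
        raise ValueError(f"invalid interval [{lo}, {hi}]: outside [0, 255]")
    p = h.probs[lo : hi + 1]
    omega = float(p.sum())
    if omega == 0.0:
        return Region(lo, hi, 0.0, (lo + hi) / 2.0, 0.0, 0.0)
    if lo == hi:
        return Region(lo, hi, omega, float(lo), 0.0, 0.0)
    levels = _LEVELS[lo : hi + 1]
    mu = float((levels * p).sum()) / omega
    sigma2 = float(((levels - mu) ** 2 * p).sum()) / omega
    return Region(lo, hi, omega, mu, sigma2, omega * sigma2)


@dataclass
class Partition:
    """An ordered, gap-free cover of [0, 255] by adjacent regions.

    The segmentation thresholds are the internal boundaries: with ``k``
    regions there are ``k - 1`` thresholds, read off as each non-final
    region's ``hi``.
    """

    regions: list[Region]
    histogram: GrayHistogram

    @property
    def n_thresholds(self) -> int:
        return len(self.regions) - 1

    def thresholds(self) -> list[int]:
        return [r.hi for r in self.regions[:-1]]

    def validate(self, tol: float = 1e-9) -> None:
        """Raise if the partition is not an exact adjacent cover of [0, 255]."""
        regs = self.regions
        if not regs:
            raise ValueError("partition has no regions")
        if regs[0].lo != 0 or regs[-1].hi != N_GRAY - 1:
            raise ValueError("partition does not cover [0, 255]")
        for prev, nxt in zip(regs, regs[1:]):
            if nxt.lo != prev.hi + 1:
                raise ValueError(
                    f"regions [{prev.lo},{prev.hi}] and [{nxt.lo},{nxt.hi}] not adjacent"
                )
        total = sum(r.omega for r in regs)
        if abs(total - 1.0) > tol:
            raise ValueError(f"region masses sum to {total}, not 1")


def build_histogram(image) -> GrayHistogram:
    """Count gray levels of a 2-D 8-bit grayscale image into a GrayHistogram.

    Rejects empty arrays, multi-channel images and values outside [0, 255].
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty input")
    if arr.ndim != 2:
        raise ValueError(f"not 8-bit gray: expected a 2-D image, got {arr.ndim}-D")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.array_equal(np.rint(arr), arr):
            raise ValueError("not 8-bit gray: non-integer pixel values")
        arr = np.rint(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > N_GRAY - 1:
        raise ValueError("not 8-bit gray: values outside [0, 255]")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=N_GRAY)
    return GrayHistogram(counts)


def histogram_from_counts(counts) -> GrayHistogram:
    """Build a GrayHistogram from an explicit 256-long count sequence."""
    return GrayHistogram(np.asarray(counts))
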