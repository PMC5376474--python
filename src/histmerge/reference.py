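"""No-cache reference implementation of the merge loop, for verification.

This module re-runs the greedy region merging with none of the
incremental bookkeeping of :mod:`histmerge.merging`: every iteration it
recomputes the statistics of *every* current region from scratch out of
the raw bin probabilities, then scans linearly for the minimum-energy
region and its smaller-energy neighbor.  It shares only the
``GrayHistogram`` container with the production path.  It exists so that
tests can demand bit-for-bit identical traces and thresholds from the
two routes on arbitrary histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import N_GRAY, GrayHistogram

_LEVELS = np.arange(N_GRAY, dtype=np.float64)


@dataclass(frozen=True)
class ReferenceStep:
    iteration: int
    selected: tuple[int, int]
    absorbed: tuple[int, int]
    merged_interval: tuple[int, int]
    merged_energy: float


def _fresh_stats(probs: np.ndarray, lo: int, hi: int) -> tuple[float, float, float, float]:
    """(omega, mu, sigma2, energy) for [lo, hi], straight from the bins.

    Mirrors the defining formulas exactly: singletons have zero variance,
    empty intervals sit at their midpoint with zero mass and energy.
    """
    p = probs[lo : hi + 1]
    omega = float(p.sum())
    if omega == 0.0:
        return 0.0, (lo + hi) / 2.0, 0.0, 0.0
    if lo == hi:
        return omega, float(lo), 0.0, 0.0
    levels = _LEVELS[lo : hi + 1]
    mu = float((levels * p).sum()) / omega
    sigma2 = float(((levels - mu) ** 2 * p).sum()) / omega
    return omega, mu, sigma2, omega * sigma2


def brute_force_merging(
    h: GrayHistogram, T: int
) -> tuple[list[int], list[ReferenceStep]]:
    """Run the merge loop to ``T`` thresholds with zero caching.

    Returns the final threshold list and the per-iteration step log.
    Selection ties go to the smallest ``lo``; a neighbor energy tie
    merges left; boundary regions merge with their only neighbor.
    """
    if not (1 <= T <= N_GRAY - 2):
        raise ValueError(f"invalid threshold count T={T}: must be in [1, 254]")
    probs = h.probs
    # region list as (lo, hi) intervals only -- no cached statistics
    intervals: list[tuple[int, int]] = [(i, i) for i in range(N_GRAY)]
    steps: list[ReferenceStep] = []
    it = 0
    while len(intervals) - 1 > T:
        it += 1
        energies = [_fresh_stats(probs, lo, hi)[3] for lo, hi in intervals]
        k = 0
        for i in range(1, len(energies)):
            if energies[i] < energies[k]:
                k = i
        if k == 0:
            j = 1
        elif k == len(intervals) - 1:
            j = k - 1
        else:
            j = k - 1 if energies[k - 1] <= energies[k + 1] else k + 1
        sel, nb = intervals[k], intervals[j]
        merged = (min(sel[0], nb[0]), max(sel[1], nb[1]))
        a, b = (j, k) if j < k else (k, j)
        intervals[a : b + 1] = [merged]
        steps.append(
            ReferenceStep(
                iteration=it,
                selected=sel,
                absorbed=nb,
                merged_interval=merged,
                merged_energy=_fresh_stats(probs, *merged)[3],
            )
        )
    thresholds = [hi for _, hi in intervals[:-1]]
    return thresholds, steps
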