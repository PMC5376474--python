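"""Greedy histogram region merging: the multithreshold segmenter.

The histogram starts as 256 singleton regions (every gray level is a
threshold).  Each iteration picks the region with minimum energy
``D = omega * sigma2`` and merges it into the adjacent region whose own
``D`` is smaller, removing one threshold, until the requested number of
thresholds ``T`` remains.  Reaching ``T`` thresholds therefore takes
exactly ``255 - T`` iterations, so the work is linear in the number of
gray levels no matter how many thresholds are requested — the point of
the method compared to exhaustive multilevel searches.

Determinism: ties in the minimum-energy scan go to the region with the
smallest ``lo``; a left/right neighbor energy tie merges left.  Boundary
regions merge with their only neighbor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .histogram import (
    N_GRAY,
    GrayHistogram,
    Partition,
    Region,
    region_stats,
)


@dataclass(frozen=True)
class MergeStep:
    """One merge: iteration index (1-based), the selected region's interval,
    the absorbed neighbor's interval, and the resulting merged region."""

    iteration: int
    selected: tuple[int, int]
    absorbed: tuple[int, int]
    merged: Region


@dataclass
class MergeTrace:
    """Ordered audit log of a merging run.

    ``energy_evaluations`` counts every region-statistics computation the
    run performed (256 at initialization plus one per merge), the costed
    operation behind the method's linear work bound.
    """

    steps: list[MergeStep] = field(default_factory=list)
    energy_evaluations: int = 0

    def __len__(self) -> int:
        return len(self.steps)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["iteration", "selected_lo", "selected_hi",
                 "neighbor_lo", "neighbor_hi", "merged_energy"]
            )
            for s in self.steps:
                w.writerow(
                    [s.iteration, s.selected[0], s.selected[1],
                     s.absorbed[0], s.absorbed[1], repr(s.merged.energy)]
                )


def initialize_partition(h: GrayHistogram) -> Partition:
    """256 singleton regions [i, i] — every gray level starts as a threshold."""
    regions = [region_stats(h, i, i) for i in range(N_GRAY)]
    return Partition(regions=regions, histogram=h)


def select_min_energy_region(p: Partition) -> int:
    """Index of the minimum-energy region; ties go to the smallest ``lo``.

    Regions are stored in gray-level order, so the first strict minimum
    is the tie-broken answer.
    """
    if len(p.regions) < 2:
        raise ValueError("nothing to merge: partition has a single region")
    best = 0
    best_energy = p.regions[0].energy
    for i in range(1, len(p.regions)):
        e = p.regions[i].energy
        if e < best_energy:
            best, best_energy = i, e
    return best


def choose_merge_neighbor(p: Partition, k: int) -> int:
    """Which neighbor absorbs region ``k``: the one with smaller energy.

    Boundary regions have a single neighbor; an energy tie merges left.
    """
    n = len(p.regions)
    if n < 2:
        raise ValueError("nothing to merge: partition has a single region")
    if not (0 <= k < n):
        raise ValueError(f"region index {k} out of range")
    if k == 0:
        return 1
    if k == n - 1:
        return n - 2
    left, right = p.regions[k - 1], p.regions[k + 1]
    return k - 1 if left.energy <= right.energy else k + 1


def merge_once(p: Partition, trace: MergeTrace | None = None) -> Partition:
    """Perform one merge in place: remove one threshold, append one step.

    The merged region's statistics are recomputed fresh over the union
    interval (one energy evaluation); no other region changes.
    """
    k = select_min_energy_region(p)
    j = choose_merge_neighbor(p, k)
    sel, nb = p.regions[k], p.regions[j]
    lo, hi = min(sel.lo, nb.lo), max(sel.hi, nb.hi)
    merged = region_stats(p.histogram, lo, hi)
    a, b = (j, k) if j < k else (k, j)
    p.regions[a : b + 1] = [merged]
    if trace is not None:
        trace.energy_evaluations += 1
        trace.steps.append(
            MergeStep(
                iteration=len(trace.steps) + 1,
                selected=sel.interval,
                absorbed=nb.interval,
                merged=merged,
            )
        )
    return p


class MergeAuditError(AssertionError):
    """Cached region statistics diverged from a fresh recomputation."""


def _audit(p: Partition, tol: float = 1e-9) -> None:
    for r in p.regions:
        fresh = region_stats(p.histogram, r.lo, r.hi)
        for name in ("omega", "mu", "sigma2", "energy"):
            got, want = getattr(r, name), getattr(fresh, name)
            if abs(got - want) > tol:
                raise MergeAuditError(
                    f"region [{r.lo},{r.hi}] cached {name}={got!r} vs fresh {want!r}"
                )


def run_merging(
    h: GrayHistogram, T: int, audit: bool = False
) -> tuple[Partition, MergeTrace]:
    """Merge the histogram down to exactly ``T`` thresholds.

    Parameters
    ----------
    h
        The gray-level histogram to segment.
    T
        Requested number of thresholds, between 1 and 254.
    audit
        When true, after every merge all cached region statistics are
        checked against a fresh recomputation (slow; for verification).

    Returns
    -------
    (partition, trace)
        The final ``T + 1``-region partition and the full merge trace
        with ``255 - T`` steps.
    """
    if not (1 <= T <= N_GRAY - 2):
        raise ValueError(f"invalid threshold count T={T}: must be in [1, 254]")
    p = initialize_partition(h)
    trace = MergeTrace(energy_evaluations=N_GRAY)
    while p.n_thresholds > T:
        merge_once(p, trace)
        if audit:
            _audit(p)
            p.validate()
    return p, trace


def thresholds_from_partition(p: Partition) -> list[int]:
    """Internal boundaries of the partition, as gray-level thresholds.

    Pixel ``g`` belongs to class ``j`` where ``thresholds[j-1] < g <=
    thresholds[j]`` (class 0: ``g <= thresholds[0]``).
    """
    return p.thresholds()


def merge_thresholds(
    h: GrayHistogram, T: int, return_trace: bool = False
):
    """Convenience entry point: histogram + T -> threshold list (+ trace)."""
    p, trace = run_merging(h, T)
    ts = thresholds_from_partition(p)
    return (ts, trace) if return_trace else ts
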