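"""Exhaustive multilevel Otsu thresholding, the classical comparator.

Otsu's criterion picks the thresholds maximizing the between-class
variance ``sum_k omega_k (mu_k - mu_global)^2``.  Multilevel Otsu is
solved here by true exhaustive search over every strictly increasing
T-tuple of thresholds in [0, 254] — C(255, T) candidates, the
combinatorial cost that motivates the region-merging alternative.  The
search is capped at T = 4 by default.

Class convention matches the merge segmenter: class ``k`` covers grays
``t_{k-1}+1 .. t_k`` inclusive, so threshold lists from both methods are
directly comparable.  Candidate tuples producing empty classes are legal
(an empty class contributes zero to the objective); ties are broken by
the lexicographically smallest tuple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import N_GRAY, GrayHistogram, region_stats

_T_MAX = N_GRAY - 2  # thresholds live in [0, 254]


@dataclass(frozen=True)
class OtsuResult:
    """Optimal thresholds, the achieved between-class variance (gray^2),
    and the number of candidate tuples the exhaustive search evaluated."""

    thresholds: tuple[int, ...]
    between_class_variance: float
    candidates_evaluated: int


def between_class_variance(h: GrayHistogram, thresholds) -> float:
    """``sum_k omega_k (mu_k - mu_global)^2`` for one candidate tuple."""
    ts = list(thresholds)
    if ts != sorted(set(ts)):
        raise ValueError("thresholds must be strictly increasing")
    mu_g = float((np.arange(N_GRAY) * h.probs).sum())
    bounds = [-1] + ts + [N_GRAY - 1]
    total = 0.0
    for a, b in zip(bounds, bounds[1:]):
        r = region_stats(h, a + 1, b)
        if r.omega > 0:
            total += r.omega * (r.mu - mu_g) ** 2
    return total


def otsu_exhaustive(h: GrayHistogram, T: int, cap: int = 4) -> OtsuResult:
    """Globally optimal T-level Otsu thresholds by exhaustive enumeration.

    Parameters
    ----------
    h
        Gray-level histogram.
    T
        Number of thresholds; must satisfy ``1 <= T <= cap``.
    cap
        Safety cap on the search depth (default 4: C(255, 4) ~ 1.7e8
        candidates is the practical limit of full enumeration).

    Notes
    -----
    Enumeration runs in lexicographic tuple order with the last
    threshold vectorized; the first strictly larger objective wins, so
    exact ties resolve to the lexicographically smallest tuple.
    """
    if T < 1:
        raise ValueError(f"invalid threshold count T={T}: must be >= 1")
    if T > cap:
        raise ValueError(
            f"exhaustive search capped at T={cap} (requested T={T}); "
            "raise `cap` explicitly to search deeper"
        )
    if T > _T_MAX:
        raise ValueError(f"invalid threshold count T={T}: must be <= {_T_MAX}")

    p = h.probs
    levels = np.arange(N_GRAY, dtype=np.float64)
    cw = np.concatenate(([0.0], np.cumsum(p)))
    cs = np.concatenate(([0.0], np.cumsum(levels * p)))
    mu_g = cs[N_GRAY]

    def seg_scalar(a: int, b: int) -> float:
        # contribution S^2/W of the class covering grays a..b (0 if empty)
        w = cw[b + 1] - cw[a]
        if w <= 0.0:
            return 0.0
        s = cs[b + 1] - cs[a]
        return s * s / w

    t_all = np.arange(_T_MAX + 1)  # 0..254
    # tail[t]: contribution of the final class (t+1 .. 255)
    w_tail = cw[N_GRAY] - cw[t_all + 1]
    s_tail = cs[N_GRAY] - cs[t_all + 1]
    tail = np.where(w_tail > 0, s_tail**2 / np.where(w_tail > 0, w_tail, 1.0), 0.0)

    best_val = -np.inf
    best: tuple[int, ...] = ()
    count = 0

    def descend(prev: int, depth: int, partial: float, prefix: tuple[int, ...]) -> None:
        nonlocal best_val, best, count
        if depth == T - 1:
            last = np.arange(prev + 1, _T_MAX + 1)
            a = prev + 1
            w = cw[last + 1] - cw[a]
            s = cs[last + 1] - cs[a]
            vals = partial + np.where(w > 0, s**2 / np.where(w > 0, w, 1.0), 0.0)
            vals = vals + tail[last]
            count += len(last)
            j = int(np.argmax(vals))
            if vals[j] > best_val:
                best_val = float(vals[j])
                best = prefix + (int(last[j]),)
            return
        for t in range(prev + 1, N_GRAY - (T - depth - 1) - 1):
            descend(t, depth + 1, partial + seg_scalar(prev + 1, t), prefix + (t,))

    descend(-1, 0, 0.0, ())
    bcv = max(best_val - mu_g * mu_g, 0.0)
    return OtsuResult(
        thresholds=best, between_class_variance=bcv, candidates_evaluated=count
    )
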