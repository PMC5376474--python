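"""The greedy region-merging loop: selection, merging, trace, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from histmerge import (
    MergeTrace,
    Partition,
    choose_merge_neighbor,
    histogram_from_counts,
    initialize_partition,
    merge_once,
    merge_thresholds,
    region_stats,
    run_merging,
    select_min_energy_region,
    thresholds_from_partition,
)

counts_strategy = arrays(
    np.int64, 256, elements=st.integers(0, 1000)
).filter(lambda c: c.sum() > 0)


class TestInitialization:
    def test_256_singletons(self, four_level_hist):
        p = initialize_partition(four_level_hist)
        assert len(p.regions) == 256
        assert all(r.lo == r.hi == i for i, r in enumerate(p.regions))
        assert p.n_thresholds == 255
        assert thresholds_from_partition(p) == list(range(255))
        p.validate()

    def test_point_mass(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = 1
        p = initialize_partition(histogram_from_counts(counts))
        assert p.regions[0].omega == 1.0
        assert all(r.omega == 0.0 for r in p.regions[1:])

    def test_all_singleton_energies_zero(self, four_level_hist):
        p = initialize_partition(four_level_hist)
        assert all(r.energy == 0.0 for r in p.regions)


def _partition_with_energies(h, intervals):
    """Build a Partition straight from given [lo, hi] intervals."""
    return Partition([region_stats(h, lo, hi) for lo, hi in intervals], h)


class TestSelection:
    def test_unique_minimum(self, four_level_hist):
        p = _partition_with_energies(
            four_level_hist, [(0, 1), (2, 2), (3, 255)]
        )
        # energies: 0.125, 0 (singleton), ~0 -> first zero wins
        assert p.regions[0].energy > 0
        assert select_min_energy_region(p) == 1

    def test_tie_breaks_to_lowest_gray(self, four_level_hist):
        p = initialize_partition(four_level_hist)  # all energies zero
        assert select_min_energy_region(p) == 0

    def test_single_region_error(self, four_level_hist):
        p = _partition_with_energies(four_level_hist, [(0, 255)])
        with pytest.raises(ValueError, match="nothing to merge"):
            select_min_energy_region(p)


class TestNeighborChoice:
    def test_boundary_regions_have_one_neighbor(self, four_level_hist):
        p = _partition_with_energies(
            four_level_hist, [(0, 0), (1, 1), (2, 255)]
        )
        assert choose_merge_neighbor(p, 0) == 1
        assert choose_merge_neighbor(p, 2) == 1

    def test_interior_takes_smaller_energy_side(self, four_level_hist):
        # left [0,1] D=0.125 > right [3,3] D=0 -> right wins for k=middle
        p = _partition_with_energies(
            four_level_hist, [(0, 1), (2, 2), (3, 3), (4, 255)]
        )
        assert choose_merge_neighbor(p, 1) == 2

    def test_interior_energy_tie_goes_left(self, four_level_hist):
        # both neighbors are zero-energy singletons
        p = _partition_with_energies(
            four_level_hist, [(0, 0), (1, 1), (2, 2), (3, 255)]
        )
        assert choose_merge_neighbor(p, 1) == 0


class TestMergeOnce:
    def test_first_two_hand_simulated_merges(self, four_level_hist):
        p = initialize_partition(four_level_hist)
        trace = MergeTrace(energy_evaluations=256)
        merge_once(p, trace)
        s1 = trace.steps[0]
        assert (s1.selected, s1.absorbed) == ((0, 0), (1, 1))
        assert s1.merged.interval == (0, 1)
        assert s1.merged.energy == pytest.approx(0.125, abs=1e-12)
        merge_once(p, trace)
        s2 = trace.steps[1]
        # min D is zero again; lowest-gray zero region is [2,2]; its right
        # neighbor [3,3] (D=0) beats the left [0,1] (D=0.125)
        assert (s2.selected, s2.absorbed) == ((2, 2), (3, 3))
        assert s2.merged.interval == (2, 3)
        assert s2.merged.energy == pytest.approx(0.09375, abs=1e-12)

    def test_region_count_drops_by_one_and_mass_conserved(
        self, random_hist_factory
    ):
        h = random_hist_factory(7)
        p = initialize_partition(h)
        for _ in range(40):
            n = len(p.regions)
            merge_once(p)
            assert len(p.regions) == n - 1
            p.validate()  # adjacency, coverage, sum(omega) == 1


class TestRunMerging:
    @pytest.mark.parametrize("bad_T", [0, -3, 255, 400])
    def test_invalid_threshold_count(self, four_level_hist, bad_T):
        with pytest.raises(ValueError, match="invalid threshold count"):
            run_merging(four_level_hist, bad_T)

    def test_T254_is_single_merge(self, random_hist_factory):
        p, trace = run_merging(random_hist_factory(11), 254)
        assert len(trace.steps) == 1
        assert p.n_thresholds == 254

    @pytest.mark.parametrize("T", [1, 2, 5, 100, 253])
    def test_trace_has_255_minus_T_steps(self, random_hist_factory, T):
        p, trace = run_merging(random_hist_factory(13), T)
        assert len(trace.steps) == 255 - T
        assert p.n_thresholds == T
        assert len(p.regions) == T + 1

    def test_four_level_T1_threshold_separates_masses(self, four_level_hist):
        p, _ = run_merging(four_level_hist, 1)
        assert thresholds_from_partition(p) == [1]

    def test_deterministic(self, random_hist_factory):
        h = random_hist_factory(17)
        p1, t1 = run_merging(h, 4)
        p2, t2 = run_merging(h, 4)
        assert thresholds_from_partition(p1) == thresholds_from_partition(p2)
        assert [(s.selected, s.absorbed) for s in t1.steps] == [
            (s.selected, s.absorbed) for s in t2.steps
        ]
        assert [s.merged.energy for s in t1.steps] == [
            s.merged.energy for s in t2.steps
        ]

    def test_audit_mode_passes_on_random_histogram(self, random_hist_factory):
        run_merging(random_hist_factory(19), 3, audit=True)

    def test_cached_stats_match_fresh_recomputation(self, random_hist_factory):
        h = random_hist_factory(23)
        p, _ = run_merging(h, 6)
        for r in p.regions:
            fresh = region_stats(h, r.lo, r.hi)
            assert r.omega == pytest.approx(fresh.omega, abs=1e-12)
            assert r.mu == pytest.approx(fresh.mu, abs=1e-12)
            assert r.sigma2 == pytest.approx(fresh.sigma2, abs=1e-12)
            assert r.energy == pytest.approx(fresh.energy, abs=1e-12)

    @pytest.mark.parametrize("T", [1, 50, 254])
    def test_energy_evaluation_count_linear_in_gray_levels(
        self, random_hist_factory, T
    ):
        _, trace = run_merging(random_hist_factory(29), T)
        assert trace.energy_evaluations == 256 + (255 - T)
        assert trace.energy_evaluations <= 2 * 256

    def test_merge_thresholds_convenience(self, four_level_hist):
        assert merge_thresholds(four_level_hist, 1) == [1]
        ts, trace = merge_thresholds(four_level_hist, 2, return_trace=True)
        assert len(ts) == 2 and len(trace.steps) == 253


class TestTraceExport:
    def test_csv_rows_match_iterations(self, tmp_path, random_hist_factory):
        _, trace = run_merging(random_hist_factory(31), 250)
        out = tmp_path / "trace.csv"
        trace.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("iteration,")
        assert len(lines) - 1 == 5  # 255 - 250


class TestMergingProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(counts=counts_strategy, T=st.integers(1, 254))
    def test_partition_laws_for_any_histogram_and_T(self, counts, T):
        h = histogram_from_counts(counts)
        p, trace = run_merging(h, T)
        assert len(trace.steps) == 255 - T
        p.validate()
        ts = thresholds_from_partition(p)
        assert all(a < b for a, b in zip(ts, ts[1:]))
        # every merged pair was adjacent at merge time
        for s in trace.steps:
            assert (
                s.selected[1] + 1 == s.absorbed[0]
                or s.absorbed[1] + 1 == s.selected[0]
            )
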