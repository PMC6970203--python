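import numpy as np
import pytest

from conftest import make_condition
from srnarefine.genome import Feature, GenomeAnnotation, IntergenicRegion
from srnarefine.scout import (
    CriteriaError,
    FilterCriteria,
    detect_peaks,
    expand_region,
    find_runs,
    fold_change_track,
    merge_regions,
    scout,
    suggest_criteria,
)


def brute_force_runs(values, threshold, min_len):
    """All maximal intervals of >=threshold positions, filtered by length."""
    n = len(values)
    runs = []
    for s in range(n):
        for e in range(s + 1, n + 1):
            if all(values[p] >= threshold for p in range(s, e)):
                if (s == 0 or values[s - 1] < threshold) and (e == n or values[e] < threshold):
                    runs.append((s, e))
    return [(s, e) for s, e in runs if e - s >= min_len]


class TestFindRuns:
    def test_basic_run(self):
        values = np.array([0, 40, 40, 40, 40, 0])
        assert find_runs(values, 34, 3) == [(1, 5)]

    def test_min_len_filters(self):
        values = np.array([0, 40, 40, 40, 40, 0])
        assert find_runs(values, 34, 5) == []

    def test_matches_brute_force_on_random_arrays(self):
        rng = np.random.default_rng(202)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            values = rng.integers(0, 5, size=n).astype(float)
            threshold = float(rng.integers(0, 5))
            min_len = int(rng.integers(1, 5))
            assert find_runs(values, threshold, min_len) == brute_force_runs(
                values, threshold, min_len
            )


class TestFoldChangeTrack:
    def test_pseudocounted_ratio(self):
        track = fold_change_track(np.array([8.0]), np.array([2.0]), 1.0)
        assert track[0] == pytest.approx(3.0)

    def test_equal_coverage_gives_one(self):
        a = np.array([0.0, 5.0, 100.0])
        assert np.allclose(fold_change_track(a, a, 1.0), 1.0)

    def test_condition_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 50, 100), rng.uniform(0, 50, 100)
        assert np.allclose(fold_change_track(a, b, 1.0), fold_change_track(b, a, 1.0))


class TestDetectPeaks:
    criteria = FilterCriteria(min_expression=34, min_expression_run=24,
                              fold_change=2.7, fold_change_run=15)

    def igr(self, length=1000):
        return IntergenicRegion("c1", "+", 0, length)

    def conditions(self, a, b):
        return (make_condition("A", {("c1", "+"): a}),
                make_condition("B", {("c1", "+"): b}))

    def test_single_differential_block(self):
        a, b = np.zeros(1000), np.zeros(1000)
        a[100:130] = 100.0
        b[100:130] = 10.0
        cond_a, cond_b = self.conditions(a, b)
        peaks = detect_peaks(cond_a, cond_b, self.igr(), self.criteria)
        assert [(p.start, p.end) for p in peaks] == [(100, 130)]
        assert peaks[0].peak_max_coverage == (100.0, 10.0)
        assert peaks[0].peak_max_fold == pytest.approx(101.0 / 11.0)

    def test_expressed_but_not_differential(self):
        a = np.zeros(1000)
        a[100:130] = 100.0
        cond_a, cond_b = self.conditions(a, a.copy())
        assert detect_peaks(cond_a, cond_b, self.igr(), self.criteria) == []

    def test_block_shorter_than_expression_run(self):
        a, b = np.zeros(1000), np.zeros(1000)
        a[100:110] = 100.0
        cond_a, cond_b = self.conditions(a, b)
        assert detect_peaks(cond_a, cond_b, self.igr(), self.criteria) == []

    def test_threshold_monotonicity(self):
        # tightening the fold criteria or the run lengths never yields more
        # peaks; tightening the expression level never covers new positions
        # (it can split runs, so the peak COUNT alone is not monotone in it)
        rng = np.random.default_rng(88)
        for trial in range(20):
            a = rng.integers(0, 80, size=500).astype(float)
            b = rng.integers(0, 80, size=500).astype(float)
            cond_a, cond_b = self.conditions(a, b)
            base = FilterCriteria(min_expression=10, min_expression_run=3,
                                  fold_change=1.5, fold_change_run=2)
            peaks_base = detect_peaks(cond_a, cond_b, self.igr(500), base)
            for tighter in [
                FilterCriteria(min_expression=10, min_expression_run=6, fold_change=1.5, fold_change_run=2),
                FilterCriteria(min_expression=10, min_expression_run=3, fold_change=2.5, fold_change_run=2),
                FilterCriteria(min_expression=10, min_expression_run=3, fold_change=1.5, fold_change_run=4),
            ]:
                peaks = detect_peaks(cond_a, cond_b, self.igr(500), tighter)
                assert len(peaks) <= len(peaks_base)
            stricter_m = FilterCriteria(min_expression=20, min_expression_run=3,
                                        fold_change=1.5, fold_change_run=2)
            covered = np.zeros(500, dtype=bool)
            for p in peaks_base:
                covered[p.start : p.end] = True
            for p in detect_peaks(cond_a, cond_b, self.igr(500), stricter_m):
                assert covered[p.start : p.end].all()


class TestExpandRegion:
    def test_symmetric_expansion(self):
        assert expand_region((1000, 1100), 200, 10_000) == (950, 1150)

    def test_clip_at_chromosome_start_no_reextension(self):
        # symmetric target [-75, 125) is clipped, never re-extended rightward
        assert expand_region((0, 50), 200, 10_000) == (0, 125)

    def test_long_region_unchanged(self):
        assert expand_region((300, 600), 200, 10_000) == (300, 600)

    def test_odd_deficit_extra_on_right(self):
        start, end = expand_region((100, 101), 200, 10_000)
        assert (start, end) == (100 - 99, 101 + 100)


def brute_force_merge(intervals, gap):
    """Transitive closure of 'within gap' via union-find."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, (s1, e1) in enumerate(intervals):
        for j, (s2, e2) in enumerate(intervals):
            if max(s1, s2) - min(e1, e2) <= gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, iv in enumerate(intervals):
        groups.setdefault(find(i), []).append(iv)
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
    )


class TestMergeRegions:
    def test_gap_within_threshold(self):
        assert merge_regions([(100, 200), (230, 300)], 30) == [(100, 300)]

    def test_gap_strictly_greater_unmerged(self):
        assert merge_regions([(100, 200), (251, 300)], 50) == [(100, 200), (251, 300)]

    def test_gap_exactly_at_threshold_merges(self):
        assert merge_regions([(100, 200), (250, 300)], 50) == [(100, 300)]

    def test_chain_merging_equals_transitive_closure(self):
        chain = [(0, 10), (40, 50), (80, 90)]
        assert merge_regions(chain, 30) == [(0, 90)]
        assert merge_regions(chain, 30) == brute_force_merge(chain, 30)

    def test_matches_union_find_on_random_instances(self):
        rng = np.random.default_rng(404)
        for _ in range(200):
            n = int(rng.integers(0, 10))
            intervals = []
            for _ in range(n):
                s = int(rng.integers(0, 300))
                intervals.append((s, s + int(rng.integers(1, 60))))
            gap = int(rng.integers(0, 60))
            assert merge_regions(intervals, gap) == brute_force_merge(intervals, gap)

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(405)
        intervals = [(int(s), int(s) + int(l)) for s, l in
                     zip(rng.integers(0, 500, 15), rng.integers(1, 80, 15))]
        once = merge_regions(intervals, 50)
        assert merge_regions(once, 50) == once
        shuffled = list(intervals)
        rng.shuffle(shuffled)
        assert merge_regions(shuffled, 50) == once


class TestScout:
    def two_srna_genome(self, separation):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        genome = GenomeAnnotation(chromosomes={"c1": seq}, features=[])
        a, b = np.zeros(5000), np.zeros(5000)
        first = (1000, 1250)
        second = (first[1] + separation, first[1] + separation + 250)
        for s, e in (first, second):
            a[s:e] = 150.0
            b[s:e] = 15.0
        cond_a = make_condition("A", {("c1", "+"): a, ("c1", "-"): np.zeros(5000)})
        cond_b = make_condition("B", {("c1", "+"): b, ("c1", "-"): np.zeros(5000)})
        return genome, cond_a, cond_b

    def test_nearby_peaks_merge_into_one_region(self):
        genome, cond_a, cond_b = self.two_srna_genome(separation=40)
        regions = scout(cond_a, cond_b, genome, FilterCriteria())
        assert len(regions) == 1
        assert regions[0].id == "possRNA1"
        assert len(regions[0].peaks) == 2

    def test_distant_peaks_stay_separate(self):
        genome, cond_a, cond_b = self.two_srna_genome(separation=80)
        regions = scout(cond_a, cond_b, genome, FilterCriteria())
        assert [r.id for r in regions] == ["possRNA1", "possRNA2"]
        gap = regions[1].start - regions[0].end
        assert gap > FilterCriteria().merge_gap

    def test_identical_coverage_yields_nothing(self, featureless_genome):
        a = np.full(1000, 100.0)
        cond_a = make_condition("A", {("c1", "+"): a, ("c1", "-"): a})
        cond_b = make_condition("B", {("c1", "+"): a.copy(), ("c1", "-"): a.copy()})
        assert scout(cond_a, cond_b, featureless_genome, FilterCriteria()) == []

    def test_deterministic_rerun(self, small_dataset):
        from srnarefine.simulate import simulate_coverage

        cond_a = simulate_coverage(small_dataset, "A")
        cond_b = simulate_coverage(small_dataset, "B")
        first = scout(cond_a, cond_b, small_dataset.annotation, FilterCriteria())
        second = scout(cond_a, cond_b, small_dataset.annotation, FilterCriteria())
        assert [(r.id, r.start, r.end, r.strand) for r in first] == [
            (r.id, r.start, r.end, r.strand) for r in second
        ]

    def test_regions_within_bounds_and_separated(self, small_dataset):
        from srnarefine.simulate import simulate_coverage

        cond_a = simulate_coverage(small_dataset, "A")
        cond_b = simulate_coverage(small_dataset, "B")
        criteria = FilterCriteria()
        regions = scout(cond_a, cond_b, small_dataset.annotation, criteria)
        assert regions
        length = small_dataset.spec.chromosome_length
        for strand in "+-":
            on_strand = sorted(
                (r for r in regions if r.strand == strand), key=lambda r: r.start
            )
            for r in on_strand:
                assert 0 <= r.start < r.end <= length
            for r1, r2 in zip(on_strand, on_strand[1:]):
                assert r2.start - r1.end > criteria.merge_gap


class TestSuggestCriteria:
    def test_uniform_coverage(self, featureless_genome):
        a = np.full(1000, 10.0)
        cond_a = make_condition("A", {("c1", "+"): a, ("c1", "-"): np.zeros(1000)})
        cond_b = make_condition("B", {("c1", "+"): a.copy(), ("c1", "-"): np.zeros(1000)})
        crit = suggest_criteria(cond_a, cond_b, featureless_genome)
        assert crit.min_expression == pytest.approx(10.0)
        assert crit.fold_change == pytest.approx(1.0)
        assert crit.min_expression_run == 15 and crit.fold_change_run == 15

    def test_all_zero_coverage_is_error(self, featureless_genome):
        z = np.zeros(1000)
        cond_a = make_condition("A", {("c1", "+"): z, ("c1", "-"): z.copy()})
        cond_b = make_condition("B", {("c1", "+"): z.copy(), ("c1", "-"): z.copy()})
        with pytest.raises(CriteriaError, match="zero"):
            suggest_criteria(cond_a, cond_b, featureless_genome)

    def test_mixed_track_equals_direct_means(self, featureless_genome):
        rng = np.random.default_rng(77)
        a = rng.integers(0, 20, 1000).astype(float)
        b = rng.integers(0, 20, 1000).astype(float)
        z = np.zeros(1000)
        cond_a = make_condition("A", {("c1", "+"): a, ("c1", "-"): z})
        cond_b = make_condition("B", {("c1", "+"): b, ("c1", "-"): z.copy()})
        crit = suggest_criteria(cond_a, cond_b, featureless_genome)
        support = (a > 0) | (b > 0)
        expected_m = np.maximum(a, b)[support].mean()
        expected_f = np.maximum((a + 1) / (b + 1), (b + 1) / (a + 1))[support].mean()
        assert crit.min_expression == pytest.approx(expected_m)
        assert crit.fold_change == pytest.approx(expected_f)


class TestCriteriaValidation:
    @pytest.mark.parametrize("kwargs", [
        {"min_expression": -1}, {"min_expression_run": 0}, {"fold_change": 0.5},
        {"merge_gap": -1}, {"min_region_length": 0}, {"pseudocount": 0.0},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(CriteriaError):
            FilterCriteria(**kwargs)


class TestMergeProperties:
    """Structural invariants of interval merging under arbitrary inputs."""

    from hypothesis import given, settings, strategies as st

    intervals = st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 80)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        max_size=12,
    )

    @given(intervals=intervals, gap=st.integers(0, 60))
    @settings(derandomize=True, max_examples=150)
    def test_output_sorted_disjoint_and_covering(self, intervals, gap):
        merged = merge_regions(intervals, gap)
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert s2 - e1 > gap  # pairwise separation strictly beyond gap
        for s, e in intervals:
            assert any(ms <= s and e <= me for ms, me in merged)  # coverage

    @given(intervals=intervals, gap=st.integers(0, 60))
    @settings(derandomize=True, max_examples=150)
    def test_idempotent(self, intervals, gap):
        once = merge_regions(intervals, gap)
        assert merge_regions(once, gap) == once
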