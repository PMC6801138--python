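"""Exact clone-picking null: closed forms vs enumeration and Monte Carlo."""

import itertools
import math
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenstat.enrichment_stats import (
    PickOutcome,
    UniformLibraryNull,
    enrichment_report,
    monte_carlo_patterns,
    partitions,
    pattern_probabilities,
    pattern_probability,
    prob_all_distinct,
    prob_all_same,
)


def enumerate_pattern_probs(null: UniformLibraryNull, k: int) -> dict[tuple[int, ...], float]:
    """Exhaustive oracle: iterate every unordered k-subset of the N clones."""
    clones = [g for g in range(null.m) for _ in range(null.c)]
    counts: Counter = Counter()
    total = 0
    for combo in itertools.combinations(range(null.N), k):
        pat = tuple(sorted(Counter(clones[i] for i in combo).values(), reverse=True))
        counts[pat] += 1
        total += 1
    return {pat: n / total for pat, n in counts.items()}


class TestClosedForms:
    def test_paper_values_at_three_significant_figures(self, screen_null):
        assert f"{prob_all_distinct(screen_null, 5):.3g}" == "0.965"
        assert f"{prob_all_same(screen_null, 5):.3g}" == "8.38e-11"

    def test_single_pick_is_trivially_both(self, screen_null, small_null):
        for null in (screen_null, small_null):
            assert prob_all_distinct(null, 1) == 1.0
            assert prob_all_same(null, 1) == 1.0

    def test_small_pool_pair_pick(self, small_null):
        # m=3, c=2, k=2: 12 of the 15 unordered pairs are distinct
        assert prob_all_distinct(small_null, 2) == pytest.approx(0.8, abs=1e-12)
        assert prob_all_same(small_null, 2) == pytest.approx(0.2, abs=1e-12)

    def test_k_beyond_copies_is_zero_not_error(self, small_null):
        assert prob_all_same(small_null, 3) == 0.0

    def test_k_beyond_distinct_guides_is_zero(self, small_null):
        assert prob_all_distinct(small_null, 4) == 0.0

    def test_k_beyond_pool_is_error(self, small_null):
        with pytest.raises(ValueError, match="cannot pick"):
            prob_all_distinct(small_null, 7)

    def test_monotone_decreasing_all_same_in_m(self):
        vals = [prob_all_same(UniformLibraryNull(m, 12), 5) for m in (50, 100, 260, 500)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_loggamma_path_matches_exact_path(self):
        # a pool big enough to force the log-gamma branch
        big = UniformLibraryNull(m=5000, c=12)
        exact_distinct = math.comb(5000, 5) * 12**5 / math.comb(60000, 5)
        exact_same = 5000 * math.comb(12, 5) / math.comb(60000, 5)
        assert prob_all_distinct(big, 5) == pytest.approx(exact_distinct, rel=1e-10)
        assert prob_all_same(big, 5) == pytest.approx(exact_same, rel=1e-10)


class TestPatternProbability:
    def test_extreme_patterns_match_dedicated_ops(self, screen_null):
        assert pattern_probability(screen_null, [1] * 5) == pytest.approx(
            prob_all_distinct(screen_null, 5), rel=1e-12
        )
        assert pattern_probability(screen_null, [5]) == pytest.approx(
            prob_all_same(screen_null, 5), rel=1e-12
        )

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_small_pool_matches_exhaustive_enumeration(self, small_null, k):
        oracle = enumerate_pattern_probs(small_null, k)
        for pat in partitions(k):
            expected = oracle.get(pat, 0.0)
            assert pattern_probability(small_null, pat) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("m,c", [(2, 2), (4, 3), (2, 5)])
    def test_enumeration_across_pool_shapes(self, m, c):
        null = UniformLibraryNull(m, c)
        k = 3
        oracle = enumerate_pattern_probs(null, k)
        for pat in partitions(k):
            assert pattern_probability(null, pat) == pytest.approx(
                oracle.get(pat, 0.0), abs=1e-12
            )

    def test_normalization_over_partitions_paper_null(self, screen_null):
        probs = pattern_probabilities(screen_null, 5)
        assert len(probs) == 7  # partitions of 5
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    @given(
        m=st.integers(min_value=2, max_value=8),
        c=st.integers(min_value=1, max_value=6),
        k=st.integers(min_value=1, max_value=6),
    )
    @settings(deadline=None, max_examples=80)
    def test_normalization_property(self, m, c, k):
        null = UniformLibraryNull(m, c)
        if k > null.N:
            return
        assert sum(pattern_probabilities(null, k).values()) == pytest.approx(1.0, abs=1e-12)

    def test_entry_order_is_irrelevant(self, screen_null):
        assert pattern_probability(screen_null, [2, 1, 1, 1]) == pattern_probability(
            screen_null, [1, 1, 2, 1]
        )

    def test_invalid_pattern_entries_rejected(self, screen_null):
        with pytest.raises(ValueError):
            pattern_probability(screen_null, [0, 5])

    def test_infeasible_pattern_has_zero_probability(self, small_null):
        assert pattern_probability(small_null, [2, 2, 2]) == pytest.approx(
            enumerate_pattern_probs(small_null, 6).get((2, 2, 2), 0.0), abs=1e-12
        )


class TestMonteCarlo:
    def test_estimates_within_three_se_of_exact(self, screen_null):
        mc = monte_carlo_patterns(screen_null, 5, reps=100_000, seed=123)
        exact = pattern_probabilities(screen_null, 5)
        est, se = mc[(1, 1, 1, 1, 1)]
        assert abs(est - exact[(1, 1, 1, 1, 1)]) < 3 * se

    def test_small_instance_all_patterns_within_three_se(self, small_null):
        mc = monte_carlo_patterns(small_null, 3, reps=50_000, seed=7)
        exact = pattern_probabilities(small_null, 3)
        for pat, (est, se) in mc.items():
            tol = 3 * se if se > 0 else 1e-9
            assert abs(est - exact[pat]) <= tol

    def test_single_copy_library_forces_all_distinct(self):
        null = UniformLibraryNull(m=10, c=1)
        mc = monte_carlo_patterns(null, 4, reps=2000, seed=1)
        assert mc[(1, 1, 1, 1)][0] == 1.0

    def test_deterministic_given_seed(self, small_null):
        a = monte_carlo_patterns(small_null, 3, reps=5000, seed=99)
        b = monte_carlo_patterns(small_null, 3, reps=5000, seed=99)
        assert a == b


class TestEnrichmentReport:
    def test_all_same_picks_reject_uniform_null(self, screen_null):
        rep = enrichment_report(PickOutcome((5,)), screen_null, alpha=0.05)
        assert rep.reject
        assert rep.point_probability == pytest.approx(8.38e-11, rel=5e-3)

    def test_all_distinct_picks_retain_null(self, screen_null):
        rep = enrichment_report(PickOutcome((1, 1, 1, 1, 1)), screen_null)
        assert not rep.reject
        assert rep.point_probability == pytest.approx(0.965, abs=5e-4)
        assert rep.tail_probability == pytest.approx(1.0, abs=1e-9)

    def test_tiny_pool_pair_verdict_matches_enumeration(self):
        null = UniformLibraryNull(m=2, c=2)
        rep = enrichment_report(PickOutcome((2,)), null)
        assert rep.point_probability == pytest.approx(1 / 3, abs=1e-12)
        assert not rep.reject  # 1/3 > 0.05

    def test_outcome_from_guide_ids(self):
        o = PickOutcome.from_guide_ids(["gOLE1_1"] * 5)
        assert o.pattern == (5,)
        o2 = PickOutcome.from_guide_ids(["a", "b", "c", "d", "e"])
        assert o2.pattern == (1, 1, 1, 1, 1)

    def test_observed_exceeding_copies_is_inconsistent(self, small_null):
        with pytest.raises(ValueError, match="exceeds copies"):
            enrichment_report(PickOutcome((3,)), small_null)
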