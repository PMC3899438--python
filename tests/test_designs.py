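"""Sampling primitives: inclusion probabilities, fixed take, design weights."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

import surveysim as ss
from surveysim.designs import systematic_positions


class TestSystematicSample:
    def test_census_returns_every_position(self, rng):
        pos = ss.systematic_sample(10, 10, rng)
        assert np.array_equal(pos, np.arange(10))

    def test_fractional_rule_always_returns_exactly_n(self, rng):
        for _ in range(2000):
            frame = int(rng.integers(1, 200))
            n = int(rng.integers(1, frame + 1))
            pos = ss.systematic_sample(frame, n, rng)
            assert len(np.unique(pos)) == n
            assert pos.min() >= 0 and pos.max() < frame

    def test_fractional_inclusion_probability_uniform(self, rng):
        """frame 10, n 2: every position should be included w.p. 0.2."""
        draws = 20000
        counts = np.zeros(10)
        for _ in range(draws):
            counts[ss.systematic_sample(10, 2, rng)] += 1
        freq = counts / draws
        se = np.sqrt(0.2 * 0.8 / draws)
        assert np.all(np.abs(freq - 0.2) <= 3 * se)

    def test_integer_interval_enumeration(self):
        """frame 4161, n 100, ceil rule: k=42, sizes 100 (starts 1-3) else 99."""
        sizes = [
            len(systematic_positions(4161, 100, "ceil", s)) for s in range(1, 43)
        ]
        assert sizes[:3] == [100, 100, 100]
        assert set(sizes[3:]) == {99}
        assert np.isclose(np.mean(sizes), 4161 / 42)

    def test_invalid_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            ss.systematic_sample(10, 11, rng)
        with pytest.raises(ValueError):
            ss.systematic_sample(10, 0, rng)


class TestSystematicPPS:
    def test_inclusion_probs_proportional_to_size(self, rng):
        _, probs = ss.systematic_pps(np.array([1, 2, 3, 4]), 2, rng)
        np.testing.assert_allclose(probs, [0.2, 0.4, 0.6, 0.8])

    def test_empirical_frequencies_match_probs(self, rng):
        sizes = np.array([1, 2, 3, 4])
        draws = 100_000
        counts = np.zeros(4)
        for _ in range(draws):
            pos, _ = ss.systematic_pps(sizes, 2, rng)
            assert len(np.unique(pos)) == 2
            counts[pos] += 1
        pi = 2 * sizes / sizes.sum()
        se = np.sqrt(pi * (1 - pi) / draws)
        assert np.all(np.abs(counts / draws - pi) <= 3 * se)

    def test_equal_sizes_reduce_to_equal_probability(self, rng):
        _, probs = ss.systematic_pps(np.full(8, 5), 3, rng)
        np.testing.assert_allclose(probs, 3 / 8)

    def test_two_unit_half_half(self, rng):
        pos, probs = ss.systematic_pps(np.array([5, 5]), 1, rng)
        np.testing.assert_allclose(probs, [0.5, 0.5])
        assert len(pos) == 1

    def test_fixed_take_over_random_frames(self, rng):
        for _ in range(10_000):
            m = int(rng.integers(2, 12))
            sizes = rng.integers(1, 30, m)
            n = int(rng.integers(1, m + 1))
            if n * sizes.max() > sizes.sum():
                continue
            pos, probs = ss.systematic_pps(sizes, n, rng)
            assert len(np.unique(pos)) == n
            assert np.all((probs > 0) & (probs <= 1))

    def test_certainty_units_rejected(self, rng):
        with pytest.raises(ValueError, match="certainty"):
            ss.systematic_pps(np.array([1, 1, 10]), 2, rng)
        with pytest.raises(ValueError):
            ss.systematic_pps(np.array([0, 1]), 1, rng)


class TestSRSWOR:
    def test_census(self, rng):
        assert np.array_equal(ss.srswor(5, 5, rng), np.arange(5))
        assert np.array_equal(ss.srswor(1, 1, rng), [0])

    def test_inclusion_probability_by_enumeration(self, rng):
        """frame 5, m 2: all 10 subsets equiprobable, so pi = 0.4 each."""
        draws = 100_000
        counts = np.zeros(5)
        for _ in range(draws):
            counts[ss.srswor(5, 2, rng)] += 1
        se = np.sqrt(0.4 * 0.6 / draws)
        assert np.all(np.abs(counts / draws - 0.4) <= 3 * se)

    def test_oversample_rejected(self, rng):
        with pytest.raises(ValueError):
            ss.srswor(5, 6, rng)


class TestSecondStageCount:
    @pytest.mark.parametrize(
        "n, f, expected",
        [
            (50, Fraction(1), 50),
            (50, Fraction(1, 4), 13),
            (51, Fraction(1, 2), 26),
            (1, Fraction(1, 5), 1),
        ],
    )
    def test_ceil_rule(self, n, f, expected):
        assert ss.second_stage_count(n, f) == expected

    def test_nearest_rule(self):
        assert ss.second_stage_count(50, Fraction(1, 4), "nearest") == 13
        assert ss.second_stage_count(49, Fraction(1, 2), "nearest") == 25

    @given(
        n=st.integers(min_value=1, max_value=500),
        num=st.integers(min_value=1, max_value=6),
        den=st.integers(min_value=1, max_value=6),
    )
    def test_count_bounds(self, n, num, den):
        f = Fraction(num, den)
        if f > 1:
            return
        m = ss.second_stage_count(n, f)
        assert 1 <= m <= n
        assert m >= f * n  # ceil never undershoots the nominal fraction


class TestMethod1:
    def test_census_stratum_has_weight_one(self, two_strata_pop, rng):
        per = int(two_strata_pop.stratum_clusters().min())
        spec = ss.DesignSpec.method1(clusters_per_stratum=per)
        draw = ss.draw_method1(two_strata_pop, spec, rng)
        # the smaller stratum is fully enumerated -> weight exactly 1
        assert draw.stratum_weights[0] == 1.0

    def test_weight_identity_on_every_draw(self, two_strata_pop, rng):
        spec = ss.DesignSpec.method1(clusters_per_stratum=10)
        pop_ind = two_strata_pop.stratum_individuals()
        for _ in range(20):
            draw = ss.draw_method1(two_strata_pop, spec, rng)
            total = draw.stratum_weights * draw.n_individuals_by_stratum
            np.testing.assert_allclose(total, pop_ind, rtol=1e-12)
            assert np.all(draw.stratum_weights > 0)
            assert np.all(np.isfinite(draw.stratum_weights))

    def test_average_sample_size_matches_expectation(self, two_strata_pop, rng):
        """E[sampled individuals] = clusters drawn x mean cluster size."""
        spec = ss.DesignSpec.method1(clusters_per_stratum=10)
        R = 300
        tot = np.zeros(2)
        for _ in range(R):
            draw = ss.draw_method1(two_strata_pop, spec, rng)
            tot += draw.n_individuals_by_stratum
        expected = 10 * (
            two_strata_pop.stratum_individuals() / two_strata_pop.stratum_clusters()
        )
        assert np.all(np.abs(tot / R / expected - 1.0) < 0.01)

    def test_infeasible_spec_rejected(self, two_strata_pop, rng):
        spec = ss.DesignSpec.method1(clusters_per_stratum=10_000)
        with pytest.raises(ss.ConfigError):
            ss.draw_method1(two_strata_pop, spec, rng)


class TestMethod2:
    def test_census_draw_has_unit_weights(self, equal_cluster_pop, rng):
        spec = ss.DesignSpec.method2(equal_cluster_pop.n_clusters, Fraction(1))
        draw = ss.draw_method2(equal_cluster_pop, spec, rng)
        np.testing.assert_allclose(draw.cluster_incl_prob, 1.0)
        np.testing.assert_allclose(draw.household_weights, 1.0)
        assert len(draw.household_indices) == equal_cluster_pop.n_households

    def test_household_total_estimator_unbiased(self, two_strata_pop, rng):
        """Mean over draws of the weighted household count hits the truth."""
        spec = ss.DesignSpec.method2(20, Fraction(1, 2))
        R = 500
        totals = np.array(
            [
                ss.draw_method2(two_strata_pop, spec, rng).household_weights.sum()
                for _ in range(R)
            ]
        )
        truth = two_strata_pop.n_households
        assert abs(totals.mean() - truth) <= 3 * totals.std(ddof=1) / np.sqrt(R)

    def test_weights_positive_and_finite(self, two_strata_pop, rng):
        spec = ss.DesignSpec.method2(15, Fraction(1, 3))
        for _ in range(10):
            draw = ss.draw_method2(two_strata_pop, spec, rng)
            w = draw.household_weights
            assert np.all(w > 0) and np.all(np.isfinite(w))
            assert np.all((draw.cluster_incl_prob > 0) & (draw.cluster_incl_prob <= 1))
            assert len(np.unique(draw.household_indices)) == len(draw.household_indices)

    def test_stratum_allocation_tracks_household_share(self, two_strata_pop, rng):
        """Sorted-frame systematic PPS: per-stratum cluster counts are within
        one unit of n times the stratum's household share, on every draw."""
        n = 24
        spec = ss.DesignSpec.method2(n, Fraction(1, 2))
        share = (
            two_strata_pop.stratum_households() / two_strata_pop.n_households
        )
        for _ in range(20):
            draw = ss.draw_method2(two_strata_pop, spec, rng)
            assert np.all(np.abs(draw.n_clusters_by_stratum - n * share) < 1)

    def test_second_stage_counts_respect_fraction(self, two_strata_pop, rng):
        spec = ss.DesignSpec.method2(12, Fraction(1, 3))
        draw = ss.draw_method2(two_strata_pop, spec, rng)
        N = two_strata_pop.cluster_n_households[draw.cluster_indices]
        expected = -(-N // 3)
        assert np.array_equal(draw.m_per_cluster, expected)
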