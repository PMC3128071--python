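"""Neutral rearrangement simulator: weights, sampling laws, comparisons."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from intercds.neutral import (
    SimConfig,
    compare_distributions,
    effective_length,
    estimate_rate,
    per_region_break_probability,
    simulate_survivors,
)


def removal_probabilities(weights, n_young):
    """Brute-force oracle: P(region i removed) for sequential weighted sampling
    without replacement, by enumerating all ordered removal sequences."""
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    p_removed = np.zeros(n)
    for seq in permutations(range(n), n_young):
        prob, remaining = 1.0, weights.sum()
        for i in seq:
            if weights[i] == 0:
                prob = 0.0
                break
            prob *= weights[i] / remaining
            remaining -= weights[i]
        for i in seq:
            p_removed[i] += prob
    return p_removed


class TestEffectiveLength:
    @pytest.mark.parametrize(
        "length,model,offset,expected",
        [(200, "A", 0, 200), (200, "B", 172, 28), (150, "B", 172, 0)],
    )
    def test_models(self, length, model, offset, expected):
        assert effective_length(length, model, offset) == expected

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            effective_length(0, "A")


class TestBreakProbability:
    def test_arithmetic(self):
        assert per_region_break_probability(200, 0.001, "A") == pytest.approx(0.2)

    def test_rate_from_young_count(self):
        assert estimate_rate([4000, 6000], 10) == pytest.approx(0.001)

    def test_model_b_below_offset_is_zero(self):
        assert per_region_break_probability(150, 0.001, "B", 172) == 0.0

    def test_probability_above_one_errors(self):
        with pytest.raises(ValueError, match="smaller"):
            per_region_break_probability(2000, 0.001, "A")


class TestSimulateSurvivors:
    def test_survivor_count_exact_in_every_replicate(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(50, 2000, size=40)
        for mode in ("sequential", "bernoulli_sweep"):
            sim = simulate_survivors(
                lengths, SimConfig(n_young=7, replicates=5, seed=3, removal_mode=mode)
            )
            assert all(len(s) == 33 for s in sim.survivors)
            assert sim.mean_counts.sum() == pytest.approx(33)

    def test_equal_lengths_removed_uniformly(self):
        """With 4 equal regions and 2 removals, each of the 6 removal pairs is
        equally likely (symmetry of weighted sampling)."""
        from intercds.neutral import _weighted_removals

        rng = np.random.default_rng(1)
        weights = np.full(4, 500.0)
        n_rep = 12_000
        counts: dict[frozenset, int] = {}
        for _ in range(n_rep):
            pair = frozenset(_weighted_removals(weights, 2, rng).tolist())
            counts[pair] = counts.get(pair, 0) + 1
        se = np.sqrt((1 / 6) * (5 / 6) / n_rep)
        assert len(counts) == 6
        for freq in counts.values():
            assert freq / n_rep == pytest.approx(1 / 6, abs=3 * se)

    def test_long_region_removed_at_weighted_rate(self):
        n_rep = 20_000
        sim = simulate_survivors(
            [100, 900], SimConfig(n_young=1, replicates=n_rep, seed=5)
        )
        removed_long = sum(1 for s in sim.survivors if s[0] == 100)
        se = np.sqrt(0.9 * 0.1 / n_rep)
        assert removed_long / n_rep == pytest.approx(0.9, abs=3 * se)

    def test_model_b_zero_weight_never_removed(self):
        sim = simulate_survivors(
            [100, 900],
            SimConfig(model="B", n_young=1, promoter_offset=100, replicates=50, seed=2),
        )
        assert all(s[0] == 100 for s in sim.survivors)

    def test_matches_enumeration_oracle_small_n(self):
        lengths = [50, 100, 200, 650]
        n_young, n_rep = 2, 20_000
        expected = removal_probabilities(lengths, n_young)
        sim = simulate_survivors(
            lengths, SimConfig(n_young=n_young, replicates=n_rep, seed=9)
        )
        freq = np.zeros(len(lengths))
        arr = np.asarray(lengths, dtype=float)
        for surv in sim.survivors:
            # all lengths distinct: membership identifies indexes
            freq += ~np.isin(arr, surv)
        freq /= n_rep
        se = np.sqrt(expected * (1 - expected) / n_rep)
        assert np.all(np.abs(freq - expected) <= 3 * se + 1e-12)

    def test_stochastic_monotonicity_in_oracle(self):
        """Longer effective length implies higher removal probability (the
        enumeration oracle itself must show this for any n_young)."""
        weights = [10, 40, 80, 200, 500]
        for n_young in (1, 2, 3, 4):
            probs = removal_probabilities(weights, n_young)
            assert np.all(np.diff(probs) > 0)

    def test_modes_agree_in_distribution(self):
        rng = np.random.default_rng(12)
        lengths = np.round(10 ** rng.normal(2.5, 0.3, 300))
        results = {}
        for mode in ("sequential", "bernoulli_sweep"):
            sim = simulate_survivors(
                lengths,
                SimConfig(n_young=15, replicates=40, seed=4, removal_mode=mode),
            )
            results[mode] = sim.pooled
        from scipy.stats import ks_2samp

        stat = ks_2samp(results["sequential"], results["bernoulli_sweep"]).statistic
        assert stat < 0.05

    def test_mean_survivor_length_not_above_initial(self):
        rng = np.random.default_rng(77)
        lengths = np.round(10 ** rng.normal(2.5, 0.35, 400))
        sim = simulate_survivors(lengths, SimConfig(n_young=60, replicates=30, seed=6))
        assert sim.pooled.mean() <= lengths.mean()

    def test_too_many_removals_errors(self):
        with pytest.raises(ValueError):
            simulate_survivors([100, 200], SimConfig(n_young=2, seed=0))

    def test_insufficient_breakable_regions_errors(self):
        with pytest.raises(ValueError, match="positive effective length"):
            simulate_survivors(
                [100, 100, 900],
                SimConfig(model="B", n_young=2, promoter_offset=150, seed=0),
            )

    def test_replicates_reproducible_given_seed(self):
        cfg = SimConfig(n_young=5, replicates=4, seed=123)
        a = simulate_survivors(list(range(100, 160)), cfg)
        b = simulate_survivors(list(range(100, 160)), cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a.survivors, b.survivors))


class TestCompareDistributions:
    def test_self_comparison_is_close(self):
        rng = np.random.default_rng(10)
        lengths = np.round(10 ** rng.normal(2.5, 0.3, 500))
        sim = simulate_survivors(lengths, SimConfig(n_young=50, replicates=10, seed=1))
        rep = compare_distributions(sim, sim.survivors[0])
        assert rep.ks_statistic < 0.1

    def test_added_right_tail_shows_positive_tail_excess(self):
        rng = np.random.default_rng(11)
        lengths = np.round(10 ** rng.normal(2.5, 0.2, 800))
        sim = simulate_survivors(lengths, SimConfig(n_young=80, replicates=10, seed=2))
        observed = np.concatenate(
            [sim.survivors[0], np.round(10 ** rng.normal(3.6, 0.1, 60))]
        )
        rep = compare_distributions(sim, observed)
        n = rep.excess.size
        assert rep.excess[int(np.ceil(2 * n / 3)):].sum() > 0
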