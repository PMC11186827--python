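import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hazprio import (
    ConcentrationPool,
    DomainError,
    HazardLevel,
    apply_processing_factor,
    compare_scenarios,
    simulate_mixed_chain,
    simulate_short_chain,
)
from hazprio.chain_sim import read_pool_csv, write_pool_csv


def pool_of(values, limit=100.0, analyte="x", limit_kind="maximum_limit"):
    return ConcentrationPool(values=tuple(values), analyte=analyte, limit=limit,
                             limit_kind=limit_kind)


class TestShortChain:
    def test_constant_pool(self):
        s = simulate_short_chain(pool_of([10.0, 10.0, 10.0]), reps=500, seed=0)
        assert s.mean == 10.0 and s.min == 10.0 and s.max == 10.0
        assert s.frac_exceeding == 0.0

    def test_all_below_limit_gives_zero_exceedance(self):
        s = simulate_short_chain(pool_of([10, 12, 38, 66]), reps=10_000, seed=1)
        assert s.frac_exceeding == 0.0

    def test_two_point_pool_converges_to_half(self):
        s = simulate_short_chain(pool_of([0.0, 200.0]), reps=100_000, seed=2)
        # Bernoulli(1/2): 5 sigma band at n = 1e5
        assert abs(s.frac_exceeding - 0.5) < 5 * 0.5 / np.sqrt(100_000)

    def test_seed_reproducibility(self):
        pool = pool_of([1.0, 5.0, 25.0, 125.0])
        a = simulate_short_chain(pool, reps=5_000, seed=42)
        b = simulate_short_chain(pool, reps=5_000, seed=42)
        assert a == b
        c = simulate_short_chain(pool, reps=5_000, seed=43)
        assert c != a

    def test_resample_converges_to_pool_statistics(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(3.0, 1.0, size=200)
        pool = pool_of(values, limit=float(np.quantile(values, 0.9)))
        s = simulate_short_chain(pool, reps=100_000, seed=4)
        assert s.mean == pytest.approx(values.mean(), rel=0.02)
        assert s.median == pytest.approx(float(np.median(values)), rel=0.05)
        assert s.max <= values.max()
        assert s.min >= values.min()

    def test_zero_reps_rejected(self):
        with pytest.raises(DomainError):
            simulate_short_chain(pool_of([1.0]), reps=0, seed=0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_of([])


class TestMixedChain:
    def test_constant_pool_averaging_invariance(self):
        s = simulate_mixed_chain(pool_of([7.0] * 5), 5, 10, reps=500, seed=0)
        assert s.min == 7.0 and s.max == 7.0 and s.mean == 7.0

    def test_degenerate_mixing_matches_short_chain_bitwise(self):
        pool = pool_of([3.0, 9.0, 27.0, 81.0])
        short = simulate_short_chain(pool, reps=2_000, seed=11)
        mixed = simulate_mixed_chain(pool, 1, 1, reps=2_000, seed=11)
        for stat in ("min", "median", "mean", "max", "frac_exceeding"):
            assert getattr(short, stat) == getattr(mixed, stat)

    def test_averages_cannot_exceed_pool_max(self):
        pool = pool_of([10, 12, 38, 66])  # T-2-like: max 66 < limit 100
        s = simulate_mixed_chain(pool, 5, 10, reps=20_000, seed=5)
        assert s.frac_exceeding == 0.0
        assert s.max <= 66.0

    def test_max_bound_hierarchy(self):
        rng = np.random.default_rng(6)
        values = rng.lognormal(4.0, 1.5, size=100)
        pool = pool_of(values, limit=float(np.quantile(values, 0.8)))
        short = simulate_short_chain(pool, reps=50_000, seed=7)
        mixed = simulate_mixed_chain(pool, 5, 10, reps=50_000, seed=7)
        assert mixed.max <= short.max <= values.max()

    def test_mean_conservation(self):
        rng = np.random.default_rng(8)
        values = rng.lognormal(3.5, 1.2, size=150)
        pool = pool_of(values, limit=1e9)
        s = simulate_mixed_chain(pool, 5, 10, reps=100_000, seed=9)
        # batch averages are unbiased for the pool mean
        sem = values.std() / np.sqrt(5 * 100_000)
        assert abs(s.mean - values.mean()) < 6 * sem

    def test_two_point_pool_mixing_dilutes_exceedance(self):
        pool = pool_of([0.0, 200.0])  # average > 100 only if every draw is high
        short = simulate_short_chain(pool, reps=50_000, seed=10)
        mixed = simulate_mixed_chain(pool, 5, 10, reps=50_000, seed=10)
        assert mixed.frac_exceeding < short.frac_exceeding

    def test_invalid_range_rejected(self):
        with pytest.raises(DomainError):
            simulate_mixed_chain(pool_of([1.0]), 0, 5, reps=10, seed=0)
        with pytest.raises(DomainError):
            simulate_mixed_chain(pool_of([1.0]), 6, 5, reps=10, seed=0)

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.floats(0.0, 1000.0), min_size=1, max_size=8), st.integers(0, 2**32 - 1))
    def test_summary_invariants(self, values, seed):
        pool = pool_of(values, limit=50.0)
        s = simulate_mixed_chain(pool, 2, 4, reps=200, seed=seed)
        assert s.min <= s.median <= s.max
        assert 0.0 <= s.frac_exceeding <= 1.0
        # averaging may round by a few ulps
        eps = 1e-9
        assert s.min >= min(values) * (1 - eps) - eps
        assert s.max <= max(values) * (1 + eps) + eps


class TestEnumerationOracle:
    @pytest.mark.parametrize("values,limit", [
        ((0.0, 50.0, 150.0, 300.0), 100.0),
        ((10.0, 90.0, 110.0), 100.0),
        ((25.0, 1300.0), 1250.0),
    ])
    def test_pairwise_mixing_matches_enumeration(self, values, limit):
        # independent oracle: exhaustive enumeration over all ordered pairs
        pairs = list(itertools.product(values, repeat=2))
        exact = sum((a + b) / 2 > limit for a, b in pairs) / len(pairs)
        pool = pool_of(values, limit=limit)
        s = simulate_mixed_chain(pool, 2, 2, reps=200_000, seed=13)
        tol = 5 * np.sqrt(max(exact * (1 - exact), 1e-6) / 200_000)
        assert abs(s.frac_exceeding - exact) < tol


class TestProcessingFactor:
    def test_pool_scaling_halves_mean(self):
        pool = pool_of([10.0, 30.0])
        scaled = apply_processing_factor(pool, 0.5)
        assert scaled.values == (5.0, 15.0)
        assert scaled.limit == pool.limit

    def test_kernel_to_flour_mean(self):
        # kernel mean 411 at the upper white-flour factor
        pool = pool_of([411.0], limit=1250.0)
        assert apply_processing_factor(pool, 0.8).values[0] == pytest.approx(328.8)

    def test_identity_factor(self):
        pool = pool_of([1.0, 2.0])
        assert apply_processing_factor(pool, 1.0).values == pool.values

    def test_summary_scaling_drops_exceedance(self):
        s = simulate_short_chain(pool_of([50.0, 150.0]), reps=100, seed=0)
        scaled = apply_processing_factor(s, 0.5)
        assert scaled.mean == pytest.approx(s.mean * 0.5)
        assert scaled.frac_exceeding is None

    @pytest.mark.parametrize("factor", [0.0, -0.5, 1.5])
    def test_out_of_range_rejected(self, factor):
        with pytest.raises(DomainError):
            apply_processing_factor(pool_of([1.0]), factor)


class TestCompareScenarios:
    def test_don_like_pool_both_high(self):
        rng = np.random.default_rng(14)
        values = np.concatenate([rng.lognormal(4.0, 1.3, 280), [15400.0] * 13])
        c = compare_scenarios(pool_of(values, limit=1250.0, analyte="DON"),
                              reps=20_000, seed=15)
        assert c.short_chain_occurrence is HazardLevel.HIGH
        assert c.conventional_occurrence is HazardLevel.HIGH

    def test_t2_like_pool_both_low(self):
        c = compare_scenarios(pool_of([10, 10, 12, 38, 66], limit=100.0,
                                      analyte="T-2", limit_kind="guidance"),
                              reps=20_000, seed=16)
        assert c.short_chain.frac_exceeding == 0.0
        assert c.conventional.frac_exceeding == 0.0
        assert c.short_chain_occurrence is HazardLevel.LOW
        assert c.conventional_occurrence is HazardLevel.LOW

    def test_reproducible(self):
        pool = pool_of([1.0, 200.0, 3.0])
        assert compare_scenarios(pool, 1000, seed=17) == compare_scenarios(pool, 1000, seed=17)


class TestPoolCsv:
    def test_round_trip(self, tmp_path):
        pool = pool_of([25.0, 60.0, 15400.0], limit=1250.0, analyte="DON")
        path = tmp_path / "pool.csv"
        write_pool_csv(pool, path)
        assert read_pool_csv(path) == pool

    def test_missing_metadata_rejected(self, tmp_path):
        path = tmp_path / "pool.csv"
        path.write_text("concentration\n1.0\n")
        with pytest.raises(DomainError, match="analyte"):
            read_pool_csv(path)
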