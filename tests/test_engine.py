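import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plurivote.engine import (
    DecisionSpec,
    decision_distribution,
    exact_accuracy,
    exact_full_pool_accuracy,
    full_pool_decision,
    full_pool_distribution,
    iterate_decisions,
    monte_carlo_accuracy,
    plurality_decision,
    sample_instances,
)
from plurivote.model import LABELS, SentimentLabel

from conftest import brute_force_distribution, make_pool, random_pool

ANTI, PRO, NEU = SentimentLabel.ANTI, SentimentLabel.PRO, SentimentLabel.NEU


class TestSampleInstances:
    def test_degenerate_pool(self):
        pool = make_pool(ANTI=20)
        rng = np.random.default_rng(0)
        assert sample_instances(pool, 5, rng) == [ANTI] * 5

    def test_determinism(self):
        pool = make_pool(ANTI=10, PRO=10)
        a = sample_instances(pool, 50, np.random.default_rng(42))
        b = sample_instances(pool, 50, np.random.default_rng(42))
        assert a == b

    def test_binomial_bound(self, pool_10_10):
        # ANTI fraction over 10000 draws within 3 binomial SEs of 0.5
        rng = np.random.default_rng(7)
        draws = sample_instances(pool_10_10, 10000, rng)
        frac = sum(lab is ANTI for lab in draws) / 10000
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 10000)

    def test_invalid_m(self, pool_10_10):
        with pytest.raises(ValueError):
            sample_instances(pool_10_10, 0, np.random.default_rng(0))


class TestPluralityDecision:
    def test_strict_plurality(self, pool_13_7):
        rng = np.random.default_rng(0)
        assert plurality_decision([ANTI, PRO, ANTI], pool_13_7, rng) is ANTI

    def test_unanimous(self, pool_13_7):
        rng = np.random.default_rng(0)
        assert plurality_decision([ANTI] * 5, pool_13_7, rng) is ANTI

    def test_tie_symmetry(self, pool_10_10):
        # 50/50 pool: a two-way tie resolves each way about half the time
        rng = np.random.default_rng(3)
        hits = sum(plurality_decision([ANTI, PRO], pool_10_10, rng) is ANTI
                   for _ in range(4000))
        assert abs(hits / 4000 - 0.5) <= 3 * np.sqrt(0.25 / 4000)

    def test_tie_proportional_to_pool(self):
        # tie between ANTI and PRO, pool 15/5: ANTI wins ~3/4 of redraws
        pool = make_pool(ANTI=15, PRO=5)
        rng = np.random.default_rng(4)
        hits = sum(plurality_decision([ANTI, PRO], pool, rng) is ANTI
                   for _ in range(4000))
        assert abs(hits / 4000 - 0.75) <= 3 * np.sqrt(0.75 * 0.25 / 4000)

    def test_empty_sample(self, pool_13_7):
        with pytest.raises(ValueError):
            plurality_decision([], pool_13_7, np.random.default_rng(0))


class TestMonteCarloAccuracy:
    def test_all_matching(self):
        pool = make_pool(NEU=20)
        spec = DecisionSpec(m=7, iterations=100, seed=0)
        assert monte_carlo_accuracy(pool, NEU, spec).accuracy == 1.0

    def test_zero_matching(self, pool_13_7):
        # human label absent from the pool can never be drawn or win a tie
        spec = DecisionSpec(m=5, iterations=500, seed=0)
        assert monte_carlo_accuracy(pool_13_7, NEU, spec).accuracy == 0.0

    def test_closed_form_13_7_m3(self, pool_13_7):
        # P(>=2 of 3 match, p=0.65) = 3*0.65^2*0.35 + 0.65^3 = 0.71825
        spec = DecisionSpec(m=3, iterations=10000, seed=11)
        acc = monte_carlo_accuracy(pool_13_7, ANTI, spec).accuracy
        assert abs(acc - 0.71825) <= 3 * np.sqrt(0.71825 * 0.28175 / 10000)

    def test_deterministic_given_seed(self, pool_13_7):
        spec = DecisionSpec(m=5, iterations=200, seed=9)
        a = monte_carlo_accuracy(pool_13_7, ANTI, spec)
        b = monte_carlo_accuracy(pool_13_7, ANTI, spec)
        assert a == b

    def test_message_order_independent(self, pool_13_7):
        # substream keyed by message id, not visit order
        other = make_pool("other", PRO=20)
        spec = DecisionSpec(m=3, iterations=300, seed=5)
        first = monte_carlo_accuracy(pool_13_7, ANTI, spec).accuracy
        monte_carlo_accuracy(other, PRO, spec)
        assert monte_carlo_accuracy(pool_13_7, ANTI, spec).accuracy == first

    def test_iterate_decisions_concurrence_flag(self, pool_13_7):
        spec = DecisionSpec(m=3, iterations=50, seed=2)
        for rec in iterate_decisions(pool_13_7, ANTI, spec):
            assert rec.concurrence == int(rec.decision is ANTI)
            assert len(rec.sampled_labels) == 3

    def test_iterate_matches_exact_within_mc_error(self, pool_13_7):
        spec = DecisionSpec(m=3, iterations=2000, seed=8)
        acc = np.mean([r.concurrence
                       for r in iterate_decisions(pool_13_7, ANTI, spec)])
        a = 0.71825
        assert abs(acc - a) <= 3 * np.sqrt(a * (1 - a) / 2000)


class TestDecisionDistribution:
    def test_normalization(self, pool_13_7):
        for m in (1, 2, 3, 8, 20):
            assert abs(decision_distribution(pool_13_7, m).sum() - 1) < 1e-12

    def test_even_split_m2(self, pool_10_10):
        dist = decision_distribution(pool_10_10, 2)
        # 0.25 + 0.25 outright plus the 0.5 tie mass split evenly
        assert np.allclose(dist, [0.5, 0.5, 0, 0, 0], atol=1e-12)

    def test_matches_brute_force_13_7(self, pool_13_7):
        for m in (1, 2, 3, 4):
            assert np.allclose(decision_distribution(pool_13_7, m),
                               brute_force_distribution(pool_13_7, m),
                               atol=1e-12)

    def test_k1_identity(self, pool_13_7):
        dist = decision_distribution(pool_13_7, 1)
        assert abs(dist[0] - 13 / 20) < 1e-12
        assert abs(dist[1] - 7 / 20) < 1e-12

    def test_mode_selected_asymptotically(self, pool_13_7):
        # unique-mode win probability grows toward 1 with m
        # (binomial closed form: 0.98624 at m=51, 0.99901 at m=101)
        a51 = exact_accuracy(pool_13_7, ANTI, 51).accuracy
        a101 = exact_accuracy(pool_13_7, ANTI, 101).accuracy
        assert a51 == pytest.approx(0.9862376949756, abs=1e-10)
        assert a101 > a51 and a101 >= 0.999

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 5))
    def test_oracle_equivalence_random_pools(self, seed, m):
        pool = random_pool(np.random.default_rng(seed))
        assert np.allclose(decision_distribution(pool, m),
                           brute_force_distribution(pool, m), atol=1e-10)


class TestExactAccuracy:
    def test_all_matching(self):
        pool = make_pool(PRO=20)
        assert exact_accuracy(pool, PRO, 9).accuracy == 1.0

    def test_13_7_m3(self, pool_13_7):
        assert abs(exact_accuracy(pool_13_7, ANTI, 3).accuracy - 0.71825) < 1e-12

    def test_10_10_m2(self, pool_10_10):
        assert abs(exact_accuracy(pool_10_10, ANTI, 2).accuracy - 0.5) < 1e-12

    def test_mc_convergence_random_pools(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            pool = random_pool(rng)
            m = int(rng.integers(1, 8))
            a = exact_accuracy(pool, pool.instances[0], m).accuracy
            spec = DecisionSpec(m, 1000, seed=int(rng.integers(1 << 20)))
            mc = monte_carlo_accuracy(pool, pool.instances[0], spec).accuracy
            assert abs(mc - a) <= max(3 * np.sqrt(a * (1 - a) / 1000), 1e-12)


class TestFullPool:
    def test_clear_mode(self):
        pool = make_pool(ANTI=12, NEU=8)
        assert full_pool_decision(pool, np.random.default_rng(0)) is ANTI

    def test_unanimous(self):
        pool = make_pool(NEU=20)
        assert full_pool_decision(pool, np.random.default_rng(0)) is NEU

    def test_tie_half_half(self, pool_10_10):
        rng = np.random.default_rng(6)
        hits = sum(full_pool_decision(pool_10_10, rng) is ANTI
                   for _ in range(4000))
        assert abs(hits / 4000 - 0.5) <= 3 * np.sqrt(0.25 / 4000)

    def test_exact_full_pool_accuracy(self, pool_10_10):
        assert exact_full_pool_accuracy(pool_10_10, ANTI).accuracy == 0.5
        assert exact_full_pool_accuracy(make_pool(ANTI=12, NEU=8), ANTI).accuracy == 1.0
        assert full_pool_distribution(pool_10_10).sum() == pytest.approx(1.0)


class TestDecisionSpec:
    def test_invalid(self):
        with pytest.raises(ValueError):
            DecisionSpec(m=0)
        with pytest.raises(ValueError):
            DecisionSpec(m=1, iterations=0)
        with pytest.raises(ValueError):
            DecisionSpec(m=1, tie_policy="coin-flip")
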