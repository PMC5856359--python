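"""Allocation rules: scores, probability vectors, wrappers, symmetry."""

import math

import numpy as np
import pytest
from scipy import stats

from banditrials import (
    BatchedAllocator,
    ConfigurationError,
    RuleSpec,
    TrialConfig,
    UndefinedStateError,
    allocate,
    protected_control_wrap,
    run_trial,
    tp_probabilities,
    ts_probabilities,
)
from banditrials.fixtures import make_fixture_states
from banditrials.gittins import GittinsTable
from banditrials.rules import make_allocator


def _config(K, T, rule, means=None, **kw):
    means = means if means is not None else tuple([0.0] * (K + 1))
    return TrialConfig(K=K, T=T, true_means=means, rule=rule, **kw)


def _empty_states(m):
    return make_fixture_states(n=[0] * m, mean=[0.0] * m)


class TestRuleSpec:
    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            RuleSpec("GITTINS")

    def test_foreign_tuning_keys_rejected(self):
        with pytest.raises(ConfigurationError):
            RuleSpec("FR", {"discount": 0.9})
        with pytest.raises(ConfigurationError):
            RuleSpec("GI", {"batch": 20})


class TestInitialization:
    @pytest.mark.parametrize("name", ["UCB", "KLU"])
    def test_ordered_burn_in(self, name, rng):
        """Patient t (1-based) receives arm t-1 while arms are empty."""
        from banditrials import ArmState

        cfg = _config(3, 20, RuleSpec(name))
        states = _empty_states(4)
        for t in range(4):
            assert allocate(RuleSpec(name), t, states, cfg, rng=rng) == t
            states[t] = ArmState(arm_id=t, n=1, total=0.0)

    @pytest.mark.parametrize("name", ["CB", "GI", "RGI", "RBI", "TS"])
    def test_random_burn_in_targets_empty_arms(self, name, rng, small_table):
        cfg = _config(2, 20, RuleSpec(name), discount=0.8)
        states = make_fixture_states(n=[3, 0, 0], mean=[0.5, 0.0, 0.0])
        for _ in range(25):
            arm = allocate(RuleSpec(name), 3, states, cfg, table=small_table, rng=rng)
            assert arm in (1, 2)


class TestScoreRules:
    def test_gi_symmetry_under_identical_states(self, rng, small_table):
        cfg = _config(2, 30, RuleSpec("GI"), discount=0.8)
        states = make_fixture_states(n=[4, 4, 4], mean=[0.2, 0.2, 0.2])
        picks = np.array(
            [allocate(RuleSpec("GI"), 12, states, cfg, table=small_table, rng=rng) for _ in range(900)]
        )
        counts = np.bincount(picks, minlength=3)
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_cb_and_gi_disagree_exactly_when_bonus_gap_dominates(self, table995, rng):
        """Hand-evaluated two-arm comparison of posterior mean vs index."""
        cfg = _config(1, 116, RuleSpec("GI"))
        states = make_fixture_states(n=[10, 2], mean=[0.3, 0.1])
        cb = allocate(RuleSpec("CB"), 12, states, cfg, rng=rng)
        assert cb == 0
        off = RuleSpec("GI").get("index_offset")
        gap = table995.bonus(2 + off) - table995.bonus(10 + off)
        gi_scores = np.array([0.3 + table995.bonus(10 + off), 0.1 + table995.bonus(2 + off)])
        expected_gi = int(np.argmax(gi_scores))
        assert (expected_gi == 1) == (gap > 0.2)
        assert allocate(RuleSpec("GI"), 12, states, cfg, table=table995, rng=rng) == expected_gi

    def test_cb_equals_gi_with_zero_index_table(self):
        """CB is the d=0 limit: identical paths under identical rng streams."""
        zero = GittinsTable(0.0, np.arange(1, 50), np.zeros(49))
        cfg_gi = _config(2, 60, RuleSpec("GI"), means=(0.0, 0.1, 0.2), discount=0.0, seed=77)
        cfg_cb = _config(2, 60, RuleSpec("CB"), means=(0.0, 0.1, 0.2), seed=77)
        res_gi = run_trial(cfg_gi, table=zero)
        res_cb = run_trial(cfg_cb)
        np.testing.assert_array_equal(res_gi.allocations, res_cb.allocations)
        np.testing.assert_array_equal(res_gi.outcomes, res_cb.outcomes)

    def test_ucb_score_formula(self, rng):
        """UCB picks the argmax of xbar + sigma*sqrt(2 ln t / n), t 1-based."""
        cfg = _config(1, 50, RuleSpec("UCB"), sigma=2.0)
        states = make_fixture_states(n=[20, 4], mean=[0.4, 0.0])
        t = 24
        scores = [
            0.4 + 2.0 * math.sqrt(2 * math.log(t + 1) / 20),
            0.0 + 2.0 * math.sqrt(2 * math.log(t + 1) / 4),
        ]
        assert allocate(RuleSpec("UCB"), t, states, cfg, rng=rng) == int(np.argmax(scores))

    def test_klu_bonus_exceeds_ucb_bonus_for_large_t(self, rng):
        """The extra 3 ln ln t term makes KLU explore laggards harder."""
        cfg = _config(1, 200, RuleSpec("KLU"))
        states = make_fixture_states(n=[150, 10], mean=[0.33, 0.0])
        t = 160
        ucb_gap = 0.33 + math.sqrt(2 * math.log(t + 1) / 150) - math.sqrt(2 * math.log(t + 1) / 10)
        klu_b = 2 * (math.log(t + 1) + 3 * math.log(math.log(t + 1)))
        klu_gap = 0.33 + math.sqrt(klu_b / 150) - math.sqrt(klu_b / 10)
        assert klu_gap < ucb_gap
        if klu_gap < 0 < ucb_gap:  # chosen states make the two rules disagree
            assert allocate(RuleSpec("KLU"), t, states, cfg, rng=rng) == 1
            assert allocate(RuleSpec("UCB"), t, states, cfg, rng=rng) == 0


class TestThompsonProbabilities:
    def test_symmetric_states_give_half(self, rng):
        cfg = _config(1, 100, RuleSpec("TS"))
        states = make_fixture_states(n=[6, 6], mean=[0.1, 0.1])
        p = ts_probabilities(states, t=50, config=cfg, mc_draws=4000, rng=rng)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p[0] == pytest.approx(0.5, abs=0.05)

    def test_zero_exponent_is_uniform(self, rng):
        cfg = _config(2, 100, RuleSpec("TS"))
        states = make_fixture_states(n=[3, 9, 2], mean=[-0.5, 1.2, 0.3])
        p = ts_probabilities(states, t=0, config=cfg, mc_draws=500, rng=rng)
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-12)

    def test_two_arm_closed_form_oracle(self, rng):
        """P(best) for K=1 equals the normal CDF of the standardized gap."""
        cfg = _config(1, 100, RuleSpec("TS"), sigma=1.3)
        n0, n1, m0, m1 = 5, 8, 0.2, 0.65
        states = make_fixture_states(n=[n0, n1], mean=[m0, m1])
        p1_exact = stats.norm.cdf((m1 - m0) / (1.3 * math.sqrt(1 / n1 + 1 / n0)))
        t = 60
        c = t / (2 * cfg.T)
        expected = p1_exact**c / (p1_exact**c + (1 - p1_exact) ** c)
        p = ts_probabilities(states, t=t, config=cfg, mc_draws=200_000, rng=rng)
        assert p[1] == pytest.approx(expected, abs=0.01)

    def test_requires_initialized_arms(self, rng):
        cfg = _config(1, 100, RuleSpec("TS"))
        with pytest.raises(UndefinedStateError):
            ts_probabilities(make_fixture_states(n=[0, 4], mean=[0, 0.1]), 5, cfg, rng=rng)


class TestTrippaProbabilities:
    def test_zero_exponents_are_uniform(self):
        cfg = _config(3, 302, RuleSpec("TP"))
        states = make_fixture_states(n=[9, 1, 5, 3], mean=[0.0, 0.9, -0.2, 0.4])
        p = tp_probabilities(states, t=0, config=cfg)
        # gamma=0 flattens experimental arms; eta=0 with balanced... here the
        # control weight is exp((max n_k - n0) * 0) / K = 1/K, so all equal.
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_balanced_counts_control_weight(self):
        cfg = _config(3, 302, RuleSpec("TP"))
        states = make_fixture_states(n=[7, 7, 7, 7], mean=[0.0, 0.1, 0.2, 0.3])
        t = 151
        p = tp_probabilities(states, t=t, config=cfg)
        # control weight is exactly 1/K before renormalisation
        gamma = 3.0 * (t / 302) ** 1.75
        sup = stats.norm.cdf(
            (np.array([0.1, 0.2, 0.3])) / math.sqrt(2.0 / 7.0)
        )
        w = sup**gamma
        expected = np.concatenate([[1.0 / 3.0], w / w.sum()])
        expected /= expected.sum()
        np.testing.assert_allclose(p, expected, rtol=1e-10)

    def test_hand_evaluation_mid_trial(self):
        """Direct recomputation of both formulas at t=151, T=302."""
        cfg = _config(3, 302, RuleSpec("TP"))
        n = [50, 30, 40, 31]
        mean = [0.05, 0.3, -0.1, 0.5]
        states = make_fixture_states(n=n, mean=mean)
        t = 151
        gamma = 3.0 * (t / 302) ** 1.75
        eta = 0.25 * (t / 302)
        sup = np.array(
            [
                stats.norm.cdf((mean[k] - mean[0]) / math.sqrt(1 / n[k] + 1 / n[0]))
                for k in (1, 2, 3)
            ]
        )
        w = sup**gamma
        ctrl = (1 / 3) * math.exp((max(n[1:]) - n[0]) * eta)
        expected = np.concatenate([[ctrl], w / w.sum()])
        expected /= expected.sum()
        p = tp_probabilities(states, t=t, config=cfg)
        np.testing.assert_allclose(p, expected, rtol=1e-10)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestProtectedControl:
    def test_control_fraction(self, rng, small_table):
        cfg = _config(3, 100, RuleSpec("CG"), discount=0.8)
        states = make_fixture_states(n=[5, 5, 5, 5], mean=[0.0, 0.3, 0.1, -0.2])
        picks = [
            protected_control_wrap(RuleSpec("GI"), 20, states, cfg, table=small_table, rng=rng)
            for _ in range(4000)
        ]
        frac = np.mean(np.array(picks) == 0)
        assert frac == pytest.approx(0.25, abs=0.03)

    def test_two_arm_coin_under_experimental_only_variant(self, rng, small_table):
        cfg = _config(1, 100, RuleSpec("CG", {"experimental_only": True}), discount=0.8)
        states = make_fixture_states(n=[8, 8], mean=[0.9, -0.9])
        picks = np.array(
            [
                allocate(
                    RuleSpec("CG", {"experimental_only": True}), 16, states, cfg,
                    table=small_table, rng=rng,
                )
                for _ in range(4000)
            ]
        )
        assert np.mean(picks == 0) == pytest.approx(0.5, abs=0.03)

    def test_symmetric_experimental_arms_equally_likely(self, rng, small_table):
        cfg = _config(2, 100, RuleSpec("CG"), discount=0.8)
        states = make_fixture_states(n=[9, 4, 4], mean=[-1.0, 0.2, 0.2])
        picks = np.array(
            [
                allocate(RuleSpec("CG"), 17, states, cfg, table=small_table, rng=rng)
                for _ in range(3000)
            ]
        )
        exp_picks = picks[picks > 0]
        assert stats.chisquare(np.bincount(exp_picks)[1:]).pvalue > 1e-3

    def test_wrap_rejects_non_index_base(self, rng):
        cfg = _config(1, 10, RuleSpec("CB"))
        with pytest.raises(ConfigurationError):
            protected_control_wrap(RuleSpec("CB"), 0, _empty_states(2), cfg, rng=rng)


class TestBatching:
    def test_recompute_schedule(self):
        """T=116, b=20: refreshes at patients 1, 21, 41, 61, 81, 101."""
        cfg = _config(1, 116, RuleSpec("TSB"), batch_size=20, seed=3)
        res = run_trial(cfg)
        assert res.arm_counts.sum() == 116
        alloc = make_allocator(cfg)
        rng = np.random.default_rng(0)
        n = np.zeros(2, dtype=int)
        mean = np.zeros(2)
        total = np.zeros(2)
        for t in range(116):
            k = alloc.choose(t, n, mean, rng)
            y = rng.standard_normal()
            n[k] += 1
            total[k] += y
            mean[k] = total[k] / n[k]
        assert alloc.recompute_times == [0, 20, 40, 60, 80, 100]

    def test_block_larger_than_trial_keeps_initial_vector(self):
        cfg = _config(1, 15, RuleSpec("TSB"), batch_size=50, seed=9)
        alloc = make_allocator(cfg)
        rng = np.random.default_rng(1)
        n = np.zeros(2, dtype=int)
        mean = np.zeros(2)
        for t in range(15):
            k = alloc.choose(t, n, mean, rng)
            n[k] += 1
        assert alloc.recompute_times == [0]
        np.testing.assert_allclose(alloc._vector, 0.5)

    def test_unit_block_recomputes_every_patient(self):
        cfg = _config(1, 12, RuleSpec("TSB"), batch_size=1, seed=4)
        alloc = make_allocator(cfg)
        rng = np.random.default_rng(2)
        n = np.zeros(2, dtype=int)
        total = np.zeros(2)
        mean = np.zeros(2)
        for t in range(12):
            k = alloc.choose(t, n, mean, rng)
            y = rng.standard_normal()
            n[k] += 1
            total[k] += y
            mean[k] = total[k] / n[k]
        assert alloc.recompute_times == list(range(12))

    def test_stateless_allocate_refuses_batched_rules(self, rng):
        cfg = _config(1, 10, RuleSpec("TSB"), batch_size=5)
        with pytest.raises(ConfigurationError):
            allocate(RuleSpec("TSB"), 0, _empty_states(2), cfg, rng=rng)

    def test_missing_batch_size_rejected(self):
        cfg = _config(1, 10, RuleSpec("FR"))
        with pytest.raises(ConfigurationError):
            BatchedAllocator(RuleSpec("TSB"), cfg, None)


class TestDistributionalProperties:
    def test_fr_counts_are_multinomial_uniform(self):
        cfg = _config(3, 600, RuleSpec("FR"), seed=42)
        res = run_trial(cfg)
        counts = res.arm_counts
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_h0_exchangeability_of_experimental_arms(self, table995):
        """Relabelling experimental arms leaves allocation counts invariant."""
        rng = np.random.default_rng(55)
        lead = []
        for r in rng.spawn(1200):
            cfg = _config(2, 30, RuleSpec("GI"), means=(0.0, 0.0, 0.0))
            res = run_trial(cfg, table=table995, rng=r)
            n1, n2 = res.arm_counts[1], res.arm_counts[2]
            if n1 != n2:
                lead.append(n1 > n2)
        p = stats.binomtest(int(np.sum(lead)), len(lead), 0.5).pvalue
        assert p > 1e-3

    def test_missing_table_is_a_configuration_error(self, rng):
        cfg = _config(1, 10, RuleSpec("GI"), discount=0.42)
        with pytest.raises(ConfigurationError):
            allocate(RuleSpec("GI"), 2, _empty_states(2), cfg, rng=rng)
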