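import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_session
from oracles import mb_loglik, random_trials, sarsa_loglik

from twostep import (
    AgentParams,
    HybridAgent,
    TaskConfig,
    Trial,
    ValueState,
    choice_prob_stage1,
    choice_prob_stage2,
    mb_values,
    net_values,
    run_session,
    session_likelihood_terms,
    session_neg_log_likelihood,
    update,
)


def params(**kw):
    base = dict(beta1=1.0, beta2=1.0, alpha1=0.5, alpha2=0.5, lam=0.5, p=0.0, w=0.5)
    base.update(kw)
    return AgentParams(**base)


class TestValuation:
    def test_mb_values_single_nonzero(self):
        q2 = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert mb_values(q2, 0.7) == pytest.approx([0.7, 0.3])

    def test_mb_values_zero(self):
        assert mb_values(np.zeros((2, 2)), 0.7) == pytest.approx([0.0, 0.0])

    def test_mb_values_hand_arithmetic(self):
        q2 = np.array([[0.4, 0.6], [0.2, 0.8]])
        # 0.7*0.6 + 0.3*0.8 and 0.3*0.6 + 0.7*0.8
        assert mb_values(q2, 0.7) == pytest.approx([0.66, 0.74])

    def test_mb_values_respects_action_state_map(self):
        q2 = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert mb_values(q2, 0.7, action_state_map=(1, 0)) == pytest.approx([0.3, 0.7])

    def test_net_values_special_cases_and_mixture(self):
        mf, mb = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert net_values(mf, mb, 0.0) == pytest.approx(mf)
        assert net_values(mf, mb, 1.0) == pytest.approx(mb)
        assert net_values(mf, mb, 0.39) == pytest.approx([0.61, 0.39])


class TestChoiceRule:
    def test_indifferent_when_beta_zero(self):
        assert choice_prob_stage1(np.zeros(2), None, 0.0, 0.0) == pytest.approx([0.5, 0.5])
        assert choice_prob_stage2(np.zeros(2), 0.0) == pytest.approx([0.5, 0.5])

    def test_perseveration_logistic(self):
        # equal values, p = 0.11, previous choice 0: P(a0) = 1/(1+e^-0.11)
        pr = choice_prob_stage1(np.zeros(2), 0, beta1=1.0, p=0.11)
        assert pr[0] == pytest.approx(1.0 / (1.0 + math.exp(-0.11)), abs=1e-12)

    def test_stage2_logistic(self):
        pr = choice_prob_stage2(np.array([0.75, 0.25]), beta2=3.69)
        assert pr[0] == pytest.approx(1.0 / (1.0 + math.exp(-3.69 * 0.5)), abs=1e-12)

    def test_greedy_limit(self):
        pr = choice_prob_stage1(np.array([1.0, 0.0]), None, beta1=100.0, p=0.0)
        assert pr[0] == pytest.approx(1.0, abs=1e-8)

    def test_swap_symmetry(self):
        pr = choice_prob_stage2(np.array([0.3, 0.9]), 2.0)
        sw = choice_prob_stage2(np.array([0.9, 0.3]), 2.0)
        assert pr[::-1] == pytest.approx(sw)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            choice_prob_stage1(np.array([np.nan, 0.0]), None, 1.0, 0.0)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0, 20), st.floats(-5, 5))
    @settings(deadline=None, max_examples=50)
    def test_sums_to_one_and_translation_invariant(self, q0, q1, beta, shift):
        base = choice_prob_stage1(np.array([q0, q1]), 0, beta, 0.3)
        shifted = choice_prob_stage1(np.array([q0 + shift, q1 + shift]), 0, beta, 0.3)
        assert base.sum() == pytest.approx(1.0, abs=1e-12)
        assert base == pytest.approx(shifted, abs=1e-9)


class TestUpdate:
    def trial(self, a1=0, s2=0, a2=0, r=1):
        return Trial(index=0, choice1=a1, state2=s2, common=True, choice2=a2,
                     reward=r, completed=True)

    def seeded_values(self):
        v = ValueState.zeros()
        v.q2[0, 0] = 0.5
        return v

    def test_lam1_only_final_reward_matters(self):
        # alpha1=1, lam=1: q_mf1 lands on the reward itself
        new, _ = update(self.seeded_values(), self.trial(r=1), params(alpha1=1.0, lam=1.0))
        assert new.q_mf1[0] == pytest.approx(1.0)

    def test_lam0_only_second_stage_value_matters(self):
        new, _ = update(self.seeded_values(), self.trial(r=1), params(alpha1=1.0, lam=0.0))
        assert new.q_mf1[0] == pytest.approx(0.5)

    def test_zero_learning_rates_freeze_values_but_report_rpes(self):
        v = self.seeded_values()
        new, rec = update(v, self.trial(r=1), params(alpha1=0.0, alpha2=0.0))
        assert np.array_equal(new.q_mf1, v.q_mf1) and np.array_equal(new.q2, v.q2)
        assert rec.delta_out == pytest.approx(0.5)
        assert rec.delta_mf_s2 == pytest.approx(0.5)

    def test_outcome_rpe_shared_between_systems(self):
        v = ValueState(q_mf1=np.array([0.2, 0.1]),
                       q2=np.array([[0.5, 0.1], [0.3, 0.9]]))
        _, rec = update(v, self.trial(a1=1, s2=1, a2=0, r=0), params())
        # delta_out depends only on the shared q2, not on which stage-1
        # valuation is in play
        assert rec.delta_out == pytest.approx(0.0 - 0.3)

    def test_incomplete_trial_rejected(self):
        bad = Trial(index=0, choice1=-1, state2=-1, common=False, choice2=-1,
                    reward=0, completed=False)
        with pytest.raises(ValueError):
            update(ValueState.zeros(), bad, params())


class TestSessionLikelihood:
    def test_chance_single_trial(self):
        sess = make_session([(0, 0, 0, 1)])
        ll1, ll2 = session_likelihood_terms(sess, params(beta1=0.0, beta2=0.0, p=0.0))
        assert ll1.sum() + ll2.sum() == pytest.approx(2 * math.log(0.5))

    def test_chance_199_trials(self):
        rng = np.random.default_rng(0)
        sess = make_session(random_trials(199, rng))
        total = -session_neg_log_likelihood(sess, params(beta1=0.0, beta2=0.0, p=0.0))
        assert total == pytest.approx(-199 * 2 * math.log(2))

    def test_empty_session_rejected(self):
        sess = make_session([(0, 0, 0, 1)], completed=[False])
        with pytest.raises(ValueError):
            session_likelihood_terms(sess, params())

    def test_incomplete_trials_contribute_nothing(self):
        tuples = random_trials(20, np.random.default_rng(1))
        full = make_session(tuples)
        flags = [i % 5 != 0 for i in range(20)]
        partial = make_session(tuples, completed=flags)
        kept = [t for t, f in zip(tuples, flags) if f]
        dense = make_session(kept)
        p = params()
        assert session_neg_log_likelihood(partial, p) == pytest.approx(
            session_neg_log_likelihood(dense, p))

    def test_self_consistency_beats_chance(self, cfg, table_params):
        sess = run_session(HybridAgent(table_params, cfg), cfg, np.random.default_rng(3))
        fitted = -session_neg_log_likelihood(sess, table_params)
        chance = -201 * 2 * math.log(2)
        assert fitted > chance


class TestSpecialCaseEquivalence:
    """The hybrid with w pinned must reduce exactly to the standalone
    learners (which share no code with the replay loop)."""

    def test_w0_matches_standalone_sarsa(self):
        rng = np.random.default_rng(10)
        trials = random_trials(1000, rng)
        sess = make_session(trials)
        p = params(beta1=4.0, beta2=3.0, alpha1=0.6, alpha2=0.4, lam=0.63,
                   p=0.2, w=0.0)
        ours = -session_neg_log_likelihood(sess, p)
        oracle = sarsa_loglik(trials, 4.0, 3.0, 0.6, 0.4, 0.63, 0.2)
        assert abs(ours - oracle) < 1e-10

    def test_w1_matches_standalone_model_based(self):
        rng = np.random.default_rng(11)
        trials = random_trials(1000, rng)
        sess = make_session(trials)
        p = params(beta1=4.0, beta2=3.0, alpha1=0.6, alpha2=0.4, lam=0.63,
                   p=0.2, w=1.0)
        ours = -session_neg_log_likelihood(sess, p)
        oracle = mb_loglik(trials, 4.0, 3.0, 0.4, 0.2)
        assert abs(ours - oracle) < 1e-10


class TestParamValidation:
    def test_learning_rates_bounded(self):
        with pytest.raises(ValueError):
            AgentParams(1, 1, 1.5, 0.5, 0.5, 0.0, 0.5)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            AgentParams(-1, 1, 0.5, 0.5, 0.5, 0.0, 0.5)

    def test_simulation_requires_unit_lam_w(self):
        p = AgentParams(1, 1, 0.5, 0.5, 1.4, 0.0, 0.5)
        with pytest.raises(ValueError):
            p.require_simulation_valid()
        # but likelihood evaluation accepts it as-is
        sess = make_session(random_trials(5, np.random.default_rng(0)))
        assert np.isfinite(session_neg_log_likelihood(sess, p))
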