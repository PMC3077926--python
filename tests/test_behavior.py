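import numpy as np
import pytest
from scipy import stats

from conftest import make_session

from twostep import (
    AgentParams,
    MODELS,
    TaskConfig,
    Trial,
    code_trial_pairs,
    predicted_stay_tables,
    stay_regression,
    stay_table,
)
from twostep.task import RewardWalks, Session

FIG2_PARAMS = AgentParams(beta1=5.19, beta2=3.69, alpha1=0.54, alpha2=0.42,
                          lam=1.0, p=0.11, w=0.5)


def logistic_session(coefs, n_pairs, rng, subject_id="s"):
    """Build a session whose stay behavior follows a known logistic law in
    the effect-coded previous-trial predictors."""
    b0, br, bc, bi = coefs
    trials = []
    choice = int(rng.integers(2))
    for i in range(n_pairs + 1):
        r = int(rng.integers(2))
        common = bool(rng.integers(2))
        s2 = choice if common else 1 - choice
        trials.append(Trial(index=i, choice1=choice, state2=s2, common=common,
                            choice2=0, reward=r, completed=True))
        x_r, x_c = r - 0.5, int(common) - 0.5
        eta = b0 + br * x_r + bc * x_c + bi * x_r * x_c
        stay = rng.random() < 1.0 / (1.0 + np.exp(-eta))
        choice = choice if stay else 1 - choice
    cfg = TaskConfig(n_trials=len(trials), block_size=len(trials))
    return Session(config=cfg, trials=trials,
                   walks=RewardWalks(probs=np.full((2, 2), 0.5)),
                   subject_id=subject_id)


class TestCodeTrialPairs:
    def test_stay_coding(self):
        sess = make_session([(0, 0, 0, 1), (0, 0, 0, 0), (1, 1, 0, 0)])
        pairs = code_trial_pairs(sess)
        assert list(pairs.stay) == [True, False]

    def test_all_incomplete_gives_empty(self):
        sess = make_session([(0, 0, 0, 1)] * 4, completed=[False] * 4)
        assert code_trial_pairs(sess).empty

    def test_pairs_with_incomplete_member_dropped(self):
        sess = make_session([(0, 0, 0, 1)] * 5,
                            completed=[True, False, True, True, True])
        pairs = code_trial_pairs(sess)
        # eligible adjacent pairs: (2,3) and (3,4)
        assert list(pairs.trial) == [2, 3]

    def test_hand_coded_five_trial_log(self):
        # (choice1, state2, choice2, reward); default map: action a -> state a
        sess = make_session([
            (0, 0, 1, 1),   # common, rewarded
            (0, 1, 0, 0),   # rare, unrewarded
            (1, 1, 1, 1),   # common, rewarded  (switch happened)
            (1, 0, 0, 0),   # rare, unrewarded
            (0, 0, 0, 1),
        ])
        pairs = code_trial_pairs(sess)
        assert list(pairs.stay) == [True, False, True, False]
        assert list(pairs.prev_reward) == [0.5, -0.5, 0.5, -0.5]
        assert list(pairs.prev_common) == [0.5, -0.5, 0.5, -0.5]

    def test_block_break_pairs_configurable(self):
        sess = make_session([(0, 0, 0, 1)] * 6,
                            config=TaskConfig(n_trials=6, block_size=3))
        assert len(code_trial_pairs(sess)) == 5
        assert len(code_trial_pairs(sess, drop_block_breaks=True)) == 4


class TestStayTable:
    def test_always_stay_agent(self):
        rng = np.random.default_rng(0)
        sessions = [logistic_session((20, 0, 0, 0), 200, rng, f"s{i}")
                    for i in range(3)]
        table = stay_table(sessions)
        assert table.probs == pytest.approx(np.ones((2, 2)))
        assert table.sem == pytest.approx(np.zeros((2, 2)), abs=1e-12)

    def test_coin_flip_chooser(self):
        rng = np.random.default_rng(1)
        table = stay_table([logistic_session((0, 0, 0, 0), 10_000, rng)])
        assert table.probs == pytest.approx(np.full((2, 2), 0.5), abs=0.05)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(2)
        sessions = [logistic_session((0.5, 1.0, 0.0, 0.8), 300, rng, f"s{i}")
                    for i in range(4)]
        table = stay_table(sessions)
        # brute-force recount straight from the raw trial logs
        for r in (0, 1):
            for c in (0, 1):
                per_subj = []
                for sess in sessions:
                    num = den = 0
                    for a, b in zip(sess.trials[:-1], sess.trials[1:]):
                        if a.reward == r and a.common == bool(c):
                            den += 1
                            num += a.choice1 == b.choice1
                    per_subj.append(num / den)
                assert table.probs[r, c] == pytest.approx(np.mean(per_subj))

    def test_empty_cell_contributes_nothing(self):
        # one subject whose previous trials are never rewarded
        rng = np.random.default_rng(3)
        s_all = logistic_session((0.5, 0.5, 0, 0), 400, rng, "full")
        s_norw = logistic_session((0.5, 0.5, 0, 0), 50, rng, "norw")
        for t in s_norw.trials:
            t.reward = 0
        table = stay_table([s_all, s_norw])
        assert np.isfinite(table.probs).all()


class TestStayRegression:
    def test_recovers_known_coefficients(self):
        truth = np.array([0.4, 1.2, -0.1, 0.9])
        rng = np.random.default_rng(4)
        sessions = [logistic_session(truth, 10_000, rng, f"s{i}") for i in range(4)]
        res = stay_regression(sessions)
        se = res.coefs.std(axis=0, ddof=1) / 2 + res.ses.mean(axis=0)
        assert np.all(np.abs(res.group_mean - truth) < 3 * se)

    def test_all_stay_cohort(self):
        rng = np.random.default_rng(5)
        sessions = [logistic_session((3.0, 0, 0, 0), 1000, rng, f"s{i}")
                    for i in range(4)]
        res = stay_regression(sessions)
        assert res.group_mean[0] > 2.0
        # the reward/transition terms are null: not significant at 0.01
        assert np.all(res.group_p[1:] > 0.01)
        assert res.separation_flagged == []  # ridge keeps estimates finite

    def test_short_sessions_excluded(self):
        rng = np.random.default_rng(6)
        sessions = [logistic_session((0.5, 1, 0, 0), 300, rng, "long"),
                    logistic_session((0.5, 1, 0, 0), 5, rng, "short")]
        res = stay_regression(sessions)
        assert res.excluded == ["short"]
        assert res.subject_ids == ["long"]


class TestPredictedStayTables:
    def test_sarsa1_reward_main_effect_no_interaction(self):
        """SARSA(1) agents repeat rewarded choices regardless of the
        transition type that produced the reward."""
        rng = np.random.default_rng(7)
        table = predicted_stay_tables(MODELS["td_only"], FIG2_PARAMS, 20,
                                      TaskConfig(), rng)
        rewarded = table.probs[1].mean()
        unrewarded = table.probs[0].mean()
        assert rewarded > unrewarded + 0.05
        for r in (0, 1):
            gap = abs(table.probs[r, 1] - table.probs[r, 0])
            assert gap < 3 * np.hypot(table.sem[r, 1], table.sem[r, 0])

    def test_model_based_crossover(self):
        rng = np.random.default_rng(8)
        table = predicted_stay_tables(MODELS["mb_only"], FIG2_PARAMS, 20,
                                      TaskConfig(), rng)
        assert table.cell(True, True) > table.cell(True, False)
        assert table.cell(False, False) > table.cell(False, True)

    def test_indifferent_agents_flat_table(self):
        rng = np.random.default_rng(9)
        flat = AgentParams(0.0, 0.0, 0.5, 0.5, 1.0, 0.0, 0.5)
        table = predicted_stay_tables(MODELS["hybrid"], flat, 10, TaskConfig(), rng)
        assert table.probs == pytest.approx(np.full((2, 2), 0.5), abs=0.06)
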