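import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from twostep import AgentParams, HybridAgent, Session, TaskConfig, Trial, run_session
from twostep.task import RewardWalks


@pytest.fixture
def cfg():
    return TaskConfig()


@pytest.fixture
def table_params():
    """Mixed-effects style point estimates used as generating values."""
    return AgentParams(beta1=4.23, beta2=2.95, alpha1=0.70, alpha2=0.40,
                       lam=0.63, p=0.17, w=0.51)


@pytest.fixture
def sim_session(cfg, table_params):
    rng = np.random.default_rng(42)
    return run_session(HybridAgent(table_params, cfg), cfg, rng, seed=42)


def make_session(trial_tuples, config=None, completed=None):
    """Build a Session from (choice1, state2, choice2, reward) tuples;
    the common flag is derived from the default action->state map."""
    config = config or TaskConfig(n_trials=len(trial_tuples))
    trials = []
    for i, (a1, s2, a2, r) in enumerate(trial_tuples):
        done = True if completed is None else completed[i]
        if done:
            common = config.action_state_map[a1] == s2
            trials.append(Trial(index=i, choice1=a1, state2=s2, common=common,
                                choice2=a2, reward=r, completed=True))
        else:
            trials.append(Trial(index=i, choice1=-1, state2=-1, common=False,
                                choice2=-1, reward=0, completed=False))
    walks = RewardWalks(probs=np.full((2, 2), 0.5))
    return Session(config=config, trials=trials, walks=walks, subject_id="crafted")
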