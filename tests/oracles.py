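"""Standalone reference learners used as independent oracles.

These implement SARSA(lambda) and a pure model-based Bellman learner from
scratch, sharing no code with the package's replay loop, so that the
hybrid model's w=0 / w=1 special cases can be checked against them.
"""

import numpy as np


def _softmax(x):
    x = np.asarray(x, float)
    e = np.exp(x - x.max())
    return e / e.sum()


def sarsa_loglik(trials, beta1, beta2, alpha1, alpha2, lam, p):
    """Log-likelihood of (choice1, state2, choice2, reward) tuples under a
    standalone SARSA(lambda) learner with perseveration."""
    Q1 = np.zeros(2)
    Q2 = np.zeros((2, 2))
    prev = None
    total = 0.0
    for a1, s2, a2, r in trials:
        logits = beta1 * Q1.copy()
        if prev is not None:
            logits[prev] += p
        total += np.log(_softmax(logits)[a1])
        total += np.log(_softmax(beta2 * Q2[s2])[a2])
        old_q2 = Q2[s2, a2]
        Q1[a1] += alpha1 * (old_q2 - Q1[a1])
        Q2[s2, a2] += alpha2 * (r - old_q2)
        Q1[a1] += alpha1 * lam * (r - old_q2)
        prev = a1
    return total


def mb_loglik(trials, beta1, beta2, alpha2, p, p_common=0.7, action_state_map=(0, 1)):
    """Log-likelihood under a standalone model-based learner: stage-1
    values from Bellman evaluation over the fixed transitions, stage-2
    values learned by TD on outcomes."""
    Q2 = np.zeros((2, 2))
    prev = None
    total = 0.0
    for a1, s2, a2, r in trials:
        qmb = np.empty(2)
        for a in (0, 1):
            s = action_state_map[a]
            qmb[a] = p_common * Q2[s].max() + (1 - p_common) * Q2[1 - s].max()
        logits = beta1 * qmb
        if prev is not None:
            logits[prev] += p
        total += np.log(_softmax(logits)[a1])
        total += np.log(_softmax(beta2 * Q2[s2])[a2])
        Q2[s2, a2] += alpha2 * (r - Q2[s2, a2])
        prev = a1
    return total


def random_trials(n, rng):
    """Random observed data: choices, states and rewards drawn uniformly
    (the transition need not be consistent with any policy)."""
    return [
        (int(rng.integers(2)), int(rng.integers(2)), int(rng.integers(2)),
         int(rng.integers(2)))
        for _ in range(n)
    ]
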