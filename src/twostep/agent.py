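"""Hybrid model-based / model-free valuation of the two-stage task.

Two learners share one table of second-stage action values ``q2``:

* the model-free system learns first-stage values ``q_mf1`` by
  SARSA(lambda) temporal-difference updates, with the eligibility
  parameter ``lam`` governing how strongly the final outcome's prediction
  error propagates directly back to the first stage (lam=1: only the
  final reward reinforces; lam=0: only the second-stage value does);
* the model-based system evaluates first-stage actions prospectively by
  Bellman's equation over the known transition probabilities,
  ``q_mb1[a] = P(common)*max_a' q2[s_a, a'] + (1-P)*max_a' q2[s_other, a']``.

Choices at stage 1 follow a softmax over the ``w``-weighted mixture of the
two valuations plus a perseveration bonus ``p`` (in logit units) for
repeating the previous first-stage choice; stage-2 choices are a plain
softmax over ``q2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .task import Session, TaskConfig, Trial

__all__ = [
    "AgentParams", "ValueState", "RpeRecord", "HybridAgent",
    "mb_values", "net_values", "choice_prob_stage1", "choice_prob_stage2",
    "update", "session_likelihood_terms", "session_neg_log_likelihood",
    "replay",
]

PARAM_NAMES = ("beta1", "beta2", "alpha1", "alpha2", "lam", "p", "w")


@dataclass(frozen=True)
class AgentParams:
    """The seven free parameters of the hybrid model.

    beta1, beta2
        softmax inverse temperatures at the two stages (>= 0).
    alpha1, alpha2
        learning rates at the two stages, in [0, 1].
    lam
        eligibility weight on the outcome prediction error at stage 1;
        nominally in [0, 1] but allowed outside during fitting.
    p
        perseveration strength, a logit bonus for repeating the previous
        first-stage choice (any sign).
    w
        model-based weight in the stage-1 mixture; nominally in [0, 1]
        but allowed outside during fitting.
    """

    beta1: float
    beta2: float
    alpha1: float
    alpha2: float
    lam: float
    p: float
    w: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha1 <= 1.0 and 0.0 <= self.alpha2 <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("softmax temperatures must be non-negative")

    def require_simulation_valid(self) -> "AgentParams":
        """Simulation additionally demands lam, w in [0, 1]."""
        if not (0.0 <= self.lam <= 1.0 and 0.0 <= self.w <= 1.0):
            raise ValueError("simulation requires lam and w in [0, 1]")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, x) -> "AgentParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))


@dataclass
class ValueState:
    """Learned values; ``q_mb1``/``q_net1`` are always derived fresh from
    ``q2`` so they can never go stale."""

    q_mf1: np.ndarray
    q2: np.ndarray
    prev_choice1: Optional[int] = None

    @classmethod
    def zeros(cls) -> "ValueState":
        return cls(q_mf1=np.zeros(2), q2=np.zeros((2, 2)))

    def q_mb1(self, p_common: float, action_state_map=(0, 1)) -> np.ndarray:
        return mb_values(self.q2, p_common, action_state_map)

    def q_net1(self, p_common: float, w: float, action_state_map=(0, 1)) -> np.ndarray:
        return net_values(self.q_mf1, self.q_mb1(p_common, action_state_map), w)


@dataclass(frozen=True)
class RpeRecord:
    """Prediction errors for one trial at the two analysis timepoints.

    ``delta_out`` is shared by both systems because the second-stage
    values are shared; only the second-stage-onset error differs.
    """

    trial: int
    delta_mf_s2: float
    delta_mb_s2: float
    delta_out: float


def mb_values(q2: np.ndarray, p_common: float, action_state_map=(0, 1)) -> np.ndarray:
    """One-step Bellman evaluation of the two first-stage actions against
    the fixed transition probabilities."""
    if not (0.5 < p_common <= 1.0):
        raise ValueError("p_common must be in (0.5, 1]")
    q2 = np.asarray(q2, dtype=float)
    best = q2.max(axis=1)  # value of each second-stage state under a greedy continuation
    out = np.empty(2)
    for a in (0, 1):
        s = action_state_map[a]
        out[a] = p_common * best[s] + (1.0 - p_common) * best[1 - s]
    return out


def net_values(q_mf1: np.ndarray, q_mb1: np.ndarray, w: float) -> np.ndarray:
    """Mixture of the two stage-1 valuations: w*MB + (1-w)*MF."""
    return w * np.asarray(q_mb1, float) + (1.0 - w) * np.asarray(q_mf1, float)


def _softmax2(x0: float, x1: float) -> np.ndarray:
    m = x0 if x0 > x1 else x1
    e0 = math.exp(x0 - m)
    e1 = math.exp(x1 - m)
    z = e0 + e1
    return np.array([e0 / z, e1 / z])


def choice_prob_stage1(
    q_net1: np.ndarray,
    prev_choice1: Optional[int],
    beta1: float,
    p: float,
) -> np.ndarray:
    """Softmax with perseveration: P(a) proportional to
    exp(beta1*q_net1[a] + p*[a == previous choice])."""
    if not np.all(np.isfinite(q_net1)):
        raise ValueError("non-finite stage-1 values")
    x0 = beta1 * float(q_net1[0]) + (p if prev_choice1 == 0 else 0.0)
    x1 = beta1 * float(q_net1[1]) + (p if prev_choice1 == 1 else 0.0)
    return _softmax2(x0, x1)


def choice_prob_stage2(q2_row: np.ndarray, beta2: float) -> np.ndarray:
    """Plain softmax over the presented second-stage state's two values."""
    if not np.all(np.isfinite(q2_row)):
        raise ValueError("non-finite stage-2 values")
    return _softmax2(beta2 * float(q2_row[0]), beta2 * float(q2_row[1]))


def update(
    values: ValueState,
    trial: Trial,
    params: AgentParams,
    p_common: float = 0.7,
    action_state_map=(0, 1),
) -> tuple[ValueState, RpeRecord]:
    """Apply one completed trial's learning updates.

    Order of operations: the second-stage-onset prediction error is taken
    against the pre-update values; the model-free stage-1 value is moved
    toward the second-stage value; the outcome error updates the
    second-stage value and, scaled by lam, also the stage-1 value
    (within-trial eligibility; traces do not persist across trials).
    Returns a fresh ValueState and the trial's prediction errors.
    """
    if not trial.completed:
        raise ValueError("cannot update from an incomplete trial")
    a1, s2, a2 = trial.choice1, trial.state2, trial.choice2
    if a1 not in (0, 1) or s2 not in (0, 1) or a2 not in (0, 1):
        raise ValueError(f"trial indices out of range: {trial}")

    q_mf1 = values.q_mf1.copy()
    q2 = values.q2.copy()
    q_mb1 = mb_values(q2, p_common, action_state_map)

    delta_mf_s2 = q2[s2, a2] - q_mf1[a1]
    delta_mb_s2 = q2[s2, a2] - q_mb1[a1]
    q_mf1[a1] += params.alpha1 * delta_mf_s2

    delta_out = trial.reward - q2[s2, a2]
    q2[s2, a2] += params.alpha2 * delta_out
    q_mf1[a1] += params.alpha1 * params.lam * delta_out

    new = ValueState(q_mf1=q_mf1, q2=q2, prev_choice1=a1)
    rec = RpeRecord(trial=trial.index, delta_mf_s2=float(delta_mf_s2),
                    delta_mb_s2=float(delta_mb_s2), delta_out=float(delta_out))
    return new, rec


# ---------------------------------------------------------------------------
# fast likelihood replay
#
# The same sequential replay underlies likelihood evaluation, regressor
# construction and the simulating agent; the inner loop is written in
# scalar Python (math.exp) because it sits inside numerical optimizers.

def _compact(session: Session) -> list[tuple[int, int, int, int, int]]:
    """(index, choice1, state2, choice2, reward) for completed trials, in order."""
    return [
        (t.index, t.choice1, t.state2, t.choice2, t.reward)
        for t in session.trials
        if t.completed
    ]


def replay(
    session: Session,
    params: AgentParams,
    collect: bool = False,
    _trials: Optional[list] = None,
):
    """Replay the learner over a session's observed choices and outcomes.

    Returns ``(ll1, ll2, records, net_chosen)`` where ``ll1``/``ll2`` are
    per-completed-trial log-probabilities of the observed first- and
    second-stage choices, and — when ``collect`` — ``records`` holds one
    RpeRecord per completed trial and ``net_chosen`` the trial-start net
    value of the chosen first-stage action.  Incomplete trials contribute
    nothing (no likelihood term, no learning, no perseveration carryover).
    """
    trials = _trials if _trials is not None else _compact(session)
    if not trials:
        raise ValueError("session has no completed trials")
    cfg = session.config
    pc = cfg.p_common
    s_of_a0, s_of_a1 = cfg.action_state_map
    b1, b2 = params.beta1, params.beta2
    al1, al2 = params.alpha1, params.alpha2
    lam, pp, w = params.lam, params.p, params.w

    q_mf0 = q_mf1_ = 0.0
    q2 = [[0.0, 0.0], [0.0, 0.0]]
    prev = -1
    ll1: list[float] = []
    ll2: list[float] = []
    records: list[RpeRecord] = []
    net_chosen: list[float] = []
    exp = math.exp
    log = math.log

    for idx, a1, s2, a2, r in trials:
        row0, row1 = q2[s_of_a0], q2[s_of_a1]
        m0 = row0[0] if row0[0] > row0[1] else row0[1]
        m1 = row1[0] if row1[0] > row1[1] else row1[1]
        qmb0 = pc * m0 + (1.0 - pc) * m1
        qmb1 = pc * m1 + (1.0 - pc) * m0
        qn0 = w * qmb0 + (1.0 - w) * q_mf0
        qn1 = w * qmb1 + (1.0 - w) * q_mf1_

        x0 = b1 * qn0 + (pp if prev == 0 else 0.0)
        x1 = b1 * qn1 + (pp if prev == 1 else 0.0)
        m = x0 if x0 > x1 else x1
        e0, e1 = exp(x0 - m), exp(x1 - m)
        z = e0 + e1
        ll1.append(log((e0 if a1 == 0 else e1) / z))

        row = q2[s2]
        y0, y1 = b2 * row[0], b2 * row[1]
        m = y0 if y0 > y1 else y1
        f0, f1 = exp(y0 - m), exp(y1 - m)
        zz = f0 + f1
        ll2.append(log((f0 if a2 == 0 else f1) / zz))

        if collect:
            net_chosen.append(qn0 if a1 == 0 else qn1)
            qmb_a1 = qmb0 if a1 == 0 else qmb1
            qmf_a1 = q_mf0 if a1 == 0 else q_mf1_
            records.append(RpeRecord(trial=idx,
                                     delta_mf_s2=row[a2] - qmf_a1,
                                     delta_mb_s2=row[a2] - qmb_a1,
                                     delta_out=r - row[a2]))

        # learning (order matters: s2 error first, then outcome error)
        d_mf = row[a2] - (q_mf0 if a1 == 0 else q_mf1_)
        d_out = r - row[a2]
        incr = al1 * (d_mf + lam * d_out)
        if a1 == 0:
            q_mf0 += incr
        else:
            q_mf1_ += incr
        row[a2] += al2 * d_out
        prev = a1

    return np.array(ll1), np.array(ll2), records, np.array(net_chosen)


def session_likelihood_terms(session: Session, params: AgentParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-completed-trial log-probabilities of the two observed choices."""
    ll1, ll2, _, _ = replay(session, params)
    return ll1, ll2


def session_neg_log_likelihood(session: Session, params: AgentParams) -> float:
    ll1, ll2 = session_likelihood_terms(session, params)
    return float(-(ll1.sum() + ll2.sum()))


class HybridAgent:
    """Stateful policy wrapper used for simulation (consumes trials via
    ``observe``, exposes choice probabilities per stage)."""

    def __init__(self, params: AgentParams, config: Optional[TaskConfig] = None):
        self.params = params.require_simulation_valid()
        self.config = config or TaskConfig()
        self.values = ValueState.zeros()

    def policy_stage1(self) -> np.ndarray:
        qn = self.values.q_net1(self.config.p_common, self.params.w,
                                self.config.action_state_map)
        return choice_prob_stage1(qn, self.values.prev_choice1,
                                  self.params.beta1, self.params.p)

    def policy_stage2(self, state2: int) -> np.ndarray:
        return choice_prob_stage2(self.values.q2[state2], self.params.beta2)

    def observe(self, trial: Trial) -> None:
        self.values, _ = update(self.values, trial, self.params,
                                self.config.p_common, self.config.action_state_map)
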