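"""Theory-light behavioral signatures of model-based vs model-free control.

The diagnostic is how the previous trial's outcome and transition type
shape the probability of repeating the same first-stage choice ("stay").
Pure reinforcement (SARSA with lam=1) predicts a main effect of reward
only; model-based prospective evaluation predicts a crossover
reward x transition interaction, because a reward earned after a rare
transition raises the value of the *other* first-stage option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .agent import AgentParams, HybridAgent
from .task import Session, TaskConfig, run_session

__all__ = [
    "StayTable", "RegressionResult",
    "code_trial_pairs", "stay_table", "stay_regression", "predicted_stay_tables",
]


@dataclass
class StayTable:
    """Stay probabilities factorially by previous reward x previous
    transition.  Axis 0: unrewarded/rewarded; axis 1: rare/common.
    ``probs`` are unweighted across-subject means, ``sem`` the standard
    error of those means, ``counts`` pooled trial-pair counts."""

    probs: np.ndarray
    sem: np.ndarray
    counts: np.ndarray

    def cell(self, rewarded: bool, common: bool) -> float:
        return float(self.probs[int(rewarded), int(common)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in (1, 0):
            for c in (1, 0):
                rows.append({
                    "prev_reward": "rewarded" if r else "unrewarded",
                    "prev_transition": "common" if c else "rare",
                    "stay_prob": self.probs[r, c],
                    "sem": self.sem[r, c],
                    "n_pairs": int(self.counts[r, c]),
                })
        return pd.DataFrame(rows)


def code_trial_pairs(session: Session, drop_block_breaks: bool = False) -> pd.DataFrame:
    """Code consecutive completed-trial pairs for the stay analysis.

    Returns a frame with one row per eligible pair: ``stay`` (the next
    trial repeats the first-stage choice), and effect-coded (+/- 1/2)
    predictors ``prev_reward`` and ``prev_common`` from the earlier trial.
    A pair is dropped if either trial is incomplete or they are not
    adjacent in the session.
    """
    rows = []
    bs = session.config.block_size
    for a, b in zip(session.trials[:-1], session.trials[1:]):
        if not (a.completed and b.completed):
            continue
        if drop_block_breaks and bs and (a.index + 1) % bs == 0:
            continue
        rows.append({
            "trial": a.index,
            "stay": a.choice1 == b.choice1,
            "prev_reward": 0.5 if a.reward else -0.5,
            "prev_common": 0.5 if a.common else -0.5,
        })
    return pd.DataFrame(rows, columns=["trial", "stay", "prev_reward", "prev_common"])


def stay_table(sessions: Sequence[Session]) -> StayTable:
    """Factorial stay proportions: per-subject cell means, then unweighted
    average (and SEM) across subjects.  A subject with an empty cell
    contributes nothing to that cell."""
    if not sessions:
        raise ValueError("need at least one session")
    per_subject = np.full((len(sessions), 2, 2), np.nan)
    counts = np.zeros((2, 2), dtype=int)
    for i, sess in enumerate(sessions):
        pairs = code_trial_pairs(sess)
        if pairs.empty:
            continue
        for r in (0, 1):
            for c in (0, 1):
                mask = (pairs.prev_reward == (r - 0.5)) & (pairs.prev_common == (c - 0.5))
                n = int(mask.sum())
                counts[r, c] += n
                if n:
                    per_subject[i, r, c] = pairs.loc[mask, "stay"].mean()
    probs = np.nanmean(per_subject, axis=0)
    n_eff = np.sum(~np.isnan(per_subject), axis=0)
    sd = np.nanstd(per_subject, axis=0, ddof=1)
    sem = np.where(n_eff > 1, sd / np.sqrt(np.maximum(n_eff, 1)), 0.0)
    return StayTable(probs=probs, sem=sem, counts=counts)


@dataclass
class RegressionResult:
    """Stay/switch logistic regression: per-subject coefficients plus
    across-subject (summary statistics) group inference.

    Columns of ``coefs``: intercept, prev_reward, prev_common, and their
    interaction (predictors effect-coded +/- 1/2).
    """

    subject_ids: list[str]
    coefs: np.ndarray           # n_subjects x 4
    ses: np.ndarray             # per-subject standard errors
    group_mean: np.ndarray
    group_median: np.ndarray
    group_t: np.ndarray
    group_p_t: np.ndarray       # one-sample t-test (reported, not primary)
    group_p: np.ndarray         # Wilcoxon signed-rank (primary inference)
    positive_ci: np.ndarray     # n_subjects x 4 bool: subject 95% CI above 0
    excluded: list[str]
    separation_flagged: list[str]

    TERMS = ("intercept", "reward", "transition", "reward_x_transition")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.TERMS,
            "group_mean": self.group_mean,
            "group_median": self.group_median,
            "t": self.group_t,
            "p": self.group_p,
            "p_ttest": self.group_p_t,
            "n_positive_ci": self.positive_ci.sum(axis=0),
        })


def _penalized_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-4):
    """Logistic ML with a small ridge penalty (guards against separation).
    Returns (beta, standard errors, separation flag)."""
    n, k = X.shape

    def negloglik(b):
        z = X @ b
        # log(1 + exp(-y*z)) with y in {-1, +1}, stably
        yz = y * z
        return float(np.sum(np.logaddexp(0.0, -yz)) + ridge * b @ b)

    def grad(b):
        z = X @ b
        s = -y * stats.logistic.cdf(-y * z)
        return X.T @ s + 2.0 * ridge * b

    res = optimize.minimize(negloglik, np.zeros(k), jac=grad, method="BFGS")
    b = res.x
    mu = stats.logistic.cdf(X @ b)
    W = mu * (1.0 - mu)
    H = (X * W[:, None]).T @ X + 2.0 * ridge * np.eye(k)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    flagged = bool(np.abs(b).max() > 15.0)
    return b, se, flagged


def stay_regression(
    sessions: Sequence[Session],
    ridge: float = 1e-4,
    min_pairs: int = 20,
) -> RegressionResult:
    """Per-subject penalized logistic fits of stay ~ reward * transition,
    with group-level inference by one-sample location tests on each
    coefficient across subjects (summary-statistics random-effects
    approximation).  The primary p-value is a Wilcoxon signed-rank test:
    subjects with a sparse factorial cell can yield quasi-separated,
    wildly inflated coefficients, and a rank test is insensitive to those
    magnitudes where a t-test is not.  The t statistics are also reported.
    Subjects with fewer than ``min_pairs`` eligible pairs are excluded.
    """
    coefs, ses, ids, excluded, flagged = [], [], [], [], []
    for sess in sessions:
        pairs = code_trial_pairs(sess)
        if len(pairs) < min_pairs:
            excluded.append(sess.subject_id)
            continue
        X = np.column_stack([
            np.ones(len(pairs)),
            pairs.prev_reward.to_numpy(),
            pairs.prev_common.to_numpy(),
            (pairs.prev_reward * pairs.prev_common).to_numpy(),
        ])
        y = np.where(pairs.stay.to_numpy(), 1.0, -1.0)
        b, se, flag = _penalized_logistic(X, y, ridge)
        coefs.append(b)
        ses.append(se)
        ids.append(sess.subject_id)
        if flag:
            flagged.append(sess.subject_id)
    if not coefs:
        raise ValueError("no subject had enough eligible trial pairs")
    coefs_a = np.array(coefs)
    ses_a = np.array(ses)
    t, p_t = stats.ttest_1samp(coefs_a, 0.0, axis=0)
    p_w = np.array([
        stats.wilcoxon(col).pvalue if np.any(col != 0) else 1.0
        for col in coefs_a.T
    ])
    z95 = stats.norm.ppf(0.975)
    positive_ci = (coefs_a - z95 * ses_a) > 0.0
    return RegressionResult(
        subject_ids=ids,
        coefs=coefs_a,
        ses=ses_a,
        group_mean=coefs_a.mean(axis=0),
        group_median=np.median(coefs_a, axis=0),
        group_t=np.asarray(t),
        group_p_t=np.asarray(p_t),
        group_p=p_w,
        positive_ci=positive_ci,
        excluded=excluded,
        separation_flagged=flagged,
    )


def predicted_stay_tables(
    spec,
    params: AgentParams,
    n_agents: int,
    config: TaskConfig,
    rng: np.random.Generator,
) -> StayTable:
    """Model-predicted stay proportions: simulate ``n_agents`` sessions
    under ``spec``'s restrictions applied to ``params``, then tabulate."""
    from dataclasses import replace as _dc_replace

    sim_params = _dc_replace(params, **getattr(spec, "restrictions", {}))
    sessions = []
    for i in range(n_agents):
        agent = HybridAgent(sim_params, config)
        sessions.append(run_session(agent, config, rng, subject_id=f"sim{i:03d}"))
    return stay_table(sessions)
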