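"""Generative model of the two-stage task environment.

Each trial: a binary first-stage choice leads to one of two second-stage
states (the "common" destination with probability ``p_common``, the other
otherwise), where a second binary choice pays 0 or 1 according to one of
four reward probabilities.  The four probabilities follow independent
Gaussian random walks with reflecting boundaries, so the best option keeps
changing and subjects must learn continually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Protocol

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig", "RewardWalks", "Trial", "Session",
    "step_walks", "sample_transition", "run_session",
    "write_session", "read_session",
]

_MAX_REFLECTIONS = 100


@dataclass(frozen=True)
class TaskConfig:
    """Generative constants of the task.

    ``action_state_map[a]`` is the second-stage state that first-stage
    action ``a`` reaches on a common transition; it is fixed for a whole
    session.  ``pay_fraction`` is bookkeeping only (fraction of nominal
    winnings actually paid out).
    """

    n_trials: int = 201
    block_size: int = 67
    p_common: float = 0.7
    walk_sd: float = 0.025
    walk_lo: float = 0.25
    walk_hi: float = 0.75
    walk_init: Optional[tuple[float, float, float, float]] = None
    pay_fraction: float = 0.20
    action_state_map: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError(f"p_common must be in (0.5, 1], got {self.p_common}")
        if not (0.0 <= self.walk_lo < self.walk_hi <= 1.0):
            raise ValueError("need 0 <= walk_lo < walk_hi <= 1")
        if self.walk_sd <= 0:
            raise ValueError("walk_sd must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if sorted(self.action_state_map) != [0, 1]:
            raise ValueError("action_state_map must be a permutation of (0, 1)")
        if self.walk_init is not None:
            lo, hi = self.walk_lo, self.walk_hi
            if len(self.walk_init) != 4 or not all(lo <= q <= hi for q in self.walk_init):
                raise ValueError("walk_init must be 4 probabilities within the walk bounds")


@dataclass
class RewardWalks:
    """Current reward probabilities for the four second-stage options.

    ``probs[s, a]`` is the payoff probability of action ``a`` in
    second-stage state ``s``; ``trajectory`` accumulates the per-trial
    history (one row per trial, columns flattened as (s0a0, s0a1, s1a0,
    s1a1)).
    """

    probs: np.ndarray
    trajectory: list[np.ndarray] = field(default_factory=list)

    def record(self) -> None:
        self.trajectory.append(self.probs.copy().ravel())

    def trajectory_array(self) -> np.ndarray:
        return np.array([row for row in self.trajectory])


@dataclass
class Trial:
    """One trial record.  Incomplete (timed-out) trials carry -1 in the
    fields that were never observed and ``completed=False``."""

    index: int
    choice1: int
    state2: int
    common: bool
    choice2: int
    reward: int
    completed: bool = True


@dataclass
class Session:
    """An ordered sequence of trials plus the latent walk trajectories
    that generated them."""

    config: TaskConfig
    trials: list[Trial]
    walks: RewardWalks
    subject_id: str = "sim"
    true_params: Optional[object] = None  # AgentParams when simulated
    seed: Optional[int] = None

    @property
    def n_completed(self) -> int:
        return sum(t.completed for t in self.trials)

    def completed_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.completed]


class ChoicePolicy(Protocol):
    """Anything that can play the task: supplies choice probabilities at
    both stages and consumes the trial outcome."""

    def policy_stage1(self) -> np.ndarray: ...

    def policy_stage2(self, state2: int) -> np.ndarray: ...

    def observe(self, trial: Trial) -> None: ...


def step_walks(
    walks: RewardWalks,
    sd: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
) -> RewardWalks:
    """Diffuse the four reward probabilities by one step.

    Adds independent N(0, sd) noise to each probability and reflects any
    proposal off the interval boundaries (q' = 2*hi - q above, 2*lo - q
    below, repeated until inside).
    """
    p = walks.probs.ravel()
    proposal = p + rng.normal(0.0, sd, size=p.shape)
    walks.probs = reflect(proposal, lo, hi).reshape(walks.probs.shape)
    return walks


def reflect(q: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values off [lo, hi] boundaries, iteratively."""
    q = np.array(q, dtype=float, copy=True)
    for _ in range(_MAX_REFLECTIONS):
        above = q > hi
        below = q < lo
        if not (above.any() or below.any()):
            return q
        q[above] = 2 * hi - q[above]
        q[below] = 2 * lo - q[below]
    raise ValueError(
        f"reflection did not converge within {_MAX_REFLECTIONS} bounces; sd too large for [{lo}, {hi}]"
    )


def sample_transition(
    choice1: int, config: TaskConfig, rng: np.random.Generator
) -> tuple[int, bool]:
    """Sample the second-stage state given the first-stage choice.

    Returns ``(state2, common)`` where ``common`` is True when the
    choice's fixed associated state was reached.
    """
    if choice1 not in (0, 1):
        raise ValueError(f"choice1 must be 0 or 1, got {choice1}")
    common = rng.random() < config.p_common
    associated = config.action_state_map[choice1]
    state2 = associated if common else 1 - associated
    return state2, common


def _init_walks(config: TaskConfig, rng: np.random.Generator) -> RewardWalks:
    if config.walk_init is not None:
        probs = np.array(config.walk_init, dtype=float).reshape(2, 2)
    else:
        probs = rng.uniform(config.walk_lo, config.walk_hi, size=(2, 2))
    return RewardWalks(probs=probs)


def run_session(
    agent: ChoicePolicy,
    config: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
    seed: Optional[int] = None,
    completion_prob: float = 1.0,
) -> Session:
    """Simulate a full session of the task with the given choice policy.

    The walks are stepped once per trial (after the trial's rewards are
    resolved), and the full latent trajectory is retained.  With
    ``completion_prob < 1`` a trial is aborted (no choices recorded) with
    the complementary probability, emulating response timeouts.
    """
    walks = _init_walks(config, rng)
    trials: list[Trial] = []
    for i in range(config.n_trials):
        walks.record()
        if completion_prob < 1.0 and rng.random() >= completion_prob:
            trial = Trial(index=i, choice1=-1, state2=-1, common=False,
                          choice2=-1, reward=0, completed=False)
        else:
            p1 = np.asarray(agent.policy_stage1(), dtype=float)
            _check_probs(p1, "stage-1")
            c1 = int(rng.random() < p1[1])
            state2, common = sample_transition(c1, config, rng)
            p2 = np.asarray(agent.policy_stage2(state2), dtype=float)
            _check_probs(p2, "stage-2")
            c2 = int(rng.random() < p2[1])
            reward = int(rng.random() < walks.probs[state2, c2])
            trial = Trial(index=i, choice1=c1, state2=state2, common=common,
                          choice2=c2, reward=reward, completed=True)
            agent.observe(trial)
        trials.append(trial)
        step_walks(walks, config.walk_sd, config.walk_lo, config.walk_hi, rng)
    return Session(config=config, trials=trials, walks=walks,
                   subject_id=subject_id, seed=seed)


def _check_probs(p: np.ndarray, label: str) -> None:
    if p.shape != (2,) or not np.all(np.isfinite(p)) or abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
        raise ValueError(f"agent returned invalid {label} probability vector: {p}")


# ---------------------------------------------------------------------------
# session I/O: trials as TSV, latent walks as a sibling TSV, config + seed
# as a JSON sidecar

_TRIAL_COLS = ["trial", "choice1", "state2", "common", "choice2", "reward", "completed"]
_WALK_COLS = ["trial", "pBA0", "pBA1", "pCA0", "pCA1"]


def session_frame(session: Session) -> pd.DataFrame:
    rows = [
        (t.index, t.choice1, t.state2, int(t.common), t.choice2, t.reward, int(t.completed))
        for t in session.trials
    ]
    return pd.DataFrame(rows, columns=_TRIAL_COLS)


def write_session(session: Session, directory: str | Path, stem: Optional[str] = None) -> Path:
    """Write a session as ``<stem>.tsv`` (+ ``<stem>_walks.tsv`` and
    ``<stem>.json``) under ``directory``; returns the trial-table path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or session.subject_id
    trial_path = directory / f"{stem}.tsv"
    session_frame(session).to_csv(trial_path, sep="\t", index=False)

    traj = session.walks.trajectory_array()
    walks_df = pd.DataFrame(traj, columns=_WALK_COLS[1:])
    walks_df.insert(0, "trial", np.arange(len(walks_df)))
    walks_df.to_csv(directory / f"{stem}_walks.tsv", sep="\t", index=False)

    sidecar = {"config": asdict(session.config), "seed": session.seed,
               "subject_id": session.subject_id}
    if session.true_params is not None:
        sidecar["true_params"] = asdict(session.true_params)
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return trial_path


def read_session(trial_path: str | Path) -> Session:
    """Read a session written by :func:`write_session`.  The walks TSV and
    JSON sidecar are optional (real logs have no latent trajectories)."""
    trial_path = Path(trial_path)
    df = pd.read_csv(trial_path, sep="\t")
    missing = set(_TRIAL_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")

    stem = trial_path.stem
    sidecar_path = trial_path.with_suffix(".json")
    config, seed, subject_id, true_params = TaskConfig(n_trials=len(df)), None, stem, None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        cfg = dict(meta.get("config", {}))
        if cfg.get("walk_init") is not None:
            cfg["walk_init"] = tuple(cfg["walk_init"])
        if "action_state_map" in cfg:
            cfg["action_state_map"] = tuple(cfg["action_state_map"])
        config = TaskConfig(**cfg)
        seed = meta.get("seed")
        subject_id = meta.get("subject_id", stem)
        if "true_params" in meta:
            from .agent import AgentParams

            true_params = AgentParams(**meta["true_params"])

    trials = [
        Trial(index=int(r.trial), choice1=int(r.choice1), state2=int(r.state2),
              common=bool(r.common), choice2=int(r.choice2), reward=int(r.reward),
              completed=bool(r.completed))
        for r in df.itertuples()
    ]

    walks_path = trial_path.with_name(f"{stem}_walks.tsv")
    if walks_path.exists():
        wdf = pd.read_csv(walks_path, sep="\t")
        traj = wdf[_WALK_COLS[1:]].to_numpy(dtype=float)
        walks = RewardWalks(probs=traj[-1].reshape(2, 2), trajectory=[row for row in traj])
    else:
        walks = RewardWalks(probs=np.full((2, 2), np.nan))

    return Session(config=config, trials=trials, walks=walks,
                   subject_id=subject_id, true_params=true_params, seed=seed)


class UniformRandomAgent:
    """Chance-level policy; useful as a baseline and for smoke tests."""

    def policy_stage1(self) -> np.ndarray:
        return np.array([0.5, 0.5])

    def policy_stage2(self, state2: int) -> np.ndarray:
        return np.array([0.5, 0.5])

    def observe(self, trial: Trial) -> None:
        pass
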