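"""Reward-prediction-error regressors for event-level neural analysis.

Two parametric series are emitted at two within-trial timepoints (the
second-stage onset and the outcome): the model-free TD prediction error,
and the difference between the model-based and model-free errors.  The
difference series is orthogonalized against the model-free series so it
captures only residual variation.  Because both systems share the
second-stage values, the difference is identically zero at outcome
events — only the second-stage-onset errors can dissociate the systems.

The sign convention for the difference is model-based minus model-free
(recorded in the output's ``sign`` metadata); analyses interpret only the
existence of a loading, not its sign.

A third series tags every trial start with the anticipatory value of the
chosen first-stage action under the fitted mixture, labeled by the
previous trial's reward x transition cell (or "switch").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .agent import AgentParams, replay
from .task import Session

__all__ = ["RegressorSet", "build_rpe_regressors", "orthogonalize", "anticipatory_values"]

DIFF_SIGN = "mb_minus_mf"


@dataclass
class RegressorSet:
    """Event table: one row per (trial, event) with the parametric values
    attached; ``events`` columns: trial, event, rpe_mf, rpe_diff,
    rpe_diff_orth, anticip_value, label."""

    events: pd.DataFrame
    sign: str = DIFF_SIGN

    def at(self, event: str) -> pd.DataFrame:
        return self.events[self.events.event == event]

    def write(self, path: str | Path) -> None:
        self.events.to_csv(path, sep="\t", index=False, na_rep="")


def orthogonalize(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Remove the projection of ``target`` onto ``reference``.

    A zero reference returns the target unchanged (with a warning).
    """
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if target.shape != reference.shape or target.ndim != 1 or target.size < 1:
        raise ValueError("target and reference must be equal-length 1-D series")
    denom = float(reference @ reference)
    if denom == 0.0:
        import warnings

        warnings.warn("reference series is identically zero; target returned unchanged")
        return target.copy()
    return target - (float(target @ reference) / denom) * reference


def _stay_labels(session: Session) -> dict[int, str]:
    """Label each completed trial: 'switch', or the previous trial's
    reward x transition cell for stays.  The first trial (no previous)
    is treated as switch-equivalent."""
    labels: dict[int, str] = {}
    prev = None
    for t in session.trials:
        if not t.completed:
            continue
        if prev is None or t.choice1 != prev.choice1:
            labels[t.index] = "switch"
        else:
            r = "reward" if prev.reward else "nonreward"
            c = "common" if prev.common else "rare"
            labels[t.index] = f"stay_{r}_{c}"
        prev = t
    return labels


def build_rpe_regressors(session: Session, params: AgentParams) -> RegressorSet:
    """Replay the hybrid learner over a session and emit the event table.

    Incomplete trials are excluded.  ``rpe_diff_orth`` is computed over
    all included events jointly (second-stage onsets and outcomes).
    """
    ll1, ll2, records, net_chosen = replay(session, params, collect=True)
    labels = _stay_labels(session)

    rows = []
    for rec, v in zip(records, net_chosen):
        lab = labels[rec.trial]
        rows.append((rec.trial, "trial_start", np.nan, np.nan, float(v), lab))
        rows.append((rec.trial, "s2_onset", rec.delta_mf_s2,
                     rec.delta_mb_s2 - rec.delta_mf_s2, np.nan, lab))
        rows.append((rec.trial, "outcome", rec.delta_out, 0.0, np.nan, lab))
    df = pd.DataFrame(rows, columns=["trial", "event", "rpe_mf", "rpe_diff",
                                     "anticip_value", "label"])

    mask = df.event.isin(["s2_onset", "outcome"])
    orth = orthogonalize(df.loc[mask, "rpe_diff"].to_numpy(),
                         df.loc[mask, "rpe_mf"].to_numpy())
    df["rpe_diff_orth"] = np.nan
    df.loc[mask, "rpe_diff_orth"] = orth
    df = df[["trial", "event", "rpe_mf", "rpe_diff", "rpe_diff_orth",
             "anticip_value", "label"]]
    return RegressorSet(events=df)


def anticipatory_values(session: Session, params: AgentParams) -> pd.DataFrame:
    """Trial-start value of the chosen first-stage action under the net
    (mixture) valuation, with the five-way previous-trial labels.

    One row per completed trial: trial, anticip_value, label.  Stay trials
    partition into exactly four cells; 'switch' covers switches and the
    first trial.
    """
    _, _, records, net_chosen = replay(session, params, collect=True)
    labels = _stay_labels(session)
    return pd.DataFrame({
        "trial": [r.trial for r in records],
        "anticip_value": net_chosen,
        "label": [labels[r.trial] for r in records],
    })
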