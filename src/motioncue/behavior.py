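"""Behavioral and oculomotor summaries across sessions.

Accuracy and reaction time are first computed per session and condition
(motion role x clarity), then averaged unweighted across sessions with the
SEM over sessions — the across-session convention of the behavioral
figures.  Pursuit summaries average eye-position traces pointwise over the
correct trials of a condition on a common 200 Hz time base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import Session

__all__ = ["BehaviorSummary", "performance_summary", "average_pursuit"]

EYE_RATE_HZ = 200.0


@dataclass
class BehaviorSummary:
    """Across-session behavioral table plus the per-session values."""

    table: pd.DataFrame        # one row per (motion_role, clarity)
    per_session: pd.DataFrame  # one row per (session, motion_role, clarity)


def performance_summary(sessions: list[Session]) -> BehaviorSummary:
    """Accuracy and reaction time per condition, averaged across sessions.

    Accuracy is the fraction of correct completed trials; reaction times
    average over correct and incorrect completed trials alike.  Aborted
    trials are excluded from both.  Cells absent from every session are
    marked missing (NaN, n_sessions = 0).
    """
    per_rows = []
    for s in sessions:
        t = s.trials
        sub = t[(t["phase"] == "active") & ~t["aborted"]]
        if sub.empty:
            continue
        grouped = sub.groupby(["motion_role", "clarity"])
        for (role, clarity), g in grouped:
            per_rows.append({
                "session_id": s.session_id,
                "motion_role": role,
                "clarity": clarity,
                "accuracy": g["correct"].astype(float).mean(),
                "reaction_ms": g["reaction_ms"].mean(),
                "n_trials": len(g),
            })
    if not per_rows:
        raise ValueError("no sessions with completed active trials")
    per_session = pd.DataFrame(per_rows)

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    table = (
        per_session.groupby(["motion_role", "clarity"])
        .agg(
            accuracy=("accuracy", "mean"),
            accuracy_sem=("accuracy", _sem),
            reaction_ms=("reaction_ms", "mean"),
            reaction_ms_sem=("reaction_ms", _sem),
            n_sessions=("session_id", "nunique"),
        )
        .reset_index()
    )
    return BehaviorSummary(table=table, per_session=per_session)


def average_pursuit(
    sessions: list[Session],
    motion_kind: str,
    clarity: float | None = None,
    shape_category: str | None = None,
    phase: str = "active",
    correct_only: bool = True,
) -> pd.DataFrame:
    """Condition-averaged eye trace (t_ms, x_mean, y_mean, n_trials).

    Traces are resampled to a uniform 200 Hz base over the target period
    and averaged pointwise across the condition's trials (correct trials
    only by default, following the figure convention).
    """
    traces = []
    duration = None
    for s in sessions:
        t = s.trials
        sub = t[(t["phase"] == phase) & (t["motion_kind"] == motion_kind)
                & ~t["aborted"]]
        if clarity is not None:
            sub = sub[sub["clarity"] == clarity]
        if shape_category is not None:
            sub = sub[sub["shape_category"] == shape_category]
        if correct_only and phase == "active":
            sub = sub[sub["correct"] == True]  # noqa: E712 (NaN-safe)
        duration = s.config.target_ms if duration is None else duration
        for tid in sub["trial_id"]:
            if int(tid) in s.eye:
                traces.append(s.eye[int(tid)])
    if not traces:
        raise ValueError("no eye traces for the requested condition")
    base = np.arange(0.0, duration + 1e-9, 1000.0 / EYE_RATE_HZ)
    xs = np.empty((len(traces), len(base)))
    ys = np.empty((len(traces), len(base)))
    for i, tr in enumerate(traces):
        xs[i] = np.interp(base, tr[:, 0], tr[:, 1])
        ys[i] = np.interp(base, tr[:, 0], tr[:, 2])
    return pd.DataFrame({
        "t_ms": base,
        "x_mean": xs.mean(axis=0),
        "y_mean": ys.mean(axis=0),
        "n_trials": len(traces),
    })
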