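"""Plain-text session storage.

Layout of a session directory::

    session.yaml       # metadata: ids, task config, neuron models
    trials.csv         # one row per trial
    spikes/neuron_<id>.csv   # columns trial_id, t_ms
    eye/trial_<id>.csv       # columns t_ms, x_deg, y_deg

The round trip is lossless: floats are written with ``repr`` precision.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import NeuronModel, Session, TaskConfig

__all__ = ["write_session", "read_session"]

_TRIAL_COLUMNS = [
    "trial_id", "phase", "block", "shape_category", "pair_id", "clarity",
    "motion_kind", "motion_role", "correct_side", "response_side", "correct",
    "rewarded", "reaction_ms", "aborted",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to a directory of CSV/YAML files."""
    path = Path(path)
    (path / "spikes").mkdir(parents=True, exist_ok=True)
    (path / "eye").mkdir(parents=True, exist_ok=True)

    meta = {
        "session_id": session.session_id,
        "monkey_label": session.monkey_label,
        "config": dataclasses.asdict(session.config),
        "neurons": [dataclasses.asdict(n) for n in session.neurons],
    }
    (path / "session.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    session.trials.to_csv(path / "trials.csv", index=False,
                          columns=_TRIAL_COLUMNS)

    for nid, by_trial in session.spikes.items():
        lines = ["trial_id,t_ms"]
        for tid in sorted(by_trial):
            lines.extend(f"{tid},{_fmt(t)}" for t in by_trial[tid])
        (path / "spikes" / f"neuron_{nid}.csv").write_text(
            "\n".join(lines) + "\n"
        )

    for tid, trace in session.eye.items():
        lines = ["t_ms,x_deg,y_deg"]
        lines.extend(
            f"{_fmt(t)},{_fmt(x)},{_fmt(y)}" for t, x, y in trace
        )
        (path / "eye" / f"trial_{tid}.csv").write_text("\n".join(lines) + "\n")
    return path


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    meta = yaml.safe_load((path / "session.yaml").read_text())
    config_d = meta["config"]
    config_d["clarity_levels"] = tuple(config_d["clarity_levels"])
    config = TaskConfig(**config_d)
    neurons = []
    for nd in meta["neurons"]:
        nd["motion_kernels"] = {
            k: tuple(v) for k, v in nd["motion_kernels"].items()
        }
        neurons.append(NeuronModel(**nd))

    trials = pd.read_csv(
        path / "trials.csv",
        dtype={"correct": "object", "rewarded": "object"},
        float_precision="round_trip",
    )
    for col in ("correct", "rewarded"):
        trials[col] = trials[col].map(
            lambda v: np.nan if pd.isna(v) else v in (True, "True")
        )

    spikes: dict[int, dict[int, np.ndarray]] = {}
    trial_ids = trials["trial_id"].to_numpy()
    for f in sorted((path / "spikes").glob("neuron_*.csv")):
        nid = int(f.stem.split("_")[1])
        df = pd.read_csv(f, float_precision="round_trip")
        by_trial = {int(tid): np.empty(0) for tid in trial_ids}
        for tid, grp in df.groupby("trial_id"):
            by_trial[int(tid)] = grp["t_ms"].to_numpy()
        spikes[nid] = by_trial

    eye: dict[int, np.ndarray] = {}
    for f in sorted((path / "eye").glob("trial_*.csv")):
        tid = int(f.stem.split("_")[1])
        eye[tid] = pd.read_csv(f, float_precision="round_trip").to_numpy()

    return Session(
        session_id=meta["session_id"], monkey_label=meta["monkey_label"],
        config=config, neurons=neurons, trials=trials, spikes=spikes, eye=eye,
    )
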