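"""Sliding analysis windows and windowed firing-rate extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import Session

__all__ = ["WindowGrid", "window_rates"]


@dataclass(frozen=True)
class WindowGrid:
    """Overlapping sliding windows covering the target and delay period.

    Defaults follow the 150 ms window / 50 ms step convention over the
    0–2,000 ms span (1,500 ms target + 500 ms delay).
    """

    window_ms: float = 150.0
    step_ms: float = 50.0
    span: tuple[float, float] = (0.0, 2000.0)

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window_ms and step_ms must be positive")
        if self.span[1] - self.span[0] < self.window_ms:
            raise ValueError("span shorter than one window")

    @property
    def starts(self) -> np.ndarray:
        last = self.span[1] - self.window_ms
        n = int(np.floor((last - self.span[0]) / self.step_ms + 1e-9)) + 1
        return self.span[0] + self.step_ms * np.arange(n)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.window_ms / 2.0

    def __len__(self) -> int:
        return len(self.starts)


def window_rates(
    session: Session,
    neuron_id: int,
    trial_ids: np.ndarray,
    start_ms: float,
    stop_ms: float,
) -> np.ndarray:
    """Firing rate (Hz) of one neuron in [start, stop) for each trial."""
    by_trial = session.spikes[neuron_id]
    width_s = (stop_ms - start_ms) / 1000.0
    counts = np.array([
        np.count_nonzero(
            (by_trial[int(t)] >= start_ms) & (by_trial[int(t)] < stop_ms)
        )
        for t in trial_ids
    ])
    return counts / width_s
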