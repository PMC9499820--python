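"""Windowed shape and motion sensitivity of active-task responses.

Motion sensitivity is assessed per shape class with a one-way ANOVA of
window firing rates across the three motion conditions available for that
class (predictive, shared, static); the full motion x shape crossing does
not exist by design, so no multifactor model is attempted.  Shape
sensitivity compares blob against spikey trials the same way.  Tests run
either in the early visual window (50–200 ms) or across a 150 ms / 50 ms
sliding grid, with Bonferroni correction over the tests within one
neuron x factor x clarity family.  A neuron's sensitivity latency is the
time of its earliest significant window.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .synthetic_data import Session
from .windows import WindowGrid, window_rates

__all__ = [
    "EARLY_VISUAL_WINDOW_MS",
    "motion_anova",
    "shape_anova",
    "early_visual_motion_fraction",
    "sliding_sensitivity",
    "sliding_pvalues",
    "sensitivity_latency",
]

EARLY_VISUAL_WINDOW_MS = (50.0, 200.0)
MOTION_ROLES = ("predictive", "shared", "static")


def _active_trials(session: Session):
    t = session.trials
    return t[(t["phase"] == "active") & ~t["aborted"]]


def _anova(groups: list[np.ndarray]) -> float:
    """One-way ANOVA p-value; NaN marks a not-testable comparison."""
    if any(len(g) < 2 for g in groups):
        return float("nan")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # zero variance everywhere
        return float("nan")
    return float(stats.f_oneway(*groups).pvalue)


def motion_anova(
    session: Session,
    neuron_id: int,
    shape_category: str,
    clarity: float,
    window_ms: tuple[float, float] = EARLY_VISUAL_WINDOW_MS,
) -> float:
    """p-value of rate differences across the 3 motion conditions.

    Groups are the predictive, shared and static trials of one shape class
    at one clarity.  Returns NaN (not testable) if a condition group is
    missing, has fewer than 2 trials, or the rates are degenerate.
    """
    sub = _active_trials(session)
    sub = sub[(sub["shape_category"] == shape_category)
              & (sub["clarity"] == clarity)]
    groups = []
    for role in MOTION_ROLES:
        tids = sub[sub["motion_role"] == role]["trial_id"].to_numpy()
        groups.append(
            window_rates(session, neuron_id, tids, *window_ms)
        )
    return _anova(groups)


def shape_anova(
    session: Session,
    neuron_id: int,
    clarity: float,
    window_ms: tuple[float, float] = EARLY_VISUAL_WINDOW_MS,
) -> float:
    """p-value of rate differences between the two shape classes."""
    sub = _active_trials(session)
    sub = sub[sub["clarity"] == clarity]
    groups = []
    for shape in ("blob", "spikey"):
        tids = sub[sub["shape_category"] == shape]["trial_id"].to_numpy()
        groups.append(window_rates(session, neuron_id, tids, *window_ms))
    return _anova(groups)


def _screened_units(
    sessions: list[Session], screened: bool
) -> list[tuple[Session, int]]:
    from .tuning import screen_task_relevant

    units = []
    for s in sessions:
        for nid in s.neuron_ids:
            if not screened or screen_task_relevant(s, nid)[0]:
                units.append((s, nid))
    return units


def early_visual_motion_fraction(
    sessions: list[Session],
    clarity: float,
    alpha: float = 0.05,
    n_tests: int | None = None,
    screened: bool = False,
) -> float:
    """Fraction of units motion-sensitive in the early visual period.

    A unit counts as motion sensitive if either shape class's motion ANOVA
    in the 50–200 ms window is significant at the Bonferroni-corrected
    level ``alpha / n_tests``; by default the family is the tests this
    analysis runs per unit (clarity levels x 2 shape classes).
    """
    units = _screened_units(sessions, screened)
    if not units:
        raise ValueError("no units to assess")
    hits = 0
    for session, nid in units:
        if n_tests is None:
            m = len(session.config.clarity_levels) * 2
        else:
            m = n_tests
        ps = [
            motion_anova(session, nid, shape, clarity)
            for shape in ("blob", "spikey")
        ]
        if any(np.isfinite(p) and p < alpha / m for p in ps):
            hits += 1
    return hits / len(units)


def sliding_pvalues(
    session: Session,
    neuron_id: int,
    factor: str,
    clarity: float,
    grid: WindowGrid,
    shape_category: str | None = None,
) -> np.ndarray:
    """Per-window ANOVA p-values for one unit and factor.

    ``factor`` is "motion" (requires ``shape_category``) or "shape".
    """
    ps = np.empty(len(grid))
    for i, start in enumerate(grid.starts):
        w = (float(start), float(start) + grid.window_ms)
        if factor == "motion":
            if shape_category is None:
                raise ValueError("motion factor needs a shape_category")
            ps[i] = motion_anova(session, neuron_id, shape_category,
                                 clarity, w)
        elif factor == "shape":
            ps[i] = shape_anova(session, neuron_id, clarity, w)
        else:
            raise ValueError(f"unknown factor {factor!r}")
    return ps


def _unit_significant_windows(
    session: Session,
    neuron_id: int,
    factor: str,
    clarity: float,
    grid: WindowGrid,
    alpha: float,
) -> np.ndarray:
    """Boolean per-window significance, Bonferroni over the grid windows.

    For the motion factor a window counts if either shape class is
    significant (each class corrected within its own window family).
    """
    thresh = alpha / len(grid)
    if factor == "motion":
        sig = np.zeros(len(grid), dtype=bool)
        for shape in ("blob", "spikey"):
            ps = sliding_pvalues(session, neuron_id, "motion", clarity,
                                 grid, shape)
            sig |= np.nan_to_num(ps, nan=1.0) < thresh
        return sig
    ps = sliding_pvalues(session, neuron_id, "shape", clarity, grid)
    return np.nan_to_num(ps, nan=1.0) < thresh


def sliding_sensitivity(
    sessions: list[Session],
    factor: str,
    clarity: float,
    grid: WindowGrid | None = None,
    alpha: float = 0.05,
    screened: bool = False,
) -> np.ndarray:
    """Population time course: fraction of units significant per window."""
    grid = WindowGrid() if grid is None else grid
    units = _screened_units(sessions, screened)
    if not units:
        raise ValueError("no units to assess")
    frac = np.zeros(len(grid))
    for session, nid in units:
        frac += _unit_significant_windows(session, nid, factor, clarity,
                                          grid, alpha)
    return frac / len(units)


def sensitivity_latency(
    pvalues: np.ndarray,
    grid: WindowGrid,
    alpha: float = 0.05,
    convention: str = "center",
) -> float | None:
    """Latency to first sensitivity from per-window p-values.

    The earliest window with p below the Bonferroni-corrected threshold
    (alpha / n_windows) defines the latency; ``convention`` selects whether
    its center (default) or start is reported.  The center convention
    compensates the early bias of overlapping windows: with a 150 ms window
    and 50 ms step, the first window overlapping an effect onset can start
    up to 100 ms before it.  Returns None if no window is significant.
    """
    ps = np.nan_to_num(np.asarray(pvalues, dtype=float), nan=1.0)
    sig = np.nonzero(ps < alpha / len(grid))[0]
    if len(sig) == 0:
        return None
    i = int(sig[0])
    if convention == "center":
        return float(grid.centers[i])
    if convention == "start":
        return float(grid.starts[i])
    raise ValueError(f"unknown latency convention {convention!r}")
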