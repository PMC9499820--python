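"""Clarity-modulation analysis of passive-viewing responses.

For each neuron, responses to its session's shape pair across clarity levels
are summarized as a tuning curve (mean rate in the 0–300 ms response window
per shape x clarity cell).  From the curve's deviations relative to the
100%-clarity response we derive:

* the **external clarity factor (ECF)** — the clarity level with the largest
  absolute modulation relative to the unblurred response,
* the **modulation index (MI)** — the signed trapezoidal integral of the
  deviation curve over clarity,
* the **principal values (PV_B, PV_S)** — the projection of each neuron's
  max-|.|-normalized deviation curve onto the population's first principal
  component, computed separately per shape (and per animal group), with the
  component's sign oriented so that PV correlates positively with MI.  A
  positive PV means the neuron's firing is enhanced by reduced clarity; a
  negative PV means it is suppressed.

Neurons are then sorted into four quadrant categories by the signs of
(PV_B, PV_S): A (+,+) enhanced, B (-,-) suppressed, C (+,-) and D (-,+)
mixed.

The module also implements the task-relevance screen used to admit neurons
into the population analyses: Welch's t-test of five post-onset task windows
against the 200 ms pre-stimulus baseline at alpha = 0.008.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import Session
from .windows import window_rates

__all__ = [
    "TuningCurve",
    "ClarityMetrics",
    "ECFResult",
    "SCREEN_WINDOWS_MS",
    "compute_tuning_curve",
    "relative_response",
    "external_clarity_factor",
    "modulation_index",
    "compute_pvs",
    "classify_quadrant",
    "population_clarity_metrics",
    "screen_task_relevant",
]

#: Task windows (ms from target onset) screened against baseline: typical IT
#: visual, late visual, very late visual, early delay, late delay.
SCREEN_WINDOWS_MS = (
    (50.0, 200.0),
    (200.0, 350.0),
    (800.0, 950.0),
    (1550.0, 1700.0),
    (1700.0, 1850.0),
)

SHAPES = ("blob", "spikey")


@dataclass
class TuningCurve:
    """Per-shape mean firing rate as a function of clarity level."""

    neuron_id: int
    clarity_levels: np.ndarray
    rates: dict[str, np.ndarray]   # shape -> mean Hz per level (NaN = missing)
    sem: dict[str, np.ndarray]
    n_trials: dict[str, np.ndarray]


@dataclass
class ECFResult:
    clarity: float
    no_modulation: bool


@dataclass
class ClarityMetrics:
    neuron_id: int
    relative_response: dict[str, np.ndarray]
    ecf_blob: ECFResult
    ecf_spikey: ECFResult
    mi_blob: float
    mi_spikey: float
    pv_blob: float
    pv_spikey: float
    category: str


def compute_tuning_curve(
    session: Session,
    neuron_id: int,
    window_ms: tuple[float, float] = (0.0, 300.0),
    bin_ms: float = 5.0,
) -> TuningCurve:
    """Mean rate per (shape, clarity) cell from the passive clarity series.

    Spike trains are binned at ``bin_ms`` and summed over the response
    window; the mean rate equals total count / window length.  Cells with no
    trials are marked missing (NaN) and excluded downstream.
    """
    trials = session.trials
    sub = trials[(trials["phase"] == "passive_clarity")]
    if sub.empty:
        raise ValueError("session has no passive clarity trials")
    levels = np.asarray(session.config.clarity_levels, dtype=float)
    t0, t1 = window_ms
    edges = np.arange(t0, t1 + 0.5 * bin_ms, bin_ms)
    width_s = (edges[-1] - edges[0]) / 1000.0
    by_trial = session.spikes[neuron_id]

    rates, sems, ns = {}, {}, {}
    for shape in SHAPES:
        r = np.full(len(levels), np.nan)
        s = np.full(len(levels), np.nan)
        n = np.zeros(len(levels), dtype=int)
        for i, c in enumerate(levels):
            cell = sub[(sub["shape_category"] == shape)
                       & (sub["clarity"] == c)]
            if cell.empty:
                continue
            counts = np.array([
                np.histogram(by_trial[int(t)], bins=edges)[0].sum()
                for t in cell["trial_id"]
            ])
            trial_rates = counts / width_s
            r[i] = trial_rates.mean()
            s[i] = (trial_rates.std(ddof=1) / np.sqrt(len(trial_rates))
                    if len(trial_rates) > 1 else 0.0)
            n[i] = len(trial_rates)
        rates[shape], sems[shape], ns[shape] = r, s, n
    return TuningCurve(neuron_id, levels, rates, sems, ns)


def relative_response(curve: TuningCurve) -> dict[str, np.ndarray]:
    """Deviation of each cell's rate from the 100%-clarity response."""
    full = np.where(curve.clarity_levels == 1.0)[0]
    out = {}
    for shape in SHAPES:
        rates = curve.rates[shape]
        if len(full) == 0 or np.isnan(rates[full[0]]):
            raise ValueError(
                f"no 100%-clarity response for shape {shape!r}"
            )
        out[shape] = rates - rates[full[0]]
    return out


def external_clarity_factor(
    deviations: np.ndarray, clarity_levels: np.ndarray
) -> ECFResult:
    """Clarity level with the largest absolute deviation.

    Ties are broken toward the lowest clarity (most-degraded
    interpretation).  An all-zero deviation curve returns clarity 1.0 with
    the no-modulation flag set.
    """
    dev = np.asarray(deviations, dtype=float)
    levels = np.asarray(clarity_levels, dtype=float)
    ok = ~np.isnan(dev)
    if ok.sum() < 2:
        raise ValueError("need at least 2 clarity levels")
    dev, levels = dev[ok], levels[ok]
    mags = np.abs(dev)
    if np.all(mags == 0.0):
        return ECFResult(clarity=1.0, no_modulation=True)
    best = mags.max()
    # lowest clarity among tied maxima; levels are sorted ascending
    idx = int(np.nonzero(mags == best)[0][0])
    return ECFResult(clarity=float(levels[idx]), no_modulation=False)


def modulation_index(
    deviations: np.ndarray, clarity_levels: np.ndarray
) -> float:
    """Signed trapezoidal integral of the deviation curve over clarity."""
    dev = np.asarray(deviations, dtype=float)
    levels = np.asarray(clarity_levels, dtype=float)
    ok = ~np.isnan(dev)
    if ok.sum() < 2:
        raise ValueError("need at least 2 clarity levels")
    return float(np.trapezoid(dev[ok], levels[ok]))


def compute_pvs(
    deviation_matrix: np.ndarray, clarity_levels: np.ndarray
) -> np.ndarray:
    """Principal values for one (shape, group) set of deviation curves.

    Rows are neurons, columns clarity levels.  Each row is normalized by its
    maximum absolute deviation (zero rows are excluded from the component
    fit and assigned PV = 0), the first principal axis of the uncentred,
    normalized set is computed by SVD, and each neuron's PV is its
    projection onto that axis.  The axis sign is oriented so that PV
    correlates positively with the modulation index, making positive PV mean
    blur-enhancement.
    """
    X = np.asarray(deviation_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    if np.isnan(X).any():
        raise ValueError("deviation matrix contains missing cells")
    norms = np.abs(X).max(axis=1)
    nonzero = norms > 0
    if nonzero.sum() < 2:
        raise ValueError("fewer than 2 neurons with nonzero modulation")
    Xn = X[nonzero] / norms[nonzero, None]
    _, _, vt = np.linalg.svd(Xn, full_matrices=False)
    pc1 = vt[0]
    pv = np.zeros(X.shape[0])
    pv[nonzero] = Xn @ pc1

    mi = np.array([
        modulation_index(row, clarity_levels) for row in X
    ])
    if np.std(pv) > 0 and np.std(mi) > 0:
        r = np.corrcoef(pv, mi)[0, 1]
    else:
        r = 0.0
    if r < 0 or (r == 0 and pc1.sum() < 0):
        pv = -pv
    return pv


def classify_quadrant(pv_blob: float, pv_spikey: float) -> str:
    """Quadrant category from the two principal values.

    A: both positive (enhanced); B: both non-positive (suppressed);
    C: blob positive only; D: spikey positive only.  Exact zeros count as
    negative (conservative: avoids over-counting enhancement).
    """
    if not (np.isfinite(pv_blob) and np.isfinite(pv_spikey)):
        raise ValueError("principal values must be finite")
    b, s = pv_blob > 0, pv_spikey > 0
    if b and s:
        return "A"
    if not b and not s:
        return "B"
    return "C" if b else "D"


def population_clarity_metrics(
    curves: list[TuningCurve],
) -> pd.DataFrame:
    """Full clarity-metrics table for one group of neurons.

    The PV computation pools the group's deviation curves per shape (one
    principal-component fit per shape), mirroring the per-animal,
    per-stimulus sets of the original analysis.  Neurons recorded in
    different animals should be passed as separate groups.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 neurons for population metrics")
    levels = curves[0].clarity_levels
    devs = {shape: [] for shape in SHAPES}
    for curve in curves:
        rel = relative_response(curve)
        for shape in SHAPES:
            devs[shape].append(rel[shape])
    pvs = {
        shape: compute_pvs(np.vstack(devs[shape]), levels)
        for shape in SHAPES
    }
    rows = []
    for i, curve in enumerate(curves):
        ecf_b = external_clarity_factor(devs["blob"][i], levels)
        ecf_s = external_clarity_factor(devs["spikey"][i], levels)
        pv_b, pv_s = float(pvs["blob"][i]), float(pvs["spikey"][i])
        rows.append({
            "neuron_id": curve.neuron_id,
            "ecf_blob": ecf_b.clarity,
            "ecf_blob_no_modulation": ecf_b.no_modulation,
            "ecf_spikey": ecf_s.clarity,
            "ecf_spikey_no_modulation": ecf_s.no_modulation,
            "mi_blob": modulation_index(devs["blob"][i], levels),
            "mi_spikey": modulation_index(devs["spikey"][i], levels),
            "pv_blob": pv_b,
            "pv_spikey": pv_s,
            "category": classify_quadrant(pv_b, pv_s),
        })
    return pd.DataFrame(rows)


def screen_task_relevant(
    session: Session,
    neuron_id: int,
    alpha: float = 0.008,
    windows_ms: tuple[tuple[float, float], ...] = SCREEN_WINDOWS_MS,
) -> tuple[bool, dict[tuple[float, float], float]]:
    """Screen one neuron for any task-evoked modulation above baseline.

    Welch's t-test compares active-trial firing rates in each task window
    against the 200 ms pre-stimulus baseline; the neuron is task-relevant if
    any window's p-value falls below ``alpha`` (0.008, the multiple-
    comparison-corrected level for five windows).  Degenerate (zero-
    variance) inputs yield p = 1.
    """
    trials = session.trials
    sub = trials[(trials["phase"] == "active") & ~trials["aborted"]]
    if len(sub) < 2:
        raise ValueError("need at least 2 completed active trials")
    tids = sub["trial_id"].to_numpy()
    pre = session.config.pre_window_ms
    baseline = window_rates(session, neuron_id, tids, -pre, 0.0)

    pvals: dict[tuple[float, float], float] = {}
    for w in windows_ms:
        resp = window_rates(session, neuron_id, tids, w[0], w[1])
        if np.std(resp) == 0.0 and np.std(baseline) == 0.0:
            pvals[w] = 1.0
            continue
        t = stats.ttest_ind(resp, baseline, equal_var=False)
        pvals[w] = float(t.pvalue) if np.isfinite(t.pvalue) else 1.0
    relevant = any(p < alpha for p in pvals.values())
    return relevant, pvals
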