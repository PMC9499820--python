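"""Synthetic experimental sessions with planted ground truth.

A session emulates one day of a macaque match-to-sample experiment on moving,
blurred shapes: four task phases (a passive survey of the full shape set, a
passive clarity series on a single shape pair, the active match-to-sample
phase, and passive viewing of the moving zero-clarity blur), parametric IT
neurons whose firing rates carry planted shape, clarity and motion-trajectory
tuning, inhomogeneous-Poisson spike trains at 1 ms resolution, a
psychophysical observer producing choices and reaction times, and
pursuit-like eye traces.

Every planted parameter is stored on the neuron model, so downstream
analyses (tuning categories, sensitivity latencies, decoders) can be checked
against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .stimuli import MOVING_KINDS, Trajectory, make_trajectory

__all__ = [
    "TaskConfig",
    "NeuronModel",
    "ObserverModel",
    "Session",
    "DEFAULT_CATEGORY_MIX",
    "CLARITY_LABELS",
    "CATEGORY_BY_LABEL",
    "simulate_session",
    "simulate_behavior",
    "simulate_eye_trace",
    "plant_population",
]

# clarity-tuning families and their tuning-category ground truth:
# A = enhanced by reduced clarity for both shapes, B = suppressed for both,
# C = enhanced for blob / suppressed for spikey, D = the reverse.
CLARITY_LABELS = ("enhanced", "suppressed", "mixed_BposSneg", "mixed_BnegSpos")
CATEGORY_BY_LABEL = {
    "enhanced": "A",
    "suppressed": "B",
    "mixed_BposSneg": "C",
    "mixed_BnegSpos": "D",
}
_LABEL_BY_CATEGORY = {v: k for k, v in CATEGORY_BY_LABEL.items()}
_CLARITY_SIGNS = {
    "enhanced": (1.0, 1.0),
    "suppressed": (-1.0, -1.0),
    "mixed_BposSneg": (1.0, -1.0),
    "mixed_BnegSpos": (-1.0, 1.0),
}

#: Default tuning-category mix (fractions of the four quadrant categories,
#: matching the reported ≈46/33/9/15% split; expressed as exact 54ths so the
#: fractions sum to one).
DEFAULT_CATEGORY_MIX = {"A": 23 / 54, "B": 18 / 54, "C": 5 / 54, "D": 8 / 54}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TaskConfig:
    """Timing, condition grid and block design of one session."""

    fixation_acquire_ms: float = 200.0
    fixation_window_deg: float = 1.0
    target_window_deg: float = 4.0
    target_ms: float = 1500.0
    delay_ms: float = 500.0
    choice_timeout_ms: float = 2000.0
    passive_stim_ms: float = 200.0
    passive_gap_ms: float = 100.0
    clarity_levels: tuple[float, ...] = (0.0, 0.3, 0.5, 0.8, 1.0)
    motion_map: dict[str, str] = field(
        default_factory=lambda: {
            "blob": "circular",
            "spikey": "triangular",
            "shared": "bimodal",
        }
    )
    blocks: int = 5
    trials_per_block: int = 180
    zero_clarity_reward_prob: float = 0.5
    pre_window_ms: float = 200.0
    abort_prob: float = 0.03
    # per-condition repetition counts of the passive phases
    passive_shape_reps: int = 0     # reps per shape in the 100-shape survey
    passive_clarity_reps: int = 50  # reps per (shape, clarity) cell
    passive_motion_reps: int = 40   # reps per motion kind at clarity 0
    n_shape_pairs: int = 50
    trajectory_amplitude_deg: float = 1.25

    def __post_init__(self) -> None:
        lv = tuple(float(c) for c in self.clarity_levels)
        if lv[0] != 0.0 or lv[-1] != 1.0 or any(
            b <= a for a, b in zip(lv, lv[1:])
        ):
            raise ValueError(
                "clarity_levels must be strictly increasing and span 0 to 1"
            )
        self.clarity_levels = lv
        mm = self.motion_map
        kinds = [mm.get("blob"), mm.get("spikey"), mm.get("shared")]
        if len(set(kinds)) != 3 or any(k not in MOVING_KINDS for k in kinds):
            raise ValueError(
                "motion_map must assign distinct moving kinds to blob, spikey "
                "and shared"
            )

    def motion_kind(self, shape: str, role: str) -> str:
        if role == "static":
            return "static"
        if role == "shared":
            return self.motion_map["shared"]
        if role == "predictive":
            return self.motion_map[shape]
        raise ValueError(f"unknown motion role {role!r}")


# ---------------------------------------------------------------------------
# neurons
# ---------------------------------------------------------------------------

@dataclass
class NeuronModel:
    """Parametric IT neuron with planted shape/clarity/motion tuning.

    The instantaneous rate is a product of the baseline and multiplicative
    gains: a visual-response gain after ``visual_latency_ms``, a per-shape
    preference, a clarity-tuning gain (monotone in clarity, or band-pass if
    ``clarity_peak`` is set), and a per-trajectory motion gain active in a
    box window of the target period.  All gains are rectified at zero.
    """

    neuron_id: int
    baseline_hz: float = 20.0
    shape_pref: dict[str, float] = field(
        default_factory=lambda: {"blob": 1.0, "spikey": 1.0}
    )
    clarity_label: str = "enhanced"
    clarity_strength: float = 0.6
    clarity_peak: float | None = None  # None -> monotone profile
    clarity_width: float = 0.25
    # kind -> (latency_ms, duration_ms, gain); gain 0 = motion-insensitive
    motion_kernels: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    visual_latency_ms: float = 80.0
    visual_gain: float = 2.0

    @property
    def category(self) -> str:
        """Planted quadrant-category ground truth (A/B/C/D)."""
        return CATEGORY_BY_LABEL[self.clarity_label]

    def _clarity_profile(self, clarity: float) -> float:
        if self.clarity_peak is None:
            return 1.0 - clarity
        w2 = 2.0 * self.clarity_width**2
        bump = math.exp(-((clarity - self.clarity_peak) ** 2) / w2)
        anchor = math.exp(-((1.0 - self.clarity_peak) ** 2) / w2)
        return bump - anchor  # zero modulation at full clarity

    def clarity_gain(self, shape: str, clarity: float) -> float:
        if self.clarity_label not in _CLARITY_SIGNS:
            raise ValueError(f"unknown clarity label {self.clarity_label!r}")
        sign_b, sign_s = _CLARITY_SIGNS[self.clarity_label]
        sign = sign_b if shape == "blob" else sign_s
        return max(0.0, 1.0 + sign * self.clarity_strength
                   * self._clarity_profile(clarity))

    def stimulus_gain(self, shape: str, clarity: float) -> float:
        """Shape x clarity gain; clarity 0 erases shape identity (the
        underlying stimulus is the circle placeholder, identical for both
        nominal categories)."""
        if clarity == 0.0:
            g = 0.5 * (
                self.shape_pref["blob"] * self.clarity_gain("blob", 0.0)
                + self.shape_pref["spikey"] * self.clarity_gain("spikey", 0.0)
            )
            return max(0.0, g)
        return max(0.0, self.shape_pref[shape] * self.clarity_gain(shape, clarity))

    def motion_gain_timecourse(self, kind: str, t_ms: np.ndarray) -> np.ndarray:
        lat, dur, gain = self.motion_kernels.get(kind, (0.0, 0.0, 0.0))
        out = np.ones_like(t_ms, dtype=float)
        if gain != 0.0:
            out[(t_ms >= lat) & (t_ms < lat + dur)] += gain
        return out


# ---------------------------------------------------------------------------
# observer
# ---------------------------------------------------------------------------

def _linear_sensitivity(clarity: float) -> float:
    return float(np.clip(clarity, 0.0, 1.0))


@dataclass
class ObserverModel:
    """Psychophysical observer for the 2-alternative match-to-sample choice.

    Shape evidence scales with clarity through ``shape_sensitivity``; motion
    evidence is available only on predictive-motion trials and has strength
    ``motion_association``.  The two cues are fused as independent
    probabilistic evidence, then mixed with a lapse rate.
    """

    shape_sensitivity: Callable[[float], float] = _linear_sensitivity
    motion_association: float = 0.9
    lapse: float = 0.12
    rt_shift_ms: float = 250.0
    rt_median_ms: float = 320.0
    rt_sigma_log: float = 0.25
    rt_static_extra_ms: float = 60.0
    pursuit_gain_base: float = 0.85
    pursuit_gain_floor: float = 0.6
    pursuit_noise_sd_deg: float = 0.12
    pursuit_drift_sd_deg: float = 0.08

    def p_correct(self, clarity: float, motion_role: str) -> float:
        ps = 0.5 + 0.5 * self.shape_sensitivity(clarity)
        pm = (
            0.5 + 0.5 * self.motion_association
            if motion_role == "predictive"
            else 0.5
        )
        num = ps * pm
        denom = num + (1.0 - ps) * (1.0 - pm)
        p = num / denom if denom > 0 else 0.5
        return (1.0 - self.lapse) * p + 0.5 * self.lapse

    def pursuit_gain(self, clarity: float) -> float:
        base, floor = self.pursuit_gain_base, self.pursuit_gain_floor
        return base * (floor + (1.0 - floor) * clarity)


def simulate_behavior(
    config: TaskConfig,
    observer: ObserverModel,
    clarity: float,
    motion_role: str,
    correct_side: str,
    rng: np.random.Generator,
) -> tuple[str, bool, float]:
    """One trial's choice: returns (response_side, rewarded, reaction_ms)."""
    p = observer.p_correct(clarity, motion_role)
    correct = rng.random() < p
    other = "left" if correct_side == "right" else "right"
    response = correct_side if correct else other
    if clarity == 0.0 and motion_role in ("shared", "static"):
        # no correct answer exists: random reward rule
        rewarded = bool(rng.random() < config.zero_clarity_reward_prob)
    else:
        rewarded = bool(correct)
    rt = observer.rt_shift_ms + rng.lognormal(
        math.log(observer.rt_median_ms), observer.rt_sigma_log
    )
    if motion_role == "static":
        rt += observer.rt_static_extra_ms
    rt = min(rt, config.choice_timeout_ms - 1.0)
    return response, rewarded, float(rt)


# ---------------------------------------------------------------------------
# eye traces
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, dt_s: float, tau_s: float) -> np.ndarray:
    alpha = math.exp(-dt_s / tau_s)
    out = np.empty_like(x)
    out[0] = x[0]
    for i in range(1, len(x)):
        out[i] = alpha * out[i - 1] + (1.0 - alpha) * x[i]
    return out


def simulate_eye_trace(
    trajectory: Trajectory,
    pursuit_gain: float,
    noise_sd_deg: float = 0.12,
    drift_sd_deg: float = 0.08,
    rng: np.random.Generator | None = None,
    sample_rate_hz: float = 200.0,
    smoothing_tau_ms: float = 80.0,
    window_deg: float = 4.0,
    max_tries: int = 10,
) -> np.ndarray:
    """Pursuit-like eye trace over the target period at 200 Hz.

    Moving targets: gain-scaled, low-passed copy of the trajectory plus a
    slow linear drift and white noise.  Static targets: drift and noise only
    (fixation).  Traces falling outside the allowed eye-position window are
    resampled, then clipped as a last resort.
    """
    if not 0.0 <= pursuit_gain <= 1.0:
        raise ValueError("pursuit_gain must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    dt_s = 1.0 / sample_rate_hz
    t_ms = np.arange(0.0, trajectory.duration_ms + 1e-9, 1000.0 * dt_s)
    t_s = t_ms / 1000.0
    if trajectory.kind == "static":
        target = np.zeros((len(t_ms), 2))
    else:
        target = np.c_[
            np.interp(t_ms, trajectory.t_ms, trajectory.positions[:, 0]),
            np.interp(t_ms, trajectory.t_ms, trajectory.positions[:, 1]),
        ]
        tau_s = smoothing_tau_ms / 1000.0
        target = np.c_[
            _lowpass(target[:, 0], dt_s, tau_s),
            _lowpass(target[:, 1], dt_s, tau_s),
        ]
        target = pursuit_gain * target
    for _ in range(max_tries):
        drift_rate = rng.normal(0.0, drift_sd_deg, size=2)  # deg/s
        eye = (
            target
            + t_s[:, None] * drift_rate[None, :]
            + rng.normal(0.0, noise_sd_deg, size=target.shape)
        )
        if np.abs(eye).max() <= window_deg:
            break
    eye = np.clip(eye, -window_deg, window_deg)
    return np.c_[t_ms, eye]


# ---------------------------------------------------------------------------
# population planting
# ---------------------------------------------------------------------------

def _largest_remainder_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    quotas = fractions * n
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def plant_population(
    proportions: dict[str, float],
    n_neurons: int,
    seed: int,
    *,
    baseline_range: tuple[float, float] = (12.0, 28.0),
    strength_range: tuple[float, float] = (0.45, 0.8),
    clarity_peak: float | None = None,
    clarity_width: float = 0.25,
    shape_pref_range: tuple[float, float] = (0.85, 1.2),
    motion_gain: float = 0.0,
    motion_latency_range_ms: tuple[float, float] = (80.0, 200.0),
    motion_duration_ms: float = 1300.0,
    visual_latency_range_ms: tuple[float, float] = (60.0, 110.0),
    visual_gain: float = 2.0,
) -> list[NeuronModel]:
    """Draw a neuron population with planted clarity-tuning categories.

    ``proportions`` maps category (A/B/C/D or tuning-family label) to a
    fraction; counts follow the largest-remainder rounding rule so they sum
    exactly to ``n_neurons``.  ``motion_gain`` > 0 additionally plants
    per-trajectory motion gains drawn uniformly from [0, motion_gain].
    """
    labels = []
    fracs = []
    for key, frac in proportions.items():
        labels.append(_LABEL_BY_CATEGORY.get(key, key))
        fracs.append(float(frac))
    unknown = [l for l in labels if l not in CLARITY_LABELS]
    if unknown:
        raise ValueError(f"unknown tuning categories: {unknown}")
    fracs = np.asarray(fracs)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"category fractions must sum to 1, got {fracs.sum()}")
    counts = _largest_remainder_counts(fracs, n_neurons)

    rng = np.random.default_rng(seed)
    neurons: list[NeuronModel] = []
    nid = 0
    for label, count in zip(labels, counts):
        for _ in range(count):
            kernels = {}
            if motion_gain > 0:
                for kind in MOVING_KINDS:
                    kernels[kind] = (
                        float(rng.uniform(*motion_latency_range_ms)),
                        float(motion_duration_ms),
                        float(rng.uniform(0.0, motion_gain)),
                    )
            neurons.append(
                NeuronModel(
                    neuron_id=nid,
                    baseline_hz=float(rng.uniform(*baseline_range)),
                    shape_pref={
                        "blob": float(rng.uniform(*shape_pref_range)),
                        "spikey": float(rng.uniform(*shape_pref_range)),
                    },
                    clarity_label=label,
                    clarity_strength=float(rng.uniform(*strength_range)),
                    clarity_peak=clarity_peak,
                    clarity_width=clarity_width,
                    motion_kernels=kernels,
                    visual_latency_ms=float(rng.uniform(*visual_latency_range_ms)),
                    visual_gain=visual_gain,
                )
            )
            nid += 1
    return neurons


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """One synthetic recording session: neurons, trials, spikes, eye traces."""

    session_id: int
    monkey_label: str
    config: TaskConfig
    neurons: list[NeuronModel]
    trials: pd.DataFrame
    # spikes[neuron_id][trial_id] -> sorted event times, ms from stimulus onset
    spikes: dict[int, dict[int, np.ndarray]]
    # eye[trial_id] -> (n, 3) array of (t_ms, x_deg, y_deg)
    eye: dict[int, np.ndarray]

    @property
    def neuron_ids(self) -> list[int]:
        return [n.neuron_id for n in self.neurons]


# phase spans in ms relative to stimulus onset (pre-window handled separately)
def _phase_span(config: TaskConfig, phase: str) -> tuple[float, float]:
    pre = -config.pre_window_ms
    if phase in ("passive_shapes", "passive_clarity"):
        return pre, config.passive_stim_ms + 300.0
    if phase == "active":
        return pre, config.target_ms + config.delay_ms
    if phase == "passive_motion":
        return pre, config.target_ms + 200.0
    raise ValueError(f"unknown phase {phase!r}")


def _poisson_spike_dict(
    rng: np.random.Generator,
    rates_hz: np.ndarray,
    trial_ids: np.ndarray,
    t0_ms: float,
) -> dict[int, np.ndarray]:
    """Draw spikes from per-trial 1 ms rate rows; returns trial -> times."""
    counts = rng.poisson(rates_hz * 1e-3)
    rows, bins = np.nonzero(counts)
    reps = counts[rows, bins]
    rows = np.repeat(rows, reps)
    bins = np.repeat(bins, reps)
    times = t0_ms + bins + rng.random(len(bins))
    out: dict[int, np.ndarray] = {int(tid): np.empty(0) for tid in trial_ids}
    order = np.argsort(rows, kind="stable")
    rows, times = rows[order], times[order]
    split_at = np.searchsorted(rows, np.arange(1, len(trial_ids)))
    for tid, chunk in zip(trial_ids, np.split(times, split_at)):
        out[int(tid)] = np.sort(chunk)
    return out


def _rates_for_phase(
    neuron: NeuronModel,
    config: TaskConfig,
    phase: str,
    trials: pd.DataFrame,
) -> np.ndarray:
    """(n_trials, n_bins) rate matrix at 1 ms bins for one phase's trials."""
    t0, t1 = _phase_span(config, phase)
    bins = np.arange(t0, t1)  # bin left edges, ms
    n_tr = len(trials)
    rate = np.full((n_tr, len(bins)), neuron.baseline_hz, dtype=float)
    lat = neuron.visual_latency_ms

    if phase in ("passive_shapes", "passive_clarity"):
        resp = (bins >= lat) & (bins < config.passive_stim_ms + lat + 100.0)
        gains = np.array([
            neuron.visual_gain * neuron.stimulus_gain(sh, cl)
            for sh, cl in zip(trials["shape_category"], trials["clarity"])
        ])
        rate[:, resp] = neuron.baseline_hz * gains[:, None]
        return rate

    # moving-stimulus phases: visual gain over the target period, motion
    # kernel multiplicative within it, baseline during the delay
    target = (bins >= lat) & (bins < config.target_ms + lat)
    gains = np.array([
        neuron.visual_gain * neuron.stimulus_gain(sh, cl)
        for sh, cl in zip(trials["shape_category"], trials["clarity"])
    ])
    base = neuron.baseline_hz * gains[:, None] * np.ones((1, len(bins)))
    kinds = trials["motion_kind"].to_numpy()
    for kind in np.unique(kinds):
        rows = np.where(kinds == kind)[0]
        mg = neuron.motion_gain_timecourse(kind, bins)
        base[rows, :] = base[rows, :] * mg[None, :]
    rate[:, target] = base[:, target]
    return np.maximum(rate, 0.0)


def _active_block_conditions(config: TaskConfig, rng: np.random.Generator):
    """Counterbalanced condition list for one active block."""
    cells = [
        (shape, clarity, role)
        for shape in ("blob", "spikey")
        for clarity in config.clarity_levels
        for role in ("predictive", "shared", "static")
    ]
    reps, rem = divmod(config.trials_per_block, len(cells))
    if rem != 0:
        raise ValueError(
            f"trials_per_block={config.trials_per_block} must be a multiple "
            f"of the {len(cells)} active condition cells"
        )
    conds = []
    for shape, clarity, role in cells:
        sides = ["left"] * (reps // 2) + ["right"] * (reps // 2)
        if reps % 2:  # odd repetition counts get a random extra side
            sides.append("left" if rng.random() < 0.5 else "right")
        rng.shuffle(sides)
        for r, side in enumerate(sides):
            # half of each cell uses the session-selected pair
            use_session_pair = r < (reps + 1) // 2
            conds.append((shape, clarity, role, side, use_session_pair))
    rng.shuffle(conds)
    return conds


def simulate_session(
    config: TaskConfig,
    neuron_specs: list[NeuronModel],
    seed: int,
    observer: ObserverModel | None = None,
    session_id: int = 0,
    monkey_label: str = "Y",
    simulate_eye: bool = True,
) -> Session:
    """Simulate one complete session (4 phases) with seeded determinism."""
    if not neuron_specs:
        raise ValueError("at least one neuron is required")
    config.__post_init__()  # re-validate (motion_map may have been mutated)
    observer = ObserverModel() if observer is None else observer
    rng = np.random.default_rng(seed)
    session_pair = int(rng.integers(config.n_shape_pairs))

    rows: list[dict] = []
    trial_id = 0

    def add_row(**kw) -> int:
        nonlocal trial_id
        base = dict(
            trial_id=trial_id, phase="", block=-1, shape_category="none",
            pair_id=-1, clarity=np.nan, motion_kind="static",
            motion_role="passive", correct_side="none", response_side="none",
            correct=np.nan, rewarded=np.nan, reaction_ms=np.nan, aborted=False,
        )
        base.update(kw)
        rows.append(base)
        trial_id += 1
        return base["trial_id"]

    # --- phase 1: passive survey of the full shape set -------------------
    if config.passive_shape_reps > 0:
        survey = [
            (pair, shape)
            for pair in range(config.n_shape_pairs)
            for shape in ("blob", "spikey")
        ] * config.passive_shape_reps
        rng.shuffle(survey)
        for pair, shape in survey:
            add_row(phase="passive_shapes", shape_category=shape,
                    pair_id=pair, clarity=1.0)

    # --- phase 2: passive clarity series on the session pair -------------
    clar_trials = [
        (shape, clarity)
        for shape in ("blob", "spikey")
        for clarity in config.clarity_levels
    ] * config.passive_clarity_reps
    rng.shuffle(clar_trials)
    for shape, clarity in clar_trials:
        add_row(phase="passive_clarity", shape_category=shape,
                pair_id=session_pair, clarity=clarity)

    # --- phase 3: active match-to-sample ---------------------------------
    for block in range(config.blocks):
        queue = _active_block_conditions(config, rng)
        while queue:
            shape, clarity, role, side, use_pair = queue.pop(0)
            aborted = bool(rng.random() < config.abort_prob)
            pair = session_pair if use_pair else int(
                rng.integers(config.n_shape_pairs)
            )
            kind = config.motion_kind(shape, role)
            if aborted:
                add_row(phase="active", block=block, shape_category=shape,
                        pair_id=pair, clarity=clarity, motion_kind=kind,
                        motion_role=role, correct_side=side, aborted=True)
                # shuffled back in with the remaining trials of the block
                pos = int(rng.integers(len(queue) + 1))
                queue.insert(pos, (shape, clarity, role, side, use_pair))
                continue
            response, rewarded, rt = simulate_behavior(
                config, observer, clarity, role, side, rng
            )
            add_row(phase="active", block=block, shape_category=shape,
                    pair_id=pair, clarity=clarity, motion_kind=kind,
                    motion_role=role, correct_side=side,
                    response_side=response, correct=(response == side),
                    rewarded=rewarded, reaction_ms=rt)

    # --- phase 4: passive viewing of the moving zero-clarity blur --------
    motion_trials = list(
        (kind,) for kind in (*MOVING_KINDS, "static")
    ) * config.passive_motion_reps
    rng.shuffle(motion_trials)
    for (kind,) in motion_trials:
        add_row(phase="passive_motion", clarity=0.0, motion_kind=kind)

    trials = pd.DataFrame(rows)

    # --- spikes -----------------------------------------------------------
    spikes: dict[int, dict[int, np.ndarray]] = {}
    for neuron in neuron_specs:
        per_neuron: dict[int, np.ndarray] = {}
        for phase in ("passive_shapes", "passive_clarity", "active",
                      "passive_motion"):
            sub = trials[trials["phase"] == phase]
            if sub.empty:
                continue
            rates = _rates_for_phase(neuron, config, phase, sub)
            t0, _ = _phase_span(config, phase)
            per_neuron.update(
                _poisson_spike_dict(rng, rates, sub["trial_id"].to_numpy(), t0)
            )
        spikes[neuron.neuron_id] = per_neuron

    # --- eye traces -------------------------------------------------------
    eye: dict[int, np.ndarray] = {}
    if simulate_eye:
        trajs = {
            kind: make_trajectory(
                kind, config.target_ms,
                amplitude_deg=config.trajectory_amplitude_deg,
            )
            for kind in (*MOVING_KINDS, "static")
        }
        track = trials[trials["phase"].isin(["active", "passive_motion"])
                       & ~trials["aborted"]]
        for tid, kind, clarity, phase in zip(
            track["trial_id"], track["motion_kind"], track["clarity"],
            track["phase"],
        ):
            if phase == "active":
                gain = observer.pursuit_gain(float(clarity))
            else:
                gain = 0.0  # fixation required during passive viewing
            eye[int(tid)] = simulate_eye_trace(
                trajs[kind], gain,
                noise_sd_deg=observer.pursuit_noise_sd_deg,
                drift_sd_deg=observer.pursuit_drift_sd_deg,
                rng=rng, window_deg=config.target_window_deg,
            )

    return Session(
        session_id=session_id, monkey_label=monkey_label, config=config,
        neurons=list(neuron_specs), trials=trials, spikes=spikes, eye=eye,
    )
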