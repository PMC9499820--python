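"""Pseudo-population construction and sliding-window motion decoding.

Neurons recorded in different sessions are combined into pseudo-populations:
for each neuron and motion class, a fixed number of trials is sampled
without replacement and aligned within class in random order, as if the
neurons had been recorded simultaneously.  A multiclass linear
maximum-margin decoder (one binary learner per unordered class pair,
aggregated by vote) is then trained per 150 ms sliding window and scored by
leave-one-out cross-validation over all pseudo-trials; the whole procedure
is repeated over iterations of trial re-sampling, and the identical pipeline
run with permuted labels provides the empirical ("shuffled label") chance
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.svm import SVC

from .synthetic_data import Session
from .windows import WindowGrid

__all__ = [
    "PseudoPopulation",
    "DecodingResult",
    "CLASSES_4WAY",
    "CLASSES_3WAY",
    "build_pseudopopulation",
    "decode_sliding",
    "shuffled_null",
    "decode_with_null",
    "decode_presets",
]

CLASSES_4WAY = ("static", "shared", "blob_predictive", "spikey_predictive")
CLASSES_3WAY = ("shared", "blob_predictive", "spikey_predictive")

#: preset -> (phase, classes, trials per class by clarity)
PRESETS = {
    "active4way": ("active", CLASSES_4WAY, {0.0: 96, "other": 64}),
    "active3way": ("active", CLASSES_3WAY, {0.0: 72, "other": 72}),
    "passive3way": ("passive_motion", CLASSES_3WAY, {0.0: 36, "other": 36}),
}


def _class_kind(session: Session, cls: str) -> str:
    mm = session.config.motion_map
    if cls == "static":
        return "static"
    if cls == "shared":
        return mm["shared"]
    if cls == "blob_predictive":
        return mm["blob"]
    if cls == "spikey_predictive":
        return mm["spikey"]
    raise ValueError(f"unknown motion class {cls!r}")


@dataclass
class PseudoPopulation:
    """Sampled spike trains of one decoding iteration.

    ``trains[neuron_index][class][j]`` is the spike-time array of the j-th
    sampled trial; pseudo-trial j of a class concatenates the j-th trials of
    all neurons.  Each neuron contributes distinct trials within an
    iteration (sampling without replacement).
    """

    classes: tuple[str, ...]
    n_trials_per_class: int
    neuron_ids: list[tuple[int, int]]  # (session_id, neuron_id)
    trains: list[dict[str, list[np.ndarray]]]
    iteration_seed: int
    clarity: float | None = None
    phase: str = "active"

    @property
    def n_features(self) -> int:
        return len(self.neuron_ids)

    def feature_matrix(
        self, start_ms: float, stop_ms: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """(pseudo-trials x neurons) window rates and integer labels."""
        width_s = (stop_ms - start_ms) / 1000.0
        n, k, d = self.n_trials_per_class, len(self.classes), self.n_features
        X = np.empty((k * n, d))
        y = np.repeat(np.arange(k), n)
        for ci, cls in enumerate(self.classes):
            for ni in range(d):
                trials = self.trains[ni][cls]
                X[ci * n: (ci + 1) * n, ni] = [
                    np.count_nonzero((t >= start_ms) & (t < stop_ms)) / width_s
                    for t in trials
                ]
        return X, y


def build_pseudopopulation(
    sessions: list[Session],
    classes: tuple[str, ...],
    clarity: float,
    n_trials: int,
    seed: int,
    phase: str = "active",
    on_short: str = "raise",
) -> PseudoPopulation:
    """Sample one pseudo-population across sessions.

    For every neuron and class, ``n_trials`` trials at the requested clarity
    are sampled uniformly without replacement and shuffled into a random
    within-class order (the alignment of pseudo-trials).  Neurons with too
    few trials either abort the build (``on_short="raise"``, the default —
    silent dropping would change the feature space between iterations) or
    are dropped with ``on_short="drop"``.
    """
    if len(classes) < 2:
        raise ValueError("need at least 2 motion classes")
    if on_short not in ("raise", "drop"):
        raise ValueError("on_short must be 'raise' or 'drop'")
    rng = np.random.default_rng(seed)
    neuron_ids: list[tuple[int, int]] = []
    trains: list[dict[str, list[np.ndarray]]] = []
    for session in sessions:
        t = session.trials
        sub = t[(t["phase"] == phase) & (t["clarity"] == clarity)]
        if phase == "active":
            sub = sub[~sub["aborted"]]
        pools = {}
        for cls in classes:
            kind = _class_kind(session, cls)
            pools[cls] = sub[sub["motion_kind"] == kind]["trial_id"].to_numpy()
        for nid in session.neuron_ids:
            short = [c for c in classes if len(pools[c]) < n_trials]
            if short:
                if on_short == "raise":
                    raise ValueError(
                        f"neuron {nid} of session {session.session_id} has "
                        f"fewer than {n_trials} trials for {short}"
                    )
                continue
            by_class = {}
            for cls in classes:
                pick = rng.choice(pools[cls], size=n_trials, replace=False)
                by_class[cls] = [session.spikes[nid][int(t)] for t in pick]
            neuron_ids.append((session.session_id, nid))
            trains.append(by_class)
    if not trains:
        raise ValueError("no usable neurons for the pseudo-population")
    return PseudoPopulation(
        classes=tuple(classes), n_trials_per_class=n_trials,
        neuron_ids=neuron_ids, trains=trains, iteration_seed=seed,
        clarity=clarity, phase=phase,
    )


# ---------------------------------------------------------------------------
# classifier: one-vs-one linear maximum-margin learners with vote aggregation
# ---------------------------------------------------------------------------

def _ovo_predict(clf: SVC, x: np.ndarray):
    """Vote-aggregated one-vs-one prediction with deterministic tie-breaks.

    Ties in the vote count are broken by the summed pairwise decision
    values, then by the lowest class index.
    """
    classes = clf.classes_
    k = len(classes)
    if k == 2:
        d = float(clf.decision_function(x[None])[0])
        return classes[1] if d > 0 else classes[0]
    df = clf.decision_function(x[None])[0]
    votes = np.zeros(k)
    score = np.zeros(k)
    m = 0
    for i in range(k):
        for j in range(i + 1, k):
            d = df[m]
            m += 1
            if d > 0:  # positive decision favors the first class of the pair
                votes[i] += 1
            else:
                votes[j] += 1
            score[i] += d
            score[j] -= d
    cand = np.nonzero(votes == votes.max())[0]
    if len(cand) > 1:
        cand = cand[score[cand] == score[cand].max()]
    return classes[int(cand[0])]


def _loo_accuracy(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Leave-one-out accuracy with leakage-free per-feature z-scoring.

    Binary learners weight classes inversely to their training-fold
    frequency: leaving one trial out makes its class underrepresented, and
    unweighted margins would be systematically biased against the held-out
    class (below-chance accuracy on label-independent data).
    """
    n = len(y)
    idx = np.arange(n)
    hits = 0
    for i in range(n):
        tr = idx != i
        Xtr = X[tr]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0.0] = 1.0  # constant features pass through harmlessly
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovo",
                  class_weight="balanced")
        clf.fit((Xtr - mu) / sd, y[tr])
        if _ovo_predict(clf, (X[i] - mu) / sd) == y[i]:
            hits += 1
    return hits / n


# ---------------------------------------------------------------------------
# sliding decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    """Per-window decoding accuracy, averaged over iterations."""

    window_starts: np.ndarray
    window_ms: float
    accuracies: np.ndarray  # (n_iterations, n_windows)
    n_classes: int
    n_trials_per_class: int
    meta: dict = field(default_factory=dict)
    shuffled: "DecodingResult | None" = None

    @property
    def n_rows(self) -> int:
        return self.n_classes * self.n_trials_per_class

    @property
    def acc_mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)

    @property
    def acc_sem(self) -> np.ndarray:
        """Standard error of the mean accuracy.

        Computed as the binomial variance of each iteration's
        cross-validated accuracy, averaged across iterations.  The
        across-iteration spread (see :attr:`acc_sem_iterations`) is not used
        here: iterations resample trials from the same finite session pool
        and are therefore correlated, so their spread understates the
        uncertainty of the mean.
        """
        p = self.accuracies
        var = (p * (1.0 - p)).mean(axis=0) / self.n_rows
        return np.sqrt(var)

    @property
    def acc_sem_iterations(self) -> np.ndarray:
        """SEM from the spread of accuracy across iterations."""
        n = self.accuracies.shape[0]
        if n < 2:
            return np.zeros(self.accuracies.shape[1])
        return self.accuracies.std(axis=0, ddof=1) / np.sqrt(n)

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes


PopulationBuilder = Callable[[int], PseudoPopulation]


def _run(
    builder: PopulationBuilder,
    grid: WindowGrid,
    n_iterations: int,
    seed: int,
    C: float,
    permuter: Callable[[np.random.Generator, int], np.ndarray] | None,
) -> DecodingResult:
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(0, 2**31 - 1, size=n_iterations)
    perm_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    accs = None
    n_classes = n_trials = None
    for it, s in enumerate(iter_seeds):
        pop = builder(int(s))
        if len(pop.classes) < 2:
            raise ValueError("need at least 2 classes to decode")
        n_classes = len(pop.classes)
        n_trials = pop.n_trials_per_class
        if accs is None:
            accs = np.zeros((n_iterations, len(grid)))
        n_rows = n_classes * n_trials
        perm = (
            permuter(perm_rng, n_rows) if permuter is not None else None
        )
        for wi, start in enumerate(grid.starts):
            X, y = pop.feature_matrix(float(start),
                                      float(start) + grid.window_ms)
            if perm is not None:
                y = y[perm]
            accs[it, wi] = _loo_accuracy(X, y, C)
    return DecodingResult(
        window_starts=grid.starts.copy(), window_ms=grid.window_ms,
        accuracies=accs, n_classes=n_classes, n_trials_per_class=n_trials,
        meta={"C": C, "seed": seed, "n_iterations": n_iterations},
    )


def decode_sliding(
    builder: PopulationBuilder,
    grid: WindowGrid | None = None,
    n_iterations: int = 20,
    seed: int = 0,
    C: float = 1.0,
) -> DecodingResult:
    """True-label sliding-window decoding.

    ``builder`` maps an iteration seed to a fresh :class:`PseudoPopulation`
    (re-sampling trials each iteration); a separate model is fit per window
    and scored by leave-one-out cross-validation.
    """
    grid = WindowGrid() if grid is None else grid
    return _run(builder, grid, n_iterations, seed, C, permuter=None)


def _default_permuter(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.permutation(n)


def shuffled_null(
    builder: PopulationBuilder,
    grid: WindowGrid | None = None,
    n_iterations: int = 20,
    seed: int = 0,
    C: float = 1.0,
    permuter: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> DecodingResult:
    """Empirical chance: the identical pipeline with permuted labels.

    Labels are permuted once per iteration (independently across
    iterations); everything else — trial sampling, windows, classifier,
    scoring — is shared with :func:`decode_sliding`.  The ``permuter`` hook
    exists so the code-path identity can be audited (an identity permuter
    reproduces the true-label result exactly).
    """
    grid = WindowGrid() if grid is None else grid
    return _run(builder, grid, n_iterations, seed, C,
                permuter=permuter or _default_permuter)


def decode_with_null(
    builder: PopulationBuilder,
    grid: WindowGrid | None = None,
    n_iterations: int = 20,
    seed: int = 0,
    C: float = 1.0,
) -> DecodingResult:
    """True-label decoding with the shuffled-label chance level attached."""
    result = decode_sliding(builder, grid, n_iterations, seed, C)
    result.shuffled = shuffled_null(builder, grid, n_iterations, seed, C)
    return result


def decode_presets(
    sessions: list[Session],
    preset: str,
    clarity: float = 0.0,
    grid: WindowGrid | None = None,
    n_iterations: int = 20,
    seed: int = 0,
    C: float = 1.0,
    on_short: str = "raise",
) -> DecodingResult:
    """Run one of the study's decoding configurations.

    * ``active4way`` — static/shared/blob-predictive/spikey-predictive at a
      given clarity; 64 trials per class (96 at clarity 0).
    * ``active3way`` — the three moving conditions at clarity 0; 72 trials.
    * ``passive3way`` — the three moving conditions during passive viewing
      of the moving blur; 36 trials.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    phase, classes, trial_map = PRESETS[preset]
    if preset != "active4way":
        clarity = 0.0
    n_trials = trial_map.get(clarity, trial_map["other"])
    for s in sessions:
        if not (s.trials["phase"] == phase).any():
            raise ValueError(
                f"session {s.session_id} lacks the {phase!r} phase"
            )

    def builder(it_seed: int) -> PseudoPopulation:
        return build_pseudopopulation(
            sessions, classes, clarity, n_trials, it_seed,
            phase=phase, on_short=on_short,
        )

    result = decode_with_null(builder, grid, n_iterations, seed, C)
    result.meta.update(
        preset=preset, clarity=clarity, classes=classes, n_trials=n_trials
    )
    return result
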