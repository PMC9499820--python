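# motioncue

Simulation and analysis of **motion-cued recognition of blurred shapes in
inferior temporal (IT) cortex**.

When shape information is degraded — think of a blurry animal in fog that
you recognize the moment it hops — its motion can carry the identity.
`motioncue` implements the full computational pipeline of a macaque
match-to-sample experiment built around this idea: monkeys view a moving,
Gaussian-blurred shape (clarity c = 1 − SD/100, down to a shapeless blurred
circle at c = 0) whose trajectory (circular, triangular, or figure-eight)
may be uniquely associated with its shape category, and neural recordings
in area IT are analyzed for clarity tuning, motion sensitivity, and
population-level decodability of the motion condition.

The package is aimed at systems/computational neuroscientists who want to
run, probe, or extend these analyses without animal data: a synthetic
session generator with planted ground truth stands in for the recordings,
so every stage is testable end to end.

## What it implements

| Module | Contents |
| --- | --- |
| `motioncue.stimuli` | blob/spikey shape pairs from Boolean unions of random polygons; Gaussian-blur clarity ladder; periodic equal-speed trajectories |
| `motioncue.synthetic_data` | 4-phase sessions, parametric IT neurons (clarity categories, motion kernels), Poisson spikes, psychophysical observer, pursuit eye traces |
| `motioncue.tuning` | tuning curves, relative responses, external clarity factor (ECF), modulation index (MI), principal values (PV_B, PV_S), quadrant categories, task-relevance screen (Welch's t, α = 0.008) |
| `motioncue.sensitivity` | one-way motion/shape ANOVAs per clarity, 150 ms / 50 ms sliding windows, population fractions, sensitivity latency |
| `motioncue.decoding` | pseudo-populations across sessions, one-vs-one linear decoders, leave-one-out CV, shuffled-label chance, study presets (64/96, 72, 36 trials) |
| `motioncue.behavior` | accuracy/RT summaries across sessions, condition-averaged pursuit traces |
| `motioncue.session_io` | lossless plain-text session storage (CSV + YAML) |

The core statistics, in the field's notation: per neuron and shape the
relative response Δr(c) = r(c) − r(1); ECF = argmax_c |Δr(c)|;
MI = ∫ Δr(c) dc; PV = projection of the max-|·|-normalized Δr curve onto
the population's first principal component, oriented so corr(PV, MI) > 0,
with quadrant categories A (PV_B, PV_S > 0, blur-enhanced) through
D (PV_B < 0 < PV_S). Decoding accuracy is leave-one-out performance of
one-vs-one linear SVMs on pseudo-trial window rates, reported against an
empirical shuffled-label chance.

## Worked example

```python
import numpy as np
from motioncue import (TaskConfig, plant_population, simulate_session,
                       compute_tuning_curve, performance_summary)
from motioncue.synthetic_data import DEFAULT_CATEGORY_MIX
from motioncue.tuning import population_clarity_metrics

cfg = TaskConfig(blocks=2, trials_per_block=60,
                 passive_clarity_reps=30, passive_motion_reps=10)
neurons = plant_population(DEFAULT_CATEGORY_MIX, 20, seed=1)
session = simulate_session(cfg, neurons, seed=42)

curves = [compute_tuning_curve(session, n.neuron_id) for n in neurons]
metrics = population_clarity_metrics(curves)
print(metrics["category"].value_counts().to_dict())
print("category recovery:",
      (metrics["category"].to_numpy()
       == np.array([n.category for n in neurons])).mean())

acc = performance_summary([session]).table.set_index(
    ["motion_role", "clarity"])["accuracy"]
print("predictive@c=0:", acc[("predictive", 0.0)],
      " static@c=0:", acc[("static", 0.0)])
```

Output:

```
{'A': 8, 'B': 7, 'D': 3, 'C': 2}
category recovery: 1.0
predictive@c=0: 1.0  static@c=0: 0.75
```

The planted category mix (≈46/33/9/15% across the four clarity-tuning
quadrants) is recovered exactly from the simulated passive-viewing spikes,
and the behavioral observer shows the task's signature: near-ceiling
accuracy at zero clarity when the motion is predictive, near chance when
it is not (0.75 here reflects only 8 trials in that summary cell of this
small session).

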