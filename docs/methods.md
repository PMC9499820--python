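# Methods

`motioncue` models and analyzes a match-to-sample experiment in which a
monkey must recognize a moving, Gaussian-blurred 2D shape and report which
of two clear choice shapes it matches. The package has two halves: a
generative half (stimuli, task, neurons, observer, eye movements) that
produces complete synthetic sessions with known ground truth, and an
analysis half (clarity tuning, windowed sensitivity, population decoding,
behavioral summaries) that recovers that ground truth. This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Stimuli

**Shape pairs.** Each pair derives from one set of control points: the
exterior boundary of the Boolean union of four overlapping random polygons
(vertices drawn on jittered rings about random centers, which guarantees
star-shaped components that overlap reliably). The "spikey" is the polygon
through the control points; the "blob" is the same polygon smoothed by
Chaikin corner cutting (default 3 passes, the `smoothing` parameter). We
chose corner cutting over an interpolating spline deliberately: a smoothing
subdivision never lengthens the boundary (each pass replaces a corner with
a chord cut), so the blob's perimeter is provably at most the spikey's,
matching the intuition that smoothing shortens an outline. An interpolating
spline through the same points would necessarily be at least as long as the
polygon and can overshoot at concave corners. Degenerate unions (polygons
that fail to merge into one simple region) are resampled internally up to a
retry limit.

**Clarity.** Shape rasters (default 256 px for a 3° stimulus, so the
largest kernels remain representable) are degraded by convolution with an
isotropic 2D Gaussian; clarity c and kernel width are linked by
SD = 100·(1−c) pixels. Convolution uses reflect padding; stimuli are
centred with margins so the boundary rule is invisible at default sizes.
The clarity-0 stimulus is a blurred circle rather than a blurred task
shape, so it carries no diagnostic shape information at all; requesting it
unblurred is an error, because an unblurred circle would itself be (wrong)
shape information. The circle's blur SD is configurable; the original
display values are not printed anywhere recoverable, and nothing downstream
depends on them.

**Trajectories.** Three closed periodic paths — circular, triangular, and
figure-eight ("bimodal") — plus a static condition. Moving paths last
1,500 ms, complete two 750 ms cycles, and are translated to share one start
(and hence end) location. The circle's radius (default 1.25°, giving a
≈±2° excursion range) is the single amplitude parameter; the triangle and
figure-eight are scaled so all three paths have identical length per cycle
and therefore identical mean speed (the triangle is traversed at constant
speed along its perimeter, giving flat velocity segments). Positions are
defined as the cumulative trapezoidal integral of the analytic velocity
samples, which makes position/velocity consistency exact by construction;
at triangle corners (which land on the 1 ms sample grid) the recorded
velocity is the average of the incoming and outgoing segment velocities,
which cancels the trapezoidal closure error pairwise. The fundamental
period is estimated by circular autocorrelation of x(t) — appropriate
because the sampled signal spans an integer number of cycles.

## Synthetic sessions

A session has four phases: a passive survey of the full 100-shape set
(optional, off by default), a passive clarity series on one
session-selected pair (200 ms stimuli, 100 ms gaps; default 50
trials per shape × clarity cell), the active match-to-sample phase
(default 5 blocks × 180 trials: 2 shapes × 5 clarity levels × 3 motion
roles × 6 repetitions, counterbalanced for response side), and passive
viewing of the moving zero-clarity blur (default 40 repetitions per motion
condition). Half of each active cell uses the session pair, half a random
pair from the full set. Aborted trials (default 3%) are reinserted at a
random position in the remaining block queue, so every block completes its
configured trial count. The default clarity ladder is (0, 0.3, 0.5, 0.8, 1);
the original ladders were chosen per animal behaviorally and only the
endpoints are fixed by design.

**Neurons.** A neuron's instantaneous rate is baseline × visual gain (after
a per-neuron visual latency) × shape preference × clarity gain × motion
gain, rectified at zero. Clarity gain is 1 + sign·strength·profile(c) with
a monotone profile (1−c) by default or a Gaussian band-pass profile
(anchored to zero modulation at c = 1) when a peak clarity is set; the
sign pattern over the two shapes defines the four planted tuning
categories (enhanced / suppressed / two mixed forms). At clarity 0 the
shape-specific factors are replaced by their two-shape average, because the
underlying stimulus is the same circle for both nominal categories — shape
is then undecodable by construction. Motion gain is a multiplicative box
kernel (latency, duration, gain) per trajectory kind; the real data show
heterogeneous timing with no stated functional form, and a box is the
simplest planted ground truth whose latency a recovery analysis can be
scored against. Spikes are drawn per 1 ms bin as Poisson counts with
uniform jitter within the bin, so counts in any aligned window are exactly
Poisson — directly testable against closed-form statistics.

**Observer.** Choice probability fuses two cues as independent evidence:
shape evidence ps = ½ + ½·sensitivity(c) (sensitivity linear in clarity by
default) and motion evidence pm = ½ + ½·association on predictive-motion
trials only (default association 0.9); the fused probability is mixed with
a lapse rate (default 0.12). This reproduces the task's signature
crossover: near-ceiling accuracy at all clarities under predictive motion,
chance at clarity 0 under shared/static motion. Zero-clarity shared/static
trials have no correct answer and are rewarded at random (probability 0.5).
Reaction times are shifted log-normal with a slower static condition;
parameters are configurable and nothing asserts their absolute values.

**Eye traces.** Pursuit is modelled as gain × (causally low-passed
trajectory, τ = 80 ms) + linear drift + white noise at 200 Hz, with the
gain shrinking linearly as clarity falls (pursuit of blurrier targets is
weaker); static trials are fixation (drift + noise only). Traces outside
the ±4° window are resampled. This emulates the condition-averaged pursuit
signature only — no saccades, no pursuit initiation dynamics — so passing
tests say nothing about saccadic structure in real data.

## Clarity tuning analysis

Tuning curves are mean rates in the 0–300 ms response window (5 ms bins)
per shape × clarity cell of the passive clarity series. Derived metrics:

* **Relative response**: arithmetic deviation from the 100%-clarity rate
  (a ratio form was rejected because it explodes at low baselines).
* **ECF**: the clarity with the largest absolute deviation; ties break
  toward the lowest clarity (the most-degraded interpretation); an all-zero
  curve returns 1.0 with a no-modulation flag. Absolute rather than signed
  modulation is used because both enhancement and suppression occur.
* **MI**: signed trapezoidal integral of the deviation curve over clarity.
* **PV**: each neuron's deviation curve is normalized by its maximum
  absolute deviation (zero-modulation neurons are excluded from the fit and
  assigned PV = 0), the first principal axis of the *uncentred* normalized
  set is computed per shape (and per animal group), and the PV is the
  projection onto that axis. Uncentred extraction is deliberate: a
  population of identical curves then has a well-defined first axis
  explaining all structure, and the projection preserves the sign of the
  deviation pattern. The axis sign — arbitrary in any such decomposition —
  is oriented so that PV correlates positively with MI, making positive PV
  mean blur-enhancement.
* **Quadrant categories**: A (+,+), B (−,−), C (+,−), D (−,+) by the signs
  of (PV_blob, PV_spikey); exact zeros count as negative, which avoids
  over-counting enhancement.

Task-relevance screening uses Welch's t-test of five task windows
(50–200, 200–350, 800–950, 1550–1700, 1700–1850 ms) against the 200 ms
pre-stimulus baseline, α = 0.008 (the corrected level for five windows);
degenerate zero-variance inputs yield p = 1.

## Windowed sensitivity

Motion sensitivity per shape class is a one-way ANOVA of window rates over
the three motion conditions available for that class (predictive, shared,
static) — the full motion × shape crossing does not exist by design, so no
multifactor model is attempted. Shape sensitivity compares blob vs spikey.
Windows are 150 ms sliding by 50 ms over the 0–2,000 ms target + delay
span, or the fixed 50–200 ms early visual window. Rates are plain
count/width; sliding windows share spikes. Correction is Bonferroni within
one neuron × factor × clarity family (the number of windows for sliding
analyses; clarity levels × shape classes for the early-visual summary);
the family definition is a configurable choice because the original
correction family is not printed.

**Latency.** A neuron's sensitivity latency is taken from its earliest
significant window — by default the window *center*, not its start.
Overlapping windows make the start convention biased early at high SNR: a
150 ms window sliding by 50 ms first overlaps an effect onset up to 100 ms
before it, so at strong effect sizes "first significant start" lands two
steps early, while the first overlapping window's center is only 25 ms
early. The start convention remains available via an argument.

## Population decoding

Pseudo-populations combine neurons across sessions: per neuron and motion
class, n trials at the requested clarity are sampled without replacement
and aligned within class in random order (re-drawn every iteration; no
finer alignment rule exists since trials were never simultaneous). Window
rates concatenate across neurons as features. The decoder is a linear
maximum-margin classifier per unordered class pair (regularization C = 1,
recorded in metadata), aggregated by vote; vote ties break by summed
pairwise decision values, then lowest class index — fully deterministic.
Features are z-scored per neuron using training folds only. Scoring is
leave-one-out over all pseudo-trials, repeated over iterations (default
20; analyses in the tests and acceptance script use 5–8 with smaller trial
counts to keep desk-scale runtimes in minutes).

Two numerical choices deserve emphasis:

* **Balanced class weights.** Each binary learner weights classes
  inversely to their training-fold frequency. Without this, leave-one-out
  is systematically below chance on label-independent data (the held-out
  trial's class is underrepresented in its training fold, and for
  near-identical class pairs the pair learner votes *against* the held-out
  class); measured at k = 3 with 12 trials/class, null accuracy is ≈0.24
  unweighted vs ≈0.34 balanced against a chance of 1/3.
* **SEM of decoding accuracy.** The reported SEM is the within-iteration
  binomial variance of the cross-validated accuracy, averaged across
  iterations — not the across-iteration spread. Iterations resample the
  same finite trial pool and are therefore correlated; their spread
  understates the uncertainty of the mean. The across-iteration SEM is
  kept as a separate field.

The shuffled-label null reruns the identical pipeline with labels permuted
once per iteration; a permuter hook allows an audit that an identity
permutation reproduces the true-label result exactly. Presets mirror the
study's configurations: 4-way motion decoding at 64 trials/class (96 at
clarity 0), 3-way moving-only at 72, and passive 3-way at 36.

Because pseudo-population trials are drawn from finite pools, true-label
decoding of label-independent data can sit slightly off theoretical chance
(pool-level chance structure recurs across iterations) — exactly the bias
the empirical shuffled-label chance exists to absorb. Comparisons should
therefore always be made against the shuffled level, as the analysis
functions do.

## Behavioral summaries

Accuracy is computed per session and condition as the fraction of correct
completed trials (aborts excluded), then averaged unweighted across
sessions with SEM over sessions; reaction times average over correct and
incorrect completed trials alike. Pursuit averages are pointwise means of
eye traces over the correct trials of a condition on a uniform 200 Hz
base.

## What the synthetic data does and does not show

The generator plants exactly the structures the analyses look for
(multiplicative clarity/motion gains, box motion kernels, an evidence-
fusing observer), so green tests demonstrate that the analysis chain
recovers known ground truth at realistic trial counts and firing rates —
they do not demonstrate that real IT neurons have these tunings, and
quantities such as the reported category proportions are inputs here, not
findings. Known limitations: no spike-sorting noise or unit instability,
no cross-trial rate drift, no correlated variability between neurons
(pseudo-populations built from truly independent synthetic sessions are
"cleaner" than real ones), box-shaped motion kernels, and eye traces
without saccades.

## Problem sizes used in tests and the acceptance script

Recovery and calibration analyses run at reduced scale chosen as the
package's own desk-scale defaults: 200 planted neurons at 50 trials/cell
for tuning recovery; 2,000 simulations for null ANOVA calibration and 60
for latency recovery (60 trials/condition, 40 Hz baseline, gain 3 kernels);
decoding with 5 neurons × 3 sessions, 16 trials/class, 5–6 iterations on
coarse window grids. Each stage's full-scale parameters remain the
defaults of the corresponding functions.
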