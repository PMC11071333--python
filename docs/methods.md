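# Methods

## Problem and model

The package decodes a sequence of activity states (stationary, walking,
running, squat) from six-axis wrist IMU data. The estimator is a hybrid
of a discriminative window classifier and a generative sequence model:

* the **window stage** treats each 50-sample (~1 s) window as an i.i.d.
  classification problem over 60 statistical features;
* the **sequence stage** models the temporal structure the window stage
  ignores: activities persist for seconds, so the true label sequence is
  strongly autocorrelated, and a lone dissenting window inside a long
  constant run is far more likely a classifier error than a real
  sub-second activity bout.

Formally, the smoothing HMM has hidden states = true window activities
and observations = the classifier's hard labels (N = M = 4). π and A are
maximum-likelihood estimates (with add-one smoothing) from the labelled
training window sequences; B is the row-normalized training confusion
matrix of the fitted classifier, i.e. an estimate of
P(predicted = o | truth = i). Decoding is the Viterbi path over the test
recording's raw label sequence. A `posterior_argmax` mode (per-window
argmax of the forward–backward posteriors) is available behind a flag;
Viterbi is the default because the decoded object of interest is the
single coherent activity sequence, not per-window marginals.

## Window features

Per channel: mean, standard deviation, variance, max, min, range,
median, RMS, skewness, excess kurtosis — the standard time-domain HAR
battery. Conventions chosen for degenerate inputs: sd/variance use the
sample (W−1) denominator; skewness/kurtosis use population central
moments and are defined as 0 for zero-variance windows; z-scoring maps
zero-variance feature columns to 0 (flagged in the normalizer). These
make noise-free stationary windows legal inputs end to end.

The mean filter truncates its averaging window at the sequence edges
rather than padding, which keeps constant signals exactly invariant —
the property the filter/feature identity tests rely on. Default width
N = 5 (0.1 s at 50 Hz): wide enough to suppress white noise visibly,
narrow relative to the shortest oscillation period being modelled
(running at 2.8 Hz ≈ 18 samples per cycle), so activity structure is not
filtered away.

Window labels are the per-sample majority, ties broken by the earliest
sample among the tied classes. Windows straddling an activity change are
**retained**: they are the realistic hard case, and dropping them would
overstate accuracy.

## Network training

The classifier is a 60–32–4 sigmoid network with half-MSE loss against
one-hot targets — deliberately the plain backpropagation recipe, not
softmax/cross-entropy. Scores handed to the HMM are the output
activations renormalized to sum to one per window: a documented
pseudo-posterior, adequate for ranking but not calibrated.

Training hyperparameters are free choices (nothing in the problem fixes
them): the pipeline default uses shuffled mini-batches of 64 at
learning rate 0.5 for 60 epochs, which drives the training loss to a
plateau on the packaged benchmark (final loss ≈ 0.014, flat over the
last ~20 epochs). `TrainConfig`'s own defaults (full batch, α = 0.1, 200
epochs) keep the textbook full-batch reading for library users who want
it. Weight initialization is uniform on ±init_scale/√fan_in with zero
biases; all randomness flows from one integer seed, so training is
bit-reproducible. Gradients are verified against central finite
differences (the module's core oracle).

## HMM numerics

Forward/backward use per-step scaling (each alpha row normalized, beta
scaled compatibly), so likelihoods of arbitrarily long sequences never
underflow and gamma = alpha ⊙ beta is row-normalized by construction;
Viterbi runs in log space. Ties in Viterbi maximizations break toward
the lower state index (asserted by test). An observation sequence that
is impossible under the model yields log-likelihood −∞ with a flag
rather than an exception, so pipelines can fall back gracefully; the
default pseudocount of 1 on all estimated matrices keeps B strictly
positive and the case unreachable in normal operation.

Baum–Welch is provided for unlabelled data. EM converges only to a
local likelihood maximum; `n_restarts` runs several seeded random
starts and keeps the best final log-likelihood, the standard remedy
(a single unlucky start on a 2-state fixture demonstrably converges to
a degenerate optimum with identical emission rows). The default
pipeline does not use EM: supervised labels exist, and the
confusion-matrix emission estimate is deterministic and directly
encodes how the classifier errs.

## Synthetic generator

Each activity is, per channel, baseline + sinusoid (random phase) +
white Gaussian noise; the accelerometer carries a (0,0,1) g gravity
baseline. The squat model adds a sawtooth ramp on z-acceleration —
rising at `trend_slope_z` g/s within each squat cycle, resetting at the
cycle boundary — reproducing the rising z-axis signature that makes
squats the most recognisable class. Defaults (chosen once as
physiologically plausible, then frozen): walking ~1.8 Hz with
0.10–0.25 g accelerometer amplitudes, running ~2.8 Hz with 0.4–0.9 g
(strictly dominating walking in both amplitude and frequency, which the
config validates), squat cycles at 0.5 Hz, noise sds of 0.02–0.08 g
(accelerometer) and 1–8 deg/s (gyroscope) by activity. Activity bouts
follow a uniform off-diagonal Markov chain with dwell times uniform on
3–10 s; the packaged benchmark is 40 sequences of ~60 s at 50 Hz,
seed 1234, split 75/25 by sequence index. The noise-elevated variant
(3× noise sds, 12 × 40 s) deliberately blurs the stationary/walking
separation to provoke the isolated misclassifications that smoothing
exists to remove.

What the generator does **not** emulate: biomechanical gait harmonics,
orientation change/quaternions, sensor bias and drift, magnetometer
channels, inter-subject variability. Passing tests therefore demonstrate
the correctness and the qualitative behaviour of the method (smoothing
helps exactly when errors are temporally isolated), not field
performance on real wrist data.

## Problem sizes and numerical behaviour

The packaged benchmark (40 × 60 s, ~11,800 windows) fits and scores in a
few seconds on one CPU; the exhaustive HMM oracle runs 200 fixtures with
N ≤ 3 states and T ≤ 6 steps, where full path enumeration is exact and
cheap. In the separable (zero-noise) limit, windows containing a single
activity are classified essentially perfectly (≥ 98% measured), but
overall accuracy stays near 0.95 rather than exactly 1.0 because
boundary-straddling windows — retained by design — have genuinely mixed
content; this is a property of the task definition, not a defect of the
classifier.

## Known limitations

* The confusion-matrix emission model assumes classifier errors are
  conditionally independent given the true state; bursty errors (e.g.
  during a sustained sensor artefact) violate this and can survive
  smoothing.
* MSE-with-sigmoid training is slow near saturated units; the defaults
  avoid the regime, but very deep or very large-α configurations can
  stall (a non-finite loss aborts with a diagnostic).
* The renormalized network outputs are not calibrated probabilities;
  the `posterior_argmax` mode inherits this approximation.
* Label smoothing cannot recover activities shorter than roughly the
  window length; sub-second bouts are invisible at 50/10 windowing.
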