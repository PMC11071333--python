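# wristhar

Decoding human activity states from wrist-worn inertial sensors, for
researchers in exercise and behavioural science who want a light-weight,
fully inspectable alternative to deep sequence models.

A wrist band samples six channels at ~50 Hz — 3-axis acceleration
(ax, ay, az, in g) and 3-axis angular velocity (gx, gy, gz, in deg/s) —
while a subject alternates between four activities: **stationary (0),
walking (1), running (2), squat (3)**. `wristhar` classifies every
~1-second window of that stream and then smooths the label sequence with
a hidden Markov model, removing the short spurious "interruptions" a
per-window classifier produces in the middle of a sustained activity.

## Method

1. **Denoising.** Each channel is mean-filtered:
   `y[n] = (1/N) Σ_{k=−(N−1)/2}^{(N−1)/2} x[n+k]` (N = 5, truncated at
   the edges).
2. **Windowing & features.** Sliding windows of 50 samples with step 10;
   per window and channel, ten time-domain statistics (mean, sd,
   variance, max, min, range, median, RMS, skewness, kurtosis) are
   concatenated into a 60-dimensional feature vector and z-scored.
3. **Window classifier (BPNN).** A feedforward network
   (60–32–4, sigmoid units) trained from scratch by backpropagation of
   the half mean-squared error `E = (1/2n) Σᵢ ‖yᵢ − ŷᵢ‖²` against one-hot
   targets, with plain gradient-descent updates
   `w ← w − α ∂E/∂w`.
4. **Sequence smoothing (HMM).** Hidden states are the true activities;
   observations are the classifier's predicted labels. π and the
   transition matrix A are estimated from the labelled training window
   sequences, and the emission matrix B from the classifier's training
   confusion matrix (`B[i,o] = P(predicted o | truth i)`, Laplace
   smoothed). Decoding replaces the raw label sequence by the Viterbi
   path (scaled forward/backward, posteriors and Baum–Welch EM are also
   provided).

A seeded synthetic generator produces labelled four-activity recordings
(sinusoid + noise per channel, plus the squat's characteristic rising
z-acceleration ramp), so the whole pipeline is trainable and testable
with no external data.

## Worked example

```python
from wristhar import simulate, pipeline

gen = simulate.GeneratorConfig(n_sequences=8, sequence_length_s=30.0, seed=7)
result = pipeline.run_benchmark(gen)
s = result.summary()
print(f"raw BPNN accuracy:      {s['raw_accuracy']:.3f}")
print(f"BPNN+HMM accuracy:      {s['smoothed_accuracy']:.3f}")
print("per-class recall (smoothed):",
      [round(r, 3) for r in s['smoothed_per_class_recall']])
```

prints

```
raw BPNN accuracy:      0.939
BPNN+HMM accuracy:      0.964
per-class recall (smoothed): [0.961, 0.98, 0.99, 0.891]
```

Eight 30-second recordings are generated, the pipeline is fitted on six
and scored on the held-out two: the window classifier alone gets 93.9% of
windows right, and HMM smoothing of its label sequence lifts this to
96.4%. The recall vector is the per-activity hit rate (stationary,
walking, running, squat) after smoothing.

The same is available from the shell:

```bash
wristhar simulate --seed 7 --out-dir data/         # labelled CSVs + manifest
wristhar train    --data-dir data/ --seed 7 --model-out model.json
wristhar decode   --model model.json --data-dir data/ --out-dir decoded/
wristhar evaluate --model model.json --data-dir data/ --out metrics.json
wristhar benchmark --seed 7                        # generate + fit + score
```

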