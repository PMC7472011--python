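# Methods

`stresswin` implements a real-time mental-stress assessment pipeline for
19-channel scalp EEG, together with the conventional feature-engineering
pipeline it is meant to replace, and the evaluation machinery to compare
the two.  This note records the models, the defaults and why, the numerical
choices, and what the synthetic test bed does and does not show.

## Pipeline model

Raw EEG (10–20 montage: Fp1, Fp2, F3, F4, F7, F8, C3, C4, T3, T4, T5, T6,
P3, P4, O1, O2, Fz, Cz, Pz; 500 Hz; microvolts) is processed as:

1. **Single band selection.**  One Butterworth band-pass, 4–30 Hz, order 4,
   second-order sections.  The stress-relevant rhythms (theta 4–8, alpha
   8–12, beta 13–30 Hz) all lie inside this range, so the classifier path
   needs exactly one filtering pass — no per-band decomposition.  Causal
   (forward-only) operation is the default because the target is streaming
   inference; zero-phase forward–backward filtering is available for batch
   analysis.  No separate 50 Hz notch is applied: the 4–30 Hz selection
   already suppresses line frequency.
2. **Windowing.**  The band-limited signal is cut into consecutive,
   non-overlapping 40 ms windows — 20 samples at 500 Hz — and stacked into a
   4D tensor `[19 × 20 × 1 × n_windows]`.  Trailing partial windows are
   dropped, never padded, so a 10-minute recording yields exactly 15,000
   windows.  Stress patterns are treated as instantaneous: the window, not
   the session, is the unit of classification.
3. **Labeling by frontal alpha asymmetry.**  Each window receives an alpha
   asymmetry score

       AAS = ln(P_α(Fp2) + ε) − ln(P_α(Fp1) + ε),

   the standard log-power frontal-asymmetry statistic; lower (negative)
   values mark stress/withdrawal.  A window is labelled *stress* iff
   AAS < 0; ties go to non-stress.  ε = 1e-12 µV² guards the logarithm on
   silent channels.  A 20-sample FFT has 25 Hz resolution and cannot see
   8–12 Hz, so alpha power at this scale is estimated by zero-phase
   filtering the *full-length* signal once (8–12 Hz, order 4) and taking
   the mean square of the filtered trace inside each window.  Labeling is
   an offline training-time operation, so the non-causal filter is
   acceptable there — and only there.
4. **Class balancing.**  All minority-class windows are kept and the
   majority class is subsampled uniformly at random (seeded, without
   replacement), giving a balanced training set of twice the minority count.
5. **CNN classifier.**  The fixed stack (valid padding, stride 1):
   conv 16@3×3 → conv 16@3×3 → maxpool 2×2 → leaky-ReLU(0.01) →
   dropout 50% → conv 10@2×2 → conv 10@2×2 → maxpool 2×2 →
   leaky-ReLU(0.01) → dropout 50% → flatten (1,320) → FC 64 →
   leaky-ReLU → FC 2 → softmax over {non_stress, stress}.
   Training: Adam on cross-entropy, batch 32, 20 epochs, reshuffled each
   epoch from a seeded stream, dropout active in training only.  The whole
   network — forward, backward, optimiser — is implemented in numpy, so a
   fixed seed reproduces weights bit-for-bit and inference needs no
   framework.  Gradients are verified against finite differences in the
   test suite, and conv/maxpool against brute-force loop oracles.

### Numerical choices in the CNN

* **Input normalisation.**  Statistics are frozen on the training tensor
  and reused verbatim everywhere: scalar mean (zero-centring) *and* scalar
  standard deviation.  Pure zero-centring was tried first and rejected:
  microvolt-scale inputs (σ ≈ 17 µV after band-passing) push the softmax
  into saturation under fan-in-scaled initialisation and the network stays
  at chance for many epochs.  Dividing by the training σ restores standard
  optimisation behaviour.  `NormStats.scale = 1` recovers plain
  zero-centring.
* **Learning rate** defaults to 3e-3.  With this from-scratch Adam and the
  fixed 20-epoch budget, 1e-3 leaves the loss on its initial plateau
  (discovering the quadratic power statistic from raw samples is the slow
  part); 3e-3 escapes it reliably.  Chosen once from a coarse sweep on a
  small development cohort.
* **Initialisation**: seeded He-style uniform with fan-in scaling, zero
  biases.  **Convolution** is cross-correlation (the usual deep-learning
  convention).  **Padding** is valid everywhere, which produces the
  11×12×10 = 1,320-feature flatten; the two FC widths (1,320→64→2) are a
  package choice since only "two fully connected layers" is fixed.
* Ordering contract of maxpool ties: `argmax` takes the first maximal
  element; backward routes the gradient to exactly one input per window.

## The conventional comparison arm

Per segment, the feature family is: band power, relative power (per-channel
band fractions summing to 1), pairwise band-power ratios, magnitude-squared
coherence for all 171 channel pairs, and left/right log-power asymmetries
for the 8 homologous pairs.  Two estimator regimes:

* **Batch sessions** (≥ 125 ms): Welch periodogram integrals and Welch
  coherence (Hann, 50% overlap).  Coherence for all pairs is computed from
  one STFT pass; the vectorised estimator is cross-checked against
  `scipy.signal.coherence` in the tests.
* **40 ms windows**: each window is band-filtered *in isolation* (causal,
  cold start) and features come from the filtered variance and the squared
  Pearson correlation of the filtered pair (coherence surrogate, columns
  named `cohw[...]` to prevent silent mixing with Welch tables).  This is
  deliberately the estimator a per-window real-time pipeline can compute:
  it sees only the 20 samples it was handed, and the filter transient makes
  it lossy.  That information loss is the point of the comparison — the
  conventional path's features degrade at real-time window lengths, while
  the CNN learns its own features from the same 20 raw samples.

In the AAS-labeled experiments the Fp1–Fp2 alpha asymmetry feature is
excluded from the family (it is the label source).  Classifiers are
scikit-learn: depth-20 decision tree, logistic regression, RBF-SVM (the
latter two behind a standardising scaler), all seeded.  For kernel-SVM cost
the harness subsamples training rows (default 4,000 for the raw-feature
arms and 8,000 for the higher-dimensional CNN-feature stage, seeded); test
rows are never subsampled.

## Evaluation protocol

Stress is the positive class: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/total; for balanced test
sets accuracy equals the mean of sensitivity and specificity.  Splits are
subject-wise (reference geometry 20/3/3 of 26) and seeded; held-out
subjects contribute nothing to any training artifact — normalisation
statistics, balancing, weights — which the tests check byte-for-byte.

The streaming harness consumes a recording in 1 s chunks through the causal
4–30 Hz filter with state carried across chunks, so streamed CNN
predictions are identical to batch predictions on the causally filtered
signal.  Wall time per chunk is *reported, never asserted* against any
fixed number (it is hardware-bound); the only asserted property is the
ordering CNN < feature-ML on the same machine, with the feature arm
represented by the RBF-SVM pipeline (tree/logistic predictions are
near-instant in this vectorised implementation, so a kernel method is the
meaningful conventional-path comparator).

The four-experiment ladder on one cohort: (1) whole-session features +
session labels, (2) window features + session labels, (3) window features +
AAS labels (AAS feature excluded), (4) raw windows + AAS labels + CNN;
plus retraining the three classifiers on the CNN's 1,320 flattened
features.

## Synthetic test bed

The study data (26 subjects, two 5-min conditions, 500 Hz, 19 channels) is
not public, so the generator emulates its geometry with controllable
physiology:

* Each channel is a sum of band-limited oscillations — delta 0.5–4 (20 µV),
  theta 4–8 (10 µV), alpha 8–12 (20 µV), beta 13–30 Hz (5 µV); a band of
  amplitude A carries power A²/2 — plus 1/f background noise (default
  exponent 1, 10 µV RMS).  Band oscillations are mixtures of 8 random
  in-band sinusoids, except the *shared prefrontal alpha generator*, which
  is a single narrowband oscillation per subject: the resting alpha rhythm
  is narrowband, and a constant-envelope shared waveform keeps the planted
  Fp2/Fp1 power ratio defined at the 40 ms scale (a broadband shared
  envelope has deep nulls where the asymmetry is momentarily unmeasurable
  by any method).
* The asymmetry is planted only on Fp1/Fp2: amplitudes are scaled by
  1/√r and √r so the Fp2/Fp1 amplitude ratio is r and the expected AAS is
  2 ln r.  Defaults: r = 2 in the relax session, r = 0.5 in the stress
  session.
* Sessions are internally heterogeneous: 10% of 200 ms sub-epochs carry the
  *opposite* condition's asymmetry, emulating the instantaneous nature of
  stress patterns (a session-level label is then the truth for most, not
  all, of its windows).  This is what separates per-window AAS labels from
  session labels in the experiment ladder.
* Everything is deterministic given (seed, subject index) via independent
  child streams of one master seed.

What passing tests show: the pipeline recovers planted asymmetry (≥ 80% of
windows get their condition's label at ratio 2 under default noise), the
CNN generalises across subjects on strongly asymmetric cohorts
(ratio 4/0.25, 5 µV noise), label permutation collapses it to chance, and
the ladder ordering CNN ≥ AAS-labeled ML ≥ session-labeled ML holds.  What
they do not show: performance on real EEG — the generator has no artifacts,
no non-stationarity beyond the planted transients, no volume-conduction
structure, and its amplitudes are conventional round numbers.  The headline
accuracies here characterise the synthetic test bed, not any clinical
capability.

## Problem sizes used in CI-style runs

Experiments are run scaled down to single-CPU scale as a package choice:
cohorts of 14 subjects (split 10/2/2) with 48 s per condition for the CNN
experiments (2,400 windows/subject, ≈ 24,000 balanced training windows),
2–4 subjects × 30–60 s for labeling-only checks, and the full 26 × 10-min
geometry only for window-count arithmetic.  The acceptance script
(`scripts/acceptance.py`) re-runs all of it from scratch under one seed.

## Known limitations

* The AAS formula, alpha band edges (8–12 here), threshold (0) and power
  estimator are unstated in the source protocol; all are isolated in
  `AasConfig` and the defaults above are the package's convention.
* EDF support is plain EDF (16-bit): annotations and subject identity ride
  in a JSON sidecar, not an EDF+ annotation channel.
* The per-window cold-start feature estimator is intentionally lossy; it is
  not a recommendation for offline spectral analysis (use the Welch batch
  mode there).
* Latency numbers depend entirely on the host; only orderings measured in
  the same process are meaningful.
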