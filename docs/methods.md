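# Methods

## Problem and pipeline

The package classifies short beat-to-beat (RR) interval sequences into
three cardiac rhythms — atrial fibrillation (AFIB), atrial flutter (AFL)
and normal sinus rhythm (NSR) — using only the rhythm information that
survives QRS detection, i.e. no ECG morphology. The processing chain is:

1. **Cohort**: one labelled RR block per patient (10 s of ECG ≈ 8–30
   beats, depending on rate).
2. **QRS detection** (when starting from sampled ECG): an energy detector
   converts each record to an RR block.
3. **Patient-disjoint partitioning**: blocks are dealt per class into 10
   parts; a patient appears in exactly one part, so no fold ever trains
   and tests on the same person.
4. **AFL scrambling**: each part's AFL blocks are concatenated in three
   independently permuted orders (AFLSC), tripling the AFL data. This
   works because the 100-beat window is longer than any single block, so
   a different patient order produces different windows.
5. **Detrending**: the slow trend of each concatenated class-per-part
   sequence is removed by a Gaussian-process smoother.
6. **Round-robin windowing**: a 100-sample window slides one sample at a
   time over the circularly extended sequence, yielding exactly one
   vector per sample.
7. **Puncturing**: AFIB and AFLSC vector sets are thinned to the part's
   NSR count by removing equidistant vectors, so training folds are
   exactly class-balanced.
8. **Classification**: a 1D residual network is trained per fold; metrics
   come from pooled confusion matrices, a binary
   arrhythmia/non-arrhythmia collapse, and one-vs-rest ROC curves.

## Synthetic cohort generator

The generator exists so the full pipeline is exercisable and testable
without any external recording. It emulates the *rhythm statistics* that
distinguish the classes, not ECG physiology:

* **NSR** — base interval 60/`mean_rate` (default 70 bpm) modulated by a
  0.25 Hz sinusoid of fractional depth 0.04 (respiratory sinus
  arrhythmia) plus Gaussian jitter with CV 0.02.
* **AFIB** — i.i.d. Gamma-distributed intervals at a mean ventricular
  rate of 185 bpm (the fast, chaotic 150–220 bpm regime) with CV 0.25
  (floored at 0.15). Gamma was chosen because it is positive,
  right-skewed and parameterized directly by mean and CV. Draws are
  floored at 0.25 s, the ventricular refractory limit — shorter intervals
  are not physiological and no detector could resolve them.
* **AFL** — the atrium cycles at `atrial_cycle` = 0.2 s (300 bpm, inside
  the 240–360 bpm flutter band) and the AV node conducts every 2nd, 3rd
  or 4th beat, so ventricular intervals are k·0.2 s with k following a
  Markov chain (stay probability 0.7) plus 2% measurement jitter. With
  zero jitter the distinct interval values are exactly the conduction
  multiples.

Beats are emitted until cumulative time exceeds the block duration
(default 10 s); the final partial interval is dropped. Identical seeds
give bitwise-identical cohorts.

What the generator does **not** model: P/flutter-wave morphology, ectopy,
detection artifacts, rate drift within a block, inter-patient rate
distributions, or any overlap regime in which AFIB and AFL ventricular
statistics become hard to separate. Classes are therefore *designed* to
be separable; a high accuracy on synthetic folds validates the data
engineering and the learner's mechanics, not clinical performance.

The toy ECG synthesiser places a narrow Gaussian R spike (σ = 12 ms) plus
smaller P/T bumps at each beat time and returns the ground-truth beat
sample indices, which makes detector recall/precision measurable exactly.

## QRS detection

A classic energy detector: band-pass 5–15 Hz (2nd-order Butterworth,
zero-phase), squared derivative, 150 ms moving-window integration, peak
picking with a 0.2 s refractory distance and an adaptive threshold at 20%
of the 95th percentile of candidate peak heights, followed by refinement
to the raw-trace extremum within ±100 ms. The trace is zero-padded by
0.5 s on both sides so boundary beats are not lost to filter transients.
Flat signals return an empty result with a warning. Detection errors are
deliberately not filtered out of the RR streams: a usable rhythm
classifier must tolerate them, so they stay in the data.

## Gaussian-process detrending

The trend is the posterior mean of a zero-mean GP regression on beat
index with a Matérn ν = 5/2 kernel (the third-order member of the
Ornstein–Uhlenbeck family); the detrended signal is the residual. The
series is mean-centred before the fit, so a constant sequence detrends to
exactly zero and the output mean is driven toward zero.

Hyperparameters (all configurable): lengthscale 25 beats; process std
defaulting to std(rr); noise std defaulting to 0.1·std(rr). The smoother
operates on beat index, not cumulative time, because the filter acts on
the RR signal directly. With these fixed (or input-scaled)
hyperparameters the operator is linear and acts as a low-pass trend
estimate: a ±1-beat alternating component passes through with > 90% of
its variance.

Two equivalent computation paths: an exact dense solve (Cholesky on the
n×n kernel matrix) for n ≤ 2000, and an O(n) state-space path — the
Matérn-5/2 process is the output of a third-order linear SDE, so a Kalman
filter plus Rauch–Tung–Striebel smoother computes the same posterior mean.
Agreement is at the 1e-13 relative level on overlapping sizes; the test
suite enforces 1e-6.

## Partitioning details

* Parts are dealt round-robin per class after a seeded shuffle of the
  patient order, so per-class part sizes differ by at most one block.
  The reference per-part counts depend on a private ordering of the
  original cohort and are not reproduction targets; the *rules* (3×
  scrambling, puncture-to-NSR, one-window-per-sample) are, and they are
  verified against the published count tables.
* Puncturing removes indices ⌊j·N/k⌋ for j = 0..k−1 when k of N vectors
  must go; gaps between removed indices differ by at most one and the
  result is deterministic.
* Scrambling draws `n_perms` independent uniform permutations; the
  unscrambled order is not additionally included (forced by the exact 3×
  interval counts). The identity permutation may occur by chance.
* Windows deliberately span patient boundaries: with ~8–30 beats per
  block and a 100-beat window, every vector mixes several patients of the
  same class and part.

## The residual network

Implemented directly in numpy (forward and backward passes, float32).
Architecture: three residual blocks with 64/128/128 filters, kernel sizes
8/5/3 inside each block, batch-norm + ReLU after each convolution, an
additive shortcut per block (1-wide convolution + batch-norm when channel
widths change), global average pooling, dense softmax. Training:
categorical cross-entropy, Adam (step 1e-3, β = 0.9/0.999), batch 16,
50 epochs in the full protocol. Inputs are standardised by the training
set's global standard deviation. Batch-norm running statistics use
momentum 0.9 so evaluation-mode statistics converge within the short
training runs used here.

Per fold, the weights of the epoch with the **highest test accuracy** are
retained (earliest epoch on ties). This model-selection-on-test rule is
part of the replicated protocol; it is optimistically biased, and the
package reproduces it rather than fixing it (see README).

Determinism: a single seed drives initialisation and batch shuffling;
repeated runs on the same machine/backend give identical histories.

## Evaluation algebra

Confusion matrices are stored true×predicted in class order (AFIB, AFL,
NSR). Per class: TP is the diagonal entry, FN the rest of the true row,
FP the rest of the predicted column, and TN the **sum of the other
diagonal entries** — the convention the reference result tables follow
(the standard multiclass TN, total − row − col + TP, is computed
alongside; the two differ by exactly the confusions among the other
classes). ACC = (TP+TN)/(TP+TN+FP+FN), SEN = TP/(TP+FN),
SPE = TN/(TN+FP), reported in percent rounded half-away-from-zero to two
decimals. Zero denominators yield missing values, never zeros.

The binary collapse merges AFIB+AFL into an arrhythmia class against NSR.
Both orientation conventions (which class the sensitivity refers to) are
emitted with explicit labels because published presentations disagree
with each other.

ROC: one-vs-rest curves per class via threshold sweep (scikit-learn
`roc_curve`), micro average by pooling all (score, indicator) pairs,
macro average by averaging per-class TPR on a 1001-point FPR grid; areas
by trapezoidal integration.

## Scaled experiment sizes

The full protocol (≈4000 patients, 10 folds × 50 epochs) is a
multi-hour training exercise. The package's own verification runs are
scaled down, keeping every structural property intact:

* acceptance script: 40 blocks/class (≈300–400 vectors per class per
  fold side), 10 parts, folds 1–2, 10 epochs;
* test suite: 30 blocks/class, fold 1, 8 epochs;
* permutation null: 3 runs of 3 epochs with labels shuffled and a
  class-balanced test side (on an imbalanced test side "chance" is the
  majority share, not 1/3, so the null is evaluated balanced);
* capacity check: 32 vectors memorised to 100% training accuracy.

On the well-separated default cohort the scaled runs reach ≥ 95%
selected test accuracy; the null lands in the chance band around 1/3.

## Known limitations

* The synthetic classes are cleanly separable by construction; no claim
  about real-ECG accuracy follows from the synthetic experiments.
* The detrending hyperparameters of the original filter are not
  recoverable from its description; the defaults above are declared, not
  inferred.
* The wavelet-based reference QRS detector is replaced by an energy
  detector; downstream stages are detector-agnostic.
* Best-test-epoch model selection leaks the test fold into model choice;
  reported fold accuracies are upper bounds on generalisation.
* The numpy trainer is single-threaded and CPU-bound; it is sized for
  correctness and auditability, not throughput.
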