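# Methods

This note documents the models, parameter choices, and numerical details
behind `ffrbio`, and states what the synthetic data can and cannot show.

## Stimulus synthesis

The evoking stimulus is a 250-ms vowel-like source-filter synthesis at
20 kHz.  The instantaneous F0 follows a half-cosine trajectory through
three anchors — onset 105 Hz, dip 89 Hz at the temporal midpoint, offset
110 Hz — chosen for smoothness and differentiability; the exact
inter-anchor shape is a free design choice, as is the 250-ms duration
(matching the response analysis window).  An alternate anchor preset
(101/87/107 Hz) is selectable via `F0_PRESETS`.  The source is a sawtooth
whose phase integrates the F0 track; formants at 330 and 2500 Hz are
imposed by two-pole resonators (bandwidths 80 and 150 Hz, unity gain at
resonance), and 10-ms raised-cosine ramps bound the waveform.  The
per-sample F0 trajectory is returned as ground truth for the
pitch-tracking code.

## Synthetic response model

Each trial (µV) is

```
x(t) = gain · [ env(t) + idio(t) ± fine(t) ](t − latency) + noise(t) [+ artifact(t)]
```

* **env** — polarity-invariant envelope-following response:
  sin φ(t) + 0.3 sin 2φ(t) with φ the stimulus F0 phase; RMS 0.15 µV.
* **fine** — fine-structure/cochlear-microphonic-like component equal to
  the stimulus waveform (RMS 0.15 µV) whose *sign follows trial
  polarity*, so a balanced polarity pair cancels it exactly.
* **idio** — the biometric signal: the harmonic source re-filtered into
  nine 100-Hz channels (80–980 Hz, 4th-order Butterworth, zero-phase),
  mixed by a per-subject unit-norm signature weight vector and
  renormalized to the session's signature strength (base 0.12 µV RMS,
  ±10% per-subject jitter; second session scaled ×1.5 — the maturation
  effect under study).
* **latency / gain** — per-subject constants (uniform 5–9 ms;
  gain 1 ± 0.05), secondary idiosyncratic cues.
* **noise** — Gaussian, sd 2.8 µV, white by default, i.i.d. across
  trials.  An AR(1) pole (`noise_ar1`) is available to color the noise
  1/f-like.
* **artifacts** — with probability 0.10 per trial, a 100-ms triangular
  excursion of 45–80 µV peak placed inside the response window, so the
  amplitude criterion always detects it.

Polarity alternates strictly (+, −, +, …).  Epochs span −50 to +250 ms.

### Why these amplitudes

The defaults were fixed once, as the package's study conditions, to make
the generator exhibit the qualitative regime the analysis targets:
single-trial SNR far below one; recognition accuracy barely above chance
for single trials and climbing steeply with averaging size; a reliable
second-session advantage at N = 50; and RMS-SNR medians that grow
monotonically with averaging size.  These goals constrain the
signature-to-in-band-noise ratio and the noise spectrum jointly: strongly
1/f-colored noise leaves so few effective samples in the 50-ms baseline
that per-average SNR estimates become too variable for the monotonicity
property, which is why the default noise is white.  The main realism
costs, stated plainly: the grand-average SNR at 1500 trials comes out
near 2.8 (adult-like) rather than the ≈1.1–1.2 typical of infant
recordings, recognition at N ≥ 50 is nearly perfect rather than merely
good, and white noise understates the low-frequency dominance of real
EEG.  Passing tests therefore demonstrate that the *pipeline* recovers
planted structure under realistic-order magnitudes — not that real infant
FFRs would yield these effect sizes.

Other things the generator does not emulate: brainstem generator
physiology, trial-to-trial latency/amplitude drift, electrode or session
artifacts beyond the amplitude criterion, and any F0-encoding difference
between sessions (both sessions share env; only the signature matures).

## Preprocessing

* **Rejection**: a trial is kept when every post-onset sample lies
  strictly within ±40 µV of its own baseline mean (the mean of the 50-ms
  pre-stimulus segment).  A global-baseline variant sits behind a flag.
  Rejection is idempotent and preserves order and labels.
* **Sub-averaging**: trials are reordered into a strict +/− interleave
  (surplus trials of the majority polarity are dropped), then a moving
  window of `averaging_size` trials advances in steps of 2 (one polarity
  pair per shift).  Even window sizes are exactly polarity-balanced; odd
  sizes (e.g. the standard N = 5) are balanced to within one trial,
  which is the best achievable.  Size 1 passes raw trials through.
* **Slicing**: Hann-windowed 20-ms slices with 15-ms overlap over the
  0–250 ms response, zero-padded to 512 points (bin spacing ≈ 39 Hz),
  magnitudes converted as 20·log₁₀(|X| + 10⁻¹²), bins restricted to
  80–980 Hz (23 bins).  A 250-ms response yields 47 slices.
* **Band channels**: half-open bins `low ≤ f < high`; the standard grid
  is the nine 100-Hz channels from 80 to 980 Hz.

## Codebook and HMM

The codebook is k-means (k-means++ init, 5 restarts by default, squared
Euclidean on dB slice vectors).  One codebook is fitted per
(session × averaging size × fold × band) on training-partition slices
*pooled across subjects* — pooling keeps log-probabilities comparable
across subject models; fitting strictly on training folds prevents
leakage (the training partition's hash is recorded on the codebook, and
fold splits are asserted disjoint at run time).

The per-subject model is a 3-state, 150-symbol discrete **Bakis HMM**:
`transmat[i, j] ≠ 0` only for j ∈ {i, i+1, i+2}; all initial probability
on state 1.  Training is Baum–Welch with scaled forward–backward
recursions, vectorized across the equal-length emission sequences:

* EM stops when the relative log-likelihood improvement drops below 1e-4
  or after 100 iterations; 5 seeded restarts by default (best final
  likelihood kept).  Emission rows are initialized from global symbol
  frequencies with seeded jitter.
* The Bakis zero mask is preserved exactly (zero transitions have zero
  expected counts), and the per-iteration log-likelihood is
  non-decreasing — both verified against brute-force path enumeration
  and an independent HMM library in the tests.
* After convergence an emission floor of 1e-6 is mixed in and rows
  renormalized so held-out sequences containing unseen symbols score
  finitely.  Flooring after (not during) EM keeps the likelihood ascent
  exact.
* Scoring is the exact forward log-probability (scaled recursion; no
  length normalization — sequences share a length within an experiment).

## Experiments

* **Cross-validation**: contiguous 2-fold splits of the accepted trials
  (k is configurable; 2 folds mirror 750-trial training halves of 1500
  accepted trials at full scale).  `training_size_trials` caps the
  training partition (default 750; `None` = use all).
* **Recognition score**: mean held-out log-probability per model,
  averaged over test sequences and folds — one score per
  subject × session × size × band.
* **Permutation null**: per permutation, accepted trials are pooled
  within session and reassigned to subject labels uniformly at random
  (counts preserved), and the *entire* procedure — sub-averaging,
  codebook, HMM training, scoring — is rerun.  100 permutations per
  model by default.  The p-value per (session, size) is the proportion
  of session/size-averaged chance scores ≥ the averaged truth score, so
  p lies exactly on {0, 0.01, …, 1}.
* **Discrimination**: argmax classification (ties → lowest subject
  index, logged) and one-vs-rest ROC per subject using each sequence's
  log-probability under that subject's model as the decision score.  The
  reported area is the macro-average of the exact per-subject
  trapezoidal AUCs; the macro-averaged curve (common FPR grid, 101
  points) is kept for display.  Area banding uses strict thresholds
  excellent > 0.9 ≥ good > 0.8 ≥ fair > 0.7 ≥ poor > 0.6 ≥ bad.
  Raw log-probabilities (not calibrated posteriors) feed the threshold
  sweep.
* **Band profile**: the recognition procedure per 100-Hz channel at one
  averaging size (default 50), with a band-specific codebook; scores and
  per-band ROC/accuracy summaries are exported as tidy tables for
  external mixed-effects modeling (deliberately out of scope here).

## F0 metrics

Contours use sliding 40-ms windows with 30-ms overlap.  Within a window
the normalized cross-correlation of the (mean-removed) segment with its
lagged self is maximized over lags corresponding to 80–120 Hz (bracketing
the stimulus anchors), with parabolic interpolation around the peak for
sub-sample lag precision; F0 = fs / lag, and the peak height (clipped to
[0, 1]) is the periodicity strength.  F0-strength is the mean peak across
windows; stimulus–response correlation is Pearson's r between the two
contours on the same window grid (optional coarse latency compensation,
default none); SNR is RMS(0–250 ms) / RMS(−50–0 ms) of the average of up
to 1500 accepted trials.  Estimates are scale-invariant.

## Orchestration and reproducibility

All randomness descends from one master seed through
`numpy.random.SeedSequence` keys of the form
(master_seed, stage-tag, session, size, fold, band, subject), so every
codebook, restart, permutation, and cohort is independently reproducible.
`run_full_study` executes simulate → recognize → permute → ROC → bands →
F0 from a declarative YAML config, writes tidy CSVs plus a JSON manifest
(config hash, seeds, version, output registry), and is byte-deterministic
across reruns of an identical config.  Cohorts persist to a single HDF5
container (or a `.npy` + JSON fallback layout); the stimulus exports as
WAV with its F0 ground-truth CSV.

## Problem sizes used by the tests and acceptance script

Reduced scales, chosen as the package's own smoke conditions:

* factorial run: 16 subjects × 2 sessions × sizes {1, 5, 50, 200} at
  600 trials/subject (600 rather than 300 because, after ~10% artifact
  rejection and polarity re-balancing, a 2-fold split must still contain
  at least one 200-trial window per partition);
* permutation: 3 subjects, one session, 240 trials, size 50,
  100 permutations;
* session-effect replication: 20 seeded replicates of 4 subjects ×
  300 trials at size 50; ROC-monotonicity: 10 replicates at 600 trials;
* smoke settings reduce k-means restarts to 1, HMM restarts to 2 (1 for
  permutations), EM iterations to 50, and cap codebook training slices
  at a seeded subsample of 20 000.  Full-scale defaults remain 5/5/100
  and uncapped.

## Known limitations

* The response model is phenomenological; recognition performance on it
  upper-bounds nothing about real infants.
* One codebook per experiment pooled across subjects is a design choice
  (standard in vector-quantization speaker recognition); a per-subject
  codebook mode exists but makes scores less comparable.
* No end state in the HMM; sequences share a fixed length by
  construction, so termination modeling is unnecessary.
* Mixed-effects modeling and post hoc contrasts on the exported score
  tables are intentionally left to external statistical software.
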