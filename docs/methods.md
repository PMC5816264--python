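# Methods

## Problem and pipeline

Myoelectric control of hand prostheses and rehabilitation exoskeletons must
distinguish gestures that recruit nearly the same forearm muscles (e.g. fist
vs. spherical vs. cylindrical grasp). Because those gestures produce
overlapping clusters in feature space, conventional classifiers trained with
equal per-class sample counts struggle. `myosweep` implements the full study
of how re-allocating per-class sample counts in a **constant-size training
set** changes per-gesture and overall recognition, from raw multichannel
surface EMG to the class-separability statistic:

1. **Synthetic sEMG** (`synth`) — a labeled 6-channel dataset whose gesture
   classes have controllably similar muscle-activation patterns.
2. **Preprocessing** (`preprocess`) — 10–400 Hz fourth-order zero-phase
   Butterworth band-pass plus a 50-Hz notch; movement onset by windowed
   integrated EMG (IEMG) thresholding; extraction of the 4-s active segment.
3. **EMD features** (`emd`, `features`) — empirical mode decomposition of
   each channel into up to 8 intrinsic mode functions (IMFs); zero-crossing
   count (ZC) and Wilson amplitude (WAMP) of the first 4 IMFs over a 2-s
   window, interleaved per channel (8 values) and concatenated over 6
   channels (48 values per trial).
4. **GA-tuned SVM** (`classifier`) — RBF-kernel C-SVM with penalty `c` and
   kernel width `g` selected by a seeded genetic algorithm maximizing
   stratified 5-fold cross-validated accuracy (hard cap 100 generations).
5. **Proportion sweep** (`sweep`) — per gesture of interest, training counts
   (6, 10, 16, 20, 26, 30, 36, 42) out of a constant 52, the other two
   gestures sharing the remainder equally; 42/18 candidate/test split per
   gesture; mean ± SD over repeated training resamples; uniform 17/17/17
   (total 51) baseline.
6. **Separability** (`distance`) — pairwise half-quadratic Mahalanobis-type
   index d(i,j) = ½ Δμᵀ[(Σᵢ+Σⱼ)/2]⁻¹Δμ and the D_out summary (mean over
   classes of each class's minimum distance to any other class), compared
   between assignments with paired resamples.

## Signal model of the generator

Each stored trial is 1 s of rest, an `active_duration` (default 4 s)
activation, and 0.5 s trailing rest at 1 kHz. The carrier is Gaussian white
noise band-pass filtered to 15–450 Hz (fourth order) and normalized to unit
RMS — the standard surrogate for the interference-pattern sEMG — multiplied
by a trapezoidal envelope with 0.25-s rise/fall. Channel `c` of gesture `k`
is scaled by `A · w_k[c] · j_trial · j_chan[c]`, where `A` sets the
signal-to-noise ratio of a weight-1 channel (default 15 dB over the
unit-variance baseline noise present everywhere), `w_k` is the gesture's
6-vector of activation weights, and the jitters are lognormal with
sd `0.1 × difficulty_scale`.

Two generator choices deserve note:

* **Similarity knob.** Within a group, gesture 1 keeps the base weight
  vector; gestures 2 and 3 add a `(1 − similarity)`-scaled perturbation
  drawn once per gesture from a uniform cube of half-width 0.5, clipped to
  [0, 1]. Similarity 1 gives identical activation patterns; the default 0.85
  is a modelling choice for "similar" gestures — no measured value exists
  for how alike real grasp types are.
* **Per-channel amplitude jitter.** Besides the per-trial scalar jitter, each
  channel gets an independent lognormal factor of the same sd. A purely
  trial-wide scalar would leave the inter-channel activation *pattern*
  noise-free, and a margin classifier would separate even near-identical
  gestures almost perfectly; independent per-muscle effort variability is
  the physiologically expected confound and produces the mid-range
  accuracies (60–80 %) at which training-set composition matters.

What the generator does **not** emulate: motor-unit firing statistics and
recruitment, electrode placement, inter-channel crosstalk, fatigue drift,
inter-subject variability, and force levels. Passing tests therefore show
that the pipeline's *mechanics* and the proportion phenomenon hold on a
realistic amplitude/spectrum model, not that the specific accuracies
transfer to human recordings.

## Numerical and algorithmic choices

* **IEMG.** The textbook window average of raw samples vanishes for a
  zero-mean signal, so the onset statistic is the mean of the **rectified**
  samples. Onset is the first 256-ms window (50-ms overlap) whose
  across-channel maximum IEMG exceeds a threshold; the default threshold is
  rest-segment mean + 3 SD of the windowed IEMG pooled over the dataset.
* **EMD.** Extrema by strict sign change of the first difference (plateaus
  take their midpoint); envelopes are natural cubic splines through the
  extrema with the two nearest extrema mirrored across each signal endpoint
  (anti-swing boundary). Sifting stops when the Cauchy criterion
  `Σ(h_prev−h_cur)²/Σh_prev² < 0.2` is met **and** the iterate's extrema and
  zero-crossing counts differ by ≤ 1 (cap 50 iterations); decomposition
  stops at a monotone remainder, fewer than 3 extrema, or 8 IMFs. Fewer than
  4 IMFs pad the feature vector with zeros.
* **WAMP.** Implemented in the waveform-length form Σ|xₖ − xₖ₋₁| over the
  feature window (the form the study defines), with an optional threshold
  that drops small differences; the classical thresholded *count* is
  available separately (`willison_amplitude_count`).
* **IMF selection.** "Contribution ratio" is read as pooled energy fraction;
  the shortest IMF prefix reaching 90 % cumulative energy is selected, and
  the pipeline default `fixed_k = 4` pins the reference configuration.
* **ZC deadband** defaults to 0 (every strict sign change counts); zeros are
  signless and never contribute.
* **Feature scaling.** Features are z-scored per dimension inside the model
  pipeline, fit on the training split only — RBF kernels need comparable
  scales, and ZC counts and WAMP sums differ by orders of magnitude.
* **GA.** Population 20, binary tournament, uniform crossover at 0.8,
  per-gene Gaussian mutation (sd 1.0 in log2 units) at 0.1, elitism 1,
  search box log₂c ∈ [−5, 15], log₂g ∈ [−15, 3], early stop after 15
  stagnant generations under the 100-generation cap. Fitness values are
  memoized per (c, g).
* **Sweep repeats** are independent training-set resamples from the
  candidate pool with the test set fixed; SDs are over those resamples.
  `retune="step"` re-runs the GA per resample; `retune="global"` tunes once
  on a uniform draw and reuses the parameters (the fast path used for
  scaled-down runs).
* **Ridge.** With 48 dimensions and as few as 5 training samples per class,
  sample covariances are singular; `ridge = 1e-3 ×` mean diagonal of the
  pooled covariance is added before inversion. The distance uses an exact
  linear solve; a separately coded explicit-inverse oracle guards it in the
  tests.
* **Peak selection.** Argmax of mean overall accuracy; ties break toward the
  most uniform counts, then the lowest step.
* **Determinism.** One master seed; per-trial generator substreams are keyed
  by (gesture index, trial index), and sweep/distance seeds are spawned via
  `SeedSequence`, so every artifact is bit-reproducible from the config.

## Problem sizes used in the shipped checks

The full protocol (3 gestures × 60 trials, 4-s activations, 8 schedule
steps) runs in `scripts/acceptance.py` with 5 training resamples per step, a
single global GA tune, and 10 paired resamples for the distance comparison.
The test suite exercises the two sweep phenomena at a reduced scale chosen
to keep the whole suite fast: 3 gestures × 30 trials (21 candidates / 9 test
per gesture), 2-s activations with a 1-s feature window on the first 4 IMFs,
4 schedule steps at constant total 24, 5 resamples, GA population 10 × ≤ 20
generations tuned once per dataset, 10 master seeds. The phenomena (monotone
recall-vs-count, non-uniform peak ≥ uniform baseline for a harder gesture)
are scale-stable in this range.

## Known limitations

* The synthetic generator's realism caveats above; absolute accuracies and
  D_out values are not comparable to human-subject numbers.
* D_out computed from small per-class samples mixes the population effect of
  re-assignment with small-sample covariance bias; the package measures the
  empirical quantity and asserts no direction for it.
* The GA is a standard real-coded implementation; no claim of optimality of
  (c, g), only of reproducibility and non-decreasing best-so-far fitness.
* One pooled synthetic "subject"; per-subject replication is left to the
  caller (loop over master seeds).
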