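# myosweep

**Training-set proportion effects on surface-EMG recognition of hand
gestures with similar muscle activities.**

Gestures such as fist, spherical, and cylindrical grasping (or finger, key,
and tape pinch) are driven by nearly identical forearm-muscle contraction
patterns, so their surface electromyogram (sEMG) feature clusters overlap
and conventional classifiers — trained with equal samples per class —
confuse them. `myosweep` is a reproducible pipeline for studying a simple
remedy: keep the training set at a constant size but **re-allocate how many
samples each gesture contributes**, and measure how per-gesture recall,
overall accuracy, and inter-class separability respond.

The package is aimed at researchers in myoelectric control and
rehabilitation engineering who want a tested, seeded implementation of the
whole chain:

* a **synthetic 6-channel sEMG generator** (band-limited Gaussian carrier,
  trapezoidal activation envelope, controllable between-gesture similarity)
  standing in for human recordings;
* **preprocessing**: 10–400 Hz fourth-order zero-phase Butterworth band-pass
  + 50-Hz notch, movement onset by windowed integrated-EMG (IEMG)
  thresholding, 4-s active-segment extraction;
* **empirical mode decomposition (EMD)** into intrinsic mode functions
  (IMFs), with zero-crossing (ZC) and Wilson amplitude (WAMP) features of
  the first 4 IMFs per channel — a 48-dimensional vector per trial
  (2 features × 4 IMFs × 6 channels);
* a **GA-tuned RBF-SVM**: penalty `c` and kernel width `g` searched in log₂
  space by a genetic algorithm (≤ 100 generations) maximizing stratified
  5-fold cross-validated accuracy;
* the **proportion sweep**: per gesture of interest, training counts
  (6, 10, 16, 20, 26, 30, 36, 42) out of a constant total of 52, the other
  two gestures sharing the remainder, against a uniform 17/17/17 baseline
  (42 candidate + 18 test trials per gesture);
* **class separability**: the pairwise Mahalanobis-type index
  d(i,j) = ½ Δμᵀ[(Σᵢ+Σⱼ)/2]⁻¹ Δμ and its D_out summary — the mean over
  classes of each class's minimum distance to any other class.

See `docs/methods.md` for the model, parameter meanings, and numerical
choices.

## Worked example

```python
from myosweep.synth import (DEFAULT_GRASP_WEIGHTS, SimulationConfig,
                            make_similar_gesture_group, simulate_dataset)
from myosweep.preprocess import FilterSpec
from myosweep.pipeline import preprocess_dataset, features_from_segments
from myosweep.config import EMDConfig, FeatureConfig
from myosweep.classifier import GAConfig
from myosweep.sweep import (AssignmentSchedule, SplitSpec, run_sweep,
                            find_peak)

specs = make_similar_gesture_group(
    DEFAULT_GRASP_WEIGHTS, ["fist", "spherical", "cylindrical"],
    similarity=0.85, rng_seed=0)
cfg = SimulationConfig(active_duration=2.0, post_rest=0.25,
                       trials_per_gesture=30, seed=0)
trials, manifest = simulate_dataset(specs, cfg)          # 90 trials
segments, thr = preprocess_dataset(trials, FilterSpec(),
                                   active_duration=2.0, rest_duration=1.0)
feats = features_from_segments(segments, EMDConfig(max_imfs=4),
                               FeatureConfig(feature_window_samples=1000))

schedule = AssignmentSchedule(("fist", "spherical", "cylindrical"),
                              ((4, 10, 10), (8, 8, 8), (12, 6, 6),
                               (18, 3, 3)), total=24)
result = run_sweep(feats, schedule, SplitSpec(21, 9, seed=0),
                   GAConfig(population_size=10, max_generation=20),
                   repeats=5, master_seed=0, retune="global",
                   uniform_per_gesture=8)
for step in result.per_step:
    print(step.counts["fist"], round(step.recall_mean["fist"], 2),
          round(step.overall_mean, 2))
print("uniform:", round(result.uniform_baseline.overall_mean, 2))
print("peak:", find_peak(result))
```

Output (seed 0):

```
4 0.02 0.57
8 0.58 0.63
12 0.87 0.5
18 1.0 0.34
uniform: 0.64
peak: (1, {'fist': 8, 'spherical': 8, 'cylindrical': 8})
```

Reading: the fist gesture's recall climbs from 2 % to 100 % as its share of
the constant-size training set grows from ~17 % to 75 %, while the overall
accuracy peaks at an intermediate assignment — exactly the trade-off the
proportion sweep is designed to expose. (This example runs the scaled-down
conditions, 30 trials and 2-s activations, so it finishes in ~10 s; the
full-protocol numbers come from the acceptance script below.)

A command-line interface mirrors the stages
(`myosweep simulate | extract | tune | sweep | distance | distance-compare |
report | run-all`), e.g.:

```bash
myosweep run-all --out runs/demo --seed 7
myosweep report --result runs/demo/sweep_result.tsv --out curves.png
```

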