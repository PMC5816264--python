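"""Synthetic multichannel surface-EMG generator.

Emulates a recording protocol in which a subject repeats hand gestures that
share nearly identical forearm-muscle activation patterns: each stored trial
contains a rest bookend, a sustained activation, and a short trailing rest.
The carrier is band-limited Gaussian noise (the standard surrogate for the
interference-pattern sEMG signal) amplitude-modulated by a trapezoidal
activation envelope; per-muscle relative activation is controlled by a
6-vector of weights per gesture, and the similarity between gestures in a
group is a single knob in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

N_CHANNELS = 6

#: default relative activations of the six forearm muscles for a grasping-
#: and pinch-like base gesture (order: FDS, PL, MB, EPI, ED, EPB analogue)
DEFAULT_GRASP_WEIGHTS = (0.8, 0.6, 0.5, 0.4, 0.7, 0.6)
DEFAULT_PINCH_WEIGHTS = (0.5, 0.7, 0.6, 0.8, 0.4, 0.6)


@dataclass(frozen=True)
class GestureSpec:
    """One gesture class: name, group, and per-muscle activation weights."""

    name: str
    group: str
    activation_weights: tuple[float, ...]
    difficulty_scale: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.activation_weights, dtype=float)
        if w.shape != (N_CHANNELS,):
            raise ValueError(
                f"activation_weights must have exactly {N_CHANNELS} entries, "
                f"got {w.shape}"
            )
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("activation weights must lie in [0, 1]")
        if w.max() <= 0:
            raise ValueError("at least one activation weight must be positive")
        if self.difficulty_scale <= 0:
            raise ValueError("difficulty_scale must be positive")
        object.__setattr__(self, "activation_weights", tuple(float(x) for x in w))


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol and signal-model parameters for one simulated session.

    ``rest_duration`` is the inter-trial rest of the protocol; only
    ``pre_rest`` seconds of rest are stored before the activation inside each
    saved trial (plus ``post_rest`` after it), so onset detection has a
    baseline to work against without storing the full idle period.
    """

    sampling_rate: float = 1000.0
    active_duration: float = 4.0
    rest_duration: float = 5.0
    pre_rest: float = 1.0
    post_rest: float = 0.5
    trials_per_gesture: int = 60
    carrier_band: tuple[float, float] = (15.0, 450.0)
    baseline_noise_sd: float = 1.0
    snr_db: float = 15.0
    similarity: float = 0.85
    amplitude_jitter_sd: float = 0.1
    envelope_ramp: float = 0.25
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.carrier_band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError(
                "carrier_band must satisfy 0 < low < high < sampling_rate/2"
            )
        if self.trials_per_gesture < 1:
            raise ValueError("trials_per_gesture must be >= 1")
        if self.active_duration <= 0:
            raise ValueError("active_duration must be positive")
        if self.pre_rest < 0 or self.post_rest < 0:
            raise ValueError("rest bookends must be non-negative")
        if not 0 <= self.similarity <= 1:
            raise ValueError("similarity must lie in [0, 1]")
        if self.baseline_noise_sd <= 0:
            raise ValueError("baseline_noise_sd must be positive")


@dataclass
class Trial:
    """One labeled multichannel recording (channels x samples)."""

    trial_id: str
    gesture: str
    signal: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_CHANNELS:
            raise ValueError(
                f"signal must be a {N_CHANNELS} x n_samples matrix, "
                f"got shape {self.signal.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def make_similar_gesture_group(
    base_weights: Sequence[float],
    names: Sequence[str],
    similarity: float,
    rng_seed: int,
    group: str = "gestures",
    difficulty_scales: Sequence[float] | None = None,
) -> list[GestureSpec]:
    """Build a group of 3 gestures with controllably similar weight vectors.

    The first gesture takes ``base_weights`` verbatim; the other two are the
    base plus a ``(1 - similarity)``-scaled perturbation drawn once per
    gesture from a zero-mean uniform cube of half-width 0.5, clipped to
    [0, 1]. At ``similarity=1`` all three vectors are identical and pairwise
    distances shrink (weakly monotonically) as similarity grows.
    """
    if not 0 <= similarity <= 1:
        raise ValueError(f"similarity must lie in [0, 1], got {similarity}")
    names = list(names)
    if len(names) != 3:
        raise ValueError(f"a similar-gesture group needs exactly 3 names, got {len(names)}")
    if len(set(names)) != 3:
        raise ValueError("gesture names must be unique")
    base = np.asarray(base_weights, dtype=float)
    # validate via a throwaway spec
    GestureSpec(names[0], group, tuple(base))
    if difficulty_scales is None:
        difficulty_scales = (1.0, 1.0, 1.0)
    if len(difficulty_scales) != 3:
        raise ValueError("difficulty_scales must have 3 entries")

    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    specs = [GestureSpec(names[0], group, tuple(base), float(difficulty_scales[0]))]
    for k in (1, 2):
        perturb = rng.uniform(-0.5, 0.5, size=N_CHANNELS)
        w = np.clip(base + (1.0 - similarity) * perturb, 0.0, 1.0)
        if w.max() <= 0:  # pathological clip; keep the strongest base muscle
            w[int(np.argmax(base))] = base.max()
        specs.append(GestureSpec(names[k], group, tuple(w), float(difficulty_scales[k])))
    return specs


def _trapezoid_envelope(n_active: int, ramp_samples: int) -> np.ndarray:
    env = np.ones(n_active)
    r = min(ramp_samples, n_active // 2)
    if r > 0:
        ramp = np.linspace(0.0, 1.0, r, endpoint=False)
        env[:r] = ramp
        env[n_active - r:] = ramp[::-1]
    return env


def _carrier_sos(config: SimulationConfig):
    lo, hi = config.carrier_band
    return sps.butter(4, (lo, hi), btype="bandpass", fs=config.sampling_rate,
                      output="sos")


def simulate_trial(
    spec: GestureSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    trial_id: str = "trial",
) -> Trial:
    """Simulate one trial: rest bookend, modulated activation, trailing rest.

    During the active window, channel ``c`` has RMS approximately
    proportional to ``activation_weights[c]``; the overall activation level
    is set so that a weight-1 channel reaches ``snr_db`` above the baseline
    noise floor. Trial-to-trial variability enters as one lognormal scalar
    per trial plus one lognormal factor per channel (per-muscle effort
    variability), both with sd ``amplitude_jitter_sd * difficulty_scale``.
    """
    fs = config.sampling_rate
    n_pre = int(round(config.pre_rest * fs))
    n_act = int(round(config.active_duration * fs))
    n_post = int(round(config.post_rest * fs))
    n = n_pre + n_act + n_post

    noise = rng.normal(0.0, config.baseline_noise_sd, size=(N_CHANNELS, n))
    carrier = rng.normal(size=(N_CHANNELS, n))
    jitter_sd = config.amplitude_jitter_sd * spec.difficulty_scale
    trial_jitter = float(np.exp(rng.normal(0.0, jitter_sd)))
    chan_jitter = np.exp(rng.normal(0.0, jitter_sd, size=N_CHANNELS))

    sos = _carrier_sos(config)
    carrier = sps.sosfiltfilt(sos, carrier, axis=1)
    carrier /= carrier.std(axis=1, keepdims=True) + 1e-300

    env = np.zeros(n)
    env[n_pre:n_pre + n_act] = _trapezoid_envelope(
        n_act, int(round(config.envelope_ramp * fs)))

    amp = config.baseline_noise_sd * 10.0 ** (config.snr_db / 20.0)
    weights = np.asarray(spec.activation_weights)
    gains = amp * trial_jitter * chan_jitter * weights
    signal = noise + carrier * env[None, :] * gains[:, None]
    return Trial(trial_id, spec.name, signal, fs)


def simulate_dataset(
    specs: Sequence[GestureSpec],
    config: SimulationConfig,
) -> tuple[list[Trial], pd.DataFrame]:
    """Simulate ``trials_per_gesture`` trials for every gesture spec.

    Returns the trials plus a manifest DataFrame (columns ``trial_id``,
    ``gesture``, ``group``, ``sampling_rate_hz``, ``path``). Per-trial random
    substreams are derived from ``config.seed`` keyed by (gesture index,
    trial index), so the dataset is deterministic and extensible without
    reshuffling earlier trials.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("need at least 2 gesture specs")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate gesture names in specs: {names}")

    trials: list[Trial] = []
    rows = []
    for gi, spec in enumerate(specs):
        for ti in range(config.trials_per_gesture):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(gi, ti))
            rng = np.random.default_rng(ss)
            trial_id = f"{spec.name}_{ti:03d}"
            trials.append(simulate_trial(spec, config, rng, trial_id=trial_id))
            rows.append({
                "trial_id": trial_id,
                "gesture": spec.name,
                "group": spec.group,
                "sampling_rate_hz": config.sampling_rate,
                "path": f"trials/{trial_id}.csv",
            })
    manifest = pd.DataFrame(rows, columns=["trial_id", "gesture", "group",
                                           "sampling_rate_hz", "path"])
    return trials, manifest
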