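import numpy as np
import pytest
from scipy import signal as sps

from myosweep.synth import (DEFAULT_GRASP_WEIGHTS, GestureSpec,
                            SimulationConfig, make_similar_gesture_group,
                            simulate_dataset, simulate_trial)

BASE = (0.8, 0.6, 0.5, 0.4, 0.7, 0.6)
NAMES = ["fist", "spherical", "cylindrical"]


def _max_pairwise_distance(specs):
    w = np.array([s.activation_weights for s in specs])
    d = [np.linalg.norm(w[i] - w[j]) for i in range(3) for j in range(i + 1, 3)]
    return max(d)


class TestSimilarGestureGroup:
    def test_identical_weights_at_full_similarity(self):
        specs = make_similar_gesture_group(BASE, NAMES, 1.0, rng_seed=7)
        assert len(specs) == 3
        for s in specs:
            assert s.activation_weights == BASE

    def test_higher_similarity_shrinks_distances(self):
        tight = make_similar_gesture_group(BASE, NAMES, 0.9, rng_seed=7)
        loose = make_similar_gesture_group(BASE, NAMES, 0.5, rng_seed=7)
        assert _max_pairwise_distance(tight) < _max_pairwise_distance(loose)

    def test_distance_monotone_on_similarity_grid(self):
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        dists = [_max_pairwise_distance(
            make_similar_gesture_group(BASE, NAMES, s, rng_seed=3))
            for s in grid]
        assert all(b <= a + 1e-12 for a, b in zip(dists, dists[1:]))

    def test_wrong_name_count_rejected(self):
        with pytest.raises(ValueError, match="3 names"):
            make_similar_gesture_group(BASE, ["a", "b"], 0.9, rng_seed=0)

    def test_invalid_similarity_rejected(self):
        with pytest.raises(ValueError, match="similarity"):
            make_similar_gesture_group(BASE, NAMES, 1.5, rng_seed=0)

    def test_gesture_spec_invariants(self):
        with pytest.raises(ValueError):
            GestureSpec("x", "g", (0.5,) * 5)
        with pytest.raises(ValueError):
            GestureSpec("x", "g", (0.5, 0.5, 0.5, 0.5, 0.5, 1.5))
        with pytest.raises(ValueError):
            GestureSpec("x", "g", (0.0,) * 6)


def _unvalidated_spec(weights):
    spec = object.__new__(GestureSpec)
    object.__setattr__(spec, "name", "null")
    object.__setattr__(spec, "group", "g")
    object.__setattr__(spec, "activation_weights", tuple(weights))
    object.__setattr__(spec, "difficulty_scale", 1.0)
    return spec


class TestSimulateTrial:
    def test_zero_weights_give_noise_only(self):
        # max-weight invariant bypassed on purpose: no activation at all
        spec = _unvalidated_spec((0.0,) * 6)
        cfg = SimulationConfig(active_duration=2.0, pre_rest=1.0,
                               post_rest=0.5, trials_per_gesture=1)
        fs = int(cfg.sampling_rate)
        ratios = []
        for seed in range(10):
            t = simulate_trial(spec, cfg, np.random.default_rng(seed))
            act = t.signal[:, fs:3 * fs]
            rest = t.signal[:, :fs]
            ratios.append(np.sqrt(np.mean(act ** 2) / np.mean(rest ** 2)))
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_snr_sets_active_to_rest_rms_ratio(self):
        spec = GestureSpec("one", "g", (1.0, 0, 0, 0, 0, 0))
        cfg = SimulationConfig(active_duration=2.0, pre_rest=1.0,
                               post_rest=0.25, snr_db=20.0,
                               trials_per_gesture=1)
        fs = int(cfg.sampling_rate)
        ratios = []
        for seed in range(50):
            t = simulate_trial(spec, cfg, np.random.default_rng(seed))
            act = t.signal[0, fs:fs + 2 * fs]
            rest = t.signal[0, :fs]
            ratios.append(np.sqrt(np.mean(act ** 2) / np.mean(rest ** 2)))
        assert 8.0 < np.mean(ratios) < 12.0

    def test_active_rms_tracks_activation_weights(self):
        spec = GestureSpec("graded", "g", (1.0, 0.5, 0.25, 1.0, 0.5, 0.25))
        cfg = SimulationConfig(active_duration=2.0, pre_rest=0.5,
                               post_rest=0.25, snr_db=30.0,
                               amplitude_jitter_sd=0.0, trials_per_gesture=1)
        fs = int(cfg.sampling_rate)
        rms = np.zeros(6)
        for seed in range(20):
            t = simulate_trial(spec, cfg, np.random.default_rng(seed))
            act = t.signal[:, fs:2 * fs]  # envelope plateau only
            rms += np.sqrt(np.mean(act ** 2, axis=1))
        ratio = rms / rms[0]
        expected = np.array(spec.activation_weights)
        assert np.allclose(ratio, expected, rtol=0.15)

    def test_deterministic_given_seed(self):
        spec = GestureSpec("fist", "g", BASE)
        cfg = SimulationConfig(active_duration=1.0, trials_per_gesture=1)
        a = simulate_trial(spec, cfg, np.random.default_rng(42))
        b = simulate_trial(spec, cfg, np.random.default_rng(42))
        assert np.array_equal(a.signal, b.signal)

    def test_active_spectrum_concentrated_in_carrier_band(self):
        spec = GestureSpec("fist", "g", BASE)
        cfg = SimulationConfig(active_duration=2.0, pre_rest=0.5,
                               post_rest=0.25, trials_per_gesture=1)
        fs = cfg.sampling_rate
        n0 = int(0.5 * fs)
        fracs = []
        for seed in range(20):
            t = simulate_trial(spec, cfg, np.random.default_rng(seed))
            for c in range(6):
                f, p = sps.welch(t.signal[c, n0:n0 + int(2 * fs)], fs=fs,
                                 nperseg=512)
                in_band = (f >= cfg.carrier_band[0]) & (f <= cfg.carrier_band[1])
                fracs.append(p[in_band].sum() / p.sum())
        assert np.mean(fracs) >= 0.90


class TestSimulateDataset:
    def test_trial_counts_and_unique_ids(self):
        specs = make_similar_gesture_group(BASE, NAMES, 0.85, rng_seed=1)
        cfg = SimulationConfig(active_duration=0.2, pre_rest=0.1,
                               post_rest=0.1, trials_per_gesture=4)
        trials, manifest = simulate_dataset(specs, cfg)
        assert len(trials) == 12
        assert manifest.shape[0] == 12
        assert manifest["trial_id"].is_unique
        assert manifest["gesture"].value_counts().eq(4).all()

    def test_two_specs_one_trial(self):
        specs = [GestureSpec("a", "g", BASE), GestureSpec("b", "g", BASE)]
        cfg = SimulationConfig(active_duration=0.2, pre_rest=0.1,
                               post_rest=0.1, trials_per_gesture=1)
        trials, manifest = simulate_dataset(specs, cfg)
        assert manifest.shape[0] == 2
        assert manifest["trial_id"].is_unique

    def test_duplicate_gesture_names_rejected(self):
        specs = [GestureSpec("a", "g", BASE), GestureSpec("a", "g", BASE)]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_dataset(specs, SimulationConfig(trials_per_gesture=1))

    def test_dataset_reproducible_from_seed(self):
        specs = make_similar_gesture_group(BASE, NAMES, 0.85, rng_seed=1)
        cfg = SimulationConfig(active_duration=0.3, pre_rest=0.1,
                               post_rest=0.1, trials_per_gesture=2, seed=9)
        t1, m1 = simulate_dataset(specs, cfg)
        t2, m2 = simulate_dataset(specs, cfg)
        assert m1.equals(m2)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.signal, b.signal)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(carrier_band=(450.0, 15.0))
        with pytest.raises(ValueError):
            SimulationConfig(carrier_band=(15.0, 600.0))
        with pytest.raises(ValueError):
            SimulationConfig(trials_per_gesture=0)
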