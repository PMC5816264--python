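import numpy as np
import pandas as pd
import pytest

from myosweep.distance import (ClassStats, class_stats, compare_assignments,
                               d_out, default_ridge, pair_distance,
                               pairwise_matrix)
from conftest import gaussian_feature_table


def _stats(mu, cov, name="c"):
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    return ClassStats(gesture=name, centroid=mu, covariance=cov, n=10)


def _brute_pair_distance(a, b):
    """Explicit inverse-based oracle, independent of the solve() code path."""
    pooled = 0.5 * (a.covariance + b.covariance)
    inv = np.linalg.inv(pooled)
    d = a.centroid - b.centroid
    return 0.5 * float(d @ inv @ d)


class TestClassStats:
    def test_identical_samples_reduce_to_ridge(self):
        df = pd.DataFrame({"trial_id": ["a", "b"], "gesture": ["g", "g"],
                           "f01": [2.0, 2.0], "f02": [1.0, 1.0]})
        st = class_stats(df, "g", ridge=0.5)
        assert np.allclose(st.centroid, [2.0, 1.0])
        assert np.allclose(st.covariance, 0.5 * np.eye(2))

    def test_moments_recovered_from_large_sample(self):
        rng = np.random.default_rng(0)
        sds = np.array([1.0, 2.0, 0.5, 3.0])
        X = rng.normal(0.0, sds, size=(5000, 4))
        df = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(1, 5)])
        df.insert(0, "gesture", "g")
        df.insert(0, "trial_id", [f"t{i}" for i in range(5000)])
        st = class_stats(df, "g")
        assert np.allclose(np.diag(st.covariance), sds ** 2, rtol=0.05)

    def test_unknown_gesture_rejected(self):
        df = gaussian_feature_table([[0, 0]], 5, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            class_stats(df, "nope")

    def test_too_few_samples_rejected(self):
        df = gaussian_feature_table([[0, 0]], 1, seed=0)
        with pytest.raises(ValueError, match="fewer than 2"):
            class_stats(df, "g1")


class TestPairDistance:
    def test_identical_classes_have_zero_distance(self):
        a = _stats([1.0, 2.0], np.eye(2))
        b = _stats([1.0, 2.0], 2 * np.eye(2))
        assert pair_distance(a, b) == 0.0

    def test_one_dimensional_closed_form(self):
        # centroids 0 and 2, unit variances: (1/2) * 2^2 / 1 = 2
        a = _stats([0.0], [[1.0]])
        b = _stats([2.0], [[1.0]])
        assert pair_distance(a, b) == pytest.approx(2.0)
        assert pair_distance(a, b, sqrt=True) == pytest.approx(np.sqrt(2.0))

    def test_symmetric_in_arguments(self, rng):
        a = _stats(rng.normal(size=3), np.diag(rng.uniform(0.5, 2, 3)))
        b = _stats(rng.normal(size=3), np.diag(rng.uniform(0.5, 2, 3)))
        assert pair_distance(a, b) == pytest.approx(pair_distance(b, a))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            pair_distance(_stats([0.0], [[1.0]]),
                          _stats([0.0, 1.0], np.eye(2)))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            dim = int(rng.integers(1, 7))
            mu_a, mu_b = rng.normal(size=(2, dim))
            La, Lb = rng.normal(size=(2, dim, dim))
            a = _stats(mu_a, La @ La.T + dim * np.eye(dim))
            b = _stats(mu_b, Lb @ Lb.T + dim * np.eye(dim))
            expected = _brute_pair_distance(a, b)
            assert pair_distance(a, b) == pytest.approx(expected,
                                                        rel=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4)) @ np.diag([1, 2, 0.5, 1.5])
        Y = rng.normal(size=(50, 4)) + 2.0
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)

        def stats_of(Z, name):
            return ClassStats(name, Z.mean(axis=0),
                              np.cov(Z, rowvar=False, ddof=1), Z.shape[0])

        before = pair_distance(stats_of(X, "x"), stats_of(Y, "y"))
        after = pair_distance(stats_of(X @ A.T, "x"), stats_of(Y @ A.T, "y"))
        assert after == pytest.approx(before, rel=1e-8)


class TestDOut:
    def test_identical_classes_give_zero(self):
        stats = [_stats([0.0, 0.0], np.eye(2), name=n) for n in "abc"]
        assert d_out(stats) == 0.0

    def test_mean_of_per_class_minima(self):
        # 1-D unit-variance classes at 0, sqrt(2)*1, -2*sqrt(2) give pairwise
        # distances 1, 4, 9; D_out = (min(1,4) + min(1,9) + min(4,9))/3 = 2
        mus = [0.0, np.sqrt(2.0), -2.0 * np.sqrt(2.0)]
        stats = [_stats([m], [[1.0]], name=f"c{i}") for i, m in enumerate(mus)]
        mat = pairwise_matrix(stats).to_numpy()
        assert np.allclose(sorted([mat[0, 1], mat[0, 2], mat[1, 2]]),
                           [1.0, 4.0, 9.0])
        assert d_out(stats) == pytest.approx(2.0)

    def test_two_classes_reduce_to_their_distance(self):
        a = _stats([0.0], [[1.0]], "a")
        b = _stats([2.0], [[1.0]], "b")
        assert d_out([a, b]) == pytest.approx(pair_distance(a, b))

    def test_bounded_by_max_pairwise(self, rng):
        stats = [_stats(rng.normal(size=3),
                        np.diag(rng.uniform(0.5, 2, 3)), name=f"c{i}")
                 for i in range(4)]
        mat = pairwise_matrix(stats).to_numpy()
        assert 0.0 <= d_out(stats) <= mat.max()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            d_out([_stats([0.0], [[1.0]])])


class TestCompareAssignments:
    def _pool(self):
        return gaussian_feature_table([[0, 0, 0], [5, 0, 0], [0, 5, 0]],
                                      n_per_class=20, sd=1.0, seed=2)

    def test_identical_assignments_give_zero_deltas(self):
        pool = self._pool()
        counts = {"g1": 8, "g2": 6, "g3": 6}
        cmp = compare_assignments(pool, ["g1", "g2", "g3"], counts, counts,
                                  repeats=3, seed=0)
        assert np.allclose(cmp.pair_deltas.to_numpy(), 0.0)
        assert np.allclose(cmp.d_out_delta, 0.0)

    def test_single_repeat_has_zero_sd(self):
        pool = self._pool()
        cmp = compare_assignments(pool, ["g1", "g2", "g3"],
                                  {"g1": 8, "g2": 6, "g3": 6},
                                  {"g1": 6, "g2": 7, "g3": 7},
                                  repeats=1, seed=0)
        summary = cmp.summary()
        assert (summary["delta_sd"] == 0.0).all()

    def test_report_structure(self):
        pool = self._pool()
        cmp = compare_assignments(pool, ["g1", "g2", "g3"],
                                  {"g1": 8, "g2": 6, "g3": 6},
                                  {"g1": 6, "g2": 7, "g3": 7},
                                  repeats=4, seed=1)
        assert cmp.pair_deltas.shape == (4, 3)  # 3 gesture pairs per repeat
        assert cmp.d_out_a.shape == (4,)
        summary = cmp.summary()
        assert set(summary["quantity"]) == {"g1|g2", "g1|g3", "g2|g3", "d_out"}

    def test_default_ridge_positive(self):
        assert default_ridge(self._pool()) > 0.0
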