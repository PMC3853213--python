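import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltccsp import (
    DegenerateInputError,
    ParameterError,
    Trial,
    TrialSet,
    average_covariance,
    correlation_weights,
    euclidean_weights,
    laplacian,
    normalized_covariance,
    sigma0,
    uniform_weights,
    weighted_covariance,
)

E = np.e


def brute_force_pairwise(X, W):
    """Independent oracle: sum of weighted pairwise outer differences,
    (1/2) sum_l sum_m (x_l - x_m)(x_l - x_m)^T W_lm."""
    S = X.shape[1]
    acc = np.zeros((X.shape[0], X.shape[0]))
    for l in range(S):
        for m in range(S):
            d = X[:, l] - X[:, m]
            acc += 0.5 * W[l, m] * np.outer(d, d)
    return acc


class TestNormalizedCovariance:
    def test_identity_trial(self):
        R = normalized_covariance(np.eye(2)).R
        np.testing.assert_allclose(R, np.diag([0.5, 0.5]), atol=1e-15)

    def test_scale_invariance(self, random_trial):
        R1 = normalized_covariance(random_trial).R
        R2 = normalized_covariance(random_trial.data * -3.7).R
        np.testing.assert_allclose(R1, R2, atol=1e-14)

    def test_outer_product_sum_oracle(self, random_trial):
        X = random_trial.data
        expected = sum(np.outer(X[:, l], X[:, l]) for l in range(X.shape[1]))
        expected /= np.trace(expected)
        np.testing.assert_allclose(normalized_covariance(X).R, expected, atol=1e-12)

    def test_all_zero_trial_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalized_covariance(np.zeros((3, 5)))


class TestCorrelationWeights:
    def test_constant_offset_gives_weight_e(self, rng):
        # x_m = x_l + c*1 has correlation exactly 1 for any offset magnitude
        x = rng.standard_normal(5)
        for c in (0.001, 1.0, 1e6):
            X = np.column_stack([x, x + c])
            w = correlation_weights(X, tau=2)
            assert w.W[0, 1] == pytest.approx(E, abs=1e-12)

    def test_anticorrelated_columns(self):
        x = np.array([1.0, -2.0, 1.0])  # zero mean, nonconstant
        X = np.column_stack([x, -x])
        w = correlation_weights(X, tau=2)
        assert w.W[0, 1] == pytest.approx(1 / E, abs=1e-12)

    def test_perfect_linear_relation(self):
        X = np.column_stack([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        w = correlation_weights(X, tau=2)
        assert w.W[0, 1] == pytest.approx(E, abs=1e-12)

    def test_tau_one_is_diagonal(self, random_trial):
        w = correlation_weights(random_trial, tau=1)
        np.testing.assert_allclose(w.W, E * np.eye(random_trial.n_samples), atol=1e-12)

    def test_offset_invariance_of_whole_matrix(self, random_trial):
        # adding c*1 to one column must not change any weight
        X = random_trial.data.copy()
        W0 = correlation_weights(X, tau=5).W
        X[:, 7] += 123.456
        np.testing.assert_allclose(correlation_weights(X, tau=5).W, W0, atol=1e-9)

    def test_zero_variance_column_neutral_weight(self, rng):
        X = rng.standard_normal((4, 6))
        X[:, 2] = 3.14  # flat across channels
        w = correlation_weights(X, tau=3)
        assert w.W[2, 3] == pytest.approx(1.0)  # exp(0): neutral
        assert w.W[2, 2] == pytest.approx(E)  # diagonal convention kept

    def test_invalid_tau(self, random_trial):
        with pytest.raises(ParameterError):
            correlation_weights(random_trial, tau=0)


class TestEuclideanWeights:
    def test_zero_distance_weight_one(self, rng):
        x = rng.standard_normal(4)
        X = np.column_stack([x, x])
        w = euclidean_weights(X, tau=2, sigma=1.0)
        assert w.W[0, 1] == pytest.approx(1.0)

    def test_large_sigma_limit(self, random_trial):
        w = euclidean_weights(random_trial, tau=3, sigma=1e12)
        band = w.W != 0
        assert np.all(w.W[band] > 1 - 1e-6)

    def test_constant_offset_suppressed(self, rng):
        # contrast with the correlation kind: growing offset kills the weight
        x = rng.standard_normal(5)
        prev = np.inf
        for c in (1.0, 10.0, 100.0):
            X = np.column_stack([x, x + c])
            w = euclidean_weights(X, tau=2, sigma=10.0)
            assert w.W[0, 1] < prev
            prev = w.W[0, 1]
        assert prev < 1e-6

    def test_invalid_sigma(self, random_trial):
        with pytest.raises(ParameterError):
            euclidean_weights(random_trial, tau=2, sigma=0.0)


class TestSigma0:
    def test_two_column_example(self):
        # columns (1,0) and (0,2): squared norms {1, 4}; population std = 1.5
        t = Trial(np.array([[1.0, 0.0], [0.0, 2.0]]), fs=10.0)
        ts = TrialSet(trials=[t, t], labels=np.array([1, 2]), fs=10.0)
        assert sigma0(ts) == pytest.approx(1.5)

    def test_pooling_equals_concatenation(self, rng):
        data = rng.standard_normal((4, 3, 10))
        ts = TrialSet.from_arrays(data, [1, 2, 1, 2], fs=10.0)
        pooled = np.concatenate([(d**2).sum(axis=0) for d in data])
        assert sigma0(ts) == pytest.approx(np.std(pooled))

    def test_constant_columns_give_zero(self):
        t = Trial(np.ones((2, 5)), fs=10.0)
        ts = TrialSet(trials=[t], labels=np.array([1]), fs=10.0)
        assert sigma0(ts) == 0.0


class TestLaplacian:
    def test_three_point_example(self):
        # S=3, tau=2, all in-band correlations equal 1
        W = E * np.array([[1.0, 1, 0], [1, 1, 1], [0, 1, 1]])
        from ltccsp.covariance import TemporalWeightMatrix

        lap = laplacian(TemporalWeightMatrix(W=W, tau=2, kind="correlation"))
        np.testing.assert_allclose(lap.d, [2 * E, 3 * E, 2 * E], atol=1e-14)
        expected = np.array([[E, -E, 0], [-E, 2 * E, -E], [0, -E, E]])
        np.testing.assert_allclose(lap.L, expected, atol=1e-14)

    def test_annihilates_constant_vector(self, random_trial):
        lap = laplacian(correlation_weights(random_trial, tau=4))
        np.testing.assert_allclose(lap.L @ np.ones(lap.L.shape[0]), 0, atol=1e-10)

    def test_psd(self, random_trial):
        lap = laplacian(correlation_weights(random_trial, tau=6))
        ev = np.linalg.eigvalsh(lap.L)
        assert ev[0] >= -1e-10 * ev[-1]


class TestWeightedCovariance:
    def test_double_sum_oracle(self, random_trial):
        w = correlation_weights(random_trial, tau=5)
        lap = laplacian(w)
        expected = brute_force_pairwise(random_trial.data, w.W)
        expected /= np.trace(expected)
        np.testing.assert_allclose(
            weighted_covariance(random_trial, lap).R, expected, atol=1e-10
        )

    def test_uniform_full_band_reduces_to_centered_covariance(self, random_trial):
        # tau = S, all-ones weights: X L X^T = S * centered covariance
        S = random_trial.n_samples
        lap = laplacian(uniform_weights(S, tau=S))
        R = weighted_covariance(random_trial, lap).R
        Xc = random_trial.data - random_trial.data.mean(axis=1, keepdims=True)
        expected = Xc @ Xc.T
        expected /= np.trace(expected)
        np.testing.assert_allclose(R, expected, atol=1e-10)

    def test_scale_invariance(self, random_trial):
        lap = laplacian(correlation_weights(random_trial, tau=4))
        R1 = weighted_covariance(random_trial, lap).R
        R2 = weighted_covariance(random_trial.data * 0.01, lap).R
        np.testing.assert_allclose(R1, R2, atol=1e-12)

    def test_time_constant_signal_degenerate(self):
        X = np.outer([1.0, 2.0], np.ones(6))  # constant in time
        lap = laplacian(uniform_weights(6, tau=6))
        with pytest.raises(DegenerateInputError):
            weighted_covariance(X, lap)


class TestAverageCovariance:
    def test_single_trial_identity(self, small_trialset):
        first = small_trialset.trials_of(1)[0]
        R = average_covariance(small_trialset.subset([0]), 1, normalized_covariance)
        np.testing.assert_allclose(R.R, normalized_covariance(first).R)

    def test_mean_and_unit_trace(self, small_trialset):
        R = average_covariance(small_trialset, 1, normalized_covariance)
        assert np.trace(R.R) == pytest.approx(1.0, abs=1e-12)
        assert R.n_trials_averaged == small_trialset.class_count(1)

    def test_missing_class_rejected(self, rng):
        ts = TrialSet.from_arrays(rng.standard_normal((2, 3, 5)), [1, 1], fs=10.0)
        with pytest.raises(Exception, match="class label 2"):
            average_covariance(ts, 2, normalized_covariance)


class TestVarianceExpansionIdentity:
    def test_quadratic_form_equals_pairwise_double_sum(self, rng):
        # for row-centered X: g^T X X^T g == (1/2S) sum_lm (g.x_l - g.x_m)^2
        X = rng.standard_normal((4, 30))
        X -= X.mean(axis=1, keepdims=True)
        S = X.shape[1]
        for _ in range(5):
            g = rng.standard_normal(4)
            d = g @ X
            double_sum = np.add.outer(d, -d) ** 2
            assert double_sum.sum() / (2 * S) == pytest.approx(
                g @ X @ X.T @ g, rel=1e-10
            )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(2, 6),
    s=st.integers(3, 25),
    data=st.data(),
)
def test_weight_and_laplacian_invariants(seed, n, s, data):
    """Band structure, symmetry, range bounds and Laplacian PSD/zero-row-sum
    hold for every generated weight matrix."""
    tau = data.draw(st.integers(1, s))
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, s))
    kind = data.draw(st.sampled_from(["correlation", "euclidean"]))
    if kind == "correlation":
        w = correlation_weights(X, tau=tau)
        lo, hi = 1 / E, E
        assert np.allclose(np.diag(w.W), E)
    else:
        w = euclidean_weights(X, tau=tau, sigma=float(data.draw(st.floats(0.1, 50))))
        lo, hi = 0.0, 1.0
        assert np.allclose(np.diag(w.W), 1.0)
    W = w.W
    np.testing.assert_allclose(W, W.T, atol=1e-12)
    idx = np.arange(s)
    out_of_band = np.abs(idx[:, None] - idx[None, :]) >= tau
    assert np.all(W[out_of_band] == 0)
    in_band = ~out_of_band
    assert np.all(W[in_band] >= lo - 1e-12) and np.all(W[in_band] <= hi + 1e-12)

    lap = laplacian(w)
    np.testing.assert_allclose(lap.L.sum(axis=1), 0, atol=1e-10)
    ev = np.linalg.eigvalsh(lap.L)
    assert ev[0] >= -1e-10 * max(ev[-1], 1.0)
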