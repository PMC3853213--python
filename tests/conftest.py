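import numpy as np
import pytest

from ltccsp import Trial, TrialSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_trial(rng):
    return Trial(rng.standard_normal((4, 50)), fs=100.0)


def make_trialset(rng, n_trials=8, n_channels=4, n_samples=40, fs=100.0):
    """Unstructured Gaussian trials with alternating labels."""
    data = rng.standard_normal((n_trials, n_channels, n_samples))
    labels = np.array([1, 2] * (n_trials // 2) + [1] * (n_trials % 2))
    return TrialSet.from_arrays(data, labels, fs)


@pytest.fixture
def small_trialset(rng):
    return make_trialset(rng)


def two_source_trialset(rng, n_trials=20, n_channels=6, n_samples=200, fs=100.0,
                        var_ratio=4.0, noise_std=0.0):
    """Linearly mixed trials where class 1 boosts source 0 and class 2
    boosts source 1; the remaining n_channels - 2 sources are unit-variance
    background common to both classes (full-rank model, so spatial filters
    are well conditioned even at noise_std = 0).  Returns (TrialSet, mixing).
    """
    A, _ = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))
    labels = np.array([1, 2] * (n_trials // 2))
    data = np.empty((n_trials, n_channels, n_samples))
    for k, lab in enumerate(labels):
        v = np.ones(n_channels)
        v[:2] = (var_ratio, 1.0) if lab == 1 else (1.0, var_ratio)
        src = rng.standard_normal((n_channels, n_samples)) * np.sqrt(v)[:, None]
        data[k] = A @ src + noise_std * rng.standard_normal((n_channels, n_samples))
    return TrialSet.from_arrays(data, labels, fs), A
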