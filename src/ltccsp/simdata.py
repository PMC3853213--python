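"""Synthetic two-class motor-imagery EEG with known ground truth.

The generator emulates the ERD/ERS variance-difference structure that
CSP-family methods exploit: band-limited (8–30 Hz) Gaussian sources with
class-dependent variances are mixed linearly into channels through a random
orthonormal mixing matrix, plus white sensor noise.  Source amplitudes are
normalized by the deterministic filter gain (not per trial), so the sample
variance of each source fluctuates naturally from trial to trial around its
class value — the fluctuation CSP-type features actually contend with.
Defaults mirror a small-laboratory motor-imagery recording: 15 channels,
2-second epochs at 250 Hz (500 samples), 50 trials per class, one source
pair with a 2:1 variance contrast in opposite directions between the
classes (a typical ERD/ERS power change), and white sensor noise of the
same order as a single source.

Outlier contamination follows the impulsive model used to stress-test CSP
robustness: each event is one scalar draw from the one-dimensional Gaussian
N(μ + 30σ, (30σ)²) — μ, σ the pooled mean and standard deviation of the
clean training data — added at a uniformly random (trial, time-point)
position, with the number of events a fraction ``freq`` of the
training-trial count n (freq swept over 0 … 0.4 in steps of 0.1).  By
default each channel at the hit time point receives an independent draw,
so every added scalar has exactly the stated 1-D marginal.  Two
alternative event shapes are available: ``common`` (one shared draw across
channels — a transient baseline shift, the artifact the correlation
weighting tolerates by construction) and ``single_channel`` (one draw in
one random channel).  Outliers are added to, not substituted for, the
clean signal, and only the training partition is ever contaminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .exceptions import ParameterError, ValidationError
from .pipeline import DEFAULT_BAND, EvalConfig, bandpass, evaluate
from .trials import TrialSet

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "OutlierSpec",
    "generate_trials",
    "generate_dataset",
    "inject_outliers",
    "robustness_benchmark",
    "BenchmarkResult",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    ``variance_profiles[c][j]`` is the expected variance of source j under
    class c ∈ {1, 2}; the default plants a symmetric 2:1 ERD/ERS-like
    contrast on sources 0 and 1 and leaves four common background sources.
    """

    n_channels: int = 15
    n_samples: int = 500
    fs: float = 250.0
    trials_per_class: int = 50
    n_sources: int = 6
    variance_profiles: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: {
            1: (2.0, 1.0, 1.0, 1.0, 1.0, 1.0),
            2: (1.0, 2.0, 1.0, 1.0, 1.0, 1.0),
        }
    )
    source_band: tuple[float, float] = DEFAULT_BAND
    noise_std: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sources > self.n_channels:
            raise ParameterError("n_sources must not exceed n_channels")
        if self.noise_std < 0:
            raise ParameterError("noise_std must be >= 0")
        for c in (1, 2):
            if c not in self.variance_profiles:
                raise ParameterError(f"variance profile missing for class {c}")
            if len(self.variance_profiles[c]) != self.n_sources:
                raise ParameterError(
                    f"class {c} profile has {len(self.variance_profiles[c])} "
                    f"entries for {self.n_sources} sources"
                )
        low, high = self.source_band
        if not (0 < low < high < self.fs / 2):
            raise ParameterError("source_band must satisfy 0 < low < high < fs/2")


@dataclass
class GroundTruth:
    """What the generator planted: the mixing matrix (orthonormal columns)
    and the indices of sources whose variance differs between classes.
    The ideal unmixing direction for source j is ``mixing[:, j]``."""

    mixing: np.ndarray
    discriminative_sources: tuple[int, ...]


@dataclass
class OutlierSpec:
    """Impulsive contamination: round(freq·n) events, each one draw from
    N(μ + 30σ, (30σ)²) at one random time point.  ``mu``/``sigma`` default
    to the pooled mean/std of the set being contaminated.

    ``mode`` controls how an event hits the N-channel time-point vector:
    ``"per_channel"`` (default) adds independent draws per channel,
    ``"common"`` adds the same scalar draw to every channel, and
    ``"single_channel"`` adds one draw to one random channel."""

    freq: float
    mu: float | None = None
    sigma: float | None = None
    seed: int = 0
    mode: str = "per_channel"

    OUTLIER_SHIFT = 30.0  # mean offset and std, in units of the clean std

    MODES = ("common", "per_channel", "single_channel")


def _orthonormal_mixing(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    A = rng.standard_normal((n, k))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))  # fix QR sign ambiguity for determinism


def _filtfilt_gain(sos: np.ndarray) -> float:
    """Std of unit white noise after forward-backward filtering.

    filtfilt applies |H(ω)|², so the output variance of white input is the
    frequency average of |H(ω)|⁴ (Parseval; edge transients neglected).
    """
    _, h = scipy.signal.sosfreqz(sos, worN=8192)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def _source_block(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    labels: np.ndarray,
    mixing: np.ndarray,
    sos: np.ndarray,
) -> np.ndarray:
    """(K, N, S) trials: band-limited sources with *expected* variance equal
    to the class profile (gain-normalized, so per-trial sample variance
    fluctuates naturally), mixed, plus white sensor noise."""
    K = labels.size
    gain = _filtfilt_gain(sos)
    data = np.empty((K, cfg.n_channels, cfg.n_samples))
    for k in range(K):
        raw = rng.standard_normal((cfg.n_sources, cfg.n_samples))
        src = scipy.signal.sosfiltfilt(sos, raw, axis=-1) / gain
        scale = np.sqrt(np.asarray(cfg.variance_profiles[int(labels[k])]))
        data[k] = mixing @ (src * scale[:, None])
        if cfg.noise_std > 0:
            data[k] += cfg.noise_std * rng.standard_normal(data[k].shape)
    return data


def _make_labels(trials_per_class: int) -> np.ndarray:
    return np.array([1, 2] * trials_per_class)


def generate_trials(cfg: GeneratorConfig) -> tuple[TrialSet, GroundTruth]:
    """Generate ``trials_per_class`` trials of each class, interleaved.

    Fully reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mixing = _orthonormal_mixing(rng, cfg.n_channels, cfg.n_sources)
    sos = scipy.signal.butter(
        4, list(cfg.source_band), btype="bandpass", fs=cfg.fs, output="sos"
    )
    labels = _make_labels(cfg.trials_per_class)
    data = _source_block(rng, cfg, labels, mixing, sos)
    disc = tuple(
        j
        for j in range(cfg.n_sources)
        if cfg.variance_profiles[1][j] != cfg.variance_profiles[2][j]
    )
    return TrialSet.from_arrays(data, labels, cfg.fs), GroundTruth(mixing, disc)


def generate_dataset(
    cfg: GeneratorConfig, test_trials_per_class: int | None = None
) -> tuple[TrialSet, TrialSet, GroundTruth]:
    """Train and test sets drawn from one generative model (shared mixing),
    with independent source/noise realizations."""
    cfg.validate()
    if test_trials_per_class is None:
        test_trials_per_class = cfg.trials_per_class
    rng = np.random.default_rng(cfg.seed)
    mixing = _orthonormal_mixing(rng, cfg.n_channels, cfg.n_sources)
    sos = scipy.signal.butter(
        4, list(cfg.source_band), btype="bandpass", fs=cfg.fs, output="sos"
    )
    tr_labels = _make_labels(cfg.trials_per_class)
    te_labels = _make_labels(test_trials_per_class)
    train = _source_block(rng, cfg, tr_labels, mixing, sos)
    test = _source_block(rng, cfg, te_labels, mixing, sos)
    disc = tuple(
        j
        for j in range(cfg.n_sources)
        if cfg.variance_profiles[1][j] != cfg.variance_profiles[2][j]
    )
    return (
        TrialSet.from_arrays(train, tr_labels, cfg.fs),
        TrialSet.from_arrays(test, te_labels, cfg.fs),
        GroundTruth(mixing, disc),
    )


def inject_outliers(ts: TrialSet, spec: OutlierSpec) -> TrialSet:
    """Return a contaminated copy of ``ts``; the input is not modified.

    Exactly ``round(freq · n_trials)`` distinct (trial, time-point) events
    are drawn; each adds N(μ+30σ, (30σ)²) contamination at that time point
    according to ``spec.mode``.
    """
    if spec.freq < 0:
        raise ParameterError(f"outlier frequency must be >= 0, got {spec.freq}")
    if spec.mode not in OutlierSpec.MODES:
        raise ParameterError(f"mode must be one of {OutlierSpec.MODES}, got {spec.mode!r}")
    count = int(round(spec.freq * ts.n_trials))
    data = ts.data  # (K, N, S) copy
    if count == 0:
        return TrialSet.from_arrays(data, ts.labels, ts.fs, ts.channel_names)
    mu = float(np.mean(data)) if spec.mu is None else float(spec.mu)
    sigma = float(np.std(data)) if spec.sigma is None else float(spec.sigma)
    if sigma <= 0:
        raise ValidationError("outlier sigma must be positive")
    shift = OutlierSpec.OUTLIER_SHIFT
    rng = np.random.default_rng(spec.seed)
    K, N, S = data.shape
    if count > K * S:
        raise ParameterError(f"cannot place {count} distinct events in {K * S} slots")
    slots = rng.choice(K * S, size=count, replace=False)
    for slot in slots:
        k, s = divmod(int(slot), S)
        if spec.mode == "common":
            data[k, :, s] += rng.normal(mu + shift * sigma, shift * sigma)
        elif spec.mode == "per_channel":
            data[k, :, s] += rng.normal(mu + shift * sigma, shift * sigma, size=N)
        else:  # single_channel
            ch = int(rng.integers(N))
            data[k, ch, s] += rng.normal(mu + shift * sigma, shift * sigma)
    return TrialSet.from_arrays(data, ts.labels, ts.fs, ts.channel_names)


# ---------------------------------------------------------------------------
# robustness benchmark
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkResult:
    """``table``: mean test accuracy (fraction), rows = outlier frequency,
    columns = method.  ``records``: one row per (repetition, freq, method)
    with the per-run accuracy and chosen τ."""

    table: pd.DataFrame
    records: pd.DataFrame


def robustness_benchmark(
    cfg: GeneratorConfig,
    methods: Sequence[str] = ("csp", "ltcsp", "ltccsp"),
    freqs: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4),
    repetitions: int = 10,
    seed: int = 0,
    eval_cfg: EvalConfig | None = None,
) -> BenchmarkResult:
    """Outlier-robustness sweep: per repetition, draw a fresh train/test
    pair, band-pass both, contaminate the *training* partition at each
    frequency, and evaluate every method.  The test partition stays clean.
    """
    eval_cfg = eval_cfg or EvalConfig()
    band = eval_cfg.band or DEFAULT_BAND
    master = np.random.default_rng(seed)
    rows = []
    for rep in range(repetitions):
        data_seed = int(master.integers(2**31 - 1))
        train, test, _ = generate_dataset(replace(cfg, seed=data_seed))
        bp_train = bandpass(train, *band)
        bp_test = bandpass(test, *band)
        for freq in freqs:
            out_seed = int(master.integers(2**31 - 1))
            contaminated = inject_outliers(
                bp_train, OutlierSpec(freq=freq, seed=out_seed)
            )
            for method in methods:
                run_cfg = replace(
                    eval_cfg, method=method, band=None, seed=int(master.integers(2**31 - 1))
                )
                res = evaluate(contaminated, bp_test, run_cfg)
                rows.append(
                    {
                        "repetition": rep,
                        "freq": freq,
                        "method": method,
                        "accuracy": res.test_accuracy,
                        "chosen_tau": res.chosen_tau,
                    }
                )
    records = pd.DataFrame(rows)
    table = records.pivot_table(index="freq", columns="method", values="accuracy")
    return BenchmarkResult(table=table, records=records)
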