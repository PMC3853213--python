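"""Covariance estimators for CSP-family spatial filtering.

CSP compares the two classes through average normalized spatial covariance
matrices: each trial ``X`` (channels x samples) contributes
``X Xᵀ / tr(X Xᵀ)`` and the per-class estimates are arithmetic means of
those unit-trace terms.  The local-temporal variants replace ``X Xᵀ`` by the
Laplacian-weighted form ``X L Xᵀ``, where ``L = D − W`` is the graph
Laplacian of a banded, symmetric, nonnegative temporal weight matrix ``W``
over the ``S`` time points of the trial:

* *correlation* weights (LTCCSP, the method this package is named after):
  ``W_lm = exp(corr(x_l, x_m))`` for ``|l − m| < τ`` and 0 outside the band,
  with ``corr`` the Pearson correlation of the two N-channel time-point
  vectors.  Because correlation is bounded in [−1, 1] and invariant to
  adding a constant offset to a time-point vector, these weights are robust
  to amplitude outliers and transient baseline shifts.
* *euclidean* weights (LTCSP): ``W_lm = exp(−‖x_l − x_m‖² / σ)`` on the same
  band.  Large-amplitude excursions get near-zero weight, which suppresses
  outliers but also suppresses legitimate high-amplitude signal.
* *uniform* weights: all ones on the band.  With a full band (τ = S) the
  weighted covariance reduces exactly to the (row-mean-centered) sample
  covariance — the CSP limit, used as an internal consistency oracle.

Scalar factors 1/S and 1/2S appearing in the pairwise-difference expansion
of the weighted quadratic form are dropped throughout: the per-trial trace
normalization cancels them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .exceptions import DegenerateInputError, ParameterError, ValidationError
from .trials import Trial, TrialSet

__all__ = [
    "TemporalWeightMatrix",
    "TemporalLaplacian",
    "CovarianceEstimate",
    "normalized_covariance",
    "correlation_matrix",
    "pairwise_sqdist",
    "correlation_weights",
    "euclidean_weights",
    "uniform_weights",
    "sigma0",
    "laplacian",
    "weighted_covariance",
    "average_covariance",
]

#: relative tolerance below which eigenvalues of PSD matrices may dip negative
PSD_RTOL = 1e-10

WeightKind = Literal["correlation", "euclidean", "uniform"]


def _as_data(t: Trial | np.ndarray) -> np.ndarray:
    if isinstance(t, Trial):
        return t.data
    arr = np.asarray(t, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a Trial or a 2-D channels x samples array")
    return arr


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TemporalWeightMatrix:
    """Banded symmetric nonnegative S x S temporal weight matrix.

    ``W[l, m] = 0`` whenever ``|l − m| >= tau`` (``tau`` is in samples; the
    band condition is purely index-based, independent of sampling rate).
    """

    W: np.ndarray
    tau: int
    kind: WeightKind
    sigma: float | None = None

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]


@dataclass
class TemporalLaplacian:
    """Graph Laplacian ``L = D − W`` of a temporal weight matrix.

    ``d`` holds the diagonal of ``D`` (row sums of W).  L is symmetric PSD
    and annihilates the constant vector (every row sums to zero).
    """

    L: np.ndarray
    d: np.ndarray

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.d)


@dataclass
class CovarianceEstimate:
    """Symmetric PSD N x N spatial covariance with unit trace."""

    R: np.ndarray
    n_trials_averaged: int = 1


# ---------------------------------------------------------------------------
# per-trial covariance terms
# ---------------------------------------------------------------------------


def normalized_covariance(t: Trial | np.ndarray) -> CovarianceEstimate:
    """Plain normalized spatial covariance ``X Xᵀ / tr(X Xᵀ)`` of one trial.

    Scale-invariant: multiplying the trial by any c ≠ 0 leaves R unchanged.
    """
    X = _as_data(t)
    M = X @ X.T
    tr = float(np.trace(M))
    if tr <= 0.0:
        raise DegenerateInputError("trial is identically zero; covariance undefined")
    R = (M + M.T) / (2.0 * tr)
    return CovarianceEstimate(R=R, n_trials_averaged=1)


# ---------------------------------------------------------------------------
# temporal weight matrices
# ---------------------------------------------------------------------------


def _band_mask(S: int, tau: int) -> np.ndarray:
    idx = np.arange(S)
    return (np.abs(idx[:, None] - idx[None, :]) < tau).astype(float)


def correlation_matrix(t: Trial | np.ndarray) -> np.ndarray:
    """S x S Pearson correlations between time-point vectors.

    ``corr[l, m]`` correlates the N channel values at time l with those at
    time m.  A time point with zero variance across channels (flat column)
    gets correlation 0 with every other time point — a neutral convention
    that neither attracts nor suppresses — while the diagonal is kept at 1.
    """
    X = _as_data(t)
    if X.shape[0] < 2:
        raise ValidationError("correlation across channels needs N >= 2")
    Xc = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Xc, axis=0)
    nz = norms > 0.0
    Z = np.zeros_like(Xc)
    Z[:, nz] = Xc[:, nz] / norms[nz]
    corr = np.clip(Z.T @ Z, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def pairwise_sqdist(t: Trial | np.ndarray) -> np.ndarray:
    """S x S squared Euclidean distances ``‖x_l − x_m‖²`` between time-point
    vectors (clipped at zero against rounding)."""
    X = _as_data(t)
    G = X.T @ X
    g = np.diag(G)
    d2 = g[:, None] + g[None, :] - 2.0 * G
    return np.clip((d2 + d2.T) / 2.0, 0.0, None)


def _check_tau(tau: int, S: int) -> int:
    tau = int(tau)
    if tau < 1:
        raise ParameterError(f"tau must be >= 1, got {tau}")
    if tau > S:
        raise ParameterError(f"tau={tau} exceeds trial length S={S}")
    return tau


def correlation_weights(t: Trial | np.ndarray, tau: int) -> TemporalWeightMatrix:
    """Banded correlation weights ``W_lm = exp(corr(x_l, x_m))``, |l−m| < τ.

    In-band weights lie in [e⁻¹, e]; the diagonal is exactly e.  Adding a
    constant vector c·1 to a time point leaves every weight unchanged
    (Pearson correlation removes per-vector means), which is the property
    that makes LTCCSP robust to baseline shifts and common-mode outliers.
    """
    X = _as_data(t)
    tau = _check_tau(tau, X.shape[1])
    corr = correlation_matrix(X)
    W = np.exp(corr) * _band_mask(X.shape[1], tau)
    return TemporalWeightMatrix(W=(W + W.T) / 2.0, tau=tau, kind="correlation")


def euclidean_weights(
    t: Trial | np.ndarray, tau: int, sigma: float
) -> TemporalWeightMatrix:
    """Banded Gaussian-kernel weights ``W_lm = exp(−‖x_l − x_m‖²/σ)``.

    In-band weights lie in (0, 1], diagonal exactly 1.  A constant-vector
    offset of growing magnitude drives the weight to 0 — the behaviour the
    correlation kind deliberately avoids.
    """
    X = _as_data(t)
    tau = _check_tau(tau, X.shape[1])
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    W = np.exp(-pairwise_sqdist(X) / float(sigma)) * _band_mask(X.shape[1], tau)
    return TemporalWeightMatrix(
        W=(W + W.T) / 2.0, tau=tau, kind="euclidean", sigma=float(sigma)
    )


def uniform_weights(S: int, tau: int) -> TemporalWeightMatrix:
    """All-ones weights on the band; with ``tau = S`` this is the CSP limit
    (weighted covariance becomes the centered sample covariance)."""
    tau = _check_tau(tau, S)
    return TemporalWeightMatrix(W=_band_mask(S, tau), tau=tau, kind="uniform")


def sigma0(train: TrialSet) -> float:
    """Scale statistic for the Euclidean kernel: the population standard
    deviation of the squared norms ``‖x_l‖²`` of all time-point vectors
    pooled across every trial of the training set.  The LTCSP convention is
    to set the kernel scale to ``σ = 7 σ₀``.
    """
    sq = np.concatenate([(t.data**2).sum(axis=0) for t in train.trials])
    if sq.size < 2:
        raise ValidationError("sigma0 needs at least two time-point vectors")
    return float(np.std(sq))


# ---------------------------------------------------------------------------
# Laplacian and weighted covariance
# ---------------------------------------------------------------------------


def laplacian(w: TemporalWeightMatrix) -> TemporalLaplacian:
    """Graph Laplacian ``L = D − W`` with ``D_ll = Σ_m W_lm``."""
    W = w.W
    if W.shape[0] != W.shape[1]:
        raise ValidationError("weight matrix must be square")
    if np.any(W < 0):
        raise ValidationError("weight matrix must be nonnegative")
    d = W.sum(axis=1)
    L = np.diag(d) - W
    return TemporalLaplacian(L=(L + L.T) / 2.0, d=d)


def weighted_covariance(
    t: Trial | np.ndarray, lap: TemporalLaplacian | np.ndarray
) -> CovarianceEstimate:
    """Laplacian-weighted normalized covariance ``X L Xᵀ / tr(X L Xᵀ)``.

    Equivalent (up to the cancelled 1/2S factor) to the weighted
    pairwise-difference sum Σ_l Σ_m (x_l − x_m)(x_l − x_m)ᵀ W_lm / 2.
    Raises if the weighted trace vanishes, which happens when the signal is
    constant in time within the band (e.g. the τ = 1 degenerate band, where
    L = 0).
    """
    X = _as_data(t)
    L = lap.L if isinstance(lap, TemporalLaplacian) else np.asarray(lap, dtype=float)
    if L.shape != (X.shape[1], X.shape[1]):
        raise ValidationError(
            f"Laplacian is {L.shape}, trial has S={X.shape[1]} samples"
        )
    M = X @ L @ X.T
    M = (M + M.T) / 2.0
    tr = float(np.trace(M))
    scale = float(np.abs(M).max())
    if tr <= 0.0 or (scale > 0 and tr < 1e-12 * scale * X.shape[0]) or scale == 0.0:
        raise DegenerateInputError(
            "weighted trace tr(X L Xᵀ) is not positive; signal is constant in "
            "time within the band (or tau too small)"
        )
    return CovarianceEstimate(R=M / tr, n_trials_averaged=1)


def average_covariance(
    ts: TrialSet,
    class_label: int,
    estimator: Callable[[Trial], CovarianceEstimate],
) -> CovarianceEstimate:
    """Arithmetic mean of per-trial unit-trace estimates for one class.

    Averaging unit-trace matrices preserves the unit trace, so every trial
    contributes equally regardless of its amplitude.
    """
    trials = ts.trials_of(class_label)
    if not trials:
        raise ValidationError(f"no trials with class label {class_label}")
    R = np.mean([estimator(t).R for t in trials], axis=0)
    return CovarianceEstimate(R=(R + R.T) / 2.0, n_trials_averaged=len(trials))
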