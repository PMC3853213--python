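"""Spatial-filter learning by simultaneous diagonalization.

All three methods (CSP, LTCSP, LTCCSP) solve the same problem on different
class covariance estimates: find the filter matrix Γ maximizing the
projected variance ratio between class X (label 1) and class Y (label 2).
The closed-form solution whitens the composite covariance and rotates into
the eigenbasis of the whitened class-X covariance:

    R_sum = R_X + R_Y = U D Uᵀ        (eigendecomposition)
    Γ = U D^{−1/2} V                   with V the eigenvectors of
                                       D^{−1/2} Uᵀ R_X U D^{−1/2}

Columns of Γ are ordered by descending class-X eigenvalue λ_j ∈ [0, 1];
because Γᵀ R_sum Γ = I, the class-Y eigenvalues are 1 − λ_j, so the first
columns maximize class-X variance and the last columns maximize class-Y
variance.  Features use the M first and M last columns ("filter pairs").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import scipy.linalg

from . import covariance as cov
from .exceptions import (
    ConditioningError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from .trials import Trial, TrialSet

__all__ = [
    "SpatialFilterModel",
    "solve_simultaneous_diag",
    "fit_csp",
    "fit_ltcsp",
    "fit_ltccsp",
    "save_model",
    "load_model",
]

#: relative eigenvalue threshold below which R_X + R_Y counts as rank deficient
RANK_RTOL = 1e-10

#: default number of filter pairs (columns kept from each end of Γ)
DEFAULT_FILTER_PAIRS = 3

#: cross-validated local temporal range, in samples
DEFAULT_TAU_GRID = tuple(range(2, 13))

#: multiplier applied to sigma0 for the Euclidean (LTCSP) kernel scale
SIGMA_MULTIPLIER = 7.0


@dataclass
class SpatialFilterModel:
    """Fitted spatial filters plus everything needed to reproduce features.

    ``Gamma`` is N x N with columns ordered by descending class-X eigenvalue;
    ``selected_columns`` gives the M first and M last column indices used for
    feature extraction.  ``Rx``/``Ry`` are the fitted average (weighted)
    class covariances, retained so the whitening and eigenvalue-pairing
    invariants can be checked after the fact.
    """

    Gamma: np.ndarray
    M: int
    method: str  # csp | ltcsp | ltccsp
    eigvals: np.ndarray
    Rx: np.ndarray
    Ry: np.ndarray
    tau: int | None = None
    sigma: float | None = None
    class_map: dict[int, str] = field(default_factory=lambda: {1: "X", 2: "Y"})
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.Gamma.shape[0]

    def selected_columns(self) -> list[int]:
        n = self.n_channels
        return list(range(self.M)) + list(range(n - self.M, n))

    def filters(self) -> np.ndarray:
        """N x 2M matrix of the selected filter columns."""
        return self.Gamma[:, self.selected_columns()]

    @property
    def label_x(self) -> int:
        return next(l for l, side in self.class_map.items() if side == "X")


def _as_matrix(R: "cov.CovarianceEstimate | np.ndarray") -> np.ndarray:
    if isinstance(R, cov.CovarianceEstimate):
        return R.R
    return np.asarray(R, dtype=float)


def solve_simultaneous_diag(
    Rx: "cov.CovarianceEstimate | np.ndarray",
    Ry: "cov.CovarianceEstimate | np.ndarray",
    ridge: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simultaneously diagonalize two symmetric PSD matrices.

    Returns ``(Gamma, eigvals)`` with ``Γᵀ(Rx+Ry)Γ = I`` and
    ``ΓᵀRxΓ = diag(eigvals)`` (eigvals descending in [0, 1]).  An optional
    explicit ridge δ adds δ·I to each input; the default is no
    regularization — a rank-deficient composite raises instead of being
    silently repaired, so method comparisons stay uncontaminated.

    Sign convention: each column is scaled so its largest-magnitude entry is
    positive, making fitted models comparable across runs and platforms.
    """
    Rx = _as_matrix(Rx).copy()
    Ry = _as_matrix(Ry).copy()
    if Rx.shape != Ry.shape or Rx.shape[0] != Rx.shape[1]:
        raise ValidationError("Rx and Ry must be square matrices of equal size")
    if ridge < 0:
        raise ParameterError(f"ridge must be nonnegative, got {ridge}")
    if ridge > 0:
        Rx += ridge * np.eye(Rx.shape[0])
        Ry += ridge * np.eye(Ry.shape[0])
    Rsum = (Rx + Ry + Rx.T + Ry.T) / 2.0
    d, U = scipy.linalg.eigh(Rsum)
    if d[-1] <= 0 or d[0] <= RANK_RTOL * d[-1]:
        raise ConditioningError(
            "R_X + R_Y is rank deficient; remove linearly dependent channels "
            "or enable an explicit ridge"
        )
    P = U / np.sqrt(d)  # U D^{-1/2}: whitening transform
    Sx = P.T @ Rx @ P
    lam, V = scipy.linalg.eigh((Sx + Sx.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    Gamma = P @ V[:, order]
    # sign fix: largest-magnitude entry of each column positive
    peaks = np.argmax(np.abs(Gamma), axis=0)
    signs = np.sign(Gamma[peaks, np.arange(Gamma.shape[1])])
    signs[signs == 0] = 1.0
    Gamma = Gamma * signs
    return Gamma, np.clip(lam, 0.0, 1.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _validate_fit_inputs(ts: TrialSet, M: int) -> None:
    ts.require_both_classes()
    if M < 1:
        raise ParameterError(f"M must be >= 1, got {M}")
    if 2 * M > ts.n_channels:
        raise ParameterError(
            f"2M = {2 * M} filters requested but only {ts.n_channels} channels"
        )


def _fit(
    ts: TrialSet,
    M: int,
    method: str,
    estimator: Callable[[Trial], "cov.CovarianceEstimate"],
    tau: int | None,
    sigma: float | None,
    class_x: int,
    ridge: float,
) -> SpatialFilterModel:
    class_y = 2 if class_x == 1 else 1
    Rx = cov.average_covariance(ts, class_x, estimator)
    Ry = cov.average_covariance(ts, class_y, estimator)
    Gamma, eigvals = solve_simultaneous_diag(Rx, Ry, ridge=ridge)
    return SpatialFilterModel(
        Gamma=Gamma,
        M=M,
        method=method,
        eigvals=eigvals,
        Rx=Rx.R,
        Ry=Ry.R,
        tau=tau,
        sigma=sigma,
        class_map={class_x: "X", class_y: "Y"},
        channel_names=list(ts.channel_names),
    )


def fit_csp(
    ts: TrialSet,
    M: int = DEFAULT_FILTER_PAIRS,
    class_x: int = 1,
    ridge: float = 0.0,
) -> SpatialFilterModel:
    """Conventional CSP: plain normalized covariances, no temporal weighting."""
    _validate_fit_inputs(ts, M)
    return _fit(
        ts, M, "csp", cov.normalized_covariance, None, None, class_x, ridge
    )


def fit_ltcsp(
    ts: TrialSet,
    M: int = DEFAULT_FILTER_PAIRS,
    tau: int = 2,
    sigma: "float | str" = "auto",
    class_x: int = 1,
    ridge: float = 0.0,
) -> SpatialFilterModel:
    """Local temporal CSP: Euclidean-kernel weighted covariances.

    ``sigma="auto"`` sets the kernel scale to 7·σ₀ with σ₀ the population
    standard deviation of the pooled squared time-point norms of ``ts``.
    """
    _validate_fit_inputs(ts, M)
    if sigma == "auto":
        sigma = SIGMA_MULTIPLIER * cov.sigma0(ts)
        if sigma <= 0:
            raise DegenerateInputError(
                "sigma0 = 0 (all squared time-point norms identical); the "
                "Euclidean kernel scale is undefined"
            )
    sigma = float(sigma)

    def estimator(t: Trial) -> "cov.CovarianceEstimate":
        w = cov.euclidean_weights(t, tau=tau, sigma=sigma)
        return cov.weighted_covariance(t, cov.laplacian(w))

    return _fit(ts, M, "ltcsp", estimator, int(tau), sigma, class_x, ridge)


def fit_ltccsp(
    ts: TrialSet,
    M: int = DEFAULT_FILTER_PAIRS,
    tau: int = 2,
    class_x: int = 1,
    ridge: float = 0.0,
) -> SpatialFilterModel:
    """Local temporal correlation CSP: banded exp-correlation weighted
    covariances.  The only tunable parameter is the temporal range τ ≥ 2."""
    _validate_fit_inputs(ts, M)
    if tau < 2:
        raise ParameterError(
            f"LTCCSP needs tau >= 2 (tau = 1 gives an empty band, L = 0); got {tau}"
        )

    def estimator(t: Trial) -> "cov.CovarianceEstimate":
        w = cov.correlation_weights(t, tau=tau)
        return cov.weighted_covariance(t, cov.laplacian(w))

    return _fit(ts, M, "ltccsp", estimator, int(tau), None, class_x, ridge)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: SpatialFilterModel, path: "str | Path") -> Path:
    """Serialize a fitted model to JSON (matrices row-major)."""
    path = Path(path)
    payload = {
        "method": model.method,
        "M": model.M,
        "n_channels": model.n_channels,
        "tau": model.tau,
        "sigma": model.sigma,
        "class_map": {str(k): v for k, v in model.class_map.items()},
        "channel_names": model.channel_names,
        "Gamma": model.Gamma.tolist(),
        "eigvals": model.eigvals.tolist(),
        "Rx": model.Rx.tolist(),
        "Ry": model.Ry.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_model(path: "str | Path") -> SpatialFilterModel:
    payload = json.loads(Path(path).read_text())
    return SpatialFilterModel(
        Gamma=np.asarray(payload["Gamma"], dtype=float),
        M=int(payload["M"]),
        method=payload["method"],
        eigvals=np.asarray(payload["eigvals"], dtype=float),
        Rx=np.asarray(payload["Rx"], dtype=float),
        Ry=np.asarray(payload["Ry"], dtype=float),
        tau=payload["tau"],
        sigma=payload["sigma"],
        class_map={int(k): v for k, v in payload["class_map"].items()},
        channel_names=list(payload["channel_names"]),
    )
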