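"""Online feature extraction: log-variance of spatially filtered trials.

For the temporally weighted methods a test trial ``C`` is filtered as
``Z = Γ_selᵀ C L^{1/2}`` with ``L`` built from the test trial's own data
(the weight matrix is data-dependent) and ``L^{1/2}`` the symmetric PSD
square root.  The feature vector is the log of the sample variance of each
row of ``Z``.  Because ``L^{1/2}`` annihilates the constant vector, each row
of ``Z`` has exactly zero mean and the variance collapses to the quadratic
form ``γᵀ (C L Cᵀ) γ / (S − 1)`` — the implementation uses that identity
(no matrix square root needed per trial); the explicit ``L^{1/2}`` route is
kept as :func:`laplacian_sqrt` and serves as the cross-check oracle in the
test suite.  For plain CSP the ``L^{1/2}`` step is skipped (identity) and
the variance is taken about the row mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import covariance as cov
from .covariance import PSD_RTOL
from .exceptions import DegenerateFeatureError, ValidationError
from .filters import SpatialFilterModel
from .trials import Trial, TrialSet

__all__ = ["FeatureVector", "laplacian_sqrt", "extract_features", "feature_matrix"]


@dataclass
class FeatureVector:
    """2M log-variance features; ``filter_ids`` names the Γ column behind
    each value (first M columns, then last M)."""

    values: np.ndarray
    filter_ids: list[int]


def laplacian_sqrt(lap: "cov.TemporalLaplacian | np.ndarray") -> np.ndarray:
    """Symmetric PSD square root of a temporal Laplacian.

    Eigenvalues in [−tol, 0) are treated as exact zeros; anything more
    negative means the input is not a Laplacian and raises.
    """
    L = lap.L if isinstance(lap, cov.TemporalLaplacian) else np.asarray(lap, dtype=float)
    lam, U = scipy.linalg.eigh((L + L.T) / 2.0)
    lam_max = max(float(lam[-1]), 0.0)
    if float(lam[0]) < -PSD_RTOL * max(lam_max, 1.0):
        raise ValidationError(
            f"matrix has eigenvalue {lam[0]:.3e} < -tol; not a valid Laplacian"
        )
    root = U * np.sqrt(np.clip(lam, 0.0, None))
    return root @ U.T


def _trial_weight_matrix(model: SpatialFilterModel, t: Trial | np.ndarray):
    if model.method == "ltccsp":
        return cov.correlation_weights(t, tau=model.tau)
    if model.method == "ltcsp":
        return cov.euclidean_weights(t, tau=model.tau, sigma=model.sigma)
    raise ValidationError(f"method {model.method!r} has no temporal weight matrix")


def extract_features(model: SpatialFilterModel, t: Trial) -> FeatureVector:
    """Log-variance features of one trial under a fitted model.

    The trial's own temporal weight matrix is built with the model's
    method/τ/σ; sample variance uses denominator S − 1.
    """
    C = t.data if isinstance(t, Trial) else np.asarray(t, dtype=float)
    if C.shape[0] != model.n_channels:
        raise ValidationError(
            f"trial has {C.shape[0]} channels, model expects {model.n_channels}"
        )
    S = C.shape[1]
    Gs = model.filters()
    if model.method == "csp":
        Z = Gs.T @ C
        var = Z.var(axis=1, ddof=1)
    else:
        lap = cov.laplacian(_trial_weight_matrix(model, C))
        Mq = C @ lap.L @ C.T
        Mq = (Mq + Mq.T) / 2.0
        var = np.einsum("ij,jk,ki->i", Gs.T, Mq, Gs) / (S - 1)
    ids = model.selected_columns()
    bad = np.flatnonzero(var <= 0.0)
    if bad.size:
        raise DegenerateFeatureError(
            f"filter column {ids[bad[0]]} produced zero projected variance"
        )
    return FeatureVector(values=np.log(var), filter_ids=ids)


def feature_matrix(model: SpatialFilterModel, ts: TrialSet) -> np.ndarray:
    """Stack features for every trial of a set into (n_trials, 2M)."""
    return np.vstack([extract_features(model, t).values for t in ts.trials])
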