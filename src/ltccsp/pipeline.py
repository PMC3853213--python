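"""End-to-end evaluation protocol for the three CSP-family methods.

The protocol mirrors standard two-class motor-imagery practice: band-pass
the epochs to the 8–30 Hz mu/beta range, pick the local temporal range τ by
stratified 10-fold cross-validation on the training set (grid {2, …, 12},
same fold split reused across the grid so comparisons are paired, ties go to
the smallest τ), fit the spatial filters on the full training set, extract
2M log-variance features, and classify with a linear-kernel SVM on
standardized features.

τ selection is the expensive step, so it runs on a cached fast path: each
trial's exp-correlation (or Gaussian-kernel) matrix is computed once, and
for every τ only the band mask, Laplacian row sums, and the N x N quadratic
``C L Cᵀ`` are rebuilt.  That single matrix serves both the class-covariance
average (after trace normalization) and the log-variance features, so each
fold fit is an N x N eigenproblem.  The fast path performs exactly the same
arithmetic as the public ``fit_*`` / ``extract_features`` route (tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline as SkPipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import covariance as cov
from . import filters as flt
from .exceptions import DegenerateInputError, ParameterError, ValidationError
from .features import feature_matrix
from .filters import DEFAULT_FILTER_PAIRS, DEFAULT_TAU_GRID, SIGMA_MULTIPLIER
from .trials import Trial, TrialSet

__all__ = [
    "EvalConfig",
    "EvalResult",
    "bandpass",
    "select_tau",
    "train_classifier",
    "evaluate",
]

logger = logging.getLogger(__name__)

#: mu/beta band used for motor-imagery preprocessing, Hz
DEFAULT_BAND = (8.0, 30.0)

BANDPASS_ORDER = 4

METHODS = ("csp", "ltcsp", "ltccsp")


@dataclass
class EvalConfig:
    """Everything the evaluation protocol depends on.

    ``band=None`` skips the band-pass (for callers that pre-filter).
    ``tau`` pins the temporal range and bypasses cross-validation.
    """

    method: str = "ltccsp"
    M: int = DEFAULT_FILTER_PAIRS
    tau_grid: tuple[int, ...] = DEFAULT_TAU_GRID
    tau: int | None = None
    cv_folds: int = 10
    band: tuple[float, float] | None = DEFAULT_BAND
    kernel: str = "linear"
    C: float = 1.0
    ridge: float = 0.0
    class_x: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"method must be one of {METHODS}, got {self.method!r}")
        if not self.tau_grid:
            raise ParameterError("tau_grid must be nonempty")
        if self.cv_folds < 2:
            raise ParameterError(f"cv_folds must be > 1, got {self.cv_folds}")


@dataclass
class EvalResult:
    test_accuracy: float
    chosen_tau: int | None
    cv_table: pd.DataFrame | None
    model: flt.SpatialFilterModel
    train_accuracy: float


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def bandpass(ts: TrialSet, low: float, high: float) -> TrialSet:
    """Zero-phase Butterworth band-pass (order 4, forward-backward) applied
    per channel per trial; dimensions unchanged."""
    if not (0.0 < low < high < ts.fs / 2.0):
        raise ParameterError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {ts.fs / 2}"
        )
    sos = scipy.signal.butter(
        BANDPASS_ORDER, [low, high], btype="bandpass", fs=ts.fs, output="sos"
    )
    filtered = scipy.signal.sosfiltfilt(sos, ts.data, axis=-1)
    return TrialSet.from_arrays(
        filtered, ts.labels, ts.fs, channel_names=ts.channel_names
    )


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


def train_classifier(
    features: np.ndarray, labels: Sequence[int], cfg: EvalConfig | None = None
) -> SkPipeline:
    """SVM on standardized features; linear kernel with unit cost by default.

    Deterministic for fixed inputs (the SVC dual solver has no randomness for
    these problem sizes).
    """
    cfg = cfg or EvalConfig()
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("classifier training needs both classes present")
    if counts.min() < 2:
        raise ValidationError("classifier training needs >= 2 examples per class")
    clf = SkPipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=cfg.kernel, C=cfg.C, random_state=cfg.seed)),
        ]
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


# ---------------------------------------------------------------------------
# tau selection (cached fast path)
# ---------------------------------------------------------------------------


def _band_masked_quadratics(
    datas: list[np.ndarray], base: list[np.ndarray], tau: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-trial ``C L Cᵀ`` (symmetrized) and unit-trace versions for one τ.

    ``base[i]`` is the trial's full exp-weight matrix (band applied here).
    """
    S = datas[0].shape[1]
    idx = np.arange(S)
    mask = (np.abs(idx[:, None] - idx[None, :]) < tau).astype(float)
    quads = []
    Rs = np.empty((len(datas),), dtype=object)
    for i, (X, B) in enumerate(zip(datas, base)):
        W = B * mask
        d = W.sum(axis=1)
        LX = d[:, None] * X.T - W @ X.T  # L @ Xᵀ without forming L
        Q = X @ LX
        Q = (Q + Q.T) / 2.0
        tr = float(np.trace(Q))
        if tr <= 0.0 or np.abs(Q).max() == 0.0:
            raise DegenerateInputError(
                f"trial {i}: weighted trace not positive at tau={tau}"
            )
        quads.append(Q)
        Rs[i] = Q / tr
    return quads, Rs


def _fold_accuracy(
    quads: list[np.ndarray],
    Rs: np.ndarray,
    labels: np.ndarray,
    S: int,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    cfg: EvalConfig,
) -> float:
    class_y = 2 if cfg.class_x == 1 else 1
    ix = [i for i in train_idx if labels[i] == cfg.class_x]
    iy = [i for i in train_idx if labels[i] == class_y]
    Rx = np.mean([Rs[i] for i in ix], axis=0)
    Ry = np.mean([Rs[i] for i in iy], axis=0)
    Gamma, _ = flt.solve_simultaneous_diag(Rx, Ry, ridge=cfg.ridge)
    n = Gamma.shape[0]
    Gs = Gamma[:, list(range(cfg.M)) + list(range(n - cfg.M, n))]

    def feats(idx: np.ndarray) -> np.ndarray:
        return np.vstack(
            [np.log(np.einsum("ij,jk,ki->i", Gs.T, quads[i], Gs) / (S - 1)) for i in idx]
        )

    clf = train_classifier(feats(train_idx), labels[train_idx], cfg)
    return float(clf.score(feats(test_idx), labels[test_idx]))


def select_tau(train: TrialSet, cfg: EvalConfig) -> tuple[int, pd.DataFrame]:
    """Pick τ by stratified k-fold cross-validation on the training set.

    The same fold assignment is reused for every τ (paired comparison);
    ties in mean accuracy resolve to the smallest τ.  Returns the chosen τ
    and the full fold-accuracy table (rows = τ, columns = folds).
    """
    if cfg.method == "csp":
        raise ParameterError("csp has no temporal range to select")
    train.require_both_classes()
    min_class = min(train.class_count(1), train.class_count(2))
    if cfg.cv_folds > min_class:
        raise ValidationError(
            f"cv_folds={cfg.cv_folds} exceeds the smaller class count "
            f"({min_class}); use fewer folds"
        )
    grid = sorted({int(t) for t in cfg.tau_grid})
    if grid[0] < 2:
        raise ParameterError(f"tau grid values must be >= 2, got {grid[0]}")
    if grid[-1] > train.n_samples:
        raise ParameterError(f"tau={grid[-1]} exceeds trial length {train.n_samples}")

    datas = [t.data for t in train.trials]
    if cfg.method == "ltccsp":
        base = [np.exp(cov.correlation_matrix(X)) for X in datas]
    else:  # ltcsp
        sigma = SIGMA_MULTIPLIER * cov.sigma0(train)
        if sigma <= 0:
            raise DegenerateInputError("sigma0 = 0; Euclidean kernel undefined")
        base = [np.exp(-cov.pairwise_sqdist(X) / sigma) for X in datas]

    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(np.zeros(train.n_trials), train.labels))

    S = train.n_samples
    table = pd.DataFrame(
        index=pd.Index(grid, name="tau"),
        columns=[f"fold_{k}" for k in range(cfg.cv_folds)],
        dtype=float,
    )
    for tau in grid:
        quads, Rs = _band_masked_quadratics(datas, base, tau)
        for k, (tr_idx, te_idx) in enumerate(splits):
            table.loc[tau, f"fold_{k}"] = _fold_accuracy(
                quads, Rs, train.labels, S, tr_idx, te_idx, cfg
            )
    means = table.mean(axis=1)
    chosen, best = grid[0], -np.inf
    for tau in grid:  # ascending: strict improvement required, ties -> smallest
        if means[tau] > best:
            chosen, best = tau, means[tau]
    logger.info("select_tau: chose tau=%d (mean CV accuracy %.3f)", chosen, best)
    return chosen, table


# ---------------------------------------------------------------------------
# end-to-end evaluation
# ---------------------------------------------------------------------------


def _fit(train: TrialSet, cfg: EvalConfig, tau: int | None) -> flt.SpatialFilterModel:
    if cfg.method == "csp":
        return flt.fit_csp(train, M=cfg.M, class_x=cfg.class_x, ridge=cfg.ridge)
    if cfg.method == "ltcsp":
        return flt.fit_ltcsp(
            train, M=cfg.M, tau=tau, sigma="auto", class_x=cfg.class_x, ridge=cfg.ridge
        )
    return flt.fit_ltccsp(train, M=cfg.M, tau=tau, class_x=cfg.class_x, ridge=cfg.ridge)


def evaluate(train: TrialSet, test: TrialSet, cfg: EvalConfig) -> EvalResult:
    """Full protocol: band-pass → τ selection → fit → features → SVM → score.

    A pure function of (data, config): repeated calls are bit-identical.
    """
    if train.n_channels != test.n_channels or train.fs != test.fs:
        raise ValidationError("train and test sets must share channels and fs")
    if cfg.band is not None:
        train = bandpass(train, *cfg.band)
        test = bandpass(test, *cfg.band)
    inner = replace(cfg, band=None)

    chosen_tau: int | None = None
    cv_table: pd.DataFrame | None = None
    if cfg.method != "csp":
        if cfg.tau is not None:
            chosen_tau = int(cfg.tau)
        else:
            grid = sorted({int(t) for t in cfg.tau_grid})
            if len(grid) == 1:
                chosen_tau = grid[0]
            else:
                chosen_tau, cv_table = select_tau(train, inner)

    model = _fit(train, cfg, chosen_tau)
    logger.info(
        "evaluate: method=%s tau=%s eigenvalue spectrum head=%s",
        cfg.method,
        chosen_tau,
        np.round(model.eigvals[:3], 3).tolist(),
    )
    Xtr = feature_matrix(model, train)
    clf = train_classifier(Xtr, train.labels, cfg)
    train_acc = float(clf.score(Xtr, train.labels))
    Xte = feature_matrix(model, test)
    test_acc = float(clf.score(Xte, test.labels))
    return EvalResult(
        test_accuracy=test_acc,
        chosen_tau=chosen_tau,
        cv_table=cv_table,
        model=model,
        train_accuracy=train_acc,
    )
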