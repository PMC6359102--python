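"""Transductive SVR: per-test-instance neighborhood selection and local fit.

Instead of one global regressor, each test instance z gets its own local
model: training examples are ranked by their squared kernel-space distance
kappa to z, and a size-N subset sigma is chosen to minimise

    sum_{i in sigma} kappa_i  +  rho * sum_{i in sigma} |y_i - median(y)| / mad(y)

where the median / median-absolute-deviation pair is the robust location
and spread of the labels in a local candidate pool.  The second term
penalises label outliers: an example that sits close to z in feature
space but carries an aberrant label is pushed out of the neighborhood.
The resulting 0/1 weight vector Omega restricts the boxes of a weighted
epsilon-SVR, so the local model is fitted on sigma alone.

Two evaluation modes mirror the method's study designs: ST-SVR draws the
training pool from the test subject's own recordings (within-subject
cross-validation), T-SVR from all subjects except the test fold (pooled).

The selection objective is optimised in two stages: the candidate pool is
the ``pool_multiplier * N`` kappa-nearest training examples; median/mad
are computed once on the pool's labels, which makes the objective
separable, so picking the N smallest per-example scores is exactly
optimal for that statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelMatrices, KernelSpec, compute_kernel_matrices, kernel_space_distance
from .svr import SVRModel, fit_weighted_svr, predict_svr

__all__ = [
    "LabeledExample",
    "TransductiveConfig",
    "DispersionStats",
    "NeighborhoodSelection",
    "dispersion_scores",
    "select_neighborhood",
    "predict_transductive",
    "predict_transductive_batch",
    "run_st_svr",
    "run_t_svr",
    "split_frame",
]


@dataclass(frozen=True)
class LabeledExample:
    """One (normalised) feature vector with a continuous stress label."""

    features: np.ndarray
    y: float
    subject_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.y <= 1.0:
            raise ValueError(f"label {self.y} outside [0, 1]")


@dataclass(frozen=True)
class TransductiveConfig:
    """Hyperparameters of the transductive regressor.

    N is the neighborhood size (5 by default, the value selected by
    cross-validation in the study design this follows); rho scales the
    label-dispersion penalty — its default 0.1 makes the MAD-normalised
    dispersion scores (typically 1-10 for genuine outliers) act as a veto
    comparable to the rbf kappa range [0, 2) without letting the penalty
    drag every neighborhood toward the pool's median label; C / epsilon
    parameterise the local SVR — the default tube half-width 0.05 keeps
    the epsilon-insensitive band inside one step of the 1/7-quantised
    Stroop label scale, so a mixed neighborhood cannot be absorbed by a
    single flat function; pool_multiplier fixes the candidate-pool size
    at pool_multiplier * N.
    """

    N: int = 5
    rho: float = 0.1
    C: float = 1.0
    epsilon: float = 0.05
    kernel: KernelSpec = field(default_factory=KernelSpec)
    pool_multiplier: int = 4

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.pool_multiplier < 1:
            raise ValueError("pool_multiplier must be >= 1")


@dataclass(frozen=True)
class DispersionStats:
    """Robust location/spread of a label pool (raw, unscaled MAD)."""

    median_y: float
    mad_y: float


@dataclass
class NeighborhoodSelection:
    """Outcome of the neighborhood search for one test instance."""

    sigma: np.ndarray
    kappa_row: np.ndarray
    dispersion_terms: np.ndarray
    objective_value: float
    omega: np.ndarray
    stats: DispersionStats
    pool: np.ndarray

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma.tolist(),
            "objective_value": self.objective_value,
            "median_y": self.stats.median_y,
            "mad_y": self.stats.mad_y,
            "pool": self.pool.tolist(),
        }


def dispersion_scores(y_pool) -> tuple[DispersionStats, np.ndarray]:
    """Per-example robust outlier scores |y - median(y)| / mad(y).

    The degenerate mad = 0 case follows the Stahel-Donoho outlyingness
    convention: a label equal to the median scores 0 (all labels
    identical means there is nothing to penalise), while a label that
    deviates from an otherwise unanimous pool is infinitely outlying.
    """
    y_pool = np.asarray(y_pool, dtype=float).ravel()
    if len(y_pool) == 0:
        raise ValueError("empty label pool")
    med = float(np.median(y_pool))
    dev = np.abs(y_pool - med)
    mad = float(np.median(dev))
    if mad == 0.0:
        return DispersionStats(med, 0.0), np.where(dev > 0, np.inf, 0.0)
    return DispersionStats(med, mad), dev / mad


def _select_from_kappa(kappa: np.ndarray, train_y: np.ndarray, config: TransductiveConfig) -> NeighborhoodSelection:
    L = len(kappa)
    if config.N > L:
        raise ValueError(f"neighborhood size N={config.N} exceeds training-set size {L}")
    pool_size = min(L, config.pool_multiplier * config.N)
    order = np.argsort(kappa, kind="stable")  # ties -> lower index
    pool = np.sort(order[:pool_size])
    stats, pool_scores = dispersion_scores(train_y[pool])

    dispersion = np.zeros(L)
    dispersion[pool] = pool_scores
    # rho = 0 must ignore the dispersion term even where it is infinite
    score = kappa + config.rho * dispersion if config.rho > 0 else kappa.copy()

    pool_order = pool[np.argsort(score[pool], kind="stable")]
    sigma = np.sort(pool_order[: config.N])
    omega = np.zeros(L)
    omega[sigma] = 1.0
    objective = float(score[sigma].sum())
    return NeighborhoodSelection(
        sigma=sigma,
        kappa_row=kappa,
        dispersion_terms=dispersion,
        objective_value=objective,
        omega=omega,
        stats=stats,
        pool=pool,
    )


def select_neighborhood(
    train_X,
    train_y,
    test_x,
    config: TransductiveConfig,
    km: KernelMatrices | None = None,
) -> NeighborhoodSelection:
    """Choose the size-N training neighborhood of one test instance.

    Deterministic: ties in either the kappa ranking or the combined score
    are broken toward the lower training index.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_y = np.asarray(train_y, dtype=float).ravel()
    if km is None:
        km = compute_kernel_matrices(train_X, np.atleast_2d(np.asarray(test_x, dtype=float)), config.kernel)
    kappa = kernel_space_distance(km)[:, 0]
    return _select_from_kappa(kappa, train_y, config)


def predict_transductive(
    train_X,
    train_y,
    test_x,
    config: TransductiveConfig,
) -> tuple[float, NeighborhoodSelection, SVRModel]:
    """Neighborhood selection, local weighted SVR fit, and prediction."""
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_y = np.asarray(train_y, dtype=float).ravel()
    sel = select_neighborhood(train_X, train_y, test_x, config)
    model = fit_weighted_svr(
        train_X, train_y, sel.omega, C=config.C, epsilon=config.epsilon, kernel=config.kernel
    )
    return float(predict_svr(model, np.asarray(test_x, dtype=float))), sel, model


def predict_transductive_batch(train_X, train_y, test_X, config: TransductiveConfig) -> np.ndarray:
    """Transductive predictions for a batch of test points (one sigma each).

    The cross-kernel matrix is evaluated once; each test point then gets
    its own neighborhood and local fit.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_y = np.asarray(train_y, dtype=float).ravel()
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    kernel = config.kernel.resolve(train_X)  # one width for ranking and fits
    km = compute_kernel_matrices(train_X, test_X, kernel)
    kappa_all = kernel_space_distance(km)
    out = np.empty(len(test_X))
    for j in range(len(test_X)):
        sel = _select_from_kappa(kappa_all[:, j], train_y, config)
        model = fit_weighted_svr(
            train_X, train_y, sel.omega, C=config.C, epsilon=config.epsilon, kernel=kernel
        )
        out[j] = predict_svr(model, test_X[j])
    return out


def split_frame(frame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a feature table into (X, y, subject_ids).

    The table must carry ``subject_id`` and ``y`` columns; every other
    numeric column is treated as a feature, in column order.
    """
    meta = {"subject_id", "y", "window_start", "window_end"}
    feat_cols = [c for c in frame.columns if c not in meta]
    X = frame[feat_cols].to_numpy(dtype=float)
    y = frame["y"].to_numpy(dtype=float)
    subjects = frame["subject_id"].to_numpy()
    return X, y, subjects


def _subject_folds(n: int, folds: int, seed: int):
    from sklearn.model_selection import KFold

    return KFold(n_splits=folds, shuffle=True, random_state=seed).split(np.arange(n))


def run_st_svr(frame, subject_id, config: TransductiveConfig, folds: int = 5, seed: int = 0):
    """Within-subject transductive evaluation (ST-SVR).

    The subject's examples are split by k-fold cross-validation; each test
    point is predicted transductively from the subject's remaining folds.
    Returns an :class:`~stressvr.evaluation.EvaluationReport`.
    """
    from .evaluation import build_report

    X, y, subjects = split_frame(frame)
    idx = np.flatnonzero(subjects == subject_id)
    if len(idx) == 0:
        raise ValueError(f"subject {subject_id!r} not present in the dataset")
    min_train = int(np.floor(len(idx) * (folds - 1) / folds))
    if len(idx) < folds or min_train < config.N:
        raise ValueError(
            f"subject {subject_id!r} has too few examples ({len(idx)}) for "
            f"{folds}-fold evaluation with N={config.N}"
        )
    y_true, y_pred, pred_idx = [], [], []
    for tr, te in _subject_folds(len(idx), folds, seed):
        tr_idx, te_idx = idx[tr], idx[te]
        yhat = predict_transductive_batch(X[tr_idx], y[tr_idx], X[te_idx], config)
        y_true.extend(y[te_idx])
        y_pred.extend(yhat)
        pred_idx.extend(te_idx)
    subj = np.full(len(y_true), subject_id, dtype=object)
    return build_report(np.array(y_true), np.array(y_pred), subj)


def run_t_svr(frame, subject_id, config: TransductiveConfig, folds: int = 5, seed: int = 0):
    """Pooled-subject transductive evaluation (T-SVR).

    Each test fold of the target subject is predicted from a pool holding
    every other subject's examples plus the target subject's remaining
    folds.
    """
    from .evaluation import build_report

    X, y, subjects = split_frame(frame)
    if len(np.unique(subjects)) < 2:
        raise ValueError("T-SVR requires a multi-subject dataset")
    idx = np.flatnonzero(subjects == subject_id)
    others = np.flatnonzero(subjects != subject_id)
    if len(idx) < folds:
        raise ValueError(f"subject {subject_id!r} has too few examples ({len(idx)}) for {folds} folds")
    y_true, y_pred = [], []
    for tr, te in _subject_folds(len(idx), folds, seed):
        pool = np.concatenate([others, idx[tr]])
        yhat = predict_transductive_batch(X[pool], y[pool], X[idx[te]], config)
        y_true.extend(y[idx[te]])
        y_pred.extend(yhat)
    subj = np.full(len(y_true), subject_id, dtype=object)
    return build_report(np.array(y_true), np.array(y_pred), subj)
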