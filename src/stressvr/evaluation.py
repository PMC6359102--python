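"""Metrics, inductive baselines, and the model-comparison harness.

Continuous predictions are scored by mean absolute error (MAE) together
with the population SD of the absolute errors, and — for comparison with
three-state stress classifiers — discretised into low (LS), medium (MS)
and high (HS) stress thirds of the [0, 1] label scale, from which a 3x3
confusion matrix and one-vs-rest F1 scores are derived.  A 0.5 cut-off
dichotomises predictions into low/high stress for field-study style
count ratios.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import KFold

from .features import apply_scaler, fit_scaler
from .kernels import KernelSpec
from .svr import SVRModel, fit_weighted_svr, predict_svr
from .transduction import TransductiveConfig, predict_transductive_batch, split_frame

__all__ = [
    "STRESS_CLASSES",
    "EvaluationReport",
    "LinearModel",
    "mae_and_sd",
    "discretize_stress",
    "f1_scores",
    "high_low_counts",
    "build_report",
    "fit_baseline_esvr",
    "fit_baseline_lr",
    "predict_lr",
    "log2_grid",
    "grid_search_cv",
    "compare_models",
]

STRESS_CLASSES = ("LS", "MS", "HS")


def mae_and_sd(y, yhat) -> tuple[float, float]:
    """Mean absolute error and population SD of the absolute errors."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat):
        raise ValueError(f"length mismatch: {len(y)} vs {len(yhat)}")
    if len(y) == 0:
        raise ValueError("empty prediction vector")
    err = np.abs(y - yhat)
    return float(err.mean()), float(err.std())


def discretize_stress(y) -> np.ndarray | str:
    """Map [0, 1] stress values onto {LS, MS, HS} thirds.

    Intervals are [0, 1/3) -> LS, [1/3, 2/3) -> MS, [2/3, 1] -> HS.
    Out-of-range values are clipped with a warning.
    """
    arr = np.asarray(y, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if (arr < 0).any() or (arr > 1).any():
        warnings.warn("stress values outside [0, 1] were clipped before discretisation", stacklevel=2)
        arr = np.clip(arr, 0.0, 1.0)
    out = np.where(arr < 1 / 3, "LS", np.where(arr < 2 / 3, "MS", "HS"))
    return str(out[0]) if scalar else out


def f1_scores(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    """3x3 confusion matrix and per-class one-vs-rest F1 after discretisation.

    Classes are ordered (LS, MS, HS); a class absent from both truth and
    prediction scores F1 = 0 with a warning.
    """
    t = discretize_stress(np.asarray(y, dtype=float))
    p = discretize_stress(np.asarray(yhat, dtype=float))
    conf = _sk_confusion(t, p, labels=list(STRESS_CLASSES))
    _, _, f1, support = precision_recall_fscore_support(
        t, p, labels=list(STRESS_CLASSES), zero_division=0
    )
    if (support == 0).any():
        absent = [c for c, s in zip(STRESS_CLASSES, support) if s == 0]
        warnings.warn(f"classes absent from the truth vector scored F1=0: {absent}", stacklevel=2)
    return conf, f1


def high_low_counts(yhat, cutoff: float = 0.5) -> tuple[int, int, float]:
    """High/low stress counts around a cut-off and their ratio.

    ``n_high`` counts predictions strictly above the cut-off; the ratio
    ``n_high / n_low`` is rounded to two decimals and reported as
    ``inf`` when there are no low-stress predictions.
    """
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(yhat) == 0:
        raise ValueError("empty prediction vector")
    n_high = int((yhat > cutoff).sum())
    n_low = len(yhat) - n_high
    ratio = math.inf if n_low == 0 else round(n_high / n_low, 2)
    return n_high, n_low, ratio


@dataclass
class EvaluationReport:
    """Continuous and discretised scores for one set of predictions."""

    mae: float
    abs_err_sd: float
    n_predictions: int
    confusion_3x3: np.ndarray
    f1_per_class: np.ndarray
    per_subject: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "abs_err_sd": self.abs_err_sd,
            "n_predictions": self.n_predictions,
            "confusion_3x3": self.confusion_3x3.tolist(),
            "f1_per_class": dict(zip(STRESS_CLASSES, self.f1_per_class.tolist())),
            "per_subject_mae": self.per_subject,
        }

    def to_text(self) -> str:
        lines = [
            f"MAE                {self.mae:.4f}",
            f"SD of |err|        {self.abs_err_sd:.4f}",
            f"n predictions      {self.n_predictions}",
            "confusion (rows = truth LS/MS/HS):",
        ]
        for cls, row in zip(STRESS_CLASSES, self.confusion_3x3):
            lines.append(f"  {cls}  " + "  ".join(f"{v:5d}" for v in row))
        lines.append(
            "F1 per class       "
            + "  ".join(f"{c}={v:.3f}" for c, v in zip(STRESS_CLASSES, self.f1_per_class))
        )
        for sid, m in self.per_subject.items():
            lines.append(f"  subject {sid}: MAE {m:.4f}")
        return "\n".join(lines)


def build_report(y, yhat, subjects=None) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from aligned truth/prediction vectors."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    mae, sd = mae_and_sd(y, yhat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conf, f1 = f1_scores(y, yhat)
    per_subject: dict[str, float] = {}
    if subjects is not None:
        subjects = np.asarray(subjects)
        for sid in pd.unique(subjects):
            m = subjects == sid
            per_subject[str(sid)] = float(np.abs(y[m] - yhat[m]).mean())
    return EvaluationReport(
        mae=mae,
        abs_err_sd=sd,
        n_predictions=len(y),
        confusion_3x3=conf,
        f1_per_class=f1,
        per_subject=per_subject,
    )


def fit_baseline_esvr(X, y, C: float = 1.0, epsilon: float = 0.1, kernel: KernelSpec | None = None) -> SVRModel:
    """Global inductive epsilon-SVR: the weighted solver with unit weights."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return fit_weighted_svr(X, y, np.ones(len(X)), C=C, epsilon=epsilon, kernel=kernel)


@dataclass
class LinearModel:
    """Ordinary least squares with intercept (minimum-norm under rank deficiency)."""

    intercept: float
    coef: np.ndarray


def fit_baseline_lr(X, y) -> LinearModel:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) == 0:
        raise ValueError("empty training data")
    A = np.column_stack([np.ones(len(X)), X])
    sol, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("singular design matrix; returning the minimum-norm solution", stacklevel=2)
    return LinearModel(intercept=float(sol[0]), coef=sol[1:])


def predict_lr(model: LinearModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X @ model.coef + model.intercept


def log2_grid(lo: float = -8.0, hi: float = 8.0, step: float = 0.5) -> np.ndarray:
    """Log2-spaced hyperparameter grid: 2**lo, ..., 2**hi in `step` exponents."""
    n = int(round((hi - lo) / step)) + 1
    return 2.0 ** (lo + step * np.arange(n))


def _cv_mae(frame, model_kind: str, config: TransductiveConfig, folds: int, seed: int) -> float:
    X, y, subjects = split_frame(frame)
    errs: list[float] = []
    for tr, te in KFold(n_splits=folds, shuffle=True, random_state=seed).split(X):
        if model_kind in ("st", "t"):
            yhat = predict_transductive_batch(X[tr], y[tr], X[te], config)
        elif model_kind == "esvr":
            m = fit_baseline_esvr(X[tr], y[tr], C=config.C, epsilon=config.epsilon, kernel=config.kernel)
            yhat = predict_svr(m, X[te])
        elif model_kind == "lr":
            yhat = predict_lr(fit_baseline_lr(X[tr], y[tr]), X[te])
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")
        errs.extend(np.abs(y[te] - yhat))
    return float(np.mean(errs))


def grid_search_cv(
    frame,
    model_kind: str,
    grid: dict[str, np.ndarray],
    base_config: TransductiveConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[TransductiveConfig, pd.DataFrame]:
    """Exhaustive CV search over a hyperparameter grid.

    ``grid`` maps TransductiveConfig field names (e.g. ``C``, ``epsilon``,
    ``rho``, ``gamma``) to candidate value arrays.  Candidates are visited
    in ascending parameter order and a configuration only replaces the
    incumbent on a strictly smaller mean CV MAE, so ties resolve to the
    smallest parameter values.  Returns the winning config and the full
    CV table.
    """
    base = base_config or TransductiveConfig()
    names = sorted(grid)
    rows = []
    best_cfg, best_mae = None, np.inf
    for values in itertools.product(*(sorted(grid[n]) for n in names)):
        cfg = base
        for n, v in zip(names, values):
            if n == "gamma":
                cfg = replace(cfg, kernel=replace(cfg.kernel, gamma=float(v)))
            elif n == "N":
                cfg = replace(cfg, N=int(v))
            else:
                cfg = replace(cfg, **{n: float(v)})
        mae = _cv_mae(frame, model_kind, cfg, folds, seed)
        rows.append(dict(zip(names, values), cv_mae=mae))
        if mae < best_mae:
            best_cfg, best_mae = cfg, mae
    return best_cfg, pd.DataFrame(rows)


def compare_models(
    frame,
    config: TransductiveConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Head-to-head comparison of LR, e-SVR, ST-SVR and T-SVR.

    For every subject the subject's examples are split into k folds; each
    test fold is predicted by (a) a pooled-training linear regression,
    (b) a pooled-training global epsilon-SVR, (c) the within-subject
    transductive ST-SVR and (d) the pooled transductive T-SVR, where the
    pooled training set holds all other subjects' examples plus the
    subject's remaining folds.  Absolute errors are pooled over all
    subjects and summarised as their mean (MAE) and population SD.

    Features are min-max normalised by a scaler fitted on the pooled
    training folds (one shared geometry for every model), and a
    ``gamma='scale'`` kernel is resolved on that pool.  On a
    single-subject dataset the T-SVR row is omitted (with a notice) and
    the pooled training set degenerates to the within-subject folds.
    """
    cfg = config or TransductiveConfig()
    X, y, subjects = split_frame(frame)
    subject_ids = pd.unique(subjects)
    multi = len(subject_ids) >= 2
    if not multi:
        warnings.warn("single-subject dataset: T-SVR row omitted from the comparison", stacklevel=2)

    model_names = ["LR", "e-SVR", "ST-SVR"] + (["T-SVR"] if multi else [])
    errs: dict[str, list[float]] = {m: [] for m in model_names}

    for sid in subject_ids:
        idx = np.flatnonzero(subjects == sid)
        others = np.flatnonzero(subjects != sid)
        for tr, te in KFold(n_splits=folds, shuffle=True, random_state=seed).split(idx):
            own = idx[tr]
            pool = np.concatenate([others, own]) if multi else own
            test = idx[te]
            if normalize:
                scaler = fit_scaler(pd.DataFrame(X[pool]))
                Xp = apply_scaler(scaler, pd.DataFrame(X[pool])).to_numpy()
                Xo = apply_scaler(scaler, pd.DataFrame(X[own])).to_numpy()
                Xt = apply_scaler(scaler, pd.DataFrame(X[test])).to_numpy()
            else:
                Xp, Xo, Xt = X[pool], X[own], X[test]
            fold_cfg = replace(cfg, kernel=cfg.kernel.resolve(Xp))

            yhat_lr = predict_lr(fit_baseline_lr(Xp, y[pool]), Xt)
            esvr = fit_baseline_esvr(Xp, y[pool], C=fold_cfg.C, epsilon=fold_cfg.epsilon, kernel=fold_cfg.kernel)
            yhat_esvr = predict_svr(esvr, Xt)
            yhat_st = predict_transductive_batch(Xo, y[own], Xt, fold_cfg)
            errs["LR"].extend(np.abs(y[test] - yhat_lr))
            errs["e-SVR"].extend(np.abs(y[test] - yhat_esvr))
            errs["ST-SVR"].extend(np.abs(y[test] - yhat_st))
            if multi:
                yhat_t = predict_transductive_batch(Xp, y[pool], Xt, fold_cfg)
                errs["T-SVR"].extend(np.abs(y[test] - yhat_t))

    rows = {
        m: {"MAE": float(np.mean(e)), "SD": float(np.std(e))}
        for m, e in errs.items()
    }
    return pd.DataFrame(rows).T.loc[model_names]
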