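"""Independent reference implementations used as test oracles.

Each oracle is deliberately naive (dense QP, brute-force enumeration,
direct triple loops) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize

from stressvr.kernels import KernelSpec, kernel_function


def qp_esvr_dual(X, y, C_vec, epsilon, spec: KernelSpec) -> np.ndarray:
    """Dense reference solution of the weighted epsilon-SVR dual.

    Solves over the 2L variables (alpha, alpha*) with per-example boxes
    [0, C_i] and the balance constraint sum(alpha - alpha*) = 0 using
    SLSQP, and returns beta = alpha - alpha*.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    C_vec = np.asarray(C_vec, dtype=float)
    L = len(y)
    K = kernel_function(spec, X, X)

    def fun(z):
        beta = z[:L] - z[L:]
        return 0.5 * beta @ K @ beta - y @ beta + epsilon * z.sum()

    def jac(z):
        g = K @ (z[:L] - z[L:])
        return np.r_[g - y + epsilon, -g + y + epsilon]

    A = np.r_[np.ones(L), -np.ones(L)]
    cons = {"type": "eq", "fun": lambda z: A @ z, "jac": lambda z: A[None, :]}
    bounds = [(0.0, c) for c in C_vec] * 2
    res = minimize(
        fun,
        np.zeros(2 * L),
        jac=jac,
        bounds=bounds,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 3000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x[:L] - res.x[L:]


def brute_third_order_cumulant(x, lags) -> float:
    """Direct triple-product sum for c3(tau1, tau2)."""
    x = np.asarray(x, dtype=float)
    t1, t2 = lags
    xt = x - x.mean()
    L = len(x)
    total = 0.0
    for n in range(L):
        if 0 <= n + t1 < L and 0 <= n + t2 < L:
            total += xt[n] * xt[n + t1] * xt[n + t2]
    return total / L


def brute_window_count(duration: float, window: float, hop: float) -> int:
    """Enumerate window start times until one would overhang the recording."""
    count, k = 0, 0
    while k * hop + window <= duration + 1e-9:
        count += 1
        k += 1
    return count


def brute_f1(y_cls, yhat_cls, labels) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest precision/recall/F1 and confusion matrix by counting."""
    y_cls = np.asarray(y_cls)
    yhat_cls = np.asarray(yhat_cls)
    conf = np.zeros((len(labels), len(labels)), dtype=int)
    for i, t in enumerate(labels):
        for j, p in enumerate(labels):
            conf[i, j] = int(np.sum((y_cls == t) & (yhat_cls == p)))
    f1 = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1[i] = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return conf, f1


def exhaustive_selection_minimum(kappa, y, N, rho) -> float:
    """Exhaustive minimum of the selection objective with pool-level stats.

    The median/MAD pair is computed once on the full candidate pool, as
    the two-stage procedure fixes it, and every size-N subset is scored.
    """
    kappa = np.asarray(kappa, dtype=float)
    y = np.asarray(y, dtype=float)
    med = np.median(y)
    dev = np.abs(y - med)
    mad = np.median(dev)
    disp = dev / mad if mad > 0 else np.where(dev > 0, np.inf, 0.0)
    scores = kappa + rho * disp if rho > 0 else kappa
    best = np.inf
    for subset in itertools.combinations(range(len(y)), N):
        best = min(best, scores[list(subset)].sum())
    return best
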