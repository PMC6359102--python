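"""Instance-weighted epsilon-SVR solved exactly by pairwise coordinate descent.

The regression model is the standard epsilon-insensitive support vector
machine, except that the box constraint of each training example i is
scaled by an individual weight: the dual variables obey
``alpha_i, alpha*_i in [0, C * w_i]``.  With 0/1 weights this restricts
the fit to a selected neighborhood; a zero weight collapses the box and
pins the example's coefficient to exactly zero.

Writing ``beta_i = alpha_i - alpha*_i`` the dual is the piecewise-quadratic
program

    min_beta  1/2 beta' K beta - y' beta + eps * ||beta||_1
    s.t.      sum_i beta_i = 0,   -C w_i <= beta_i <= C w_i

which this module solves by an SMO-style scheme: pick the maximally
KKT-violating pair, minimise the objective exactly along the feasible
segment ``beta + t (e_i - e_j)`` (piecewise quadratic in t with kinks
where beta_i or beta_j crosses zero), repeat until the KKT gap falls
below tolerance.  Exact 1-D minimisation plus maximal-violation selection
gives monotone descent and convergence for this convex problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, kernel_function

__all__ = ["SVRModel", "SVRConvergenceError", "fit_weighted_svr", "predict_svr"]


class SVRConvergenceError(RuntimeError):
    """Raised when the dual solver fails to reach the KKT tolerance."""


@dataclass
class SVRModel:
    """A fitted (weighted) epsilon-SVR.

    ``beta`` has one entry per training example of the *original* problem
    (zero wherever the weight was zero); the prediction is
    ``f(x) = sum_i beta_i k(x_i, x) + b``.
    """

    beta: np.ndarray
    b: float
    support_indices: np.ndarray
    kernel: KernelSpec
    X: np.ndarray = field(repr=False)
    C: float = 1.0
    epsilon: float = 0.1
    n_iter: int = 0
    kkt_gap: float = 0.0

    def to_dict(self) -> dict:
        sv = self.support_indices
        return {
            "beta": self.beta[sv].tolist(),
            "b": self.b,
            "support_indices": sv.tolist(),
            "support_vectors": self.X[sv].tolist(),
            "kernel": self.kernel.to_dict(),
            "C": self.C,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        sv = np.asarray(d["support_indices"], dtype=int)
        n = int(sv.max()) + 1 if len(sv) else 0
        beta = np.zeros(max(n, len(sv)))
        X = np.asarray(d["support_vectors"], dtype=float)
        full_X = np.zeros((len(beta), X.shape[1] if X.ndim == 2 and X.size else 0))
        if len(sv):
            beta[sv] = d["beta"]
            full_X[sv] = X
        return cls(
            beta=beta,
            b=float(d["b"]),
            support_indices=sv,
            kernel=KernelSpec.from_dict(d["kernel"]),
            X=full_X,
            C=float(d.get("C", 1.0)),
            epsilon=float(d.get("epsilon", 0.1)),
        )


def _line_minimum(a: float, c: float, bi: float, bj: float, eps: float, t_lo: float, t_hi: float) -> float:
    """Exact minimiser of 1/2 a t^2 + c t + eps(|bi+t| + |bj-t|) on [t_lo, t_hi]."""
    if t_hi <= t_lo:
        return 0.0
    knots = {t_lo, t_hi}
    for bp in (-bi, bj):
        if t_lo < bp < t_hi:
            knots.add(bp)
    knots = sorted(knots)

    def phi(t: float) -> float:
        return 0.5 * a * t * t + c * t + eps * (abs(bi + t) + abs(bj - t))

    candidates = list(knots)
    for u, v in zip(knots[:-1], knots[1:]):
        m = 0.5 * (u + v)
        si = 1.0 if bi + m >= 0 else -1.0
        sj = 1.0 if bj - m >= 0 else -1.0
        if a > 0:
            t_star = -(c + eps * (si - sj)) / a
            if u < t_star < v:
                candidates.append(t_star)
    return min(candidates, key=phi)


def fit_weighted_svr(
    X,
    y,
    weights,
    C: float = 1.0,
    epsilon: float = 0.1,
    kernel: KernelSpec | None = None,
    tol: float = 1e-9,
    max_iter: int = 200_000,
) -> SVRModel:
    """Fit the instance-weighted epsilon-SVR dual to optimality.

    Parameters
    ----------
    X, y
        Training features (L x d) and labels (length L).
    weights
        Per-example box scalings in [0, 1].  Zero-weight examples are
        excluded from the problem exactly (their coefficients are zero by
        the collapsed box constraint); at least one weight must be positive.
    C, epsilon
        Global penalty and tube half-width.
    tol
        KKT-gap stopping tolerance of the dual.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    if not (len(X) == len(y) == len(weights)):
        raise ValueError("X, y and weights must have equal length")
    if np.any(weights < 0) or np.any(weights > 1):
        raise ValueError("weights must lie in [0, 1]")
    if not C > 0:
        raise ValueError("C must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    kernel = (kernel or KernelSpec()).resolve(X)

    active = np.flatnonzero(weights > 0)
    if len(active) == 0:
        raise ValueError("all weights are zero: nothing to fit")

    Xa, ya = X[active], y[active]
    Ca = C * weights[active]
    L = len(active)
    K = kernel_function(kernel, Xa, Xa)

    beta = np.zeros(L)
    g = -ya.copy()  # g = K beta - y
    n_iter = 0
    gap = np.inf
    for n_iter in range(1, max_iter + 1):
        up = g + np.where(beta >= 0, epsilon, -epsilon)
        dn = g + np.where(beta <= 0, -epsilon, epsilon)
        up_ok = beta < Ca - 1e-14
        dn_ok = beta > -Ca + 1e-14
        if not up_ok.any() or not dn_ok.any():
            gap = 0.0
            break
        i = int(np.argmin(np.where(up_ok, up, np.inf)))
        j = int(np.argmax(np.where(dn_ok, dn, -np.inf)))
        gap = dn[j] - up[i]
        if gap <= tol or i == j:
            break
        a = K[i, i] + K[j, j] - 2.0 * K[i, j]
        c = g[i] - g[j]
        t_lo = max(-Ca[i] - beta[i], beta[j] - Ca[j])
        t_hi = min(Ca[i] - beta[i], beta[j] + Ca[j])
        t = _line_minimum(max(a, 0.0), c, beta[i], beta[j], epsilon, t_lo, t_hi)
        if t == 0.0:
            break  # no feasible descent left (numerical edge)
        beta[i] += t
        beta[j] -= t
        g += t * (K[:, i] - K[:, j])
    else:
        raise SVRConvergenceError(
            f"SMO did not converge in {max_iter} iterations (KKT gap {gap:.3e}, L={L})"
        )

    g = K @ beta - ya  # refresh against accumulated drift

    # bias from free support vectors; midpoint of the KKT interval otherwise
    bound_tol = 1e-9
    pos_free = (beta > bound_tol) & (beta < Ca - bound_tol)
    neg_free = (beta < -bound_tol) & (beta > -Ca + bound_tol)
    b_vals = np.concatenate([-(g[pos_free] + epsilon), -(g[neg_free] - epsilon)])
    if len(b_vals):
        b = float(np.mean(b_vals))
    else:
        up = g + np.where(beta >= 0, epsilon, -epsilon)
        dn = g + np.where(beta <= 0, -epsilon, epsilon)
        up_ok = beta < Ca - 1e-14
        dn_ok = beta > -Ca + 1e-14
        lo = dn[dn_ok].max() if dn_ok.any() else up[up_ok].min()
        hi = up[up_ok].min() if up_ok.any() else dn[dn_ok].max()
        b = float(-(lo + hi) / 2.0)

    full_beta = np.zeros(len(X))
    full_beta[active] = beta
    support = np.flatnonzero(np.abs(full_beta) > bound_tol)
    return SVRModel(
        beta=full_beta,
        b=b,
        support_indices=support,
        kernel=kernel,
        X=X,
        C=C,
        epsilon=epsilon,
        n_iter=n_iter,
        kkt_gap=float(max(gap, 0.0)),
    )


def predict_svr(model: SVRModel, X) -> np.ndarray | float:
    """Evaluate f(x) = sum_i beta_i k(x_i, x) + b at one or more points."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    sv = model.support_indices
    if len(sv) == 0:
        out = np.full(len(X2), model.b)
    else:
        Kx = kernel_function(model.kernel, X2, model.X[sv])
        out = Kx @ model.beta[sv] + model.b
    return float(out[0]) if single else out
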