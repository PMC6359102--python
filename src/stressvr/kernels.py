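"""Kernel evaluation and feature-space distances for the transductive model.

The neighborhood of a test instance is judged in the kernel-induced
feature space: for a kernel k with implicit map Phi, the squared distance
``||Phi(x) - Phi(z)||^2 = k(x,x) - 2 k(x,z) + k(z,z)`` is computable from
Gram-matrix entries alone, so candidate training examples can be ranked
without ever materialising Phi.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel

__all__ = [
    "KernelSpec",
    "KernelMatrices",
    "kernel_function",
    "compute_kernel_matrices",
    "kernel_space_distance",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    kind: ``"rbf"`` (default), ``"linear"`` or ``"polynomial"``.
    gamma: RBF width / polynomial scale; either a positive number or the
    string ``"scale"`` (the default), which resolves to
    ``1 / (n_features * Var(X))`` on the training features at hand so one
    concrete width is shared by neighborhood ranking and the local fit.
    """

    kind: str = "rbf"
    gamma: float | str = "scale"
    degree: int = 3
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if isinstance(self.gamma, str):
            if self.gamma != "scale":
                raise ValueError(f"gamma must be positive or 'scale', got {self.gamma!r}")
        elif self.kind in ("rbf", "polynomial") and not self.gamma > 0:
            raise ValueError("gamma must be positive")

    @property
    def is_resolved(self) -> bool:
        return not isinstance(self.gamma, str)

    def resolve(self, X: np.ndarray) -> "KernelSpec":
        """Pin ``gamma='scale'`` to a concrete value for the given features."""
        if self.is_resolved:
            return self
        X = np.atleast_2d(np.asarray(X, dtype=float))
        var = float(X.var())
        gamma = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
        return replace(self, gamma=gamma)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "gamma": self.gamma, "degree": self.degree, "coef0": self.coef0}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


@dataclass
class KernelMatrices:
    """Gram matrices for one train/test pairing.

    Ktr is the L x L training Gram matrix, Kte_diag the length-M vector of
    k(z_j, z_j), and Kcross the L x M cross matrix with entries k(x_i, z_j).
    """

    Ktr: np.ndarray
    Kte_diag: np.ndarray
    Kcross: np.ndarray


def kernel_function(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Evaluate k(a_i, b_j) for all row pairs of A and B."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if not spec.is_resolved:
        raise ValueError("gamma='scale' must be resolved against training features first")
    if spec.kind == "rbf":
        return rbf_kernel(A, B, gamma=spec.gamma)
    if spec.kind == "linear":
        return linear_kernel(A, B)
    return polynomial_kernel(A, B, degree=spec.degree, gamma=spec.gamma, coef0=spec.coef0)


def compute_kernel_matrices(train_X: np.ndarray, test_X: np.ndarray, spec: KernelSpec) -> KernelMatrices:
    """Training Gram matrix, test diagonal, and train-test cross matrix."""
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    spec = spec.resolve(train_X)
    Ktr = kernel_function(spec, train_X, train_X)
    Kcross = kernel_function(spec, train_X, test_X)
    if spec.kind == "rbf":
        Kte_diag = np.ones(len(test_X))
    else:
        Kte_diag = np.array([kernel_function(spec, z[None, :], z[None, :])[0, 0] for z in test_X])
    return KernelMatrices(Ktr=Ktr, Kte_diag=Kte_diag, Kcross=Kcross)


def kernel_space_distance(km: KernelMatrices) -> np.ndarray:
    """Squared feature-space distance kappa_{i,j} = K_ii - 2 K_ij + K_jj.

    Nonnegative for any positive semidefinite kernel (clipped at a tiny
    negative tolerance introduced by floating point); zero exactly when
    x_i = z_j for strictly positive-definite kernels.
    """
    kappa = np.diag(km.Ktr)[:, None] - 2.0 * km.Kcross + km.Kte_diag[None, :]
    return np.maximum(kappa, -1e-10)
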