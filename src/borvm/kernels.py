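"""Kernel functions and Gram matrices for the RVM basis.

Four families are supported — gaussian (RBF), laplacian, polynomial and
sigmoid — parameterized the conventional way: the scale ``gamma`` multiplies
the squared L2 distance, the L1 distance, or the inner product respectively.
The sigmoid kernel is indefinite; downstream fitting never assumes a
positive-definite Gram matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KERNEL_FAMILIES", "KernelSpec", "kernel_eval", "gram_matrix"]

KERNEL_FAMILIES = ("gaussian", "laplacian", "polynomial", "sigmoid")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its hyperparameters.

    ``coef0`` applies to polynomial and sigmoid kernels only; ``degree``
    (an integer in [1, 5]) to polynomial only. Unused parameters are ignored.
    """

    family: str
    gamma: float
    coef0: float = 0.0
    degree: int = 3

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.family == "polynomial" and not 1 <= int(self.degree) <= 5:
            raise ValueError(f"degree must be in [1, 5], got {self.degree}")

    def to_dict(self) -> dict:
        d = {"family": self.family, "gamma": float(self.gamma)}
        if self.family in ("polynomial", "sigmoid"):
            d["coef0"] = float(self.coef0)
        if self.family == "polynomial":
            d["degree"] = int(self.degree)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(
            family=d["family"],
            gamma=float(d["gamma"]),
            coef0=float(d.get("coef0", 0.0)),
            degree=int(d.get("degree", 3)),
        )


def _as_2d(a) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"expected 1-D or 2-D input, got ndim={arr.ndim}")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite entries in kernel input")
    return arr


def gram_matrix(spec: KernelSpec, X, Z=None) -> np.ndarray:
    """Kernel matrix K[i, j] = k(X[i], Z[j]); Z defaults to X."""
    X = _as_2d(X)
    Z = X if Z is None else _as_2d(Z)
    if X.shape[0] == 0 or Z.shape[0] == 0:
        raise ValueError("empty input to gram_matrix")
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if spec.family == "gaussian":
        return np.exp(-spec.gamma * cdist(X, Z, "sqeuclidean"))
    if spec.family == "laplacian":
        return np.exp(-spec.gamma * cdist(X, Z, "cityblock"))
    inner = spec.gamma * (X @ Z.T) + spec.coef0
    if spec.family == "polynomial":
        return inner ** int(spec.degree)
    return np.tanh(inner)  # sigmoid


def kernel_eval(spec: KernelSpec, u, v) -> float:
    """Evaluate k(u, v) for a single pair of vectors."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(gram_matrix(spec, u[None, :], v[None, :])[0, 0])
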