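"""Kernel functions and Gram-matrix construction for kernel RVMs.

A :class:`KernelSpec` names the basis family of an RVM design matrix.
``linear_basis`` means the features themselves (plus an intercept column)
are used as basis functions, so sparsity falls on markers; the remaining
families are kernels evaluated between pairs of individuals, so sparsity
falls on training points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "DEFAULT_GAMMA_GRID",
    "kernel_value",
    "kernel_matrix",
]

#: Gaussian bandwidths used for model selection over raw 0/1 genotypes.
DEFAULT_GAMMA_GRID = (1e-4, 2e-4, 3e-4)

_FAMILIES = ("linear_basis", "linear_kernel", "polynomial", "gaussian")

#: Ordering used to break exact ties during model selection (simpler first).
FAMILY_COMPLEXITY = {f: i for i, f in enumerate(_FAMILIES)}


@dataclass(frozen=True)
class KernelSpec:
    """Basis family of an RVM plus the kernel parameters it needs.

    Parameters
    ----------
    family:
        One of ``linear_basis``, ``linear_kernel``, ``polynomial``,
        ``gaussian``.
    gamma:
        Gaussian bandwidth, ``K(x, x') = exp(-gamma * ||x - x'||^2)``;
        required iff ``family == "gaussian"``.
    c, d:
        Polynomial offset (>= 0) and degree (>= 1),
        ``K(x, x') = (x . x' + c)^d``; meaningful only for ``polynomial``.
        A linear kernel is the polynomial kernel with ``c = 0, d = 1``.
    """

    family: str
    gamma: float | None = None
    c: float = 0.0
    d: int = 1

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "gaussian":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("gaussian kernel requires gamma > 0")
        elif self.gamma is not None:
            raise ValueError(f"gamma is only meaningful for the gaussian family, not {self.family!r}")
        if self.family == "polynomial":
            if self.c < 0:
                raise ValueError("polynomial kernel requires c >= 0")
            if self.d < 1:
                raise ValueError("polynomial kernel requires integer degree d >= 1")

    @property
    def is_kernel(self) -> bool:
        """True for pairwise-kernel families (everything but ``linear_basis``)."""
        return self.family != "linear_basis"

    def label(self) -> str:
        """Short human-readable name used in comparison tables and logs."""
        if self.family == "gaussian":
            return f"gaussian(gamma={self.gamma:g})"
        if self.family == "polynomial":
            return f"polynomial(c={self.c:g}, d={self.d})"
        return {"linear_basis": "linear basis", "linear_kernel": "linear kernel"}[self.family]

    # Convenience constructors --------------------------------------------
    @classmethod
    def linear_basis(cls) -> "KernelSpec":
        return cls("linear_basis")

    @classmethod
    def linear(cls) -> "KernelSpec":
        return cls("linear_kernel")

    @classmethod
    def polynomial(cls, c: float = 0.0, d: int = 2) -> "KernelSpec":
        return cls("polynomial", c=c, d=d)

    @classmethod
    def gaussian(cls, gamma: float) -> "KernelSpec":
        return cls("gaussian", gamma=gamma)


def kernel_value(x: np.ndarray, x2: np.ndarray, spec: KernelSpec) -> float:
    """Evaluate ``K(x, x2)`` for a single pair of input vectors."""
    x = np.asarray(x, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x.shape != x2.shape:
        raise ValueError(f"input vectors have mismatched lengths {x.size} and {x2.size}")
    if spec.family == "linear_basis":
        raise ValueError("linear_basis is not a pairwise kernel; build the design matrix instead")
    if spec.family == "gaussian":
        diff = x - x2
        return float(np.exp(-spec.gamma * diff @ diff))
    if spec.family == "polynomial":
        return float((x @ x2 + spec.c) ** spec.d)
    return float(x @ x2)  # linear_kernel


def kernel_matrix(X: np.ndarray, Y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix ``G[i, j] = K(X[i], Y[j])``, computed vectorised.

    Equals entrywise :func:`kernel_value` evaluation to machine precision.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature-count mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if spec.family == "linear_basis":
        raise ValueError("linear_basis is not a pairwise kernel; build the design matrix instead")
    if spec.family == "gaussian":
        d2 = cdist(X, Y, metric="sqeuclidean")
        return np.exp(-spec.gamma * d2)
    prod = X @ Y.T
    if spec.family == "polynomial":
        return (prod + spec.c) ** spec.d
    return prod
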