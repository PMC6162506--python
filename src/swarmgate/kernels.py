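"""Kernel functions for the soft-margin SVM.

Four families are supported, in the single-parameter convention used when
a tuner searches over one kernel parameter ``g``:

- linear:      k(x, y) = x.y
- polynomial:  k(x, y) = (g * x.y + coef0)^d
- rbf:         k(x, y) = exp(-g * ||x - y||^2), i.e. g = 1/(2 sigma^2)
- sigmoid:     k(x, y) = tanh(beta * x.y + theta)

The textbook Gaussian ``exp(-||x-y||^2 / (2 sigma^2))`` is recovered at
``g = 1/(2 sigma^2)`` and the plain polynomial ``(x.y)^d`` at ``g = 1,
coef0 = 0``.  Each family reads only its own parameters; the rest are
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["KernelSpec", "kernel_eval", "gram", "KERNEL_FAMILIES"]

KERNEL_FAMILIES = ("linear", "polynomial", "rbf", "sigmoid")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its parameters.

    ``g`` is the single tunable kernel parameter (rbf width / polynomial
    inner-product scale); ``degree`` and ``coef0`` apply to the polynomial
    family; ``beta`` and ``theta`` to the sigmoid family.
    """

    family: str = "rbf"
    g: float = 0.7
    degree: int = 3
    coef0: float = 0.0
    beta: float = 1.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family in ("polynomial", "rbf") and not self.g > 0:
            raise ValueError("kernel parameter g must be positive")
        if self.family == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")

    def with_g(self, g: float) -> "KernelSpec":
        """Copy with the tunable parameter replaced (tuner substitution)."""
        d = asdict(self)
        d["g"] = float(g)
        return KernelSpec(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def kernel_eval(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate ``k(x, y)`` for a single pair of vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(gram(spec, x[None, :], y[None, :])[0, 0])


def gram(spec: KernelSpec, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Kernel matrix ``K[i, j] = k(X[i], Y[j])`` (``Y=None`` means ``Y=X``)."""
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if spec.family == "linear":
        return X @ Y.T
    if spec.family == "polynomial":
        return (spec.g * (X @ Y.T) + spec.coef0) ** spec.degree
    if spec.family == "rbf":
        sq = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Y**2, axis=1)[None, :]
            - 2.0 * (X @ Y.T)
        )
        np.maximum(sq, 0.0, out=sq)
        return np.exp(-spec.g * sq)
    # sigmoid
    return np.tanh(spec.beta * (X @ Y.T) + spec.theta)
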