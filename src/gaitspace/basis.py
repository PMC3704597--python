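"""Orthonormal basis container shared by the PCA and SVM decompositions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BasisError
from .stats import LosoRateResult

__all__ = ["OrthonormalBasis", "check_orthonormal", "gram_schmidt"]


def check_orthonormal(vectors: np.ndarray, tol_dot: float = 1e-8, tol_norm: float = 1e-10) -> None:
    """Raise :class:`BasisError` unless the rows are pairwise orthonormal."""
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    G = V @ V.T
    norms = np.abs(np.diag(G) - 1.0)
    if norms.max(initial=0.0) > tol_norm:
        raise BasisError(f"vector norms deviate from 1 by up to {norms.max():.3e}")
    off = np.abs(G - np.diag(np.diag(G)))
    if off.max(initial=0.0) > tol_dot:
        raise BasisError(f"pairwise dot products up to {off.max():.3e} exceed {tol_dot}")


def gram_schmidt(vector: np.ndarray, against: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Purge ``vector`` of its components along the rows of ``against``.

    Returns the re-normalized residual; raises if the residual norm falls
    below ``tol`` (the vector lay in the span of ``against``).
    """
    v = np.asarray(vector, dtype=float).copy()
    A = np.atleast_2d(against)
    if A.size:
        v -= A.T @ (A @ v)
    n = np.linalg.norm(v)
    if n < tol:
        raise BasisError("vector lies in the span of the existing basis")
    return v / n


@dataclass
class OrthonormalBasis:
    """Ordered unit vectors in data space with per-vector bookkeeping.

    vectors : (k, p) array, one unit vector per row.
    variance : raw variance score per vector (eigenvalue-like, descending for
        a PCA basis).
    variance_fraction : share of the data's total sum of squares captured by
        each vector.
    rates : optional per-vector leave-one-subject-out classification results.
    effect_sizes : optional per-vector Cohen's d of the projections.
    """

    vectors: np.ndarray
    variance: np.ndarray | None = None
    variance_fraction: np.ndarray | None = None
    rates: list[LosoRateResult] | None = None
    effect_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))

    def __len__(self) -> int:
        return 0 if self.vectors.size == 0 else self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def validate(self, tol_dot: float = 1e-8, tol_norm: float = 1e-10) -> "OrthonormalBasis":
        if len(self):
            check_orthonormal(self.vectors, tol_dot, tol_norm)
        return self

    def project(self, X: np.ndarray) -> np.ndarray:
        """Coordinates of rows of X in this basis: (n, k)."""
        return np.asarray(X, dtype=float) @ self.vectors.T

    def significant_mask(self) -> np.ndarray:
        if self.rates is None:
            raise ValueError("no classification rates attached")
        return np.array([r.significant for r in self.rates], dtype=bool)
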