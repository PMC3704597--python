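"""Iterative linear-SVM subspace decomposition of dichotomous kinematic data.

The method replaces variance (PCA) with classifiability as the criterion for
building a basis.  One step extracts a discriminant direction with a linear
support vector machine under leave-one-subject-out cross-validation:

* for every held-out subject, fit a soft-margin linear SVM on the remaining
  subjects' whitened trials; the linear kernel makes the discriminant
  ``d = sum_i alpha_i y_i x_i`` a vector of the data space;
* classify the held-out subject's trials with that fold's decision function
  and apply the trial-level binomial test;
* the step's basis vector is the mean of the sign-aligned fold directions,
  renormalized; the step's classification rate is the fraction of
  classifiable subjects.

Accepted directions are deflated out of the data (projection onto the
orthogonal complement) and the step repeats until the rate loses subject-level
significance.  The accepted vectors span the SVM space — the part of the
movement that distinguishes the two conditions; a PCA of the final residual
spans its orthogonal complement — the part that does not.  Together they form
an orthonormal basis of the data space, and every vector carries the fraction
of total variance it explains (mean squared projection over total sum of
squares).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.svm import SVC

from .basis import OrthonormalBasis, check_orthonormal, gram_schmidt
from .errors import BasisError, DegenerateDataError
from .layout import AssembledMatrix
from .pca import _svd_basis
from .stats import (
    ClassifiabilityRule,
    LosoRateResult,
    classification_rate,
    cohens_d,
    normality_gate,
    subject_classifiable,
)

__all__ = [
    "Discriminant",
    "FoldFit",
    "DecompositionResult",
    "SVMSubspaceDecomposition",
    "fit_linear_discriminant",
    "loso_discriminant",
    "deflate",
    "svm_decompose",
    "explained_variance",
    "complement_pca",
]


@dataclass
class FoldFit:
    """One leave-one-subject-out fold of a discriminant extraction."""

    subject: str
    direction: np.ndarray  # unit vector, sign-aligned across folds
    bias: float
    scale: float  # |w| of the unnormalized discriminant
    correct: int
    total: int
    classifiable: bool


@dataclass
class Discriminant:
    """A unit discriminant direction with its decision offset.

    ``direction`` is unit-norm; the raw SVM decision function is
    ``f(x) = scale * (direction . x) + bias`` and its sign assigns the
    condition.  ``per_fold`` holds the LOSO folds when the discriminant was
    produced by cross-validation.
    """

    direction: np.ndarray
    bias: float
    scale: float = 1.0
    per_fold: list[FoldFit] = field(default_factory=list)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(X, float) @ self.direction) + self.bias


def fit_linear_discriminant(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = 1e-3
) -> Discriminant:
    """Fit a single soft-margin linear SVM and return its discriminant.

    The direction is the normalized weight vector ``w = sum alpha_i y_i x_i``;
    the normalization factor |w| is recorded in ``scale`` so the linear-kernel
    decision function is recoverable exactly.  ``tol`` is the QP stopping
    tolerance (tighten it for hard-margin geometry checks).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = list(dict.fromkeys(y.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    svc = SVC(kernel="linear", C=C, tol=tol)
    svc.fit(X, y)
    w = svc.coef_[0]
    norm = float(np.linalg.norm(w))
    if norm == 0.0:
        raise DegenerateDataError("SVM returned a zero weight vector")
    d = Discriminant(direction=w / norm, bias=float(svc.intercept_[0]), scale=norm)
    d._classes = svc.classes_  # positive decision -> classes_[1]
    return d


def _predict(disc: Discriminant, X: np.ndarray):
    pos, neg = disc._classes[1], disc._classes[0]
    return np.where(disc.decision(X) > 0, pos, neg)


def loso_discriminant(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    C: float = 1.0,
    rule: ClassifiabilityRule | None = None,
) -> tuple[Discriminant, LosoRateResult]:
    """Leave-one-subject-out discriminant: mean fold direction + rate.

    Fold directions are sign-aligned (non-negative dot product with the first
    fold) before averaging; the mean is renormalized to unit length so it can
    serve as a basis vector.  The reported bias is the mean of the aligned
    fold biases and plays no role in the basis itself.
    """
    rule = rule or ClassifiabilityRule()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    subjects = list(dict.fromkeys(groups))
    if len(subjects) < 3:
        raise ValueError("LOSO needs >= 3 subjects")
    folds: list[FoldFit] = []
    ref: np.ndarray | None = None
    dir_sum = np.zeros(X.shape[1])
    bias_sum = 0.0
    for s in subjects:
        test = groups == s
        try:
            disc = fit_linear_discriminant(X[~test], y[~test], C=C)
        except Exception as e:  # propagate with the fold identified
            raise type(e)(f"fold holding out subject {s!r}: {e}") from e
        pred = _predict(disc, X[test])
        correct = int((pred == y[test]).sum())
        total = int(test.sum())
        direction, bias = disc.direction, disc.bias
        if ref is None:
            ref = direction
        elif float(direction @ ref) < 0:
            direction, bias = -direction, -bias
        dir_sum += direction
        bias_sum += bias
        folds.append(
            FoldFit(
                subject=str(s),
                direction=direction,
                bias=bias,
                scale=disc.scale,
                correct=correct,
                total=total,
                classifiable=subject_classifiable(correct, total, rule),
            )
        )
    mean_dir = dir_sum / len(subjects)
    n = float(np.linalg.norm(mean_dir))
    if n == 0.0:
        raise DegenerateDataError("fold directions cancelled; mean discriminant is zero")
    overall = Discriminant(
        direction=mean_dir / n, bias=bias_sum / len(subjects), scale=1.0, per_fold=folds
    )
    flags = [f.classifiable for f in folds]
    rate, significant = classification_rate(flags, rule)
    per_subject = {f.subject: (f.correct, f.total, f.classifiable) for f in folds}
    return overall, LosoRateResult(rate, significant, per_subject, rule)


def deflate(X: np.ndarray, direction: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project every row of X onto the orthogonal complement of ``direction``."""
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > tol:
        raise BasisError(f"direction norm {np.linalg.norm(d):.12f} is not 1 +/- {tol}")
    X = np.asarray(X, dtype=float)
    return X - np.outer(X @ d, d)


def explained_variance(vectors: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Fraction of the total sum of squares captured by each unit vector."""
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    X = np.asarray(X, dtype=float)
    total = float((X**2).sum())
    if total == 0.0:
        raise DegenerateDataError("matrix has zero total variance")
    if V.size == 0:
        return np.zeros(0)
    return ((X @ V.T) ** 2).sum(axis=0) / total


def complement_pca(X_deflated: np.ndarray, rank_tol: float = 1e-10) -> OrthonormalBasis:
    """PCA basis of the residual left after removing the SVM space."""
    X = np.asarray(X_deflated, dtype=float)
    s_max = np.linalg.norm(X, 2) if X.size else 0.0
    if s_max == 0.0:
        return OrthonormalBasis(vectors=np.zeros((0, X.shape[1])))
    vectors, variance = _svd_basis(X, rank_tol)
    return OrthonormalBasis(vectors=vectors, variance=variance)


@dataclass
class DecompositionResult:
    """Outcome of the iterative SVM decomposition.

    svm_basis : accepted discriminant directions (the SVM space), with
        per-vector rates, variance fractions and the first vector's effect
        size attached.
    complement_basis : PCA basis of the orthogonal complement with variance
        fractions.
    discriminants : the accepted :class:`Discriminant` objects (fold detail).
    iteration_log : one entry per iteration including the final rejected one:
        ``{"iteration", "rate", "significant", "accepted", "per_subject"}``.
    termination : "rate_below_threshold", "rank_exhausted" or "max_iter".
    effect_size_first : Cohen's d of the projections on the first SVM vector
        (None when the SVM space is empty).
    normality_first : Lilliefors pass/fail per condition for those projections.
    rule, C : the statistical rule and SVM box constraint used.
    """

    svm_basis: OrthonormalBasis
    complement_basis: OrthonormalBasis
    discriminants: list[Discriminant]
    iteration_log: list[dict]
    termination: str
    effect_size_first: float | None
    normality_first: dict[str, bool] | None
    rule: ClassifiabilityRule
    C: float

    @property
    def n_svm_vectors(self) -> int:
        return len(self.svm_basis)

    def joint_basis(self) -> np.ndarray:
        """SVM basis stacked over the complement basis (full orthonormal set)."""
        parts = [b.vectors for b in (self.svm_basis, self.complement_basis) if len(b)]
        if not parts:
            return np.zeros((0, self.svm_basis.dim))
        return np.vstack(parts)


class SVMSubspaceDecomposition(BaseEstimator):
    """Iterative extraction of orthogonal SVM discriminants (sklearn-style).

    Parameters
    ----------
    C : float
        Soft-margin box constraint of the linear SVM.  The data are already
        whitened, so no internal rescaling is applied; the SVM-space
        dimensionality is known to be sensitive to this parameter, which is
        why it is recorded in every result.
    mode : {"paper", "exact"}
        Binomial threshold mode; the iteration stops when the LOSO
        classification rate loses subject-level significance under this rule.
    alpha : float
        Significance level of the binomial tests.
    max_iter : int
        Safety cap on accepted iterations (the rank bounds them anyway).
    rank_tol, gs_tol : float
        Numerical rank cutoff and Gram–Schmidt re-orthogonalization tolerance.

    Attributes
    ----------
    result_ : :class:`DecompositionResult`
    svm_basis_ : (m, p) array of accepted unit discriminant directions.
    complement_basis_ : (r, p) PCA basis of the orthogonal complement.
    rates_ : per accepted vector :class:`LosoRateResult`.
    variance_fraction_svm_, variance_fraction_complement_ : per-vector shares
        of the total sum of squares.
    """

    def __init__(
        self,
        C: float = 1.0,
        mode: str = "paper",
        alpha: float = 0.05,
        max_iter: int = 100,
        rank_tol: float = 1e-10,
        gs_tol: float = 1e-10,
    ):
        self.C = C
        self.mode = mode
        self.alpha = alpha
        self.max_iter = max_iter
        self.rank_tol = rank_tol
        self.gs_tol = gs_tol

    def fit(self, X, y=None, *, groups=None):
        X = np.asarray(X, dtype=float)
        if y is None or groups is None:
            raise ValueError(
                "SVMSubspaceDecomposition.fit requires y (conditions) and groups (subjects)"
            )
        y = np.asarray(y)
        groups = np.asarray(groups)
        rule = ClassifiabilityRule(mode=self.mode, alpha=self.alpha)
        s_max = float(np.linalg.norm(X, 2))
        if s_max == 0.0:
            raise DegenerateDataError("matrix has zero total variance")
        rank = int(np.linalg.matrix_rank(X, tol=self.rank_tol * s_max))

        accepted: list[np.ndarray] = []
        discriminants: list[Discriminant] = []
        rates: list[LosoRateResult] = []
        log: list[dict] = []
        residual = X.copy()
        termination = "max_iter"
        for it in range(1, self.max_iter + 1):
            if len(accepted) >= rank or float(np.linalg.norm(residual, 2)) <= self.rank_tol * s_max:
                termination = "rank_exhausted"
                break
            disc, rate = loso_discriminant(residual, y, groups, C=self.C, rule=rule)
            entry = {
                "iteration": it,
                "rate": rate.rate,
                "significant": rate.significant,
                "accepted": rate.significant,
                "per_subject": dict(rate.per_subject),
            }
            log.append(entry)
            if not rate.significant:
                termination = "rate_below_threshold"
                break
            direction = disc.direction
            if accepted:  # numerical drift guard; analytically already orthogonal
                direction = gram_schmidt(direction, np.array(accepted), tol=self.gs_tol)
            accepted.append(direction)
            disc.direction = direction
            discriminants.append(disc)
            rates.append(rate)
            residual = deflate(residual, direction)

        svm_vectors = np.array(accepted) if accepted else np.zeros((0, X.shape[1]))
        comp = complement_pca(residual, self.rank_tol)
        if len(svm_vectors) and len(comp):
            check_orthonormal(np.vstack([svm_vectors, comp.vectors]))

        effect = norm_gate = None
        svm_fracs = explained_variance(svm_vectors, X) if len(svm_vectors) else np.zeros(0)
        comp_fracs = explained_variance(comp.vectors, X) if len(comp) else np.zeros(0)
        comp.variance_fraction = comp_fracs
        effects = None
        if len(svm_vectors):
            effects = np.array([cohens_d(X @ v, y) for v in svm_vectors])
            effect = float(effects[0])
            counts = [int((y == c).sum()) for c in dict.fromkeys(y.tolist())]
            if min(counts) >= 4:
                norm_gate = normality_gate(X @ svm_vectors[0], y, alpha=self.alpha)
        svm_basis = OrthonormalBasis(
            vectors=svm_vectors,
            variance_fraction=svm_fracs,
            rates=rates,
            effect_sizes=effects,
        )
        self.result_ = DecompositionResult(
            svm_basis=svm_basis,
            complement_basis=comp,
            discriminants=discriminants,
            iteration_log=log,
            termination=termination,
            effect_size_first=effect,
            normality_first=norm_gate,
            rule=rule,
            C=self.C,
        )
        self.svm_basis_ = svm_vectors
        self.complement_basis_ = comp.vectors
        self.rates_ = rates
        self.variance_fraction_svm_ = svm_fracs
        self.variance_fraction_complement_ = comp_fracs
        self.effect_size_first_ = effect
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, space: str = "svm"):
        """Project rows of X onto the SVM space or its complement."""
        basis = {"svm": self.svm_basis_, "complement": self.complement_basis_}[space]
        return np.asarray(X, dtype=float) @ basis.T


def svm_decompose(
    matrix: AssembledMatrix,
    C: float = 1.0,
    rule: ClassifiabilityRule | None = None,
    max_iter: int = 100,
) -> DecompositionResult:
    """Run the full iterative decomposition on a whitened assembled matrix."""
    if not matrix.whitened:
        raise ValueError("svm_decompose expects a whitened matrix")
    rule = rule or ClassifiabilityRule()
    est = SVMSubspaceDecomposition(C=C, mode=rule.mode, alpha=rule.alpha, max_iter=max_iter)
    est.fit(matrix.values, matrix.labels, groups=matrix.groups)
    return est.result_
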