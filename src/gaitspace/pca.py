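"""PCA basis of the whitened matrix and its classifying/non-classifying split.

The PCA basis orders directions by explained variance.  Variance, however, is
not classifiability: the condition difference of interest typically hides in
higher-order components.  Each PCA vector is therefore scored by
leave-one-subject-out classification — rebuild the PCA without one subject,
project that subject's trials on the vector of the same ordinal index, assign
each trial with the shared 1-D midpoint rule, and gate with the binomial
tests.  Vectors with a significant rate form the classifying PCA space; the
rest form its non-classifying counterpart.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .basis import OrthonormalBasis
from .errors import DegenerateDataError, FoldRankError
from .layout import AssembledMatrix
from .stats import (
    ClassifiabilityRule,
    LosoRateResult,
    classification_rate,
    cohens_d,
    midpoint_assign,
    subject_classifiable,
)

__all__ = ["ClassifyingPCA", "pca_basis", "loso_rate_per_vector", "classifying_pca_space"]

#: relative singular-value cutoff for the numerical rank
RANK_TOL = 1e-10


def _svd_basis(X: np.ndarray, rank_tol: float = RANK_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Right-singular vectors and variance scores of X up to numerical rank."""
    X = np.asarray(X, dtype=float)
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        raise DegenerateDataError("matrix has rank 0")
    r = int((s > rank_tol * s[0]).sum())
    variance = s[:r] ** 2 / X.shape[0]
    return Vt[:r], variance


def pca_basis(matrix: AssembledMatrix | np.ndarray, rank_tol: float = RANK_TOL) -> OrthonormalBasis:
    """PCA basis (descending variance) of a whitened matrix via SVD."""
    X = matrix.values if isinstance(matrix, AssembledMatrix) else np.asarray(matrix, float)
    vectors, variance = _svd_basis(X, rank_tol)
    total = float((X**2).sum())
    return OrthonormalBasis(
        vectors=vectors,
        variance=variance,
        variance_fraction=variance * X.shape[0] / total,
    )


class ClassifyingPCA(BaseEstimator):
    """PCA with per-component leave-one-subject-out classification scoring.

    Parameters
    ----------
    n_components : int or None
        How many leading PCA vectors to score; None scores all up to rank.
    mode : {"paper", "exact"}
        Binomial threshold mode of the classifiability rule.
    alpha : float
        Significance level of both binomial tests.
    stability_cosine : float
        Fold-to-full |cosine| below which an ordinal-matching instability
        warning is emitted for a component.

    Attributes
    ----------
    components_ : (r, p) array of unit vectors (descending variance).
    explained_variance_ : per-component variance scores.
    explained_variance_ratio_ : fractions of the total sum of squares.
    rates_ : list of :class:`LosoRateResult`, one per scored component.
    significant_ : boolean mask over scored components.
    classifying_components_, nonclassifying_components_ : the partition.
    effect_sizes_ : Cohen's d of the projections per scored component.
    """

    def __init__(
        self,
        n_components: int | None = None,
        mode: str = "paper",
        alpha: float = 0.05,
        rank_tol: float = RANK_TOL,
        stability_cosine: float = 0.7,
    ):
        self.n_components = n_components
        self.mode = mode
        self.alpha = alpha
        self.rank_tol = rank_tol
        self.stability_cosine = stability_cosine

    def fit(self, X, y=None, *, groups=None):
        """Fit on a whitened trials x variables matrix.

        ``y`` are the two condition labels per row, ``groups`` the subject per
        row; both are required.
        """
        X = np.asarray(X, dtype=float)
        if y is None or groups is None:
            raise ValueError("ClassifyingPCA.fit requires y (conditions) and groups (subjects)")
        y = np.asarray(y)
        groups = np.asarray(groups)
        rule = ClassifiabilityRule(mode=self.mode, alpha=self.alpha)
        vectors, variance = _svd_basis(X, self.rank_tol)
        total = float((X**2).sum())
        k = len(vectors) if self.n_components is None else min(self.n_components, len(vectors))
        rates, effects = _score_components(
            X, y, groups, vectors[:k], rule, self.stability_cosine, self.rank_tol
        )
        self.components_ = vectors
        self.explained_variance_ = variance
        self.explained_variance_ratio_ = variance * X.shape[0] / total
        self.rates_ = rates
        self.effect_sizes_ = effects
        self.significant_ = np.array([r.significant for r in rates], dtype=bool)
        self.classifying_components_ = vectors[:k][self.significant_]
        self.nonclassifying_components_ = vectors[:k][~self.significant_]
        self.rule_ = rule
        self.n_scored_ = k
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.components_.T

    def basis_(self) -> OrthonormalBasis:
        """The scored PCA basis with rates and effect sizes attached."""
        k = self.n_scored_
        return OrthonormalBasis(
            vectors=self.components_[:k],
            variance=self.explained_variance_[:k],
            variance_fraction=self.explained_variance_ratio_[:k],
            rates=self.rates_,
            effect_sizes=self.effect_sizes_,
        )


def _score_components(X, y, groups, vectors, rule, stability_cosine, rank_tol):
    """LOSO-score each component ordinal; returns (rates, effect_sizes)."""
    subjects = list(dict.fromkeys(groups))
    if len(subjects) < 3:
        raise ValueError("LOSO scoring needs >= 3 subjects")
    conds = tuple(dict.fromkeys(y.tolist()))
    k = len(vectors)
    # per-fold PCA, computed once and reused for every ordinal
    fold_vectors: dict[str, np.ndarray] = {}
    for s in subjects:
        Vs, _ = _svd_basis(X[groups != s], rank_tol)
        fold_vectors[s] = Vs
    rates: list[LosoRateResult] = []
    effects = np.empty(k)
    for j in range(k):
        per_subject: dict[str, tuple[int, int, bool]] = {}
        for s in subjects:
            Vs = fold_vectors[s]
            if j >= len(Vs):
                raise FoldRankError(
                    f"fold without subject {s!r} has rank {len(Vs)} <= ordinal {j}"
                )
            v = Vs[j]
            cos = float(v @ vectors[j])
            if cos < 0:  # sign-align to the full-data vector
                v = -v
                cos = -cos
            if cos < stability_cosine:
                warnings.warn(
                    f"component {j + 1}: fold (held-out {s!r}) matches the "
                    f"full-data vector with |cos|={cos:.2f} < {stability_cosine}",
                    stacklevel=2,
                )
            test = groups == s
            proj_train = X[~test] @ v
            proj_test = X[test] @ v
            pred = midpoint_assign(proj_train, y[~test], proj_test, conds)
            correct = int((pred == y[test]).sum())
            total = int(test.sum())
            per_subject[str(s)] = (correct, total, subject_classifiable(correct, total, rule))
        flags = [ok for *_, ok in per_subject.values()]
        rate, significant = classification_rate(flags, rule)
        rates.append(LosoRateResult(rate, significant, per_subject, rule))
        effects[j] = cohens_d(X @ vectors[j], y)
    return rates, effects


def loso_rate_per_vector(
    matrix: AssembledMatrix,
    vector_index: int,
    rule: ClassifiabilityRule | None = None,
    rank_tol: float = RANK_TOL,
) -> LosoRateResult:
    """LOSO classification rate of the PCA vector with 1-based ordinal index."""
    rule = rule or ClassifiabilityRule()
    est = ClassifyingPCA(
        n_components=vector_index, mode=rule.mode, alpha=rule.alpha, rank_tol=rank_tol
    ).fit(matrix.values, matrix.labels, groups=matrix.groups)
    return est.rates_[vector_index - 1]


def classifying_pca_space(
    basis: OrthonormalBasis, rates: list[LosoRateResult]
) -> tuple[OrthonormalBasis, OrthonormalBasis]:
    """Partition a scored basis into (classifying, non-classifying) sub-bases."""
    if len(rates) != len(basis):
        raise ValueError("one rate per basis vector required")
    mask = np.array([r.significant for r in rates], dtype=bool)

    def _sub(m):
        idx = np.flatnonzero(m)
        return OrthonormalBasis(
            vectors=basis.vectors[idx],
            variance=None if basis.variance is None else basis.variance[idx],
            variance_fraction=None
            if basis.variance_fraction is None
            else basis.variance_fraction[idx],
            rates=[rates[i] for i in idx],
        )

    return _sub(mask), _sub(~mask)
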