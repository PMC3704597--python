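"""ICA refinement of the SVM space to a single discriminant.

The SVM space is redundant: every one of its basis vectors separates the same
two conditions, so projections on any two of them are correlated.  Running an
independent component analysis on the data's coordinates *within* the SVM
space isolates statistically independent directions; at most one of them can
carry the condition dependence (two independent discriminants would not be
independent), and that one is the ICA discriminant.

The default algorithm is extended infomax (the classical EEG-style choice),
deterministic given a seed; a FastICA alternative is configurable.  ICA
directions are mapped back to data space and unit-normalized — they span the
SVM space but are generally not orthogonal.  Because ICA solutions are not
guaranteed unique, the seed and algorithm are always recorded.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA

from .basis import OrthonormalBasis
from .errors import ConvergenceError, EmptyDataError
from .layout import AssembledMatrix
from .stats import ClassifiabilityRule, LosoRateResult, cohens_d, loso_project_rate
from .svm import DecompositionResult, explained_variance

__all__ = ["ICAResult", "ICASubspaceDiscriminant", "ica_in_subspace", "select_ica_discriminant"]


class ICAResult:
    """Container mirroring the fitted attributes of the estimator (see there)."""

    def __init__(self, **kw):
        self.__dict__.update(kw)


class ICASubspaceDiscriminant(BaseEstimator):
    """ICA inside the SVM space with LOSO scoring of every ICA vector.

    Parameters
    ----------
    algorithm : {"infomax", "fastica"}
        "infomax" = extended infomax; "fastica" = sklearn's deflationary
        FastICA with a logcosh contrast.
    random_state : int
        Seed of the ICA initialization (recorded in reports; ICA uniqueness
        is not guaranteed).
    mode, alpha : classifiability rule of the per-vector scoring.

    Attributes
    ----------
    ica_vectors_ : (m, p) unit vectors in data space ordered by descending
        classification rate ("first" = best classifying).
    mixing_, unmixing_ : transforms between SVM-space coordinates and source
        coordinates (``sources = coords @ unmixing_.T``,
        ``coords ~= sources @ mixing_.T``), ordered like ``ica_vectors_``.
    rates_ : per-vector :class:`LosoRateResult` of the source coordinates.
    effect_sizes_ : per-vector Cohen's d of the source coordinates.
    discriminant_index_ : 0-based index of the selected discriminant in the
        ordered vectors (in practice 0), or None when no vector classifies
        significantly.
    """

    def __init__(
        self,
        algorithm: str = "infomax",
        random_state: int = 0,
        mode: str = "paper",
        alpha: float = 0.05,
        max_iter: int = 500,
    ):
        self.algorithm = algorithm
        self.random_state = random_state
        self.mode = mode
        self.alpha = alpha
        self.max_iter = max_iter

    def fit(self, X, y=None, *, groups=None, basis: np.ndarray | OrthonormalBasis = None):
        """Fit on the whitened matrix given the SVM basis spanning the subspace."""
        X = np.asarray(X, dtype=float)
        if y is None or groups is None or basis is None:
            raise ValueError("fit requires y, groups and basis (the SVM space)")
        B = basis.vectors if isinstance(basis, OrthonormalBasis) else np.atleast_2d(basis)
        m = B.shape[0]
        if m == 0:
            raise EmptyDataError("SVM space is empty; nothing for the ICA to rotate")
        if X.shape[0] < 10 * m:
            import warnings

            warnings.warn(
                f"{X.shape[0]} trials for a {m}-dimensional space (< 10 x dim); "
                "ICA estimates may be unstable",
                stacklevel=2,
            )
        coords = X @ B.T  # (n, m) coordinates within the SVM space
        if m == 1:
            unmixing = np.eye(1)
        else:
            unmixing = self._unmix(coords)
        mixing = np.linalg.pinv(unmixing)
        cond = float(np.linalg.cond(mixing))
        # data-space direction of source j = image of the j-th mixing column
        vectors = (B.T @ mixing).T  # (m, p)
        norms = np.linalg.norm(vectors, axis=1)
        vectors = vectors / norms[:, None]
        rule = ClassifiabilityRule(mode=self.mode, alpha=self.alpha)
        # the ICA base is non-orthogonal, so the coordinate of the data along
        # ICA vector j is its source value (dual-basis functional), not a raw
        # dot product — raw projections onto oblique vectors would leak the
        # discriminant source into every component
        sources = coords @ unmixing.T
        rates = [loso_project_rate(sources[:, j], y, groups, rule) for j in range(m)]
        effects = np.array([cohens_d(sources[:, j], y) for j in range(m)])
        # order by rate (descending), ties by effect size
        order = sorted(range(m), key=lambda j: (-rates[j].rate, -effects[j]))
        vectors = vectors[order]
        rates = [rates[j] for j in order]
        effects = effects[order]
        mixing = mixing[:, order]
        unmixing = unmixing[order, :]
        self.ica_vectors_ = vectors
        self.mixing_ = mixing
        self.unmixing_ = unmixing
        self.condition_number_ = cond
        self.rates_ = rates
        self.effect_sizes_ = effects
        self.variance_fraction_ = explained_variance(vectors, X)
        self.basis_ = B
        self.rule_ = rule
        best = 0
        self.discriminant_index_ = best if rates[best].significant else None
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Source coordinates of rows of X (via the SVM-space coordinates)."""
        return (np.asarray(X, float) @ self.basis_.T) @ self.unmixing_.T

    def _unmix(self, coords: np.ndarray) -> np.ndarray:
        if self.algorithm == "infomax":
            from mne.preprocessing import infomax

            return infomax(
                coords,
                extended=True,
                max_iter=self.max_iter,
                rng=np.random.default_rng(self.random_state),
                verbose="error",
            )
        if self.algorithm == "fastica":
            ica = FastICA(
                n_components=coords.shape[1],
                algorithm="deflation",
                fun="logcosh",
                whiten="unit-variance",
                random_state=self.random_state,
                max_iter=self.max_iter,
            )
            ica.fit(coords)
            if ica.n_iter_ >= self.max_iter:
                raise ConvergenceError(f"FastICA did not converge in {ica.n_iter_} iterations")
            return ica.components_
        raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def result_(self) -> ICAResult:
        return ICAResult(
            ica_vectors=self.ica_vectors_,
            mixing=self.mixing_,
            unmixing=self.unmixing_,
            condition_number=self.condition_number_,
            rates=self.rates_,
            effect_sizes=self.effect_sizes_,
            variance_fraction=self.variance_fraction_,
            discriminant_index=self.discriminant_index_,
            seed=self.random_state,
            algorithm=self.algorithm,
        )


def ica_in_subspace(
    matrix: AssembledMatrix,
    svm_basis: OrthonormalBasis | np.ndarray,
    seed: int = 0,
    algorithm: str = "infomax",
    rule: ClassifiabilityRule | None = None,
) -> ICAResult:
    """Run ICA on the SVM-space coordinates of a whitened assembled matrix."""
    rule = rule or ClassifiabilityRule()
    est = ICASubspaceDiscriminant(
        algorithm=algorithm, random_state=seed, mode=rule.mode, alpha=rule.alpha
    ).fit(matrix.values, matrix.labels, groups=matrix.groups, basis=svm_basis)
    return est.result_()


def select_ica_discriminant(result: ICAResult) -> tuple[int | None, float | None, float | None]:
    """(1-based discriminant index, rate, effect size); index None if none significant."""
    idx = result.discriminant_index
    if idx is None:
        return None, None, None
    return idx + 1, result.rates[idx].rate, float(result.effect_sizes[idx])
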