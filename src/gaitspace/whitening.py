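"""Within-subject whitening of the data matrix.

Between-subject differences (anthropometry, individual movement style) dwarf
the condition effect of interest, so every variable is standardized within
each subject: subtract that subject's mean over all of their trials and
conditions pooled, divide by the corresponding standard deviation.  The
resulting matrix has zero mean and unit SD per variable within every subject
block, and the retained statistics allow exact de-whitening for metric
reconstruction.

The standard deviation uses the sample (n-1) denominator by default,
configurable via ``ddof``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateVariableError, StateError
from .layout import AssembledMatrix

__all__ = ["SubjectStats", "SubjectWhitener", "whiten", "dewhiten"]


@dataclass
class SubjectStats:
    """Per-subject, per-variable mean and SD used for (de-)whitening.

    ``degenerate[s]`` flags variables whose SD was zero for subject ``s``
    (only populated when whitening ran with ``on_degenerate="zero"``).
    """

    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    ddof: int = 1
    degenerate: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return list(self.mean)

    def degenerate_columns(self, subject: str) -> list[int]:
        """1-based column indices flagged degenerate for a subject."""
        mask = self.degenerate.get(subject)
        if mask is None:
            return []
        return [int(i) + 1 for i in np.flatnonzero(mask)]


class SubjectWhitener(BaseEstimator, TransformerMixin):
    """Per-subject standardization transformer.

    Unlike a plain ``StandardScaler``, statistics are computed and applied per
    subject group, so ``groups`` must accompany both ``fit`` and ``transform``
    (held-out subjects are whitened by their own statistics, never by the
    training subjects').

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom of the SD (1 = sample SD over trials).
    on_degenerate : {"error", "zero"}, default "error"
        Zero-SD variables either raise, or are set to 0 and flagged in
        ``stats_.degenerate`` (keeps the full column layout).
    """

    def __init__(self, ddof: int = 1, on_degenerate: str = "error"):
        self.ddof = ddof
        self.on_degenerate = on_degenerate

    def fit(self, X, y=None, *, groups=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (trials x variables)")
        if groups is None:
            raise ValueError("SubjectWhitener requires groups= (subject per row)")
        groups = np.asarray(groups)
        if groups.shape[0] != X.shape[0]:
            raise ValueError("groups length must match number of rows")
        if self.on_degenerate not in ("error", "zero"):
            raise ValueError("on_degenerate must be 'error' or 'zero'")
        mean: dict[str, np.ndarray] = {}
        std: dict[str, np.ndarray] = {}
        degen: dict[str, np.ndarray] = {}
        for s in _unique_in_order(groups):
            block = X[groups == s]
            if block.shape[0] < 2:
                raise ValueError(
                    f"subject {s!r} has {block.shape[0]} row(s); whitening needs >= 2"
                )
            mean[s] = block.mean(axis=0)
            std[s] = block.std(axis=0, ddof=self.ddof)
            zero = std[s] == 0.0
            if zero.any():
                if self.on_degenerate == "error":
                    cols = np.flatnonzero(zero)[:5] + 1
                    raise DegenerateVariableError(
                        f"subject {s!r} has zero SD in {int(zero.sum())} "
                        f"variable(s), e.g. columns {cols.tolist()} (1-based); "
                        "use on_degenerate='zero' to zero and flag them"
                    )
                degen[s] = zero
        self.stats_ = SubjectStats(mean=mean, std=std, ddof=self.ddof, degenerate=degen)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, groups=None):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        groups = self._check_groups(X, groups)
        out = np.empty_like(X)
        for s in _unique_in_order(groups):
            if s not in self.stats_.mean:
                raise StateError(f"no whitening statistics for subject {s!r}")
            idx = groups == s
            sd = self.stats_.std[s]
            zero = self.stats_.degenerate.get(s)
            safe_sd = sd if zero is None else np.where(zero, 1.0, sd)
            out[idx] = (X[idx] - self.stats_.mean[s]) / safe_sd
            if zero is not None:
                out[np.ix_(np.flatnonzero(idx), np.flatnonzero(zero))] = 0.0
        return out

    def inverse_transform(self, X, *, groups=None):
        """De-whiten: multiply by the subject SD and add the subject mean back."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        groups = self._check_groups(X, groups)
        out = np.empty_like(X)
        for s in _unique_in_order(groups):
            if s not in self.stats_.mean:
                raise StateError(f"no whitening statistics for subject {s!r}")
            idx = groups == s
            sd = self.stats_.std[s]
            zero = self.stats_.degenerate.get(s)
            safe_sd = sd if zero is None else np.where(zero, 0.0, sd)
            out[idx] = X[idx] * safe_sd + self.stats_.mean[s]
        return out

    def _check_fitted(self):
        if not hasattr(self, "stats_"):
            raise StateError("SubjectWhitener is not fitted")

    def _check_groups(self, X, groups):
        if groups is None:
            raise ValueError("transform requires groups= (subject per row)")
        groups = np.asarray(groups)
        if groups.shape[0] != X.shape[0]:
            raise ValueError("groups length must match number of rows")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} variables, fitted for {self.n_features_in_}"
            )
        return groups


def _unique_in_order(groups: np.ndarray) -> list:
    seen: dict = {}
    for g in groups:
        seen.setdefault(g, None)
    return list(seen)


def whiten(
    matrix: AssembledMatrix, ddof: int = 1, on_degenerate: str = "error"
) -> AssembledMatrix:
    """Whiten an assembled matrix within each subject; stats are retained.

    Returns a new :class:`AssembledMatrix` with ``whitened=True`` and
    ``subject_stats`` set; the input is untouched.
    """
    if matrix.whitened:
        raise StateError("matrix is already whitened")
    w = SubjectWhitener(ddof=ddof, on_degenerate=on_degenerate)
    groups = matrix.groups
    values = w.fit(matrix.values, groups=groups).transform(matrix.values, groups=groups)
    return matrix.with_values(values, whitened=True, subject_stats=w.stats_)


def dewhiten(matrix: AssembledMatrix) -> AssembledMatrix:
    """Invert :func:`whiten` using the stored per-subject statistics."""
    if not matrix.whitened:
        raise StateError("matrix is not whitened")
    if matrix.subject_stats is None:
        raise StateError("matrix carries no whitening statistics")
    stats = matrix.subject_stats
    out = np.empty_like(matrix.values)
    groups = matrix.groups
    for s in _unique_in_order(groups):
        idx = groups == s
        sd = stats.std[s]
        zero = stats.degenerate.get(s)
        safe_sd = sd if zero is None else np.where(zero, 0.0, sd)
        out[idx] = matrix.values[idx] * safe_sd + stats.mean[s]
    return matrix.with_values(out, whitened=False, subject_stats=None)
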