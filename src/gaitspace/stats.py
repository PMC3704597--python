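"""Classifiability statistics: binomial gating, effect sizes, the 1-D rule.

Classification above chance is judged at two levels with one-sided exact
binomial tests (p = 0.5, alpha = 0.05 by default):

* trial level — a held-out subject is "classifiable" when enough of their
  trials are assigned to the correct condition;
* subject level — a basis vector classifies significantly when enough
  held-out subjects are classifiable.  The fraction of classifiable subjects
  is the classification rate.

Two threshold modes exist.  ``exact`` uses the smallest k with
P(X >= k) <= alpha under Binomial(n, 1/2) — 26 of 40 trials, 9 of 11
subjects.  ``paper`` reproduces the printed historical counts (25 of 40,
8 of 11), which correspond to requiring P(X > k) <= alpha instead; both
generalize to any n and the active mode is stamped into every report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .errors import DegenerateDataError

__all__ = [
    "ClassifiabilityRule",
    "binomial_threshold",
    "subject_classifiable",
    "classification_rate",
    "cohens_d",
    "normality_gate",
    "midpoint_assign",
    "loso_project_rate",
    "LosoRateResult",
]


def binomial_threshold(
    n: int, alpha: float = 0.05, p: float = 0.5, mode: str = "exact"
) -> int | None:
    """Minimal success count deemed significant under Binomial(n, p).

    ``exact``: smallest k with P(X >= k) <= alpha; returns None when even
    k = n fails.  ``paper``: smallest k with P(X >= k+1) <= alpha, which
    reproduces the historical printed counts (25/40, 8/11) and always exists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if mode not in ("exact", "paper"):
        raise ValueError("mode must be 'exact' or 'paper'")
    shift = 0 if mode == "exact" else 1
    # P(X >= k + shift) = sf(k + shift - 1)
    for k in range(n + 1):
        if sps.binom.sf(k + shift - 1, n, p) <= alpha:
            return k
    return None


@dataclass(frozen=True)
class ClassifiabilityRule:
    """Shared statistical configuration of the classifiability tests.

    mode : "paper" (historical printed thresholds) or "exact" (exact
    one-sided binomial tail); alpha and the chance probability apply to both
    the trial-level and subject-level tests.
    """

    mode: str = "paper"
    alpha: float = 0.05
    success_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.mode in ("paper-compat", "paper_compat"):
            object.__setattr__(self, "mode", "paper")
        if self.mode not in ("paper", "exact"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def trial_threshold(self, n: int) -> int | None:
        """Minimal correct-trial count for a subject with n held-out trials."""
        return binomial_threshold(n, self.alpha, self.success_probability, self.mode)

    def subject_threshold(self, n: int) -> int | None:
        """Minimal classifiable-subject count out of n subjects."""
        return binomial_threshold(n, self.alpha, self.success_probability, self.mode)


def subject_classifiable(correct: int, total: int, rule: ClassifiabilityRule) -> bool:
    """Trial-level binomial test: is a held-out subject classifiable?"""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= correct <= total:
        raise ValueError(f"correct={correct} outside 0..{total}")
    thr = rule.trial_threshold(total)
    return thr is not None and correct >= thr


def classification_rate(
    classifiable: "list[bool] | np.ndarray", rule: ClassifiabilityRule
) -> tuple[float, bool]:
    """Fraction of classifiable subjects and its subject-level significance."""
    flags = np.asarray(classifiable, dtype=bool)
    if flags.size < 1:
        raise ValueError("need at least one subject")
    thr = rule.subject_threshold(flags.size)
    significant = thr is not None and int(flags.sum()) >= thr
    return float(flags.mean()), significant


def cohens_d(values: np.ndarray, labels: np.ndarray) -> float:
    """Absolute Cohen's d between the two label groups (pooled sample SD)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    conds = _two_conditions(labels)
    a = values[labels == conds[0]]
    b = values[labels == conds[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0.0:
        raise DegenerateDataError("pooled SD is zero; Cohen's d undefined")
    return float(abs(a.mean() - b.mean()) / pooled)


def normality_gate(
    values: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> dict[str, bool]:
    """Lilliefors normality decision per condition group (True = passes).

    The Lilliefors test is a Kolmogorov–Smirnov test against a normal with
    estimated mean and SD.  Effect sizes are still reported when a group
    fails, but callers flag them.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, bool] = {}
    for c in _two_conditions(labels):
        grp = values[labels == c]
        if len(grp) < 4:
            raise ValueError(f"group {c!r} has n={len(grp)} < 4; Lilliefors needs >= 4")
        _, pval = _lilliefors(grp, dist="norm")
        out[str(c)] = bool(pval > alpha)
    return out


def midpoint_assign(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    test_values: np.ndarray,
    conditions: tuple,
) -> np.ndarray:
    """1-D assignment: threshold at the midpoint of the training group means.

    The side above the midpoint is the condition with the larger training
    mean.  If the training means coincide the rule is degenerate; a warning
    is raised and every test value is assigned to the first condition
    (chance-level behavior).
    """
    a, b = conditions
    mu_a = float(np.mean(train_values[train_labels == a]))
    mu_b = float(np.mean(train_values[train_labels == b]))
    if mu_a == mu_b:
        warnings.warn(
            "degenerate 1-D rule: equal training means, chance assignment",
            stacklevel=2,
        )
        return np.full(len(test_values), a, dtype=object)
    hi, lo = (a, b) if mu_a > mu_b else (b, a)
    mid = 0.5 * (mu_a + mu_b)
    return np.where(np.asarray(test_values, dtype=float) > mid, hi, lo)


@dataclass
class LosoRateResult:
    """Leave-one-subject-out classification outcome of one direction."""

    rate: float
    significant: bool
    per_subject: dict[str, tuple[int, int, bool]]  # subject -> (correct, total, classifiable)
    rule: ClassifiabilityRule = field(default_factory=ClassifiabilityRule)

    @property
    def n_classifiable(self) -> int:
        return sum(1 for _, _, ok in self.per_subject.values() if ok)


def loso_project_rate(
    values: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    rule: ClassifiabilityRule | None = None,
) -> LosoRateResult:
    """Score 1-D projections by leave-one-subject-out classification.

    For every held-out subject the midpoint rule is trained on all other
    subjects' projections and applied to the held-out trials; the trial-level
    binomial test marks the subject classifiable, and the subject-level test
    judges the aggregate rate.  Shared by the PCA and ICA vector scoring.
    """
    rule = rule or ClassifiabilityRule()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    conds = _two_conditions(labels)
    per_subject: dict[str, tuple[int, int, bool]] = {}
    for s in dict.fromkeys(groups):
        test = groups == s
        train = ~test
        if len(set(labels[test])) < 2:
            raise ValueError(f"subject {s!r} lacks trials in both conditions")
        pred = midpoint_assign(values[train], labels[train], values[test], conds)
        correct = int((pred == labels[test]).sum())
        total = int(test.sum())
        per_subject[str(s)] = (
            correct,
            total,
            subject_classifiable(correct, total, rule),
        )
    flags = [ok for _, _, ok in per_subject.values()]
    rate, significant = classification_rate(flags, rule)
    return LosoRateResult(rate=rate, significant=significant, per_subject=per_subject, rule=rule)


def _two_conditions(labels: np.ndarray) -> tuple:
    conds = list(dict.fromkeys(np.asarray(labels).tolist()))
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    return conds[0], conds[1]
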