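import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gaitspace import (
    ClassifiabilityRule,
    binomial_threshold,
    classification_rate,
    cohens_d,
    loso_project_rate,
    normality_gate,
    subject_classifiable,
)
from gaitspace.errors import DegenerateDataError
from gaitspace.stats import midpoint_assign


class TestBinomialThreshold:
    @pytest.mark.parametrize(
        "n,mode,expected",
        [
            (5, "exact", 5),
            (4, "exact", None),
            (40, "exact", 26),
            (11, "exact", 9),
            (40, "paper", 25),
            (11, "paper", 8),
        ],
    )
    def test_known_thresholds(self, n, mode, expected):
        assert binomial_threshold(n, mode=mode) == expected

    def test_exact_tail_property_exhaustive(self):
        """Exact thresholds are the smallest k with P(X>=k) <= alpha, n <= 64."""
        prev = 0
        for n in range(1, 65):
            k = binomial_threshold(n, mode="exact")
            if k is None:
                continue
            assert sps.binom.sf(k - 1, n, 0.5) <= 0.05
            if k > 0:
                assert sps.binom.sf(k - 2, n, 0.5) > 0.05
            assert k >= prev  # monotone non-decreasing in n
            prev = k

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            binomial_threshold(0)
        with pytest.raises(ValueError):
            binomial_threshold(10, alpha=1.5)
        with pytest.raises(ValueError):
            binomial_threshold(10, p=0.0)


class TestClassifiability:
    def test_printed_trial_counts(self):
        paper = ClassifiabilityRule(mode="paper")
        exact = ClassifiabilityRule(mode="exact")
        assert subject_classifiable(25, 40, paper)
        assert not subject_classifiable(25, 40, exact)
        assert subject_classifiable(26, 40, exact)

    @pytest.mark.parametrize("mode", ["paper", "exact"])
    def test_perfect_classification(self, mode):
        rule = ClassifiabilityRule(mode=mode)
        for total in (5, 11, 40):
            assert subject_classifiable(total, total, rule)

    def test_rates(self):
        paper = ClassifiabilityRule(mode="paper")
        exact = ClassifiabilityRule(mode="exact")
        rate, sig = classification_rate([True] * 8 + [False] * 3, paper)
        assert rate == pytest.approx(8 / 11)
        assert sig
        _, sig_exact = classification_rate([True] * 8 + [False] * 3, exact)
        assert not sig_exact
        _, sig9 = classification_rate([True] * 9 + [False] * 2, exact)
        assert sig9
        rate0, sig0 = classification_rate([False] * 7, paper)
        assert rate0 == 0.0 and not sig0

    def test_mode_alias(self):
        assert ClassifiabilityRule(mode="paper-compat").mode == "paper"


class TestCohensD:
    def test_printed_toy_groups(self):
        assert cohens_d(np.array([1, 2, 3, 3, 4, 5.0]), np.array(list("aaabbb"))) == 2.0

    def test_identical_means(self):
        v = np.array([1.0, 2.0, 1.0, 2.0])
        assert cohens_d(v, np.array(list("aabb"))) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        v = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 9.0])
        labels = np.array(list("aaabbb"))
        assert cohens_d(c * v, labels) == pytest.approx(cohens_d(v, labels))

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            cohens_d(np.array([1.0, 1.0, 2.0, 2.0]), np.array(list("aabb")))


class TestNormalityGate:
    def test_normal_passes_uniform_fails(self):
        rng = np.random.default_rng(42)
        values = np.concatenate([rng.normal(size=500), rng.uniform(-1, 1, 500)])
        labels = np.array(["norm"] * 500 + ["unif"] * 500)
        result = normality_gate(values, labels)
        assert result == {"norm": True, "unif": False}

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n=3"):
            normality_gate(np.arange(7.0), np.array(["a"] * 3 + ["b"] * 4))


class TestLosoProjectRate:
    def _groups(self, n_subj, per_subj):
        return np.repeat([f"s{i}" for i in range(n_subj)], per_subj)

    def test_perfect_separation(self):
        n_subj, per_cond = 5, 6
        labels = np.tile(["a"] * per_cond + ["b"] * per_cond, n_subj)
        values = np.where(labels == "a", 1.0, -1.0) + np.random.default_rng(0).normal(
            0, 0.01, n_subj * 2 * per_cond
        )
        res = loso_project_rate(values, labels, self._groups(n_subj, 2 * per_cond))
        assert res.rate == 1.0 and res.significant

    def test_null_is_rarely_significant(self):
        rng = np.random.default_rng(123)
        n_subj, per_cond = 8, 10
        labels = np.tile(["a"] * per_cond + ["b"] * per_cond, n_subj)
        groups = self._groups(n_subj, 2 * per_cond)
        hits = sum(
            loso_project_rate(rng.normal(size=len(labels)), labels, groups,
                              ClassifiabilityRule(mode="exact")).significant
            for _ in range(50)
        )
        assert hits <= 5  # <= 10% of 50 label-independent draws

    def test_monotone_transform_invariance(self):
        """Any affine increasing transform preserves the midpoint decisions."""
        labels = np.tile(["a"] * 4 + ["b"] * 4, 4)
        groups = self._groups(4, 8)
        values = np.where(labels == "a", 2.0, -1.0) + np.random.default_rng(1).normal(
            0, 0.5, 32
        )
        base = loso_project_rate(values, labels, groups)
        scaled = loso_project_rate(3.0 * values + 7.0, labels, groups)
        assert base.per_subject == scaled.per_subject

    def test_sign_flip_invariance(self):
        labels = np.tile(["a"] * 4 + ["b"] * 4, 4)
        groups = self._groups(4, 8)
        values = np.where(labels == "a", 1.0, -1.0) + np.random.default_rng(2).normal(
            0, 0.3, 32
        )
        assert (
            loso_project_rate(values, labels, groups).rate
            == loso_project_rate(-values, labels, groups).rate
        )

    def test_degenerate_training_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            pred = midpoint_assign(
                np.array([1.0, 1.0]), np.array(["a", "b"]), np.array([5.0]), ("a", "b")
            )
        assert pred[0] == "a"
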