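import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats as sps

from gaitspace import (
    ClassifiabilityRule,
    EffectComponent,
    SVMSubspaceDecomposition,
    complement_pca,
    deflate,
    explained_variance,
    fit_linear_discriminant,
    loso_discriminant,
    svm_decompose,
    truth_alignment,
)
from gaitspace.errors import BasisError, DegenerateDataError

from conftest import hard_margin_oracle, null_whitened, planted_whitened


class TestLinearDiscriminant:
    def test_symmetric_pair(self):
        d = fit_linear_discriminant(np.array([[-1.0], [1.0]]), np.array(["a", "b"]))
        assert abs(abs(d.direction[0]) - 1.0) < 1e-10
        assert d.decision(np.array([[0.0]]))[0] == pytest.approx(0.0, abs=1e-9)
        # both training points on the correct side
        signs = np.sign(d.decision(np.array([[-1.0], [1.0]])))
        assert signs[0] != signs[1]

    def test_2d_hard_margin_geometry(self):
        """Groups {(0,0),(0,1)} vs {(2,0),(2,1)}: plane at x=1, normal (1,0)."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
        y = np.array(["a", "a", "b", "b"])
        d = fit_linear_discriminant(X, y, C=1e6)
        assert abs(abs(d.direction[0]) - 1.0) < 1e-8
        assert abs(d.direction[1]) < 1e-8
        assert d.decision(np.array([[1.0, 0.5]]))[0] == pytest.approx(0.0, abs=1e-8)

    def test_kernel_sum_identity(self):
        """Linear-kernel decision = scale * (x . direction) + bias, to 1e-8."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6))
        y = np.where(X[:, 0] + 0.2 * rng.normal(size=30) > 0, "a", "b")
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        d = fit_linear_discriminant(X, y)
        from sklearn.svm import SVC

        svc = SVC(kernel="linear", C=1.0).fit(X, y)
        probe = rng.normal(size=(10, 6))
        np.testing.assert_allclose(
            d.decision(probe), svc.decision_function(probe), atol=1e-8
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_linear_discriminant(np.zeros((3, 2)), np.array(["a", "a", "a"]))

    @pytest.mark.parametrize("seed", range(5))
    def test_hard_margin_matches_nearest_point_oracle(self, seed):
        """Max-margin direction equals the convex-hull nearest-point oracle."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 2))
        B = rng.normal(size=(6, 2)) + np.array([6.0, 1.0])
        X = np.vstack([A, B])
        y = np.array(["a"] * 6 + ["b"] * 6)
        d = fit_linear_discriminant(X, y, C=1e8, tol=1e-12)
        direction, margin = hard_margin_oracle(A, B)
        assert abs(abs(direction @ d.direction) - 1.0) < 1e-6
        assert 2.0 / d.scale == pytest.approx(margin, abs=1e-6)


class TestDeflate:
    @settings(derandomize=True, max_examples=50)
    @given(
        row=arrays(np.float64, 5, elements=st.floats(-10, 10)),
        raw=arrays(
            np.float64, 5, elements=st.floats(-2, 2)
        ).filter(lambda v: np.linalg.norm(v) > 0.1),
    )
    def test_output_orthogonal_and_idempotent(self, row, raw):
        d = raw / np.linalg.norm(raw)
        out = deflate(row[None, :], d)
        assert abs(out @ d)[0] < 1e-10
        np.testing.assert_allclose(deflate(out, d), out, atol=1e-12)

    def test_parallel_row_zeroed(self):
        d = np.array([0.6, 0.8])
        np.testing.assert_allclose(deflate(3 * d[None, :], d), 0.0, atol=1e-12)

    def test_orthogonal_row_unchanged(self):
        d = np.array([1.0, 0.0])
        row = np.array([[0.0, 2.5]])
        np.testing.assert_allclose(deflate(row, d), row, atol=1e-12)

    def test_non_unit_rejected(self):
        with pytest.raises(BasisError):
            deflate(np.ones((1, 2)), np.array([1.0, 1.0]))


class TestExplainedVariance:
    def test_axis_toy(self):
        X = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        fr = explained_variance(np.eye(2), X)
        np.testing.assert_allclose(fr, [0.8, 0.2])

    def test_single_row_on_basis_vector(self):
        e = np.eye(3)
        X = e[0][None, :]
        np.testing.assert_allclose(explained_variance(e, X), [1.0, 0.0, 0.0])

    def test_full_basis_sums_to_one(self, planted):
        w, _ = planted
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(w.n_variables, 50)))
        # not a complete basis; use SVD basis instead for completeness
        from gaitspace import pca_basis

        basis = pca_basis(w)
        assert explained_variance(basis.vectors, w.values).sum() == pytest.approx(
            1.0, abs=1e-8
        )

    def test_zero_matrix(self):
        with pytest.raises(DegenerateDataError):
            explained_variance(np.eye(2), np.zeros((3, 2)))


class TestLosoDiscriminant:
    def test_planted_effect_fully_classifiable(self, planted):
        w, truth = planted
        disc, rate = loso_discriminant(
            w.values, w.labels, w.groups, rule=ClassifiabilityRule(mode="exact")
        )
        assert rate.rate == 1.0 and rate.significant
        # fold directions nearly parallel after sign alignment
        dirs = np.array([f.direction for f in disc.per_fold])
        gram = dirs @ dirs.T
        assert gram[np.triu_indices(len(dirs), 1)].min() >= 0.8
        assert abs(np.linalg.norm(disc.direction) - 1.0) < 1e-10

    def test_shuffled_labels_not_significant(self, planted):
        w, _ = planted
        rng = np.random.default_rng(99)
        y = w.labels.copy()
        rng.shuffle(y)
        _, rate = loso_discriminant(
            w.values, y, w.groups, rule=ClassifiabilityRule(mode="exact")
        )
        assert not rate.significant


class TestDecomposition:
    @pytest.fixture(scope="class")
    def decomposed(self):
        w, truth = planted_whitened(seed=1)
        est = SVMSubspaceDecomposition(mode="exact").fit(
            w.values, w.labels, groups=w.groups
        )
        return w, truth, est

    def test_planted_direction_recovered(self, decomposed):
        _, truth, est = decomposed
        assert est.result_.n_svm_vectors >= 1
        al = truth_alignment(est.svm_basis_, truth)
        assert al["cosines"][0] >= 0.95

    def test_joint_basis_orthonormal(self, decomposed):
        _, _, est = decomposed
        J = est.result_.joint_basis()
        G = J @ J.T
        assert np.abs(G - np.eye(len(G))).max() < 1e-8

    def test_variance_conservation(self, decomposed):
        _, _, est = decomposed
        total = est.variance_fraction_svm_.sum() + est.variance_fraction_complement_.sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_accepted_rates_significant_final_rejected(self, decomposed):
        _, _, est = decomposed
        res = est.result_
        assert all(r.significant for r in res.svm_basis.rates)
        assert res.termination == "rate_below_threshold"
        assert not res.iteration_log[-1]["significant"]

    def test_complement_vectors_do_not_classify(self, decomposed):
        from gaitspace import loso_project_rate

        w, _, est = decomposed
        rule = ClassifiabilityRule(mode="exact")
        for v in est.complement_basis_[:3]:
            assert not loso_project_rate(w.values @ v, w.labels, w.groups, rule).significant

    def test_null_data_yields_empty_svm_basis(self):
        w = null_whitened(seed=4)
        res = svm_decompose(w, rule=ClassifiabilityRule(mode="exact"))
        assert res.n_svm_vectors == 0
        assert res.termination == "rate_below_threshold"
        assert len(res.complement_basis) > 0

    def test_iteration_bounded_by_rank(self, decomposed):
        _, _, est = decomposed
        assert est.result_.n_svm_vectors <= np.linalg.matrix_rank(
            np.asarray(est.svm_basis_) if len(est.svm_basis_) else np.zeros((1, 1))
        ) + len(est.complement_basis_)


class TestRedundancy:
    def test_timing_effect_gives_correlated_svm_projections(self):
        """A condition-timing effect yields a multi-D SVM space whose
        projections are mutually correlated (the redundancy property)."""
        w, _ = planted_whitened(
            seed=1,
            trials_per_condition=20,
            effect_snr=None,
            effects=(
                EffectComponent(
                    marker=3, axis=3, center=16, width=3, amplitude=0.5,
                    shape="timing", timing_delta=6.0, timing_sd=1.5,
                ),
            ),
        )
        res = svm_decompose(w, rule=ClassifiabilityRule(mode="paper"))
        assert res.n_svm_vectors >= 2
        r, p = sps.pearsonr(
            w.values @ res.svm_basis.vectors[0], w.values @ res.svm_basis.vectors[1]
        )
        assert abs(r) > 0 and p < 0.05


class TestComplementPca:
    def test_zero_residual_empty_basis(self):
        basis = complement_pca(np.zeros((4, 6)))
        assert len(basis) == 0

    def test_rank_matches(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4)) @ rng.normal(size=(4, 8))  # rank 4
        assert len(complement_pca(X)) == 4
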