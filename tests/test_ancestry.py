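import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prismvote.ancestry import (
    PCAncestry,
    assign_strata,
    fit_pca,
    membership_likelihood,
    normalize,
    posterior_propensity,
    project,
    propensity_matrix,
    read_eigenvec,
    weighted_score,
    write_eigenvec,
)
from prismvote.simulate import draw_maf_spectra, simulate_genotypes


class TestNormalize:
    def test_single_column_arithmetic(self):
        # g = (0,1,2): mean 1, p = (1+3)/(2+6) = 0.5, scale sqrt(0.5)
        nm = normalize(np.array([[0.0], [1.0], [2.0]]))
        np.testing.assert_allclose(nm.X.ravel(), [-1.41421356, 0.0, 1.41421356],
                                   atol=1e-8)
        assert nm.p[0] == pytest.approx(0.5)

    def test_constant_column_is_zero(self):
        nm = normalize(np.ones((5, 1)))
        np.testing.assert_allclose(nm.X, 0.0)

    def test_monomorphic_column_finite(self):
        # shrunk frequency (1+0)/(2+8) = 0.1 keeps the scale positive
        nm = normalize(np.zeros((4, 1)))
        assert nm.p[0] == pytest.approx(0.1)
        assert np.isfinite(nm.X).all()
        np.testing.assert_allclose(nm.X, 0.0)

    def test_columns_centered(self):
        rng = np.random.default_rng(0)
        nm = normalize(rng.binomial(2, 0.3, (40, 15)).astype(float))
        np.testing.assert_allclose(nm.X.mean(axis=0), 0.0, atol=1e-12)
        assert ((nm.p > 0) & (nm.p < 1)).all()


class TestPCA:
    @pytest.mark.parametrize("n,p", [(20, 50), (50, 20)])
    def test_matches_dense_eigendecomposition(self, n, p):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(n, p))
        q = 5
        model = fit_pca(X, q=q)
        lam_ref = np.sort(np.linalg.eigvalsh(X @ X.T / p))[::-1][:q]
        np.testing.assert_allclose(model.eigenvalues, lam_ref, atol=1e-8)
        # eigenvectors diagonalize the covariance
        psi = X @ X.T / p
        for r in range(q):
            v = model.eigenvectors[:, r]
            np.testing.assert_allclose(psi @ v, model.eigenvalues[r] * v,
                                       atol=1e-8)

    def test_weights_normalized_eigenvalues(self):
        # construct a spectrum with top eigenvalues (3, 1) -> a = (0.75, 0.25)
        rng = np.random.default_rng(2)
        n, p = 30, 40
        Qm, _ = np.linalg.qr(rng.normal(size=(n, n)))
        V, _ = np.linalg.qr(rng.normal(size=(p, n)))
        s = np.sqrt(np.array([3.0, 1.0] + [1e-4] * (n - 2)) * p)
        X = Qm @ np.diag(s) @ V.T
        model = fit_pca(X, q=2)
        np.testing.assert_allclose(model.weights, [0.75, 0.25], atol=1e-6)
        np.testing.assert_allclose(model.weights.sum(), 1.0)

    def test_single_component_degenerate(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 8))
        model = fit_pca(X, q=1)
        np.testing.assert_allclose(model.weights, [1.0])
        np.testing.assert_allclose(model.scores, model.eigenvectors[:, 0])

    def test_q_exceeding_rank_raises(self):
        X = np.outer(np.arange(6.0), np.ones(4))  # rank 1 after thinking
        with pytest.raises(ValueError):
            fit_pca(X - X.mean(0), q=3)
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).normal(size=(5, 3)), q=4)

    def test_two_population_separation(self):
        # Balding-Nichols Fst 0.1: thresholding w recovers labels >= 99%
        rng = np.random.default_rng(10)
        p1, p2 = draw_maf_spectra(2000, 0.1, rng)
        Q = np.zeros((500, 2))
        Q[:250, 0] = 1.0
        Q[250:, 1] = 1.0
        G = simulate_genotypes(p1, p2, Q, rng).astype(float)
        model = fit_pca(normalize(G), q=10)
        w = model.scores
        labels = (w > np.median(w)).astype(int)
        truth = (np.arange(500) >= 250).astype(int)
        acc = max((labels == truth).mean(), (labels != truth).mean())
        assert acc >= 0.99

    def test_projection_reproduces_training_loadings(self):
        rng = np.random.default_rng(4)
        G = rng.binomial(2, 0.3, (30, 60)).astype(float)
        nm = normalize(G)
        model = fit_pca(nm, q=4)
        U = project(model, G)
        np.testing.assert_allclose(U, model.eigenvectors, atol=1e-8)
        w = weighted_score(U, model.weights)
        np.testing.assert_allclose(w, model.scores, atol=1e-8)


class TestStrata:
    def test_two_bins_arithmetic(self):
        model, labels = assign_strata(np.array([1.0, 2.0, 3.0, 4.0]), K=2)
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])
        np.testing.assert_allclose(model.centers, [1.5, 3.5])
        np.testing.assert_allclose(model.priors, [0.5, 0.5])
        np.testing.assert_allclose(model.variances, [0.5, 0.5])

    def test_single_stratum(self):
        model, labels = assign_strata(np.array([3.0, 1.0, 2.0]), K=1)
        assert model.K == 1
        np.testing.assert_allclose(model.priors, [1.0])
        assert set(labels) == {0}

    def test_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(5)
        model, _ = assign_strata(rng.normal(size=103), K=4)
        assert model.sizes.max() - model.sizes.min() <= 1
        assert model.sizes.sum() == 103

    def test_undersized_stratum_raises(self):
        with pytest.raises(ValueError, match="smaller K"):
            assign_strata(np.array([1.0, 2.0, 3.0]), K=2)

    def test_centers_strictly_increasing(self):
        rng = np.random.default_rng(6)
        model, _ = assign_strata(rng.normal(size=60), K=5)
        assert (np.diff(model.centers) > 0).all()
        assert model.priors.sum() == pytest.approx(1.0)


class TestMembership:
    def test_zero_distance_probability_one(self):
        assert membership_likelihood(0.3, 0.3, 0.7) == pytest.approx(1.0)

    def test_chi_squared_tail_value(self):
        # standardized squared distance 3.841459 is the 5% point of chi2_1
        lik = membership_likelihood(np.sqrt(3.841459), 0.0, 1.0)
        assert lik == pytest.approx(0.05, abs=1e-4)

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 4, 30)
        lik = membership_likelihood(d, 0.0, 1.0)
        assert (np.diff(lik) < 0).all()

    def test_posterior_arithmetic(self):
        post = posterior_propensity([0.8, 0.2], [0.75, 0.25])
        np.testing.assert_allclose(post, [0.6 / 0.65, 0.05 / 0.65], atol=1e-8)

    def test_posterior_symmetry_and_degenerate_prior(self):
        np.testing.assert_allclose(
            posterior_propensity([0.5, 0.5], [0.5, 0.5]), [0.5, 0.5])
        np.testing.assert_allclose(
            posterior_propensity([0.3, 0.9], [1.0, 0.0]), [1.0, 0.0])

    def test_zero_likelihood_falls_back_to_priors(self):
        with pytest.warns(RuntimeWarning, match="zero likelihood"):
            post = posterior_propensity([0.0, 0.0], [0.7, 0.3])
        np.testing.assert_allclose(post, [0.7, 0.3])

    @given(st.lists(st.floats(1e-6, 1e3), min_size=2, max_size=6),
           st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_row_sum(self, lik, scale):
        lik = np.array(lik)
        priors = np.full(len(lik), 1.0 / len(lik))
        a = posterior_propensity(lik, priors)
        b = posterior_propensity(scale * lik, priors)
        np.testing.assert_allclose(a, b, rtol=1e-9)
        assert abs(a.sum() - 1.0) < 1e-10
        assert ((a >= 0) & (a <= 1)).all()

    def test_propensity_matrix_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        w = rng.normal(size=200)
        strata, _ = assign_strata(w, K=4)
        M = propensity_matrix(rng.normal(size=50), strata)
        assert M.shape == (50, 4)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-10)


class TestEigenvecIO:
    def test_plink_dialect_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        G = rng.binomial(2, 0.3, (25, 40)).astype(float)
        model = fit_pca(normalize(G), q=3)
        samples = [f"S{i}" for i in range(25)]
        prefix = str(tmp_path / "pca")
        write_eigenvec(model, samples, prefix)
        back_samples, back = read_eigenvec(prefix)
        assert back_samples == samples
        np.testing.assert_allclose(back.eigenvectors, model.eigenvectors)
        np.testing.assert_allclose(back.scores, model.scores)


class TestPCAncestryEstimator:
    def test_fit_predict_labels_match_populations(self):
        rng = np.random.default_rng(11)
        p1, p2 = draw_maf_spectra(500, 0.2, rng)
        Q = np.zeros((120, 2))
        Q[:60, 0] = 1.0
        Q[60:, 1] = 1.0
        G = simulate_genotypes(p1, p2, Q, rng)
        est = PCAncestry(q=5, K=2).fit(G.astype(float))
        hard = est.predict()
        truth = (np.arange(120) >= 60).astype(int)
        acc = max((hard == truth).mean(), (hard != truth).mean())
        assert acc >= 0.95
        M = est.predict_proba()
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-10)
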