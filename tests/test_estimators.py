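"""Standardization, GRM/LD construction, and the heritability estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heritsim import estimators as est
from heritsim import simdata
from heritsim.estimators import NonIdentifiableError


def _sim(spec, n, h2=0.8, seed=0, backend="binomial_threshold"):
    freqs = simdata.draw_allele_freqs(spec.n_base, seed=seed)
    data = simdata.sim_genotypes(n, spec, freqs, backend=backend, seed=seed + 1)
    trait = simdata.sim_phenotype(data, h2, seed=seed + 2)
    return data, trait


class TestStandardize:
    def test_symmetric_half_frequency_column(self):
        std = est.standardize(np.array([[0], [1], [2]]))
        assert np.allclose(std.gamma[:, 0], [-np.sqrt(2), 0.0, np.sqrt(2)])

    def test_empirical_columns_centered_unit_scale(self):
        # near-unit variance requires Hardy-Weinberg counts
        G = np.random.default_rng(0).binomial(2, 0.3, size=(500, 6))
        std = est.standardize(G)
        assert np.allclose(std.gamma.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose((std.gamma**2).mean(axis=0), 1.0, atol=0.2)

    def test_monomorphic_dropped_with_warning(self):
        G = np.array([[2, 0], [2, 1], [2, 2]])
        with pytest.warns(UserWarning, match="monomorphic"):
            std = est.standardize(G)
        assert std.M == 1
        assert np.array_equal(std.kept, [False, True])

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValueError, match="no usable"):
            est.standardize(np.full((4, 3), 2))

    def test_alpha_minus_one_is_default(self):
        G = np.random.default_rng(1).integers(0, 3, size=(50, 4))
        a = est.standardize(G)
        b = est.standardize(G, alpha=-1.0)
        assert np.allclose(a.gamma, b.gamma)

    def test_literal_exponent_variant_differs(self):
        G = np.random.default_rng(2).integers(0, 3, size=(50, 4))
        lit = est.standardize(G, alpha=-1.0, literal_exponent=True)
        assert not np.allclose(lit.gamma, est.standardize(G).gamma)


class TestGRMAndLD:
    def test_orthogonal_rows_give_identity_grm(self):
        std = est.StdGenotypeMatrix(
            gamma=np.array([[1.0, 1.0], [1.0, -1.0]]),
            freq_source="true", alpha=-1.0, kept=np.ones(2, bool),
        )
        assert np.allclose(est.compute_grm(std).psi, np.eye(2))
        assert np.allclose(est.compute_ld(std).sigma, np.eye(2))

    def test_duplicated_individual_and_marker(self):
        g = np.random.default_rng(3).standard_normal((4, 3))
        g[1] = g[0]
        std = est.StdGenotypeMatrix(g, "true", -1.0, np.ones(3, bool))
        psi = est.compute_grm(std).psi
        assert psi[0, 1] == pytest.approx(psi[0, 0])
        g2 = np.random.default_rng(4).standard_normal((5, 3))
        g2 = np.column_stack([g2, g2[:, 0]])
        std2 = est.StdGenotypeMatrix(g2, "true", -1.0, np.ones(4, bool))
        sig = est.compute_ld(std2).sigma
        assert sig[0, 3] == pytest.approx(sig[0, 0])

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_grm_matches_double_loop_oracle(self, seed):
        g = np.random.default_rng(seed).standard_normal((5, 7))
        std = est.StdGenotypeMatrix(g, "true", -1.0, np.ones(7, bool))
        psi = est.compute_grm(std).psi
        brute = np.empty((5, 5))
        for i in range(5):
            for k in range(5):
                brute[i, k] = sum(g[i, j] * g[k, j] for j in range(7)) / 7
        assert np.allclose(psi, brute, atol=1e-12)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_trace_identity(self, seed):
        # n^2 tr(Sigma^2) = M^2 tr(Psi^2) is exact algebra
        g = np.random.default_rng(seed).standard_normal((6, 4))
        std = est.StdGenotypeMatrix(g, "true", -1.0, np.ones(4, bool))
        psi = est.compute_grm(std).psi
        sig = est.compute_ld(std).sigma
        lhs = 6**2 * np.trace(sig @ sig)
        rhs = 4**2 * np.trace(psi @ psi)
        assert abs(lhs - rhs) <= 1e-10 * abs(rhs)


class TestHERegression:
    def test_small_worked_example(self):
        y = np.array([1.0, 2.0, -1.0])
        psi = np.eye(3)
        psi[0, 1] = psi[1, 0] = 0.1
        psi[0, 2] = psi[2, 0] = 0.2
        psi[1, 2] = psi[2, 1] = 0.3
        fit = est.he_regression(y, psi)
        assert fit.diagnostics["S_YPsi"] == pytest.approx(-0.6)
        assert fit.diagnostics["S_PsiPsi"] == pytest.approx(0.14)
        assert fit.sigma_g2_hat == pytest.approx(-0.6 / 0.14)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        A = rng.standard_normal((n, n)) * 0.1
        psi = A @ A.T + np.eye(n)
        y = rng.standard_normal(n)
        fit = est.he_regression(y, psi)
        num = sum(y[i] * y[k] * psi[i, k] for k in range(n) for i in range(k))
        den = sum(psi[i, k] ** 2 for k in range(n) for i in range(k))
        assert fit.sigma_g2_hat == pytest.approx(num / den, rel=1e-10)

    def test_diagonal_grm_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            est.he_regression(np.array([1.0, 2.0, 3.0]), np.eye(3))

    def test_matrix_form_close_to_exact_form(self):
        # the matrix form replaces y'diag(Psi)y by n, which is tight only
        # for a variance-standardized phenotype
        data, trait = _sim(simdata.LDStructureSpec("independent", m=500), 500, seed=10)
        y = trait.y / trait.y.std(ddof=1)
        std = est.standardize_data(data)
        grm = est.compute_grm(std)
        a = est.he_regression(y, grm).sigma_g2_hat
        b = est.he_matrix_form(y, grm).sigma_g2_hat
        assert abs(a - b) / abs(a) < 0.02

    def test_matrix_form_preconditions(self):
        with pytest.raises(NonIdentifiableError):
            est.he_matrix_form(np.random.default_rng(5).standard_normal(20), np.eye(20))
        data, trait = _sim(simdata.LDStructureSpec("independent", m=20), 100, seed=11)
        grm = est.compute_grm(est.standardize_data(data))
        with pytest.raises(ValueError, match="variance"):
            est.he_matrix_form(3.0 * trait.y, grm)


class TestDickerFamily:
    def test_dicker1_orthonormal_design_is_zero(self):
        gamma = np.array([[1.0, 1.0], [1.0, -1.0]])
        std = est.StdGenotypeMatrix(gamma, "true", -1.0, np.ones(2, bool))
        # ||Gamma'y||^2 = 4 and M y'y = 4 cancel exactly; the constant
        # phenotype leaves h2 undefined (NaN), not an error
        fit = est.dicker1(np.array([1.0, 1.0]), std)
        assert fit.sigma_g2_hat == pytest.approx(0.0)
        assert np.isnan(fit.h2_hat)
        # same cancellation for a non-constant phenotype
        assert est.dicker1(np.array([1.0, -1.0]), std).sigma_g2_hat == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=15)
    @given(st.integers(0, 10_000))
    def test_dicker1_quadratic_form_identity(self, seed):
        # M y'Psi y - M y'y equals ||Gamma'y||^2 - M y'y identically
        rng = np.random.default_rng(seed)
        g = rng.standard_normal((8, 5))
        y = rng.standard_normal(8)
        std = est.StdGenotypeMatrix(g, "true", -1.0, np.ones(5, bool))
        psi = est.compute_grm(std).psi
        lhs = 5 * (y @ psi @ y) - 5 * (y @ y)
        gty = g.T @ y
        rhs = gty @ gty - 5 * (y @ y)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_dicker1_sigma_identity_whitening_equals_dicker1(self):
        rng = np.random.default_rng(6)
        q, _ = np.linalg.qr(rng.standard_normal((50, 10)))
        gamma = np.sqrt(50) * q  # Sigma = Gamma'Gamma/n = I exactly
        std = est.StdGenotypeMatrix(gamma, "true", -1.0, np.ones(10, bool))
        y = rng.standard_normal(50)
        a = est.dicker1(y, std).sigma_g2_hat
        b = est.dicker1_sigma(y, std).sigma_g2_hat
        assert a == pytest.approx(b, rel=1e-10)

    def test_dicker1_sigma_refuses_wide_design(self):
        data, trait = _sim(simdata.LDStructureSpec("independent", m=30), 20, seed=12)
        std = est.standardize_data(data)
        with pytest.raises(ValueError, match="not invertible"):
            est.dicker1_sigma(trait.y, std, mode="inverse")

    def test_dicker1_sigma_unbiased_with_population_ld(self):
        # whitening by the population LD matrix removes the LD bias in the
        # tall-design regime
        spec = simdata.LDStructureSpec("autocorrelation", m=25, rho=0.6)
        vals = []
        for s in range(100):
            data, trait = _sim(spec, 500, seed=1000 + 3 * s, backend="gaussian")
            std = est.standardize_data(data)
            fit = est.dicker1_sigma(trait.y, std, sigma=data.true_ld)
            vals.append(fit.sigma_g2_hat)
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - 0.8) < 3 * se

    def test_dicker1_sigma_empirical_whitening_shrinks(self):
        # whitening by the same data's empirical Sigma collapses to the
        # column-space projection, shrinking by about (n-M)/(n+1)
        spec = simdata.LDStructureSpec("autocorrelation", m=25, rho=0.6)
        vals = []
        for s in range(60):
            data, trait = _sim(spec, 500, seed=7000 + 3 * s, backend="gaussian")
            std = est.standardize_data(data)
            vals.append(est.dicker1_sigma(trait.y, std).sigma_g2_hat)
        expected = 0.8 * (500 - 50) / 501
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - expected) < 3 * se + 0.02

    def test_dicker2_mu1_unit_diagonal(self):
        data, trait = _sim(simdata.LDStructureSpec("independent", m=50), 200, seed=13)
        std = est.standardize_data(data)
        fit = est.dicker2(trait.y, std)
        assert fit.diagnostics["mu1"] == pytest.approx(1.0, abs=0.05)

    def test_dicker2_degenerate_identity_sigma(self):
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.standard_normal((12, 12)))
        gamma = np.sqrt(12) * q  # Sigma = I with M = n: mu2 = 0
        std = est.StdGenotypeMatrix(gamma, "true", -1.0, np.ones(12, bool))
        with pytest.raises(NonIdentifiableError, match="mu2"):
            est.dicker2(rng.standard_normal(12), std)

    def test_dicker2_tracks_he(self):
        data, trait = _sim(
            simdata.LDStructureSpec("autocorrelation", m=100, rho=0.8), 1000, seed=14
        )
        std = est.standardize_data(data)
        he = est.he_regression(trait.y, est.compute_grm(std)).sigma_g2_hat
        d2 = est.dicker2(trait.y, std).sigma_g2_hat
        assert abs(he - d2) / abs(he) < 0.02


class TestLikelihood:
    def test_single_observation_value(self):
        # n=1, Psi=[1], y=0: -(1/2) log(2 pi)
        ll = est.mvn_loglik(np.array([0.0]), np.array([[1.0]]), 0.5, 0.5)
        assert ll == pytest.approx(-0.9189385332046727)

    def test_identity_grm_flat_ridge(self):
        y = np.random.default_rng(8).standard_normal(30)
        psi = np.eye(30)
        # likelihood depends on (sg2, se2) only through the sum
        a = est.mvn_loglik(y, psi, 0.3, 0.7)
        b = est.mvn_loglik(y, psi, 0.6, 0.4)
        assert a == pytest.approx(b, rel=1e-12)

    @settings(derandomize=True, max_examples=10)
    @given(st.integers(0, 10_000))
    def test_eigendecomposition_matches_dense_solve(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((50, 20))
        psi = A @ A.T / 20
        y = rng.standard_normal(50)
        sg2, se2 = 0.7, 0.4
        V = sg2 * psi + se2 * np.eye(50)
        sign, logdet = np.linalg.slogdet(V)
        direct = -0.5 * (50 * np.log(2 * np.pi) + logdet + y @ np.linalg.solve(V, y))
        assert est.mvn_loglik(y, psi, sg2, se2) == pytest.approx(direct, abs=1e-8)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            est.mvn_loglik(np.zeros(3), np.eye(3), -2.0, 1.0)

    def test_fit_identity_grm_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            est.fit_variance_components(np.random.default_rng(9).standard_normal(40), np.eye(40))

    def test_fit_recovers_truth_on_average(self):
        spec = simdata.LDStructureSpec("independent", m=100)
        vals = []
        for s in range(10):
            data, trait = _sim(spec, 800, seed=2000 + 3 * s)
            grm = est.compute_grm(est.standardize_data(data))
            vals.append(est.fit_variance_components(trait.y, grm).h2_hat)
        assert abs(np.mean(vals) - 0.8) < 0.1

    def test_null_trait_hits_lower_boundary(self):
        spec = simdata.LDStructureSpec("independent", m=50)
        freqs = simdata.draw_allele_freqs(100, seed=30)
        data = simdata.sim_genotypes(300, spec, freqs, seed=31)
        y = np.random.default_rng(32).standard_normal(300)  # sigma_g2 = 0
        grm = est.compute_grm(est.standardize_data(data))
        fit = est.fit_variance_components(y, grm)
        assert fit.diagnostics["boundary"] or fit.h2_hat < 0.05

    def test_reml_close_to_ml_at_moderate_n(self):
        data, trait = _sim(simdata.LDStructureSpec("independent", m=50), 300, seed=33)
        grm = est.compute_grm(est.standardize_data(data))
        ml = est.fit_variance_components(trait.y, grm, method="ML").h2_hat
        reml = est.fit_variance_components(trait.y, grm, method="REML").h2_hat
        assert abs(ml - reml) < 0.1


class TestGoldStandard:
    def test_pure_genetic_trait_gives_one(self):
        rng = np.random.default_rng(10)
        gamma = rng.standard_normal((40, 5))
        beta = rng.standard_normal(5)
        y = gamma @ beta
        assert est.gold_standard(gamma, beta, y).h2_hat == pytest.approx(1.0)

    def test_null_effects_give_zero(self):
        rng = np.random.default_rng(11)
        gamma = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        assert est.gold_standard(gamma, np.zeros(5), y).h2_hat == 0.0

    def test_tracks_truth_with_smaller_spread_than_he(self):
        spec = simdata.LDStructureSpec("independent", m=100)
        gold, he = [], []
        for s in range(30):
            data, trait = _sim(spec, 500, seed=4000 + 3 * s)
            std = est.standardize_data(data)
            gold.append(est.gold_standard_from_trait(trait).h2_hat)
            he.append(est.he_regression(trait.y, est.compute_grm(std)).h2_hat)
        assert abs(np.mean(gold) - 0.8) < 0.05
        assert np.std(gold, ddof=1) < np.std(he, ddof=1)

    def test_zero_variance_phenotype(self):
        with pytest.raises(ValueError):
            est.gold_standard(np.zeros((5, 2)), np.zeros(2), np.ones(5))


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.1, 3.0, -2.0])
    def test_sigma_g2_scales_quadratically_h2_invariant(self, c):
        data, trait = _sim(simdata.LDStructureSpec("independent", m=30), 150, seed=15)
        std = est.standardize_data(data)
        grm = est.compute_grm(std)
        for fn in (
            lambda y: est.he_regression(y, grm),
            lambda y: est.dicker1(y, std),
            lambda y: est.dicker2(y, std),
        ):
            base = fn(trait.y)
            scaled = fn(c * trait.y)
            assert scaled.sigma_g2_hat == pytest.approx(c**2 * base.sigma_g2_hat, rel=1e-9)
            assert scaled.h2_hat == pytest.approx(base.h2_hat, rel=1e-9)
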