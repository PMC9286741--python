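import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

from gxeqtl import (FounderProbMatrix, VarianceComponents, build_covariance,
                    compute_kinship, fit_emma, fit_gxemm, gradients,
                    neg_log_likelihood)
from gxeqtl.gxemm import _nll_and_grad, _pack


def _marker_map(chroms, positions=None):
    n = len(chroms)
    return pd.DataFrame({
        "marker_id": [f"mk{i}" for i in range(n)],
        "chrom": chroms,
        "pos_bp": positions if positions is not None else range(100, 100 * (n + 1), 100),
    })


def _one_hot(states):
    states = np.asarray(states)
    P = np.zeros(states.shape + (8,))
    np.put_along_axis(P, states[..., None], 1.0, axis=-1)
    return P


class TestKinship:
    def test_identical_mosaics_give_unit_kinship(self):
        states = np.tile(np.array([0, 3, 3, 5, 7]), (2, 1))
        fp = FounderProbMatrix(_one_hot(states), _marker_map(["chr1"] * 5))
        K = compute_kinship(fp).K
        assert K == pytest.approx(np.ones((2, 2)))

    def test_disjoint_mosaics_give_zero_cross_kinship(self):
        states = np.array([[0, 1, 2, 3, 4], [5, 6, 7, 5, 6]])
        fp = FounderProbMatrix(_one_hot(states), _marker_map(["chr1"] * 5))
        K = compute_kinship(fp).K
        assert K[0, 1] == 0.0
        assert K[0, 0] == 1.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(8), size=(20, 50))
        fp = FounderProbMatrix(probs, _marker_map(["chr1"] * 25 + ["chr2"] * 25))
        K = compute_kinship(fp).K
        brute = np.zeros((20, 20))
        for m in range(20):
            for n in range(20):
                brute[m, n] = np.mean([probs[m, v] @ probs[n, v]
                                       for v in range(50)])
        np.testing.assert_allclose(K, brute, atol=1e-12)

    def test_loco_excludes_whole_chromosome(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet(np.ones(8), size=(10, 40))
        fp = FounderProbMatrix(probs, _marker_map(["chr1"] * 20 + ["chr2"] * 20))
        K_loco = compute_kinship(fp, exclude_chrom="chr1")
        fp2 = FounderProbMatrix(probs[:, 20:], _marker_map(["chr2"] * 20))
        np.testing.assert_allclose(K_loco.K, compute_kinship(fp2).K, atol=1e-14)
        assert K_loco.excluded_chrom == "chr1"

    def test_excluding_everything_is_an_error(self):
        fp = FounderProbMatrix(_one_hot(np.zeros((2, 3), dtype=int)),
                               _marker_map(["chr1"] * 3))
        with pytest.raises(ValueError, match="no markers"):
            compute_kinship(fp, exclude_chrom="chr1")

    def test_founder_prob_diagonal_bounds(self, small_sim):
        d = np.diag(small_sim["K"].K)
        assert (d >= 1 / 8 - 1e-12).all() and (d <= 1 + 1e-12).all()


@pytest.fixture(scope="module")
def instance30():
    rng = np.random.default_rng(30)
    N, E = 30, 2
    A = rng.standard_normal((N, N))
    K = A @ A.T / N
    Z = np.zeros((N, E))
    Z[np.arange(N), rng.integers(E, size=N)] = 1
    X = np.column_stack([np.ones(N), rng.standard_normal(N)])
    Y = 1.0 + rng.standard_normal(N) * 2
    return Y, X, K, Z


class TestLikelihood:
    def test_iid_reduction_matches_gaussian_ols(self):
        rng = np.random.default_rng(3)
        N = 40
        X = np.ones((N, 1))
        Y = rng.standard_normal(N) * 1.3 + 5
        rho2, sigma2 = 0.4, 0.9
        vc = VarianceComponents(np.zeros(1), rho2, [0.0], [sigma2])
        nll = neg_log_likelihood(vc, Y, X, np.eye(N), np.ones((N, 1)))
        v = rho2 + sigma2
        resid = Y - Y.mean()
        expected = 0.5 * (N * np.log(2 * np.pi * v) + resid @ resid / v)
        assert nll == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_multivariate_normal(self, instance30):
        Y, X, K, Z = instance30
        vc = VarianceComponents(np.zeros(2), 0.5, [0.3, 0.7], [1.0, 1.4])
        Lam = build_covariance(vc, K, Z)
        Li = np.linalg.inv(Lam)
        alpha = np.linalg.solve(X.T @ Li @ X, X.T @ Li @ Y)
        ll = scipy.stats.multivariate_normal.logpdf(Y, X @ alpha, Lam)
        assert neg_log_likelihood(vc, Y, X, K, Z) == pytest.approx(-ll, rel=1e-12)

    def test_invariant_to_sample_permutation(self, instance30):
        Y, X, K, Z = instance30
        vc = VarianceComponents(np.zeros(2), 0.5, [0.3, 0.7], [1.0, 1.4])
        perm = np.random.default_rng(4).permutation(len(Y))
        a = neg_log_likelihood(vc, Y, X, K, Z)
        b = neg_log_likelihood(vc, Y[perm], X[perm], K[np.ix_(perm, perm)], Z[perm])
        assert a == pytest.approx(b, rel=1e-12)

    def test_collinear_fixed_effects_rejected(self, instance30):
        Y, X, K, Z = instance30
        vc = VarianceComponents(np.zeros(3), 0.5, [0.3, 0.7], [1.0, 1.4])
        Xc = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            neg_log_likelihood(vc, Y, Xc, K, Z)


class TestGradients:
    def test_matches_central_finite_differences(self, instance30):
        Y, X, K, Z = instance30
        rng = np.random.default_rng(5)
        for _ in range(10):
            s2 = rng.uniform(0.5, 2.0, 2)
            r2 = rng.uniform(0.1, 1.0)
            om = rng.uniform(0.1, 1.0, 2)
            vc = VarianceComponents(np.zeros(2), r2, om, s2, constrained=False)
            g = gradients(vc, Y, X, K, Z)
            ga = np.concatenate([g["sigma2"], [g["rho2"]], g["omega"]])
            th0 = _pack(s2, r2, om)
            for i in range(len(th0)):
                h = 1e-6 * max(abs(th0[i]), 1.0)
                tp, tm = th0.copy(), th0.copy()
                tp[i] += h
                tm[i] -= h
                fd = -(_nll_and_grad(tp, Y, X, K, Z)[0]
                       - _nll_and_grad(tm, Y, X, K, Z)[0]) / (2 * h)
                assert ga[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_gradient_vanishes_at_unconstrained_optimum(self):
        # simulate from the model so the optimum lies in the interior
        rng = np.random.default_rng(60)
        N = 60
        A = rng.standard_normal((N, N))
        K = A @ A.T / N
        Z = np.zeros((N, 2))
        Z[np.arange(N), rng.integers(2, size=N)] = 1
        X = np.ones((N, 1))
        vc_true = VarianceComponents(np.zeros(1), 0.5, [0.8, 0.6], [1.0, 1.2])
        L = np.linalg.cholesky(build_covariance(vc_true, K, Z))
        Y = L @ rng.standard_normal(N)
        fit = fit_gxemm(Y, X, K, Z, constrained=False, seed=0)
        # polish to a tight stationary point, then check the gradient norm
        res = scipy.optimize.minimize(
            _nll_and_grad, _pack(fit.sigma2, fit.rho2, fit.omega),
            args=(Y, X, K, Z), jac=True, method="BFGS",
            options={"gtol": 1e-9, "maxiter": 200})
        assert np.linalg.norm(res.jac) < 1e-6

    def test_quadratic_term_matches_dense_algebra(self, instance30):
        Y, X, K, Z = instance30
        vc = VarianceComponents(np.zeros(2), 0.4, [0.2, 0.3], [1.0, 1.2])
        Lam = build_covariance(vc, K, Z)
        Li = np.linalg.inv(Lam)
        P = Li - Li @ X @ np.linalg.inv(X.T @ Li @ X) @ X.T @ Li
        g = gradients(vc, Y, X, K, Z)
        dense = -0.5 * np.trace(Li @ K) + 0.5 * Y @ P @ K @ P @ Y
        assert g["rho2"] == pytest.approx(dense, rel=1e-10)


class TestFits:
    def test_null_truth_recovers_zero_genetics(self, small_sim):
        K, Z = small_sim["K"], small_sim["Z"]
        N = K.K.shape[0]
        X = np.ones((N, 1))
        shares = []
        rng = np.random.default_rng(6)
        for _ in range(15):
            Y = rng.standard_normal(N)
            fit = fit_gxemm(Y, X, K, Z, seed=0, n_starts=1)
            genetic = fit.rho2 + fit.omega.sum()
            shares.append(genetic / (genetic + fit.sigma2.mean()))
        assert np.median(shares) < 0.1

    def test_constrained_boundary_gives_exact_zero(self, small_sim):
        K, Z = small_sim["K"], small_sim["Z"]
        N = K.K.shape[0]
        X = np.ones((N, 1))
        rng = np.random.default_rng(8)
        hit = False
        for _ in range(10):
            Y = rng.standard_normal(N)
            un = fit_gxemm(Y, X, K, Z, constrained=False, seed=0, n_starts=1)
            if (un.omega < -1e-4).any():
                con = fit_gxemm(Y, X, K, Z, constrained=True, seed=0, n_starts=1)
                assert (con.omega[un.omega < -1e-4] == 0.0).all()
                hit = True
        assert hit, "no replicate produced a negative unconstrained optimum"

    def test_nesting_and_multistart_invariants(self, small_sim, small_phenotype):
        K, Z = small_sim["K"], small_sim["Z"]
        Y = small_phenotype["Y"]
        X = np.ones((len(Y), 1))
        g = fit_gxemm(Y, X, K, Z, seed=1, n_starts=3)
        e = fit_emma(Y, X, K, seed=1, n_starts=3)
        assert g.loglik >= e.loglik - 1e-6  # EMMA nested in GxEMM
        # best-of-starts beats every start's initial likelihood
        th = _pack(g.sigma2, g.rho2, g.omega)
        assert -_nll_and_grad(th, Y, X, K.K, Z.astype(float))[0] == pytest.approx(
            g.loglik, rel=1e-9)

    def test_fit_deterministic_given_seed(self, small_sim, small_phenotype):
        K, Z = small_sim["K"], small_sim["Z"]
        Y = small_phenotype["Y"]
        X = np.ones((len(Y), 1))
        a = fit_gxemm(Y, X, K, Z, seed=42, n_starts=2)
        b = fit_gxemm(Y, X, K, Z, seed=42, n_starts=2)
        np.testing.assert_array_equal(a.sigma2, b.sigma2)
        np.testing.assert_array_equal(a.omega, b.omega)
        assert a.rho2 == b.rho2

    def test_emma_iid_reduction_matches_ols_variance(self):
        rng = np.random.default_rng(9)
        N = 120
        X = np.column_stack([np.ones(N), rng.standard_normal(N)])
        Y = X @ np.array([3.0, 0.5]) + rng.standard_normal(N)
        fit = fit_emma(Y, X, np.eye(N), seed=0)
        resid = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
        mle_var = float(resid @ resid) / N
        assert fit.rho2 + fit.sigma2[0] == pytest.approx(mle_var, abs=1e-6)
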