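import numpy as np
import pytest
from scipy.optimize import brentq, minimize
from scipy.special import expit

from mmlgp.kernels import KernelStack, combine, gaussian_gram, median_bandwidth
from mmlgp.model import (
    MultiLabelGP,
    collapse_equivalence_check,
    decide,
    full_prior_cov,
    laplace_fit,
    predict_latent,
    predict_proba,
    predict_proba_ghq,
    sample_weights,
)
from reference import BinaryLaplaceGP


def toy_problem(rng, n=4, Q=2):
    X = rng.standard_normal((n, 2))
    K = gaussian_gram(X, median_bandwidth(X))
    C = np.array([[1.0, 0.5], [0.5, 1.0]])[:Q, :Q]
    Y = rng.choice([-1, 1], size=(n, Q))
    Y[:, 0][Y.sum(axis=1) == -Q] = 1  # every row >= 1 positive
    return K, C, Y


class TestSampleWeights:
    def test_balanced_single_label_uniform(self):
        Y = np.array([[1, -1], [-1, 1], [1, -1], [-1, 1]])
        assert np.allclose(sample_weights(Y), 1.0)

    def test_minority_upweighted_exact_values(self):
        # 9 samples carry only L1, one carries only L2
        Y = -np.ones((10, 2), dtype=int)
        Y[:9, 0] = 1
        Y[9, 1] = 1
        w = sample_weights(Y)
        assert np.allclose(w[:9], 5 / 9)
        assert w[9] == pytest.approx(5.0)

    def test_duplication_invariance(self, rng):
        Y = rng.choice([-1, 1], size=(12, 3))
        Y[:, 0][(Y > 0).sum(axis=1) == 0] = 1
        w1 = sample_weights(Y)
        w2 = sample_weights(np.vstack([Y, Y]))
        assert np.allclose(w2[:12], w1)

    def test_mean_one(self, rng):
        Y = rng.choice([-1, 1], size=(30, 4), p=[0.8, 0.2])
        Y[:, 0][(Y > 0).sum(axis=1) == 0] = 1
        assert sample_weights(Y).mean() == pytest.approx(1.0, abs=1e-12)

    def test_row_without_positive_rejected(self):
        with pytest.raises(ValueError, match="no positive"):
            sample_weights(np.array([[1, -1], [-1, -1]]))


class TestPriorConstruction:
    def test_identity_C_factorizes(self, rng):
        K = gaussian_gram(rng.standard_normal((3, 2)), 1.0)
        S = full_prior_cov(np.eye(2), K)
        assert np.allclose(S[:3, :3], K)
        assert np.allclose(S[3:, 3:], K)
        assert np.allclose(S[:3, 3:], 0.0)

    def test_explicit_tensor_expansion(self, rng):
        K, C, _ = toy_problem(rng, n=2)
        S = full_prior_cov(C, K)
        for k in range(2):
            for l in range(2):
                for i in range(2):
                    for j in range(2):
                        assert S[k * 2 + i, l * 2 + j] == pytest.approx(
                            C[k, l] * K[i, j]
                        )

    def test_kronecker_spectrum(self, rng):
        K, C, _ = toy_problem(rng, n=3)
        ev = np.sort(np.linalg.eigvalsh(full_prior_cov(C, K)))
        outer = np.sort(np.outer(np.linalg.eigvalsh(C), np.linalg.eigvalsh(K)).ravel())
        assert np.allclose(ev, outer, atol=1e-8)


class TestCollapseEquivalence:
    def test_single_view_trivial(self, rng):
        X = rng.standard_normal((3, 2))
        stack = KernelStack([gaussian_gram(X, 1.0)], [1.0], ["v"])
        assert collapse_equivalence_check(stack, np.eye(2), np.array([1.0]))

    def test_two_view_random(self, rng):
        X1, X2 = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        stack = KernelStack(
            [gaussian_gram(X1, 1.0), gaussian_gram(X2, 0.7)], [1.0, 0.7], ["a", "b"]
        )
        C = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert collapse_equivalence_check(stack, C, np.array([0.3, 1.2]))

    def test_selection_weight(self, rng):
        X1, X2 = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        K1 = gaussian_gram(X1, 1.0)
        stack = KernelStack([K1, gaussian_gram(X2, 1.0)], [1.0, 1.0], ["a", "b"])
        C = np.eye(2)
        assert collapse_equivalence_check(stack, C, np.array([1.0, 0.0]))
        assert np.allclose(
            full_prior_cov(C, combine(stack, np.array([1.0, 0.0]))),
            np.kron(C, K1),
        )


class TestLaplaceFit:
    def test_one_sample_fixed_point(self):
        """n=1, Q=1, unit kernel, positive label: the mode solves
        g = sigma(-g)."""
        post = laplace_fit(
            np.array([[1.0]]), np.array([[1.0]]), np.array([[1]]), np.ones(1)
        )
        g_star = brentq(lambda g: g - expit(-g), 0.0, 1.0, xtol=1e-12)
        assert post.G_hat[0, 0] == pytest.approx(g_star, abs=1e-6)
        assert g_star == pytest.approx(0.4012, abs=5e-4)

    def test_sign_flip_symmetry(self, rng):
        K, C, Y = toy_problem(rng)
        w = np.ones(len(Y))
        post_pos = laplace_fit(K, C, Y, w)
        post_neg = laplace_fit(K, C, -Y, w)
        assert np.allclose(post_pos.G_hat, -post_neg.G_hat, atol=1e-8)

    def test_mode_matches_generic_optimizer(self, rng):
        """Tiny instance: the Newton mode equals direct numerical
        maximization of the exact log posterior."""
        K, C, Y = toy_problem(rng, n=2, Q=2)
        w = np.array([1.3, 0.7])
        w = w / w.mean()
        post = laplace_fit(K, C, Y, w)
        Sigma = np.kron(C, K) + 1e-10 * np.eye(4)
        Si = np.linalg.inv(Sigma)

        def neg_psi(gvec):
            G = gvec.reshape(2, 2).T
            ll = np.sum(w[:, None] * np.log(expit(Y * G)))
            return -(ll - 0.5 * gvec @ Si @ gvec)

        res = minimize(neg_psi, np.zeros(4), method="BFGS",
                       options={"gtol": 1e-12})
        assert np.allclose(post.G_hat.T.ravel(), res.x, atol=1e-6)

    def test_mode_stationarity(self, rng):
        K, C, Y = toy_problem(rng, n=6, Q=2)
        post = laplace_fit(K, C, Y, np.ones(6), tol=1e-8)
        assert post.grad_norm < 1e-8

    def test_curvature_bounds(self, rng):
        K, C, Y = toy_problem(rng, n=5, Q=2)
        w = sample_weights(Y)
        post = laplace_fit(K, C, Y, w)
        assert np.all(post.W >= 0)
        assert np.all(post.W <= w.max() / 4 + 1e-12)


class TestPrediction:
    def test_far_test_point_reverts_to_prior(self, rng):
        K, C, Y = toy_problem(rng, n=5, Q=2)
        post = laplace_fit(K, C, Y, np.ones(5))
        mu, Sig = predict_latent(post, np.zeros(5), kss=1.0)
        assert np.allclose(mu, 0.0, atol=1e-12)
        assert np.allclose(Sig, C, atol=1e-10)

    def test_matches_dense_kronecker_oracle(self, rng):
        """Q=2, n=3: factorized prediction equals the brute-force dense
        conditional of the Laplace approximation."""
        K, C, Y = toy_problem(rng, n=3, Q=2)
        w = np.array([1.2, 0.9, 0.9])
        w /= w.mean()
        post = laplace_fit(K, C, Y, w)
        kstar = K[:, 0] * 0.8  # synthetic cross-kernel
        kss = 1.0
        mu, Sig = predict_latent(post, kstar, kss)

        Sigma = np.kron(C, K)
        Sfs = np.kron(C, kstar[:, None])
        Wd = np.diag(post.W.T.ravel())
        # dense: mu* = Sfs^T Sigma^-1 ghat ; cov* = kss C - Sfs^T (Sigma + W^-1)^-1 Sfs
        ghat = post.G_hat.T.ravel()
        mu_dense = Sfs.T @ np.linalg.solve(Sigma + 1e-12 * np.eye(6), ghat)
        mid = np.linalg.inv(Sigma + np.linalg.inv(Wd + 1e-14 * np.eye(6)))
        Sig_dense = kss * C - Sfs.T @ mid @ Sfs
        assert np.allclose(mu, mu_dense, atol=1e-6)
        assert np.allclose(Sig, Sig_dense, atol=1e-6)

    def test_mc_probabilities_basics(self, rng):
        p = predict_proba(np.zeros(3), 1e-12 * np.eye(3), n_samples=2000, seed=1)
        assert np.allclose(p, 0.5, atol=1e-6)
        p = predict_proba(np.array([10.0]), np.array([[0.01]]), n_samples=500, seed=1)
        assert p[0] > 0.99

    def test_mc_reproducible(self):
        mu, Sig = np.array([0.3, -0.2]), np.array([[1.0, 0.4], [0.4, 1.0]])
        p1 = predict_proba(mu, Sig, 1000, seed=42)
        p2 = predict_proba(mu, Sig, 1000, seed=42)
        assert np.array_equal(p1, p2)

    def test_mc_agrees_with_quadrature(self):
        mu, var = np.array([1.0]), np.array([[4.0]])
        S = 50_000
        p_mc = predict_proba(mu, var, S, seed=7)[0]
        p_q = predict_proba_ghq(mu, var)[0]
        # binomial-style SE bound for the MC average
        se = np.sqrt(p_q * (1 - p_q) / S)
        assert abs(p_mc - p_q) < 3 * se * 2  # sigma values are correlated draws

    def test_mc_error_scales_as_inverse_sqrt(self):
        """log-log regression of the MC standard error on S has slope
        close to -1/2."""
        mu, Sig = np.array([0.7]), np.array([[2.0]])
        p_ref = predict_proba_ghq(mu, Sig)[0]
        sizes = [250, 1000, 4000]
        ses = []
        for S in sizes:
            errs = [
                predict_proba(mu, Sig, S, seed=1000 + r)[0] - p_ref
                for r in range(40)
            ]
            ses.append(np.std(errs))
        slope = np.polyfit(np.log(sizes), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)


class TestDecide:
    def test_threshold_rule(self):
        assert np.array_equal(
            decide(np.array([0.9, 0.4, 0.6]), 0.5), [True, False, True]
        )

    def test_fallback_to_top1(self):
        assert np.array_equal(decide(np.array([0.2, 0.1]), 0.5), [True, False])

    def test_boundary_strict_with_tiebreak(self):
        assert np.array_equal(decide(np.array([0.5, 0.5]), 0.5), [True, False])


class TestReductionToBinaryGP:
    def test_identity_C_single_view_matches_independent_binary_gp(self, rng):
        """With C = I, one view and uniform weights the multi-label
        model must coincide with independent per-label binary Laplace
        GP classifiers."""
        n, Q = 10, 2
        X = rng.standard_normal((n, 2))
        theta = median_bandwidth(X)
        K = gaussian_gram(X, theta)
        Y = rng.choice([-1, 1], size=(n, Q))
        Y[:, 0][(Y > 0).sum(axis=1) == 0] = 1
        Xtest = rng.standard_normal((4, 2))
        kx = gaussian_gram(X, theta, Xtest)

        post = laplace_fit(K, np.eye(Q), Y, np.ones(n), tol=1e-10)
        P_multi = np.vstack([
            predict_proba_ghq(*predict_latent(post, kx[:, i], 1.0))
            for i in range(4)
        ])
        P_binary = np.empty_like(P_multi)
        for q in range(Q):
            ref = BinaryLaplaceGP(K, Y[:, q])
            for i in range(4):
                P_binary[i, q] = ref.predict_proba(kx[:, i], 1.0)
        assert np.max(np.abs(P_multi - P_binary)) < 1e-6


class TestEstimatorSurface:
    def test_fit_predict_end_to_end(self, tiny_dataset):
        model = MultiLabelGP(
            learn_C=False, learn_a=False, proba_method="ghq", seed=0
        ).fit(tiny_dataset)
        res = model.predict([v.matrix[:5] for v in tiny_dataset.views])
        assert len(res) == 5
        for r in res:
            assert r.decided.any()
            assert np.all((r.probabilities >= 0) & (r.probabilities <= 1))
            # ranking consistent with probabilities
            p = r.probabilities
            assert all(
                p[r.ranking[i]] >= p[r.ranking[i + 1]] - 1e-12
                for i in range(len(p) - 1)
            )

    def test_evidence_trace_monotone(self, tiny_dataset):
        model = MultiLabelGP(
            proba_method="ghq", max_evals=60, maxiter=8, seed=0
        ).fit(tiny_dataset)
        tr = model.opt_trace_
        assert len(tr) >= 1
        assert all(b >= a - 1e-6 for a, b in zip(tr, tr[1:]))

    def test_identical_views_learn_symmetric_weights(self, tiny_dataset):
        """Two copies of the same informative view get (near-)equal
        learned combination weights."""
        from mmlgp.data import MultiViewDataset

        v = tiny_dataset.views[0]
        ds = MultiViewDataset(
            accessions=tiny_dataset.accessions,
            views=[v, v],
            Y=tiny_dataset.Y,
            label_names=tiny_dataset.label_names,
        )
        model = MultiLabelGP(
            learn_C=False, learn_a=True, proba_method="ghq",
            max_evals=80, maxiter=10,
        ).fit(ds)
        a1, a2 = model.a_
        assert abs(a1 - a2) / ((a1 + a2) / 2) < 0.3

    def test_zero_positive_label_dropped(self, rng):
        from mmlgp.data import FeatureView, MultiViewDataset

        X = rng.standard_normal((12, 2))
        Y = -np.ones((12, 3), dtype=int)
        Y[:, 0] = 1  # label 2 never positive
        Y[::3, 1] = 1
        ds = MultiViewDataset(
            accessions=[f"A{i}" for i in range(12)],
            views=[FeatureView("v", X)],
            Y=Y,
            label_names=["a", "b", "c"],
        )
        model = MultiLabelGP(learn_C=False, learn_a=False, proba_method="ghq").fit(ds)
        res = model.predict([X[:2]])
        for r in res:
            assert r.probabilities[2] == 0.0
            assert not r.decided[2]
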