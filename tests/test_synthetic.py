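import numpy as np
import pytest
from scipy.special import expit

from mmlgp.kernels import gaussian_gram
from mmlgp.synthetic import (
    GeneratorSpec,
    generate,
    preset,
    raise_multilabel_fraction,
    sample_correlation,
)


class TestSampleCorrelation:
    def test_zero_coupling_identity(self):
        assert np.array_equal(sample_correlation(5, 0.0), np.eye(5))

    def test_designated_pair(self):
        C = sample_correlation(4, 0.9, pairs=[(0, 1)])
        assert C[0, 1] == pytest.approx(0.9)
        assert C[2, 3] == pytest.approx(0.0)
        assert np.linalg.eigvalsh(C).min() >= 0

    def test_random_draws_stay_psd(self, rng):
        for i in range(20):
            C = sample_correlation(6, 0.7, pairs=[(0, 1), (1, 2)],
                                   noise=0.3, seed=int(rng.integers(1 << 30)))
            assert np.allclose(np.diag(C), 1.0)
            assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestGenerate:
    def test_same_seed_identical(self):
        spec = preset("coupled", seed=9)
        d1, d2 = generate(spec), generate(spec)
        assert np.array_equal(d1.Y, d2.Y)
        for v1, v2 in zip(d1.views, d2.views):
            assert np.array_equal(v1.matrix, v2.matrix)

    def test_every_row_has_a_positive(self):
        ds = generate(preset("humlike", seed=3))
        assert ((ds.Y > 0).sum(axis=1) >= 1).all()

    def test_multilabel_fraction_near_target(self):
        fracs = []
        for seed in range(5):
            ds = generate(preset("coupled", seed=seed))
            fracs.append(((ds.Y > 0).sum(axis=1) >= 2).mean())
        assert abs(np.mean(fracs) - 0.17) < 0.06

    def test_humlike_shape_and_rare_label(self):
        ds = generate(preset("humlike", seed=1))
        assert ds.n_samples == 400 and ds.n_labels == 14 and ds.n_views == 5
        rates = (ds.Y > 0).mean(axis=0)
        assert rates[-1] < 0.03  # the rare location
        assert rates.max() / max(rates.min(), 1e-9) > 5  # heavy imbalance

    def test_positive_rate_matches_rejection_aware_oracle(self):
        """Empirical per-label positive rate agrees with an independent
        simulation of the same latent->Bernoulli->rejection process."""
        rates = []
        for seed in range(10):
            ds = generate(GeneratorSpec(
                n=150, Q=6, m=1, view_dims=(2,), offsets=np.full(6, -2.0),
                multilabel_frac=None, seed=seed,
            ))
            rates.append((ds.Y > 0).mean())
        emp = np.mean(rates)

        # oracle: marginal latent per entry is N(0, 1) (unit-diagonal C
        # and kernel, a = 1); each row keeps its latent and resamples
        # labels until one positive appears, exactly as the generator does
        orng = np.random.default_rng(123)
        sims = []
        for _ in range(30000):
            g = orng.standard_normal(6)
            p = expit(g - 2.0)
            while True:
                y = orng.random(6) < p
                if y.any():
                    sims.append(y.mean())
                    break
        oracle = np.mean(sims)
        se = np.std(rates) / np.sqrt(len(rates)) + np.std(sims) / np.sqrt(len(sims))
        assert abs(emp - oracle) < 3 * max(se, 1e-3)

    def test_coupled_labels_co_occur_more_than_matched_identity_null(self):
        """Coupling raises pair co-occurrence relative to the identical
        generator with C = I.  (The forced >=1-positive row constraint
        shifts the conditional marginals, so the matched null is the
        right comparison, not the product of marginals.)"""
        co_coupled, co_null = [], []
        for seed in range(10):
            pos = generate(preset("coupled", seed=seed)).Y > 0
            co_coupled.append(
                (pos[:, 0] & pos[:, 1]).sum() + (pos[:, 2] & pos[:, 3]).sum()
            )
            pos0 = generate(preset("independent", seed=seed)).Y > 0
            co_null.append(
                (pos0[:, 0] & pos0[:, 1]).sum() + (pos0[:, 2] & pos0[:, 3]).sum()
            )
        wins = sum(c > n for c, n in zip(co_coupled, co_null))
        assert wins >= 8
        assert np.mean(co_coupled) > np.mean(co_null)

    def test_unconditional_coupling_exceeds_independence_product(self):
        """Without the row constraint, coupled-pair co-occurrence
        exceeds the product of the marginals."""
        co, prod = [], []
        for seed in range(10):
            spec = preset("coupled", seed=seed)
            spec = GeneratorSpec(**{**spec.__dict__, "require_positive": False})
            pos = generate(spec).Y > 0
            co.append((pos[:, 0] & pos[:, 1]).mean())
            prod.append(pos[:, 0].mean() * pos[:, 1].mean())
        assert np.mean(co) > np.mean(prod)
        assert sum(c > p for c, p in zip(co, prod)) >= 8

    def test_latent_covariance_matches_prior(self):
        """Empirical covariance of latents across replicates at fixed
        inputs converges to C (x) sum a_j K_j."""
        spec = GeneratorSpec(
            n=5, Q=2, m=1, view_dims=(2,),
            C=np.array([[1.0, 0.6], [0.6, 1.0]]),
            offsets=np.zeros(2), multilabel_frac=None, seed=0,
        )
        base = generate(spec)
        X = base.views[0].matrix
        th = base.ground_truth["bandwidths"][0]
        target = np.kron(spec.C, gaussian_gram(X, th))

        def empirical_cov(n_rep):
            rng = np.random.default_rng(77)
            L = np.linalg.cholesky(target + 1e-10 * np.eye(10))
            draws = (L @ rng.standard_normal((10, n_rep))).T
            return np.cov(draws, rowvar=False)

        err_small = np.linalg.norm(empirical_cov(300) - target)
        err_big = np.linalg.norm(empirical_cov(20000) - target)
        assert err_big < err_small / 3

    def test_infeasible_fraction_raises(self):
        spec = GeneratorSpec(
            n=30, Q=2, m=1, view_dims=(2,), multilabel_frac=0.999999, seed=0
        )
        with pytest.raises(ValueError, match="unreachable"):
            generate(spec)


class TestRaiseMultilabelFraction:
    def test_keeps_all_multis_and_hits_target(self, rng):
        ds = generate(preset("coupled", seed=4, n=240))
        out = raise_multilabel_fraction(ds, 0.40, rng)
        frac = ((out.Y > 0).sum(axis=1) >= 2).mean()
        assert abs(frac - 0.40) < 0.03
        n_multi_in = ((ds.Y > 0).sum(axis=1) >= 2).sum()
        n_multi_out = ((out.Y > 0).sum(axis=1) >= 2).sum()
        assert n_multi_in == n_multi_out
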