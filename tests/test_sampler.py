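"""Gibbs sampler: conditional updates, oracles, bookkeeping and summaries."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from bayesrc.genodata import PhenotypeTable, VariantClassMap
from bayesrc.pedigree import AMatrix
from bayesrc.sampler import (
    GibbsSampler,
    MixtureSpec,
    PosteriorSummary,
    default_sigma2_g,
    run_chain,
    sample_component_and_effect,
    sample_mixture_proportions,
    sample_polygenic,
    sample_residual_variance,
    summarize_chains,
)


def std_design(rng, n, m):
    W = rng.standard_normal((n, m))
    return (W - W.mean(0)) / W.std(0, ddof=1)


def make_pheno(y, X=None):
    n = len(y)
    if X is None:
        X = np.zeros((n, 0))
    return PhenotypeTable(
        ids=[str(i) for i in range(n)], y=y, X=X,
        fixed_effect_labels=[f"x{j}" for j in range(X.shape[1])],
    )


def two_class_map(m):
    return VariantClassMap(
        class_index=1 + (np.arange(m) % 2),
        class_labels=["A", "B"],
        category=np.array(["A", "B"] * (m // 2)),
    )


class TestMixtureSpec:
    def test_first_tier_must_be_null(self):
        with pytest.raises(ValueError, match="0 first tier"):
            MixtureSpec(sigma2_g=1.0, variance_fractions=(1e-5, 1e-4, 1e-3, 1e-2))

    def test_alpha_broadcast(self):
        spec = MixtureSpec(sigma2_g=1.0)
        assert spec.alpha_for(3).shape == (3, 4)


class TestSingleClassEquivalence:
    def test_bayesr_is_single_class_bayesrc(self, rng):
        """A one-class BayesRC chain and a BayesR chain are the same chain."""
        n, m = 60, 40
        W = std_design(rng, n, m)
        y = W[:, 0] * 0.5 + rng.standard_normal(n)
        pheno = make_pheno(y, np.ones((n, 1)))
        spec = MixtureSpec(sigma2_g=default_sigma2_g(pheno, 0.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            single = VariantClassMap.single_class(m)
            r1 = run_chain(pheno, W, None, spec, 200, 100, seed=11)
            r2 = run_chain(pheno, W, single, spec, 200, 100, seed=11)
        np.testing.assert_array_equal(r1.traces["sigma2_e"], r2.traces["sigma2_e"])
        np.testing.assert_array_equal(r1.traces["P"], r2.traces["P"])
        np.testing.assert_array_equal(r1.summary.pip, r2.summary.pip)
        np.testing.assert_array_equal(r1.summary.vbar, r2.summary.vbar)


class TestComponentUpdate:
    def test_degenerate_proportions_force_null(self, rng):
        n, m = 40, 12
        W = std_design(rng, n, m)
        y = W @ rng.normal(0, 0.5, m) + rng.standard_normal(n)
        pheno = make_pheno(y)
        spec = MixtureSpec(sigma2_g=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = GibbsSampler(pheno, W, None, spec, seed=2,
                             fixed_proportions=(1.0, 0.0, 0.0, 0.0))
            for _ in range(50):
                s.step()
        assert np.all(s.state.z == 0)
        assert np.all(s.state.v == 0.0)

    def test_kernel_matches_reference_updates(self, rng):
        """One compiled sweep reproduces the pure-python conditional update."""
        n, m = 30, 16
        W = std_design(rng, n, m)
        y = W @ rng.normal(0, 0.3, m) + rng.standard_normal(n)
        pheno = make_pheno(y)
        spec = MixtureSpec(sigma2_g=1.5)
        P = np.array([0.4, 0.3, 0.2, 0.1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = GibbsSampler(pheno, W, None, spec, seed=31,
                             fixed_proportions=P, fix_sigma2_e=0.8)
        # replicate the step's random stream
        ref_rng = np.random.default_rng(31)
        perm = ref_rng.permutation(m)
        unif = ref_rng.random(m)
        gauss = ref_rng.standard_normal(m)
        resid = y.copy()
        v = np.zeros(m)
        z = np.zeros(m, dtype=int)
        logP = np.log(np.maximum(P, 1e-300))
        tau2 = spec.component_variances()
        for t, i in enumerate(perm):
            sample_component_and_effect(
                i, resid, v, z, W, np.ones(n), logP, tau2, 0.8,
                unif[t], gauss[t],
            )
        s.step()
        np.testing.assert_array_equal(s.state.z, z)
        np.testing.assert_allclose(s.state.v, v, atol=1e-4)
        np.testing.assert_allclose(s.state.resid, resid, atol=1e-4)

    def test_component_posterior_matches_quadrature(self, rng):
        """Sampled component frequencies for a single variant agree with
        numerical integration of the exact one-variant marginal likelihood."""
        n = 50
        x = rng.integers(0, 3, n).astype(float)
        W = ((x - x.mean()) / x.std(ddof=1)).reshape(-1, 1)
        s2g, s2e = 2.0, 1.0
        y = W[:, 0] * 0.45 + rng.standard_normal(n)
        tau2 = np.array([0.0, 1e-4, 1e-3, 1e-2]) * s2g

        def loglik(v):
            return -0.5 * np.sum((y - W[:, 0] * v) ** 2) / s2e

        post = [0.25 * np.exp(loglik(0.0))]
        for t2 in tau2[1:]:
            sd = np.sqrt(t2)
            f = lambda v: np.exp(loglik(v)) * np.exp(-v * v / (2 * t2)) / (
                sd * np.sqrt(2 * np.pi)
            )
            post.append(0.25 * quad(f, -10 * sd - 2, 10 * sd + 2, limit=400)[0])
        post = np.array(post)
        post /= post.sum()

        pheno = make_pheno(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = GibbsSampler(pheno, W, None, MixtureSpec(sigma2_g=s2g), seed=3,
                             fix_sigma2_e=s2e,
                             fixed_proportions=(0.25, 0.25, 0.25, 0.25))
            counts = np.zeros(4)
            for _ in range(20000):
                s.step()
                counts[s.state.z[0]] += 1
        np.testing.assert_allclose(counts / counts.sum(), post, atol=0.015)

    def test_null_data_leaves_no_signal(self, rng):
        """Pure-noise phenotypes: effects average to ~0 and the residual
        variance recovers the phenotypic variance."""
        n, m = 200, 120
        W = std_design(rng, n, m)
        y = rng.standard_normal(n)
        pheno = make_pheno(y)
        spec = MixtureSpec(sigma2_g=default_sigma2_g(pheno, 0.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_chain(pheno, W, two_class_map(m), spec, 2000, 1000, seed=6)
        assert np.abs(res.summary.vbar).max() < 0.2
        assert res.summary.sigma2_e == pytest.approx(np.var(y), rel=0.2)
        # fitted genetic values carry (almost) none of the phenotypic variance
        gv = W @ res.summary.vbar
        assert np.var(gv) < 0.2 * np.var(y)


class TestDirichletUpdate:
    def test_posterior_mean_closed_form(self, rng):
        draws = np.array([
            sample_mixture_proportions(np.array([996, 2, 1, 1]), np.ones(4), rng)
            for _ in range(10000)
        ])
        np.testing.assert_allclose(
            draws.mean(0), np.array([997, 3, 2, 2]) / 1004.0, atol=0.01
        )

    def test_prior_case(self, rng):
        draws = np.array([
            sample_mixture_proportions(np.zeros(4), np.ones(4), rng)
            for _ in range(8000)
        ])
        np.testing.assert_allclose(draws.mean(0), 0.25, atol=0.02)

    def test_negative_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="negative"):
            sample_mixture_proportions(np.array([-1, 0, 0, 1]), np.ones(4), rng)

    def test_assignments_track_proportions(self, rng):
        """With an uninformative likelihood the component frequencies of the
        z draws match the fixed proportions (chain self-consistency)."""
        n, m = 30, 60
        W = std_design(rng, n, m)
        y = rng.standard_normal(n) * 1e-6  # essentially no signal
        pheno = make_pheno(y)
        P = np.array([0.5, 0.3, 0.15, 0.05])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = GibbsSampler(pheno, W, None, MixtureSpec(sigma2_g=1e-9), seed=8,
                             fixed_proportions=P, fix_sigma2_e=1.0)
            freq = np.zeros(4)
            for _ in range(400):
                s.step()
                freq += np.bincount(s.state.z, minlength=4)
        np.testing.assert_allclose(freq / freq.sum(), P, atol=0.02)


class TestPolygenic:
    def test_identity_a_matches_ridge_formula(self, rng):
        n = 40
        w = np.ones(n)
        r = rng.standard_normal(n)
        s2a, s2e = 0.7, 1.3
        A_inv = np.eye(n)
        expect = (w * r / s2e) / (w / s2e + 1.0 / s2a)
        draws = np.array([
            sample_polygenic(r, w, A_inv, s2a, s2e, rng) for _ in range(3000)
        ])
        np.testing.assert_allclose(draws.mean(0), expect, atol=0.08)

    def test_shrinkage_limit(self, rng):
        n = 30
        r = rng.standard_normal(n)
        w = np.ones(n)
        A_inv = np.eye(n)
        big = np.mean(np.abs([sample_polygenic(r, w, A_inv, 1.0, 1.0, rng)
                              for _ in range(200)]))
        small = np.mean(np.abs([sample_polygenic(r, w, A_inv, 0.01, 1.0, rng)
                                for _ in range(200)]))
        assert small < big

    def test_no_pedigree_polygenic_disabled(self, rng):
        n, m = 40, 10
        W = std_design(rng, n, m)
        y = rng.standard_normal(n)
        pheno = make_pheno(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = GibbsSampler(pheno, W, None, MixtureSpec(sigma2_g=0.5), seed=1)
            for _ in range(20):
                s.step()
        assert np.all(s.state.a == 0.0)

    def test_runs_with_pedigree_matrix(self, rng):
        n, m = 30, 10
        # a simple block-relative A: full-sib pairs
        A = np.eye(n)
        for k in range(0, n, 2):
            A[k, k + 1] = A[k + 1, k] = 0.5
        ids = [str(i) for i in range(n)]
        W = std_design(rng, n, m)
        y = rng.standard_normal(n)
        pheno = make_pheno(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_chain(pheno, W, None, MixtureSpec(sigma2_g=0.5), 100, 50,
                            seed=5, A=AMatrix(ids=ids, values=A))
        assert np.isfinite(res.summary.sigma2_a) and res.summary.sigma2_a > 0


class TestResidualVariance:
    def test_closed_form_mean(self, rng):
        n = 100
        e = rng.standard_normal(n)
        w = np.ones(n)
        ss = float(np.sum(w * e * e))
        draws = [sample_residual_variance(e, w, rng) for _ in range(20000)]
        # x = ss / chi2(n-2) has mean ss/(n-4)
        assert np.mean(draws) == pytest.approx(ss / (n - 4), rel=0.05)

    def test_weight_scaling_of_the_scale(self, rng):
        n = 100
        e = rng.standard_normal(n)
        w = np.ones(n)
        m1 = np.mean([sample_residual_variance(e, w, rng) for _ in range(5000)])
        m2 = np.mean([sample_residual_variance(e, 2 * w, rng) for _ in range(5000)])
        assert m2 == pytest.approx(2 * m1, rel=0.1)

    def test_zero_residuals_collapse(self, rng):
        e = np.full(50, 1e-9)
        draws = [sample_residual_variance(e, np.ones(50), rng) for _ in range(100)]
        assert max(draws) < 1e-14


class TestBookkeeping:
    def test_incremental_residual_agrees_with_recomputation(self, rng):
        n, m = 80, 100
        W = std_design(rng, n, m)
        y = W @ rng.normal(0, 0.3, m) + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        pheno = make_pheno(y, X)
        spec = MixtureSpec(sigma2_g=default_sigma2_g(pheno, 0.5))
        s = GibbsSampler(pheno, W, two_class_map(m), spec, seed=9,
                         resid_check_interval=100)
        for _ in range(1000):  # raises DivergenceError if drift > 1e-6
            s.step()
        assert np.abs(s.recomputed_residual() - s.state.resid).max() < 1e-6

    def test_beta_counts_partition_classes(self, rng):
        n, m = 50, 60
        W = std_design(rng, n, m)
        y = rng.standard_normal(n)
        pheno = make_pheno(y)
        spec = MixtureSpec(sigma2_g=0.5)
        res = run_chain(pheno, W, two_class_map(m), spec, 300, 150, seed=12)
        sizes = two_class_map(m).class_sizes()
        np.testing.assert_array_equal(
            res.traces["beta"].sum(axis=2), np.tile(sizes, (300, 1))
        )
        np.testing.assert_allclose(res.traces["P"].sum(axis=2), 1.0, atol=1e-12)

    def test_fractional_dosages_use_generic_path(self, rng):
        """Mean-imputed (fractional) dosages cannot use the int8 fast path;
        the sampler must fall back to the generic kernel transparently."""
        from bayesrc.genodata import GenotypeMatrix

        n, m = 30, 8
        dos = rng.integers(0, 3, size=(n, m)).astype(np.float32)
        dos[0, 0] = 0.733  # a mean-imputed call
        g = GenotypeMatrix(
            individual_ids=[f"i{k}" for k in range(n)],
            variant_ids=[f"v{j}" for j in range(m)],
            chrom=np.array(["1"] * m), pos=np.arange(1, m + 1), dosages=dos,
        )
        pheno = make_pheno(rng.standard_normal(n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = GibbsSampler(pheno, None, None, MixtureSpec(sigma2_g=0.5),
                             seed=1, genotypes=g)
            for _ in range(30):
                s.step()
        assert s.X8 is None
        assert np.abs(s.recomputed_residual() - s.state.resid).max() < 1e-6

    def test_invalid_burn_in_rejected(self, rng):
        pheno = make_pheno(rng.standard_normal(20))
        s = GibbsSampler(pheno, std_design(rng, 20, 4), None,
                         MixtureSpec(sigma2_g=0.5), seed=1)
        with pytest.raises(ValueError, match="burn_in"):
            s.run(10, 10)


class TestGewekePriorRecovery:
    def test_successive_conditional_matches_priors(self, rng):
        """Regenerating y from the model each iteration, the marginal draws
        of P and sigma2_e must match their priors (Dirichlet(1,1,1,1) and
        scaled inverse-chi^2 with nu0=12, s0^2=1)."""
        n, m = 12, 6
        W = std_design(np.random.default_rng(99), n, m)
        pheno = make_pheno(np.random.default_rng(99).standard_normal(n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = GibbsSampler(pheno, W, None, MixtureSpec(sigma2_g=1.0), seed=4,
                             variance_prior=(12.0, 1.0), resid_check_interval=0)
            P_draws, s2e_draws = [], []
            for _ in range(4000):
                s.step()
                e = rng.normal(0, np.sqrt(s.state.sigma2_e), n)
                s.set_phenotypes(W @ s.state.v + e)
                P_draws.append(s.state.P[0].copy())
                s2e_draws.append(s.state.sigma2_e)
        np.testing.assert_allclose(np.mean(P_draws, axis=0), 0.25, atol=0.05)
        assert np.mean(s2e_draws) == pytest.approx(12.0 / 10.0, abs=0.15)


class TestSummaries:
    @staticmethod
    def fake_summary(mean, m=3):
        return PosteriorSummary(
            pip=np.full(m, mean), vbar=np.full(m, mean),
            class_component_counts=np.full((1, 4), mean),
            proportions=np.full((1, 4), 0.25), sigma2_e=mean, sigma2_a=0.0,
            b=np.array([mean]), n_post=10,
        )

    def test_single_chain_identity(self):
        s = summarize_chains([self.fake_summary(0.3)])
        assert s.sigma2_e == 0.3
        np.testing.assert_array_equal(s.pip, [0.3, 0.3, 0.3])

    def test_hand_computed_mean_and_spread(self):
        vals = [0.1, 0.2, 0.3, 0.2, 0.2]
        s = summarize_chains([self.fake_summary(v) for v in vals])
        assert s.sigma2_e == pytest.approx(0.2)
        assert s.spread("sigma2_e") == pytest.approx(
            np.std(vals, ddof=1) / np.sqrt(5)
        )

    def test_identical_seeds_zero_spread(self, rng):
        n, m = 30, 10
        W = std_design(rng, n, m)
        pheno = make_pheno(rng.standard_normal(n))
        spec = MixtureSpec(sigma2_g=0.5)
        chains = [run_chain(pheno, W, None, spec, 100, 50, seed=7)
                  for _ in range(3)]
        s = summarize_chains(chains)
        assert s.spread("sigma2_e") == 0.0

    def test_unequal_lengths_rejected(self):
        a = self.fake_summary(0.1)
        b = self.fake_summary(0.1)
        b.n_post = 20
        with pytest.raises(ValueError, match="unequal"):
            summarize_chains([a, b])
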