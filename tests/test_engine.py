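import numpy as np
import pytest
from scipy import stats

from antebayes import _kernels
from antebayes.data_model import PhenotypeData
from antebayes.engine import (
    ChainConfig,
    MethodSpec,
    PosteriorChain,
    Sampler,
    SamplerOptions,
    batch_means_mcse,
    posterior_summary,
    run_chain,
)
from antebayes.priors import MixturePrior, Priors
from conftest import make_geno


def small_chain_cfg(n_iter=200, burn_in=50, thin=5, seed=0):
    return ChainConfig(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)


class TestConfigContracts:
    def test_saved_cycle_count(self):
        assert ChainConfig(n_iter=100, burn_in=50, thin=10, seed=0).n_saved == 5

    def test_default_protocol(self):
        cfg = ChainConfig()
        assert (cfg.n_iter, cfg.burn_in, cfg.thin, cfg.bayesb_inner_mh) == (
            350_000, 50_000, 10, 100,
        )

    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=100, burn_in=100)

    def test_fixed_pi_only_for_antebayesb(self):
        with pytest.raises(ValueError):
            MethodSpec("bayesCpi", fixed_pi=0.9)
        with pytest.raises(ValueError):
            MethodSpec("anteBayesB")
        assert MethodSpec("anteBayesB", fixed_pi=0.95).fixed_pi == 0.95


class TestFixedEffects:
    def test_one_point_conjugate_posterior(self):
        """Single animal, intercept only, sigma_e2 fixed: beta ~ N(y, sigma_e2)."""
        g = make_geno(np.zeros((1, 1), dtype=int))
        p = PhenotypeData(y=np.array([5.0]))
        s = Sampler(
            g, p, MethodSpec("bayesCpi"),
            options=SamplerOptions(fixed_pi=1.0 - 1e-12, fix_sigma_g2=True,
                                   fix_sigma_e2=True),
        )
        s.state.sigma_e2 = 2.0
        rng = np.random.default_rng(1)
        draws = np.empty(20_000)
        for i in range(draws.size):
            s.cycle(rng)
            draws[i] = s.state.beta[0]
        assert stats.kstest(draws, stats.norm(5.0, np.sqrt(2.0)).cdf).pvalue > 0.01

    def test_posterior_mean_matches_least_squares(self):
        """With all SNPs forced null, E[beta | y] is the OLS/GLS estimate."""
        rng = np.random.default_rng(2)
        n = 40
        g = make_geno(rng.integers(0, 3, (n, 3)))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, -2.0]) + 0.5 * rng.standard_normal(n)
        p = PhenotypeData(y=y, fixed_design=X)
        s = Sampler(
            g, p, MethodSpec("bayesCpi"),
            options=SamplerOptions(fixed_pi=1.0 - 1e-12, fix_sigma_g2=True),
        )
        chain_rng = np.random.default_rng(3)
        betas = np.empty((4000, 2))
        for i in range(betas.shape[0]):
            s.cycle(chain_rng)
            betas[i] = s.state.beta
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        mcse = np.array([batch_means_mcse(betas[:, k]) for k in range(2)])
        assert np.all(np.abs(betas.mean(axis=0) - ols) < 4 * mcse)

    def test_zero_design_column_rejected(self):
        g = make_geno(np.zeros((4, 2), dtype=int))
        X = np.column_stack([np.ones(4), np.zeros(4)])
        X[0, 1] = 0.0
        p = PhenotypeData.__new__(PhenotypeData)
        p.y = np.zeros(4)
        p.fixed_design = X
        p.fixed_labels = ["a", "b"]
        with pytest.raises(ValueError, match="all-zero column"):
            Sampler(g, p, MethodSpec("bayesCpi"))


class TestMarkerSweepKernel:
    def test_zero_column_gives_prior_odds(self):
        """Uninformative marker: inclusion probability equals 1 - pi exactly."""
        n, m = 5, 1
        Zt = np.zeros((m, n))
        r = np.random.default_rng(4).standard_normal(n)
        for pi in (0.2, 0.8):
            eff = np.zeros(m)
            ind = np.zeros(m, dtype=np.int64)
            u = np.array([1.0 - pi - 1e-9])  # just below the inclusion threshold
            _kernels.cpi_sweep(Zt, np.zeros(m), r.copy(), eff, ind, pi, 1.0, 1.0,
                               u, np.zeros(m))
            assert ind[0] == 1
            eff[:] = 0
            u = np.array([1.0 - pi + 1e-9])
            _kernels.cpi_sweep(Zt, np.zeros(m), r.copy(), eff, ind, pi, 1.0, 1.0,
                               u, np.zeros(m))
            assert ind[0] == 0

    def test_prior_dominance_at_pi_one(self):
        rng = np.random.default_rng(5)
        Zt = rng.integers(0, 3, (3, 8)).astype(float)
        r = rng.standard_normal(8) * 5
        eff = np.ones(3)
        ind = np.ones(3, dtype=np.int64)
        _kernels.cpi_sweep(Zt, (Zt**2).sum(1), r, eff, ind, 1.0 - 1e-15, 1.0, 1.0,
                           np.full(3, 1e-12), np.zeros(3))
        assert np.all(ind == 0) and np.all(eff == 0)


class TestConjugateScalars:
    @pytest.fixture
    def sampler(self, toy_geno, toy_pheno):
        priors = Priors(mixture=MixturePrior(v_g=4.0, s_g2=1.0))
        return Sampler(toy_geno, toy_pheno, MethodSpec("bayesCpi"), priors=priors)

    def test_pi_update_is_beta_conjugate(self, sampler):
        # m=4 markers, m1=0 non-null -> Beta(5, 1): mean 5/6
        rng = np.random.default_rng(6)
        draws = np.empty(100_000)
        for i in range(draws.size):
            sampler._update_pi(0, rng)
            draws[i] = sampler.state.pi
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 5.0 / 6.0) < 4 * se
        assert abs(draws.var(ddof=1) - 5.0 / (36.0 * 7.0)) < 0.001

    def test_shared_variance_conjugate_update(self, sampler):
        # v=4, s2=1, two unit effects -> chi^-2(6, 1): mean 6/4 = 1.5
        rng = np.random.default_rng(7)
        draws = np.empty(100_000)
        for i in range(draws.size):
            sampler._update_variances(m1=2, ssq=2.0, rng=rng)
            draws[i] = sampler.state.sigma_g2
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.5) < 4 * se

    def test_shared_variance_no_data_recovers_prior(self, sampler):
        rng = np.random.default_rng(8)
        draws = np.empty(50_000)
        for i in range(draws.size):
            sampler._update_variances(m1=0, ssq=0.0, rng=rng)
            draws[i] = sampler.state.sigma_g2
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.0) < 6 * se  # chi^-2(4,1) mean 2, heavy tail

    def test_doubling_effects_gives_stochastically_larger_variances(self, sampler):
        rng = np.random.default_rng(9)
        small = np.empty(4000)
        large = np.empty(4000)
        for i in range(4000):
            sampler._update_variances(m1=2, ssq=2.0, rng=rng)
            small[i] = sampler.state.sigma_g2
            sampler._update_variances(m1=2, ssq=8.0, rng=rng)
            large[i] = sampler.state.sigma_g2
        assert stats.mannwhitneyu(large, small, alternative="greater").pvalue < 1e-6


class TestResidualVariance:
    def test_two_point_distribution(self, toy_geno):
        """Residuals (1,-1): flat-prior FCD is chi^-2(1, 2)."""
        g = toy_geno.subset_animals([0, 1])
        p = PhenotypeData(y=np.zeros(2))
        s = Sampler(g, p, MethodSpec("bayesCpi"))
        rng = np.random.default_rng(10)
        draws = np.empty(50_000)
        for i in range(draws.size):
            s.state.residual = np.array([1.0, -1.0])
            s._update_residual_variance(rng)
            draws[i] = s.state.sigma_e2
        # chi^-2(1, 2) = inv-gamma(1/2, rate 1)
        ks = stats.kstest(draws, stats.invgamma(0.5, scale=1.0).cdf)
        assert ks.pvalue > 0.01

    def test_scale_equivariance(self, toy_geno):
        g = toy_geno.subset_animals([0, 1, 2])
        p = PhenotypeData(y=np.zeros(3))
        s = Sampler(g, p, MethodSpec("bayesCpi"))
        base = np.array([0.3, -1.0, 0.7])
        out = {c: np.empty(20_000) for c in (1.0, 3.0)}
        for c in out:
            rng = np.random.default_rng(11)
            for i in range(out[c].size):
                s.state.residual = c * base
                s._update_residual_variance(rng)
                out[c][i] = s.state.sigma_e2
        np.testing.assert_allclose(out[3.0], 9.0 * out[1.0], rtol=1e-12)

    def test_degenerate_fit_rejected(self, toy_geno, toy_pheno):
        s = Sampler(toy_geno, toy_pheno, MethodSpec("bayesCpi"))
        s.state.residual = np.zeros(toy_geno.n_animals)
        with pytest.raises(FloatingPointError, match="degenerate"):
            s._update_residual_variance(np.random.default_rng(0))


class TestRunChain:
    def test_seeded_runs_are_bit_identical(self, toy_geno, toy_pheno):
        spec = MethodSpec("anteBayesCpi")
        cfg = small_chain_cfg(seed=13)
        a = run_chain(toy_geno, toy_pheno, spec, cfg)
        b = run_chain(toy_geno, toy_pheno, spec, cfg)
        for k in a.traces:
            np.testing.assert_array_equal(a.traces[k], b.traces[k])
        np.testing.assert_array_equal(a.effect_mean, b.effect_mean)
        np.testing.assert_array_equal(a.t_mean, b.t_mean)

    def test_saved_count_matches_protocol(self, toy_geno, toy_pheno):
        ch = run_chain(toy_geno, toy_pheno, MethodSpec("bayesCpi"),
                       ChainConfig(n_iter=100, burn_in=50, thin=10, seed=1))
        assert ch.n_saved == 5
        assert ch.traces["pi"].size == 5

    def test_indicator_means_bounded(self, toy_geno, toy_pheno):
        ch = run_chain(toy_geno, toy_pheno, MethodSpec("bayesCpi"), small_chain_cfg())
        assert np.all(ch.indicator_mean >= 0) and np.all(ch.indicator_mean <= 1)

    def test_nan_state_aborts_with_cycle_index(self, toy_geno, toy_pheno):
        s = Sampler(toy_geno, toy_pheno, MethodSpec("bayesCpi"), small_chain_cfg())
        y = toy_pheno.y.copy()
        y[0] = np.nan
        s.set_response(y)
        with pytest.raises(FloatingPointError, match="cycle 1"):
            s.run()

    def test_incremental_residual_matches_recomputation(self, toy_geno, toy_pheno):
        s = Sampler(
            toy_geno, toy_pheno, MethodSpec("anteBayesCpi"),
            options=SamplerOptions(refresh_every=10**9),
        )
        rng = np.random.default_rng(14)
        for _ in range(1000):
            s.cycle(rng)
        scale = max(1.0, float(np.max(np.abs(s.state.residual))))
        assert s.refresh_residual() / scale < 1e-8


class TestPosteriorSummary:
    def test_constant_trace_has_zero_mcse(self, toy_geno):
        chain = PosteriorChain(
            method="bayesCpi", config=small_chain_cfg(),
            marker_ids=toy_geno.marker_ids,
            traces={"pi": np.full(100, 0.5)},
            effect_mean=np.zeros(4), indicator_mean=np.zeros(4), n_saved=100,
        )
        s = posterior_summary(chain)
        row = s.scalars.set_index("parameter").loc["pi"]
        assert row["mean"] == 0.5 and row["mcse"] == 0.0

    def test_batch_means_on_iid_normal(self):
        x = np.random.default_rng(15).standard_normal(10_000)
        assert batch_means_mcse(x) == pytest.approx(0.01, rel=0.5)

    def test_empty_chain_rejected(self, toy_geno):
        chain = PosteriorChain(
            method="bayesCpi", config=small_chain_cfg(),
            marker_ids=toy_geno.marker_ids, traces={},
            effect_mean=np.zeros(4), indicator_mean=np.zeros(4), n_saved=0,
        )
        with pytest.raises(ValueError):
            posterior_summary(chain)
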