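import numpy as np
import pytest
from scipy.stats import poisson

from scbudget import (CountMatrix, GammaPrior, GeneratorSpec, PointPrior,
                      CorrelatedGammaPrior, correlation, fit_gamma_mom,
                      gene_statistics, inactive_probability, moments,
                      pairwise_inactive_probability, sample_counts)
from scbudget.counts import SizeFactors
from scbudget.estimators import inactive_coeffs, moments_arrays


def _sf(n_cells, s=1.0):
    return SizeFactors(gamma=np.ones(n_cells), n_reads=s)


def _poisson_expectation(fn, x, s, tol=1e-16):
    """Exact E[fn(Y)] for Y ~ Poisson(s*x), summed to negligible tail mass."""
    y_max = max(50, int(poisson.isf(tol, s * x)) + 10)
    ys = np.arange(y_max)
    return float(poisson.pmf(ys, s * x) @ fn(ys))


class TestMoments:
    def test_single_cell_second_moment(self):
        # y = 2, s = 1: plug-in M2 = 4, EB (falling factorial) M2 = 2
        cm = CountMatrix(np.array([[2]]), ["c"], ["g"])
        m = moments(cm, _sf(1), 2)
        assert m.plugin[1, 0] == 4.0
        assert m.eb[1, 0] == 2.0

    def test_all_zero_counts_give_zero_moments(self):
        cm = CountMatrix(np.zeros((5, 2), dtype=int), list("abcde"), ["g1", "g2"])
        m = moments(cm, _sf(5, 2.0), 3)
        assert np.all(m.plugin == 0) and np.all(m.eb == 0)

    def test_first_moments_identical(self, gamma_poisson_data):
        cm, truth = gamma_poisson_data
        m = moments(cm, truth.size_factors(), 3)
        assert np.array_equal(m.plugin[0], m.eb[0])

    def test_eb_second_moment_unbiased_plugin_inflated(self):
        # X fixed at 0.5, s = 2: E[eb M2] = 0.25, E[plugin M2] = 0.25 + 0.5/2
        rng = np.random.default_rng(5)
        n = 100_000
        y = rng.poisson(2 * 0.5, size=(n, 1)).astype(float)
        plugin, eb = moments_arrays(y, np.full(n, 2.0), 2)
        t_eb = (y * (y - 1)).ravel() / 4.0
        t_plugin = (y**2).ravel() / 4.0
        assert abs(eb[1, 0] - 0.25) < 3 * t_eb.std(ddof=1) / np.sqrt(n)
        assert abs(plugin[1, 0] - 0.5) < 3 * t_plugin.std(ddof=1) / np.sqrt(n)

    @pytest.mark.parametrize("x,s,k", [
        (0.5, 2.0, 1), (0.5, 2.0, 2), (0.5, 2.0, 3), (0.5, 2.0, 4),
        (0.1, 0.5, 2), (0.1, 0.5, 3), (2.0, 0.2, 2), (2.0, 5.0, 4),
        (1.0, 1.0, 3), (3.0, 0.05, 2),
    ])
    def test_factorial_moment_exactly_unbiased(self, x, s, k):
        # E[Y(Y-1)...(Y-k+1)] = (s x)^k under Poisson(s x)
        def falling(ys):
            out = np.ones_like(ys, dtype=float)
            for r in range(k):
                out *= ys - r
            return out / s**k
        assert _poisson_expectation(falling, x, s) == pytest.approx(x**k, abs=1e-8)

    def test_invalid_k_rejected(self, tiny_counts):
        sf = SizeFactors(np.ones(2), 200.0)
        with pytest.raises(ValueError, match="k_max"):
            moments(tiny_counts, sf, 0)

    def test_permutation_invariance(self, gamma_poisson_data):
        cm, truth = gamma_poisson_data
        sf = truth.size_factors()
        perm = np.random.default_rng(3).permutation(cm.n_cells)
        cm_p = CountMatrix(cm.values[perm], [cm.cell_ids[i] for i in perm],
                           cm.gene_ids)
        sf_p = SizeFactors(gamma=truth.gamma[perm], n_reads=sf.n_reads)
        m, m_p = moments(cm, sf, 2), moments(cm_p, sf_p, 2)
        assert np.allclose(m.eb, m_p.eb)


class TestGeneStatistics:
    def test_arithmetic_from_moments(self):
        from scbudget.estimators import MomentEstimates
        m = MomentEstimates(gene_ids=["g"], plugin=np.array([[1.0], [2.0]]),
                            eb=np.array([[1.0], [2.0]]), n_cells=10)
        stats = gene_statistics(m)
        assert stats.var_plugin[0] == 1.0
        assert stats.cv_plugin[0] == 1.0
        assert stats.fano_plugin[0] == 1.0

    def test_pure_poisson_gene_has_zero_eb_cv(self):
        # constant X: all observed variance is Poisson noise; the EB CV must
        # vanish while the plug-in CV stays near sqrt(1/(s*mu))
        spec = GeneratorSpec.single(PointPrior(0.5), depth=2.0, n_genes=30, seed=21)
        cm, truth = sample_counts(spec, 50000)
        stats = gene_statistics(moments(cm, truth.size_factors(), 2))
        cv_eb = np.where(stats.valid_eb, stats.cv_eb, 0.0)
        assert np.nanmean(cv_eb) < 0.1
        assert np.nanmean(stats.cv_plugin) == pytest.approx(
            np.sqrt(1 / (2.0 * 0.5)), rel=0.1)

    def test_negative_eb_variance_flagged_invalid(self):
        # Underdispersed counts: plug-in variance below the mean
        values = np.ones((10, 1), dtype=int)
        cm = CountMatrix(values, [f"c{i}" for i in range(10)], ["g"])
        stats = gene_statistics(moments(cm, _sf(10), 2))
        assert not stats.valid_eb[0]
        assert np.isnan(stats.cv_eb[0])

    def test_plugin_inflation_law(self):
        # E[var_plugin] - Var[X] = E[X]/s, checked at several depths
        rng = np.random.default_rng(17)
        n, reps = 100_000, 20
        r, theta = 2.0, 0.5
        for s in (0.5, 1.0, 5.0):
            infl = np.empty(reps)
            for i in range(reps):
                x = rng.gamma(r, theta, size=n)
                y = rng.poisson(s * x)[:, None]
                plugin, _ = moments_arrays(y, np.full(n, s), 2)
                infl[i] = (plugin[1, 0] - plugin[0, 0] ** 2) - r * theta**2
            se = infl.std(ddof=1) / np.sqrt(reps)
            assert abs(infl.mean() - (r * theta) / s) < 3 * se


class TestGammaFit:
    def test_method_of_moments_identities(self):
        from scbudget.estimators import GeneStatistics
        stats = GeneStatistics(
            gene_ids=["a", "b"], n_cells=10,
            mean=np.array([1.0, 1.0]), var_plugin=np.array([2.0, 1.0]),
            var_eb=np.array([1.0, 0.5]), cv_plugin=np.zeros(2),
            cv_eb=np.zeros(2), fano_plugin=np.zeros(2), fano_eb=np.zeros(2),
            valid_eb=np.array([True, True]))
        fit = fit_gamma_mom(stats)
        assert fit.shape[0] == 1.0 and fit.scale[0] == 1.0
        assert fit.shape[1] == 2.0 and fit.scale[1] == 0.5

    def test_parameter_recovery_and_plugin_bias(self):
        spec = GeneratorSpec.single(GammaPrior(2.0, 0.5), depth=1.0,
                                    n_genes=1, seed=33)
        cm, truth = sample_counts(spec, 100_000)
        stats = gene_statistics(moments(cm, truth.size_factors(), 2))
        fit = fit_gamma_mom(stats)
        assert fit.shape[0] == pytest.approx(2.0, rel=0.05)
        r_plugin = stats.mean[0] ** 2 / stats.var_plugin[0]
        assert r_plugin < 1.0  # inflated variance biases the shape low


class TestCorrelation:
    def test_diagonal_is_one_for_valid_genes(self, gamma_poisson_data):
        cm, truth = gamma_poisson_data
        corr = correlation(cm, truth.size_factors())
        d = np.diag(corr.pearson_eb)
        stats = gene_statistics(moments(cm, truth.size_factors(), 2))
        assert np.all(d[stats.valid_eb] == 1.0)

    def test_independent_genes_uncorrelated(self):
        spec = GeneratorSpec.single(GammaPrior(2.0, 0.5), depth=1.0,
                                    n_genes=8, seed=41)
        cm, truth = sample_counts(spec, 100_000)
        corr = correlation(cm, truth.size_factors())
        off = corr.pearson_eb[np.triu_indices(8, k=1)]
        se = off.std(ddof=1) / np.sqrt(len(off))
        assert abs(off.mean()) < 3 * se + 0.005

    def test_eb_recovers_perfect_correlation_plugin_attenuated(self):
        # identical latent expressions at depth 0.5: plug-in Pearson is
        # attenuated by sqrt(VarX / (VarX + EX/s)) = sqrt(0.5/2.5) ~ 0.447
        spec = GeneratorSpec(priors=(CorrelatedGammaPrior(2.0, 0.5, 2, 1.0),),
                             depth=0.5, seed=42)
        cm, truth = sample_counts(spec, 100_000)
        corr = correlation(cm, truth.size_factors())
        attenuation = 0.5 / (0.5 + 1.0 / 0.5)  # cov/var_plugin ratio
        # EB variance estimates have ~4% sd here, so allow ~3 SE around 1
        assert corr.pearson_eb[0, 1] == pytest.approx(1.0, abs=0.1)
        assert corr.pearson_plugin[0, 1] == pytest.approx(attenuation, abs=0.03)
        assert corr.pearson_plugin[0, 1] < 0.8

    def test_clamping_retains_raw_value(self):
        spec = GeneratorSpec(priors=(CorrelatedGammaPrior(2.0, 0.5, 2, 1.0),),
                             depth=0.5, seed=1)
        cm, truth = sample_counts(spec, 500)
        corr = correlation(cm, truth.size_factors())
        assert np.all(corr.pearson_eb[corr.valid] <= 1.0)
        assert np.all(corr.pearson_eb[corr.valid] >= -1.0)
        # raw values can exceed the bounds but never disagree in sign
        i, j = 0, 1
        if corr.valid[i, j] and abs(corr.pearson_eb_raw[i, j]) > 1:
            assert corr.pearson_eb[i, j] == np.sign(corr.pearson_eb_raw[i, j])


class TestInactiveProbability:
    def test_kappa_zero_gives_one(self, gamma_poisson_data):
        cm, truth = gamma_poisson_data
        est = inactive_probability(cm, truth.size_factors(), kappa=0.0)
        assert np.all(est.p0_eb == 1.0)

    def test_kappa_equal_depth_matches_zero_fraction(self, gamma_poisson_data):
        # gamma == 1 required so that kappa = s_c exactly for every cell
        spec = GeneratorSpec.single(GammaPrior(2.0, 0.5), depth=2.0,
                                    n_genes=4, seed=2)
        cm, truth = sample_counts(spec, 5000)
        est = inactive_probability(cm, truth.size_factors(), kappa=2.0)
        assert np.allclose(est.p0_eb, est.p0_plugin)

    @pytest.mark.parametrize("x,s,kappa", [
        (0.5, 2.0, 1.0), (0.5, 2.0, 2.0), (0.1, 1.0, 0.5), (1.0, 5.0, 2.5),
        (2.0, 0.5, 0.2), (0.3, 10.0, 25.0), (1.5, 4.0, 4.0), (0.05, 20.0, 1.0),
        (0.7, 3.0, 0.0), (1.0, 1.0, 1.0),
    ])
    def test_eb_coefficients_exactly_unbiased(self, x, s, kappa):
        # sum_y Poi(y; s x) (1 - kappa/s)^y = exp(-kappa x)
        val = _poisson_expectation(
            lambda ys: inactive_coeffs(ys, np.full(len(ys), s), kappa).ravel(),
            x, s)
        assert val == pytest.approx(np.exp(-kappa * x), abs=1e-8)

    def test_instability_warning_for_large_kappa(self):
        spec = GeneratorSpec.single(GammaPrior(2.0, 0.5), depth=0.5,
                                    n_genes=1, seed=3)
        cm, truth = sample_counts(spec, 100)
        with pytest.warns(RuntimeWarning, match="unstable"):
            est = inactive_probability(cm, truth.size_factors(), kappa=2.0)
        assert est.n_unstable_cells == 100

    def test_negative_kappa_rejected(self, gamma_poisson_data):
        cm, truth = gamma_poisson_data
        with pytest.raises(ValueError, match="kappa"):
            inactive_probability(cm, truth.size_factors(), kappa=-1.0)


class TestPairwiseInactiveProbability:
    def test_kappa_zero_gives_one(self, gamma_poisson_data):
        cm, truth = gamma_poisson_data
        est = pairwise_inactive_probability(
            cm, truth.size_factors(), 0.0,
            pairs=[(cm.gene_ids[0], cm.gene_ids[1])])
        assert est.p0_eb[0] == 1.0

    def test_kappa_equal_depth_matches_joint_zero_fraction(self):
        spec = GeneratorSpec.single(GammaPrior(2.0, 0.5), depth=2.0,
                                    n_genes=3, seed=4)
        cm, truth = sample_counts(spec, 5000)
        pairs = [("gene0000", "gene0001"), ("gene0001", "gene0002")]
        est = pairwise_inactive_probability(cm, truth.size_factors(), 2.0, pairs)
        assert np.allclose(est.p0_eb, est.p0_plugin)

    def test_product_identity_for_shared_expression(self):
        # X1 = X2 = 0.5, s = 2, kappa = 1: E[a_Y1 a_Y2] = e^{-2 kappa x}
        rng = np.random.default_rng(8)
        n = 200_000
        y = rng.poisson(1.0, size=(n, 2))  # s*x = 1 for both genes
        a = inactive_coeffs(y, np.full(n, 2.0), 1.0)
        est = (a[:, 0] * a[:, 1]).mean()
        se = (a[:, 0] * a[:, 1]).std(ddof=1) / np.sqrt(n)
        assert abs(est - np.exp(-1.0)) < 3 * se

    def test_duplicate_gene_in_pair_rejected(self, gamma_poisson_data):
        cm, truth = gamma_poisson_data
        with pytest.raises(ValueError, match="duplicates"):
            pairwise_inactive_probability(cm, truth.size_factors(), 1.0,
                                          pairs=[("gene0000", "gene0000")])


class TestDepthConsistency:
    def test_eb_cv_stable_plugin_cv_inflates_under_thinning(self):
        # EB CV estimates agree between full and 5x-thinned data; plug-in CV
        # strictly inflates as the depth drops.
        from scbudget import SubsampleSpec, thin_counts
        spec = GeneratorSpec.single(GammaPrior(2.0, 0.5), depth=2.5,
                                    n_genes=25, seed=51)
        cm, truth = sample_counts(spec, 20000)
        sf_full = truth.size_factors()
        thinned = thin_counts(cm, SubsampleSpec(rate=0.2, seed=52))
        sf_thin = SizeFactors(gamma=truth.gamma.copy(), n_reads=0.5)
        assert np.all(thinned.mean_reads_per_cell() >= 0.1)
        st_full = gene_statistics(moments(cm, sf_full, 2))
        st_thin = gene_statistics(moments(thinned, sf_thin, 2))
        diff = st_thin.cv_eb - st_full.cv_eb
        se = np.nanstd(diff, ddof=1) / np.sqrt(np.isfinite(diff).sum())
        assert abs(np.nanmean(diff)) < 3 * se
        assert np.all(st_thin.cv_plugin > st_full.cv_plugin)
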