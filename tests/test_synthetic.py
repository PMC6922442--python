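import numpy as np
import pytest
from scipy import optimize, stats

from emci import (
    CopulaSpec,
    Marginal,
    ValidationError,
    build_linear_pathway,
    compute_fcc,
    exchangeable_correlation,
    generate_copula_ensemble,
    generate_fcc_ensemble,
    run_coverage_experiment,
    sample_elasticities,
)


class TestLinearPathway:
    def test_three_reaction_chain_matrix(self):
        net = build_linear_pathway(3)
        np.testing.assert_array_equal(
            net.stoichiometry, [[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]
        )
        np.testing.assert_allclose(net.stoichiometry @ net.reference_flux, 0.0)

    def test_two_reaction_chain_single_metabolite(self):
        net = build_linear_pathway(2)
        assert (net.m, net.r) == (1, 2)

    @pytest.mark.parametrize("r", [2, 5, 12])
    def test_full_row_rank(self, r):
        net = build_linear_pathway(r)
        assert np.linalg.matrix_rank(net.stoichiometry) == r - 1

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValidationError):
            build_linear_pathway(1)


class TestElasticities:
    def test_sparsity_matches_participation(self):
        net = build_linear_pathway(6)
        e = sample_elasticities(net, seed=0)
        np.testing.assert_array_equal(e.elasticity != 0.0, net.participation())

    def test_substrate_and_product_sign_ranges(self):
        net = build_linear_pathway(4)
        rng = np.random.default_rng(1)
        for _ in range(200):
            E = sample_elasticities(net, rng).elasticity
            NT = net.stoichiometry.T
            subs, prods = E[NT < 0], E[NT > 0]
            assert np.all((subs > 0.0) & (subs <= 1.0))
            assert np.all((prods >= -1.0) & (prods < 0.0))

    def test_seed_reproducibility(self):
        net = build_linear_pathway(5)
        a = sample_elasticities(net, seed=7).elasticity
        b = sample_elasticities(net, seed=7).elasticity
        np.testing.assert_array_equal(a, b)


class TestFCC:
    def test_summation_and_connectivity_theorems(self):
        net = build_linear_pathway(8)
        rng = np.random.default_rng(2)
        for _ in range(100):
            e = sample_elasticities(net, rng)
            C = compute_fcc(net, e).values
            np.testing.assert_allclose(C.sum(axis=1), 1.0, atol=1e-8)
            np.testing.assert_allclose(C @ e.elasticity, 0.0, atol=1e-8)

    def test_two_step_chain_against_finite_difference(self):
        # concrete rate-law realization: v1 = e1 * x^eps_p, v2 = e2 * x^eps_s
        # with one internal metabolite x; perturb enzyme activity e1 and
        # measure d ln J / d ln e1 on the numerically solved steady state
        eps_p, eps_s = -0.6, 0.35
        net = build_linear_pathway(2)
        from emci import ElasticitySample

        C = compute_fcc(net, ElasticitySample(np.array([[eps_p], [eps_s]]))).values

        def steady_flux(e1, e2=1.0):
            f = lambda x: e1 * x**eps_p - e2 * x**eps_s
            x = optimize.brentq(f, 1e-8, 1e8)
            return e2 * x**eps_s

        h = 1e-6
        fd = (np.log(steady_flux(1.0 + h)) - np.log(steady_flux(1.0 - h))) / (2 * h)
        assert C[0, 0] == pytest.approx(fd, abs=1e-5)
        assert C[0, 0] == pytest.approx(eps_s / (eps_s - eps_p), abs=1e-10)
        assert C[0, 1] == pytest.approx(1.0 - fd, abs=1e-5)


class TestFCCEnsemble:
    def test_rows_inherit_summation_theorem(self):
        net = build_linear_pathway(6)
        ens = generate_fcc_ensemble(net, target_reaction=0, n_models=300, seed=3)
        assert (ens.n, ens.p) == (300, 6)
        np.testing.assert_allclose(ens.values.sum(axis=1), 1.0, atol=1e-8)

    def test_marginals_are_skewed(self):
        net = build_linear_pathway(10)
        ens = generate_fcc_ensemble(net, target_reaction=0, n_models=2_000, seed=4)
        assert np.abs(stats.skew(ens.values, axis=0)).max() > 0.5

    def test_seed_reproducibility(self):
        net = build_linear_pathway(5)
        a = generate_fcc_ensemble(net, 1, 100, seed=5)
        b = generate_fcc_ensemble(net, 1, 100, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestCopulaEnsemble:
    def test_normal_marginals_recover_latent_correlation(self, rng):
        p, n = 4, 10_000
        R = exchangeable_correlation(p, 0.6)
        spec = CopulaSpec(
            np.zeros(p), np.ones(p), R, tuple(Marginal() for _ in range(p))
        )
        ens = generate_copula_ensemble(spec, n, seed=6)
        observed = np.corrcoef(ens.values, rowvar=False)
        assert np.abs(observed - R).max() < 3.0 / np.sqrt(n) + 0.02

    def test_true_means_recovered_by_sample_means(self):
        mu = np.array([-1.0, 0.0, 2.5])
        sd = np.array([0.5, 1.0, 2.0])
        spec = CopulaSpec(
            mu, sd, np.eye(3),
            (
                Marginal("lognormal_shifted", 0.7),
                Marginal("gamma_shifted", 1.2),
                Marginal("normal"),
            ),
        )
        n = 100_000
        ens = generate_copula_ensemble(spec, n, seed=7)
        assert np.all(
            np.abs(ens.values.mean(axis=0) - mu) < 4.0 * sd / np.sqrt(n) + 1e-3
        )
        np.testing.assert_allclose(ens.values.std(axis=0, ddof=1), sd, rtol=0.05)

    @pytest.mark.parametrize(
        "marginal,sign",
        [
            (Marginal("lognormal_shifted", 0.8), 1),
            (Marginal("lognormal_shifted", -0.8), -1),
            (Marginal("gamma_shifted", 1.5), 1),
        ],
    )
    def test_skew_parameter_sets_sample_skewness_sign(self, marginal, sign):
        spec = CopulaSpec(np.zeros(1), np.ones(1), np.eye(1), (marginal,))
        ens = generate_copula_ensemble(spec, 20_000, seed=8)
        assert np.sign(stats.skew(ens.values[:, 0])) == sign

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            CopulaSpec(np.zeros(2), np.ones(2), np.eye(3), (Marginal(), Marginal()))
        with pytest.raises(ValidationError):
            Marginal("lognormal_shifted", 0.0)


class TestCoverageHarness:
    def test_uncorrected_coverage_matches_closed_form(self):
        # independent normals, p=20: simultaneous coverage of uncorrected
        # univariate CIs should be near 0.95^20 = 0.358
        p = 20
        spec = CopulaSpec(
            np.zeros(p), np.ones(p), np.eye(p), tuple(Marginal() for _ in range(p))
        )
        rep = run_coverage_experiment(
            spec, "univariate", 0.05, n=200, reps=400, seed=9
        )
        expected = 0.95**p
        assert rep.simultaneous_coverage == pytest.approx(expected, abs=0.08)

    def test_bonferroni_conservative_on_same_spec(self):
        p = 20
        spec = CopulaSpec(
            np.zeros(p), np.ones(p), np.eye(p), tuple(Marginal() for _ in range(p))
        )
        rep = run_coverage_experiment(
            spec, "bonferroni", 0.05, n=200, reps=400, seed=10
        )
        mc_se = np.sqrt(0.05 * 0.95 / 400)
        assert rep.simultaneous_coverage >= 0.95 - 3 * mc_se
        np.testing.assert_allclose(
            rep.marginal_coverages + rep.left_miss + rep.right_miss, 1.0
        )
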