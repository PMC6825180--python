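"""Multivariate probit JSDM: sampler contracts, decomposition, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from jsdmkit import jsdm
from jsdmkit.tables import ROLE_SIMULATED, SiteTable


def make_sites(X, Y, species=None, predictors=None):
    n = len(X)
    species = species or [f"s{j}" for j in range(Y.shape[1])]
    predictors = predictors or [f"p{i}" for i in range(X.shape[1])]
    return SiteTable(
        coords=pd.DataFrame({"lon": np.zeros(n), "lat": np.zeros(n)}),
        X=pd.DataFrame(X, columns=predictors),
        Y=pd.DataFrame(Y.astype(np.int8), columns=species),
        role=np.full(n, ROLE_SIMULATED))


def simulate_probit(n, alpha, B, R, seed):
    rng = np.random.default_rng(seed)
    P = B.shape[1]
    X = rng.standard_normal((n, P))
    z = alpha + X @ B.T + rng.standard_normal((n, B.shape[0])) \
        @ np.linalg.cholesky(R).T
    return X, (z > 0).astype(np.int8)


SHORT = dict(chains=2, iterations=2500, burn_in=500, thin=5)


class TestSamplerContracts:
    def test_all_one_species_rejected_by_name(self):
        X = np.random.default_rng(0).standard_normal((50, 1))
        Y = np.column_stack([np.ones(50), np.random.default_rng(1)
                             .integers(0, 2, 50)])
        sites = make_sites(X, Y, species=["always", "mixed"])
        with pytest.raises(jsdm.JSDMError, match="always"):
            jsdm.fit_jsdm(sites, jsdm.JSDMSpec(**SHORT))

    def test_draw_count_contract(self):
        alpha = np.array([0.0, -0.2])
        B = np.array([[1.0], [-0.5]])
        X, Y = simulate_probit(150, alpha, B, np.eye(2), seed=2)
        spec = jsdm.JSDMSpec(chains=3, iterations=730, burn_in=100, thin=7)
        post = jsdm.fit_jsdm(make_sites(X, Y), spec)
        assert post.n_draws == 3 * ((730 - 100) // 7)

    def test_retained_R_draws_are_valid_correlations(self):
        alpha = np.zeros(3)
        B = np.array([[1.0], [-0.8], [0.3]])
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.5
        X, Y = simulate_probit(200, alpha, B, R, seed=3)
        post = jsdm.fit_jsdm(make_sites(X, Y), jsdm.JSDMSpec(**SHORT))
        for Rd in post.rcorr[::20]:
            np.testing.assert_allclose(Rd, Rd.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(Rd), 1.0, atol=1e-12)
            np.linalg.cholesky(Rd)

    def test_bit_reproducible_under_seed(self):
        X, Y = simulate_probit(100, np.zeros(2),
                               np.array([[1.0], [0.5]]), np.eye(2), seed=4)
        sites = make_sites(X, Y)
        spec = jsdm.JSDMSpec(chains=2, iterations=600, burn_in=100, thin=5,
                             seed=7)
        p1 = jsdm.fit_jsdm(sites, spec)
        p2 = jsdm.fit_jsdm(sites, spec)
        np.testing.assert_array_equal(p1.alpha, p2.alpha)
        np.testing.assert_array_equal(p1.beta, p2.beta)
        np.testing.assert_array_equal(p1.rcorr, p2.rcorr)

    def test_identity_fixed_sampler_matches_independent_probits(self):
        """With R frozen at I the JSDM factorizes: posterior means of B
        should match independent per-species probit MLEs (statsmodels)."""
        import statsmodels.api as sm

        alpha = np.array([0.2, -0.4])
        B = np.array([[1.2, -0.5], [0.3, 0.8]])
        X, Y = simulate_probit(600, alpha, B, np.eye(2), seed=5)
        sites = make_sites(X, Y)
        spec = jsdm.JSDMSpec(chains=2, iterations=4000, burn_in=1000,
                             thin=5, fix_identity=True, seed=1)
        post = jsdm.fit_jsdm(sites, spec)
        W = sm.add_constant(X)
        for j in range(2):
            mle = sm.Probit(Y[:, j], W).fit(disp=0).params
            assert abs(post.posterior_mean_alpha().iloc[j] - mle[0]) < 0.15
            np.testing.assert_allclose(
                post.posterior_mean_beta().iloc[j].to_numpy(), mle[1:],
                atol=0.2)

    def test_species_permutation_equivariance(self):
        """Permuting the species order permutes the posterior summaries."""
        alpha = np.array([0.3, -0.3, 0.0])
        B = np.array([[1.0, 0.0], [0.0, 1.0], [-0.7, 0.4]])
        R = np.eye(3)
        R[0, 2] = R[2, 0] = 0.5
        X, Y = simulate_probit(500, alpha, B, R, seed=6)
        species = ["a", "b", "c"]
        perm = [2, 0, 1]
        spec = jsdm.JSDMSpec(chains=2, iterations=3000, burn_in=1000,
                             thin=5, seed=3)
        p1 = jsdm.fit_jsdm(make_sites(X, Y, species=species), spec)
        p2 = jsdm.fit_jsdm(make_sites(X, Y[:, perm],
                                      species=[species[i] for i in perm]),
                           spec)
        m1 = p1.posterior_mean_beta().loc[["a", "b", "c"]]
        m2 = p2.posterior_mean_beta().loc[["a", "b", "c"]]
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), atol=0.15)
        r1 = p1.posterior_mean_rcorr().loc["a", "c"]
        r2 = p2.posterior_mean_rcorr().loc["a", "c"]
        assert abs(r1 - r2) < 0.15

    def test_posterior_io_roundtrip(self, tmp_path):
        X, Y = simulate_probit(120, np.zeros(2),
                               np.array([[1.0], [-0.6]]), np.eye(2), seed=8)
        post = jsdm.fit_jsdm(make_sites(X, Y),
                             jsdm.JSDMSpec(chains=2, iterations=500,
                                           burn_in=100, thin=5))
        post.write_dir(tmp_path / "post")
        back = jsdm.JSDMPosterior.read_dir(tmp_path / "post")
        np.testing.assert_allclose(back.alpha, post.alpha, atol=1e-12)
        np.testing.assert_allclose(back.beta, post.beta, atol=1e-12)
        np.testing.assert_allclose(back.rcorr, post.rcorr, atol=1e-12)
        assert back.species == post.species


def fixed_posterior(alpha_draws, beta_draws, X, species=None):
    """Construct a JSDMPosterior with hand-set draws for closed-form checks."""
    alpha_draws = np.asarray(alpha_draws, dtype=float)
    beta_draws = np.asarray(beta_draws, dtype=float)
    D, J = alpha_draws.shape
    P = beta_draws.shape[2]
    species = species or [f"s{j}" for j in range(J)]
    predictors = [f"p{i}" for i in range(P)]
    Y = np.zeros((len(X), J), dtype=np.int8)
    Y[0] = 1  # keep the binary-response invariant satisfied
    sites = make_sites(np.asarray(X, dtype=float), Y, species=species,
                       predictors=predictors)
    return jsdm.JSDMPosterior(
        species=species, predictors=predictors, alpha=alpha_draws,
        beta=beta_draws, rcorr=np.broadcast_to(np.eye(J), (D, J, J)).copy(),
        chain=np.zeros(D, dtype=int), sites=sites,
        spec=jsdm.JSDMSpec(chains=1, iterations=D + 1, burn_in=0, thin=1))


class TestResidualCorrelation:
    def test_diagonal_is_exactly_one_with_zero_sd(self):
        post = fixed_posterior(np.zeros((4, 2)), np.zeros((4, 2, 1)),
                               np.linspace(-1, 1, 5)[:, None])
        res = jsdm.residual_correlation(post)
        diag = res[res.species_a == res.species_b]
        assert (diag["mean"] == 1.0).all()
        assert (diag["sd"] == 0.0).all()

    def test_summary_is_symmetric(self):
        X, Y = simulate_probit(150, np.zeros(2),
                               np.array([[1.0], [0.5]]), np.eye(2), seed=9)
        post = jsdm.fit_jsdm(make_sites(X, Y),
                             jsdm.JSDMSpec(chains=1, iterations=800,
                                           burn_in=100, thin=5))
        res = jsdm.residual_correlation(post).set_index(
            ["species_a", "species_b"])
        assert res.loc[("s0", "s1"), "mean"] == res.loc[("s1", "s0"), "mean"]
        assert res.loc[("s0", "s1"), "sd"] == res.loc[("s1", "s0"), "sd"]


class TestEnvironmentalCorrelation:
    def test_identical_coefficients_give_plus_one(self):
        X = np.linspace(-2, 2, 10)[:, None]
        alpha = np.zeros((3, 2))
        beta = np.tile([[1.5]], (3, 2, 1))
        post = fixed_posterior(alpha, beta, X)
        env = jsdm.environmental_correlation(post).set_index(
            ["species_a", "species_b"])
        assert env.loc[("s0", "s1"), "mean"] == pytest.approx(1.0)

    def test_negated_coefficients_give_minus_one(self):
        X = np.linspace(-2, 2, 10)[:, None]
        beta = np.stack([np.array([[2.0], [-2.0]])] * 3)
        post = fixed_posterior(np.zeros((3, 2)), beta, X)
        env = jsdm.environmental_correlation(post).set_index(
            ["species_a", "species_b"])
        assert env.loc[("s0", "s1"), "mean"] == pytest.approx(-1.0)

    def test_five_site_fixture_matches_direct_pearson(self):
        X = np.array([[0.1, -1.0], [0.5, 0.3], [-0.7, 1.2], [1.4, 0.0],
                      [-0.2, -0.8]])
        alpha = np.array([[0.3, -0.1]])
        beta = np.array([[[1.0, -0.4], [0.2, 0.9]]])
        post = fixed_posterior(alpha, beta, X)
        lp0 = alpha[0, 0] + X @ beta[0, 0]
        lp1 = alpha[0, 1] + X @ beta[0, 1]
        expect = np.corrcoef(lp0, lp1)[0, 1]
        env = jsdm.environmental_correlation(post).set_index(
            ["species_a", "species_b"])
        assert env.loc[("s0", "s1"), "mean"] == pytest.approx(expect,
                                                              abs=1e-12)
        assert env.loc[("s0", "s1"), "sd"] == 0.0

    def test_fewer_than_three_sites_rejected(self):
        post = fixed_posterior(np.zeros((2, 2)), np.ones((2, 2, 1)),
                               np.array([[0.0], [1.0]]))
        with pytest.raises(jsdm.JSDMError):
            jsdm.environmental_correlation(post)

    def test_cooccurrence_summary_layout(self):
        X = np.linspace(-1, 1, 6)[:, None]
        post = fixed_posterior(np.zeros((3, 3)),
                               np.random.default_rng(0)
                               .normal(size=(3, 3, 1)), X)
        summary = jsdm.cooccurrence_summary(post)
        assert list(summary.columns) == ["pair", "env_mean", "env_sd",
                                         "res_mean", "res_sd"]
        assert len(summary) == 3  # unordered pairs of 3 species


def chains_posterior(arrays_by_chain):
    """Posterior with one scalar parameter per species from given chains."""
    chains = [np.asarray(a, dtype=float) for a in arrays_by_chain]
    D = sum(len(c) for c in chains)
    alpha = np.concatenate(chains)[:, None]
    X = np.linspace(-1, 1, 5)[:, None]
    post = fixed_posterior(alpha, np.zeros((D, 1, 1)), X)
    post.chain = np.concatenate([np.full(len(c), i)
                                 for i, c in enumerate(chains)])
    return post


class TestConvergenceCheck:
    def test_identical_chains_have_rhat_near_one(self):
        draws = np.random.default_rng(1).standard_normal(400)
        report = jsdm.convergence_check(chains_posterior([draws, draws]))
        row = report.table.set_index("parameter").loc["alpha[s0]"]
        assert report.available
        assert abs(row["rhat"] - 1.0) < 0.02
        assert not report.flagged

    def test_shifted_chains_are_flagged(self):
        rng = np.random.default_rng(2)
        c1 = rng.standard_normal(400)
        c2 = rng.standard_normal(400) + 5.0
        report = jsdm.convergence_check(chains_posterior([c1, c2]))
        assert "alpha[s0]" in report.flagged
        row = report.table.set_index("parameter").loc["alpha[s0]"]
        assert row["rhat"] > 1.5

    def test_ess_of_independent_draws_near_draw_count(self):
        rng = np.random.default_rng(3)
        chains = [rng.standard_normal(1000) for _ in range(2)]
        report = jsdm.convergence_check(chains_posterior(chains))
        row = report.table.set_index("parameter").loc["alpha[s0]"]
        assert abs(row["ess"] - 2000) < 0.2 * 2000

    def test_single_chain_marked_unavailable(self):
        report = jsdm.convergence_check(
            chains_posterior([np.random.default_rng(4).standard_normal(200)]))
        assert not report.available
        assert report.flagged == []
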