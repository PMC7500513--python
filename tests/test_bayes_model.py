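"""Model building blocks, likelihood oracles, HPDI, and the sampler."""

import numpy as np
import pytest
from scipy import integrate, stats

from percross.bayes_model import (
    Hpdi,
    McmcConfig,
    ModelData,
    bvn_rect_prob,
    fit,
    hpdi,
    indirect_effect,
    log_likelihood,
    ordinal_probit_probs,
    piecewise_predictor,
    posterior_summary,
    rw_metropolis,
)
from percross.synthetic_data import SyntheticConfig, generate_model_data


class TestPiecewisePredictor:
    @pytest.mark.parametrize(
        "t, tau, intercept, slope, expected",
        [(5, 3, 0.0, 1.0, 2.0), (1, 3, 0.7, 1.0, 0.7), (10, 4, 0.5, 0.0, 0.5)],
    )
    def test_examples(self, t, tau, intercept, slope, expected):
        assert piecewise_predictor(t, tau, intercept, slope) == pytest.approx(expected)

    def test_constant_after_breakpoint(self):
        vals = piecewise_predictor(np.arange(4, 21), 4.0, 0.2, 0.3)
        assert np.allclose(vals, vals[0])


class TestOrdinalProbitProbs:
    def test_closed_form(self):
        probs = ordinal_probit_probs(0.0, (-1.0, 0.0, 1.0))
        expected = np.diff([0.0, *stats.norm.cdf([-1.0, 0.0, 1.0]), 1.0])
        assert np.max(np.abs(probs - expected)) < 1e-10

    def test_extreme_eta(self):
        assert np.allclose(ordinal_probit_probs(40.0, (-1, 0, 1)), [0, 0, 0, 1])

    def test_normalization_and_monotonicity(self):
        rng = np.random.default_rng(0)
        etas = np.sort(rng.normal(0, 2, 40))
        probs = ordinal_probit_probs(etas, (-0.8, 0.2, 1.3))
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-12)
        # stochastic ordering: upper-tail mass is nondecreasing in eta
        for k in range(1, 4):
            tail = probs[:, k:].sum(axis=1)
            assert np.all(np.diff(tail) >= -1e-12)

    def test_bad_cutpoints(self):
        with pytest.raises(ValueError):
            ordinal_probit_probs(0.0, (1.0, 0.0, 2.0))


class TestBvnRect:
    @pytest.mark.parametrize(
        "rect",
        [
            (-0.5, 1.2, -0.3, 0.9),
            (-np.inf, 0.0, -np.inf, 0.0),
            (0.5, np.inf, -1.0, 0.3),
            (-2.0, -1.0, 1.0, 2.0),
        ],
    )
    @pytest.mark.parametrize("rho", [0.5, -0.35])
    def test_against_quadrature(self, rect, rho):
        a1, b1, a2, b2 = rect
        got = float(bvn_rect_prob(a1, b1, a2, b2, rho, nq=64))
        s = np.sqrt(1 - rho**2)

        def integrand(z):
            return stats.norm.pdf(z) * (
                stats.norm.cdf((b2 - rho * z) / s) - stats.norm.cdf((a2 - rho * z) / s)
            )

        want, _ = integrate.quad(integrand, max(a1, -10), min(b1, 10), epsabs=1e-12)
        assert got == pytest.approx(want, abs=1e-6)

    def test_rho_zero_factorizes(self):
        got = float(bvn_rect_prob(-1.0, 0.5, -0.2, 2.0, 0.0))
        want = (stats.norm.cdf(0.5) - stats.norm.cdf(-1.0)) * (
            stats.norm.cdf(2.0) - stats.norm.cdf(-0.2)
        )
        assert got == pytest.approx(want, abs=1e-12)


def tiny_params(n_ind, n_teams, **overrides):
    p = {
        "a": np.zeros(n_ind),
        "b": np.zeros(n_ind),
        "tau_S": np.full(n_ind, 3.0),
        "u": np.zeros(n_ind),
        "v": np.zeros(n_ind),
        "tau_P": np.full(n_ind, 3.0),
        "c": np.zeros(n_teams),
        "lambda_S": 0.0,
        "lambda_G": 0.0,
        "gamma_S": 0.0,
        "gamma_G": 0.0,
        "gamma_D": 0.0,
        "rho": 0.0,
        "kappa": np.array([-1.0, 0.0, 1.0]),
    }
    p.update(overrides)
    return p


def data_from(s_rows, g_rows, y_rows, n_teams=2, T=20):
    return ModelData.from_rows(n_teams, s_rows, g_rows, y_rows, T)


class TestLogLikelihood:
    def test_single_observation_closed_form(self):
        # one click, Y=2, everything zero, symmetric cutpoints
        data = data_from([(0, 0, 1, 1, 0)], [(0, 1, 0)], [(0, 0, 1, 2, 1, 1, 0)])
        p = tiny_params(4, 2)
        want = (
            np.log(stats.norm.cdf(0.0))  # S=1 at eta 0
            + np.log(stats.norm.cdf(0.0))  # G=1 at eta 0
            + np.log(stats.norm.cdf(0.0) - stats.norm.cdf(-1.0))  # Y=2
        )
        assert log_likelihood(data, p) == pytest.approx(want, abs=1e-10)

    def test_duplicating_data_doubles_loglik(self):
        s = [(0, 0, 1, 1, 0), (1, 0, 2, 0, 1)]
        g = [(0, 1, 0), (0, 0, 1)]
        y = [(0, 0, 1, 2, 1, 1, 0), (1, 0, 2, 4, 0, 0, 1)]
        p = tiny_params(4, 2, gamma_G=0.4, lambda_S=0.2)
        ll1 = log_likelihood(data_from(s, g, y), p)
        ll2 = log_likelihood(data_from(s + s, g + g, y + y), p)
        assert ll2 == pytest.approx(2 * ll1, abs=1e-9)

    def test_pair_term_matches_2d_quadrature(self):
        # one dyad, both members respond in trial 1 -> bivariate term
        rho = 0.5
        y = [(0, 0, 1, 2, 1, 1, 1), (1, 0, 1, 3, 1, 1, 1)]
        data = data_from([], [], y)
        assert len(data.pair_idx) == 1
        p = tiny_params(4, 2, rho=rho, u=np.array([0.3, -0.2, 0.0, 0.0]))
        got = log_likelihood(data, p, nq=64)
        # rectangle bounds for Y=2 at eta 0.3 and Y=3 at eta -0.2
        lo1, hi1 = -1.0 - 0.3, 0.0 - 0.3
        lo2, hi2 = 0.0 + 0.2, 1.0 + 0.2
        want, _ = integrate.dblquad(
            lambda z2, z1: stats.multivariate_normal.pdf(
                [z1, z2], cov=[[1, rho], [rho, 1]]
            ),
            lo1,
            hi1,
            lo2,
            hi2,
            epsabs=1e-12,
        )
        assert got == pytest.approx(np.log(want), abs=1e-6)

    def test_rho_zero_is_product_of_marginals(self):
        y = [(0, 0, 1, 2, 1, 1, 1), (1, 0, 1, 3, 1, 1, 1)]
        data = data_from([], [], y)
        p = tiny_params(4, 2, rho=0.0)
        got = log_likelihood(data, p)
        want = np.log(stats.norm.cdf(0) - stats.norm.cdf(-1)) + np.log(
            stats.norm.cdf(1) - stats.norm.cdf(0)
        )
        assert got == pytest.approx(want, abs=1e-9)

    def test_nonfinite_params_raise(self):
        data = data_from([(0, 0, 1, 1, 0)], [(0, 1, 0)], [])
        p = tiny_params(4, 2, lambda_S=np.nan)
        with pytest.raises(ValueError):
            log_likelihood(data, p)


class TestHpdi:
    def test_normal_quantile_oracle(self):
        rng = np.random.default_rng(42)
        iv = hpdi(rng.standard_normal(10**6), 0.95)
        assert iv.lower == pytest.approx(-1.96, abs=0.02)
        assert iv.upper == pytest.approx(1.96, abs=0.02)

    def test_constant_draws(self):
        iv = hpdi(np.full(200, 3.7))
        assert (iv.lower, iv.upper) == (3.7, 3.7)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, 1.0, 5000)
        iv = hpdi(x)
        iv_shift = hpdi(x + 10.0)
        assert iv_shift.lower == pytest.approx(iv.lower + 10.0, abs=1e-9)
        assert iv_shift.upper == pytest.approx(iv.upper + 10.0, abs=1e-9)

    def test_mass_domain(self):
        with pytest.raises(ValueError):
            hpdi(np.zeros(200), 1.5)


class TestRwMetropolis:
    def test_conjugate_normal_mean(self):
        # posterior of mu with prior N(0,1) and 25 obs of N(mu, 2^2):
        rng = np.random.default_rng(3)
        x = rng.normal(1.5, 2.0, 25)
        post_var = 1.0 / (1.0 + len(x) / 4.0)
        post_mean = post_var * (x.sum() / 4.0)

        def logpdf(m):
            return -0.5 * m**2 - np.sum((x - m) ** 2) / 8.0

        draws = rw_metropolis(logpdf, 0.0, n=20000, seed=9, warmup=2000)
        se = np.sqrt(post_var / 500)  # generous effective-sample allowance
        assert np.mean(draws) == pytest.approx(post_mean, abs=4 * se)
        assert np.std(draws) == pytest.approx(np.sqrt(post_var), rel=0.1)


@pytest.fixture(scope="module")
def small_fit():
    data, _ = generate_model_data(SyntheticConfig(n_teams=6, n_trials=10, seed=5))
    mcmc = McmcConfig(chains=2, warmup=150, draws=150, ess_threshold=0.0, rhat_threshold=10.0)
    return data, fit(data, mcmc=mcmc, seed=7)


class TestFit:
    def test_same_seed_same_draws(self, small_fit):
        data, res1 = small_fit
        res2 = fit(data, mcmc=res1.config, seed=7)
        for name in res1.draws:
            assert np.array_equal(res1.draws[name], res2.draws[name])

    def test_draw_shapes_and_summary(self, small_fit):
        data, res = small_fit
        assert res.draws["gamma_G"].shape == (2, 150)
        assert res.draws["a"].shape == (2, 150, data.n_individuals)
        summ = posterior_summary(res)
        assert set(summ["parameter"]) >= {"lambda_S", "gamma_G", "rho", "mu_tau_P"}
        assert (summ["hpdi_lower"] <= summ["hpdi_upper"]).all()

    def test_needs_two_teams(self):
        data, _ = generate_model_data(SyntheticConfig(n_teams=1, n_trials=5, seed=0))
        with pytest.raises(ValueError, match="2 teams"):
            fit(data)

    def test_degenerate_data_warns(self):
        cfg = SyntheticConfig(n_teams=3, n_trials=5, seed=1, mu_a=8.0, sigma_a=0.01, mu_c=8.0)
        data, _ = generate_model_data(cfg)
        with pytest.warns(UserWarning, match="degenerate"):
            fit(
                data,
                mcmc=McmcConfig(chains=2, warmup=20, draws=20, ess_threshold=0.0, rhat_threshold=10.0),
                seed=0,
            )

    def test_no_learning_limit_matches_plain_probit(self):
        # slopes pinned at zero and vanishing random effects reduce the
        # individual-success submodel to a pooled probit S ~ Phi(mu + lam*D);
        # its posterior mean should match the statsmodels MLE on a larger n
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        n_teams, n_trials = 25, 30
        s_rows, g_rows = [], []
        true_int, true_lam = 0.3, 0.7
        for j in range(n_teams):
            for t in range(1, n_trials + 1):
                D = int(rng.uniform() < 0.3)
                g_rows.append((j, 0, D))
                for m in range(2):
                    s = int(rng.uniform() < stats.norm.cdf(true_int + true_lam * D))
                    s_rows.append((2 * j + m, j, t, s, D))
        data = ModelData.from_rows(n_teams, s_rows, g_rows, [], n_trials)
        fixed = {
            "b": 0.0,
            "tau_S": 1.0,
            "sigma_a": 0.02,
            "sigma_b": 0.01,
            "v": 0.0,
            "tau_P": 1.0,
            "rho": 0.0,
        }
        res = fit(
            data,
            mcmc=McmcConfig(
                chains=2, warmup=400, draws=400, fixed=fixed,
                ess_threshold=0.0, rhat_threshold=10.0,
            ),
            seed=3,
        )
        X = np.column_stack(
            [np.ones(len(data.s_val)), np.asarray([r[4] for r in s_rows])]
        )
        mle = sm.Probit(data.s_val, X).fit(disp=0)
        lam_hat = float(np.mean(res.stacked("lambda_S")))
        int_hat = float(np.mean(res.stacked("mu_a")))
        assert lam_hat == pytest.approx(mle.params[1], abs=0.12)
        assert int_hat == pytest.approx(mle.params[0], abs=0.08)


class TestIndirectEffect:
    def test_product_is_drawwise_multiplication(self, small_fit):
        _, res = small_fit
        ie = indirect_effect(res, mode="product")
        assert np.allclose(ie, res.stacked("lambda_G") * res.stacked("gamma_G"))

    def test_zero_gamma_gives_zero_effect(self, small_fit):
        _, res = small_fit
        res.draws = dict(res.draws)
        res.draws["gamma_G"] = np.zeros_like(res.draws["gamma_G"])
        assert np.all(indirect_effect(res, mode="product") == 0.0)

    def test_sign_propagates(self, small_fit):
        _, res = small_fit
        res.draws = dict(res.draws)
        res.draws["gamma_G"] = np.abs(res.draws["gamma_G"]) + 0.01
        res.draws["lambda_G"] = np.abs(res.draws["lambda_G"]) + 0.01
        assert np.all(indirect_effect(res, mode="product") > 0)

    def test_contrast_mode_runs(self, small_fit):
        _, res = small_fit
        ie = indirect_effect(res, mode="contrast")
        assert ie.shape == res.stacked("gamma_G").shape
        assert np.all(np.isfinite(ie))


class TestModelData:
    def test_pairing_by_team_and_trial(self):
        y = [
            (0, 0, 1, 2, 1, 1, 0),  # team 0 trial 1 member 0
            (1, 0, 1, 3, 1, 1, 0),  # team 0 trial 1 member 1 -> pair
            (2, 1, 1, 1, 0, 0, 0),  # team 1 trial 1, alone -> single
            (0, 0, 2, 4, 1, 1, 1),  # team 0 trial 2, alone -> single
        ]
        data = data_from([], [], y)
        assert len(data.pair_idx) == 1
        assert sorted(data.single_idx.tolist()) == [2, 3]
        i1, i2 = data.pair_idx[0]
        assert data.y_ind[i1] % 2 == 0 and data.y_ind[i2] % 2 == 1
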