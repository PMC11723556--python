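"""Sandwiched correlation distributions, EM fitting and model ranking."""
import numpy as np
import pytest
from scipy import integrate, optimize, stats

from plumespect import corrmodels as cm


class TestAlapFromGaussian:
    def test_symmetric_case_is_unit_laplacian(self):
        p = cm.alap_from_gaussian(1.0, 0.0, 0.0)
        assert p.pos == p.neg == (0.5,)
        assert p.pdf(0.0) == pytest.approx(1.0)
        assert p.cdf(0.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("sigma2,rho", [(1.0, 0.3), (0.5, -0.6), (2.0, 0.8)])
    def test_mean_equals_sigma2_rho(self, sigma2, rho):
        p = cm.alap_from_gaussian(sigma2, rho)
        assert p.mean() == pytest.approx(sigma2 * rho, rel=1e-10)

    def test_nonzero_rho_perp_shrinks_normaliser(self):
        p = cm.alap_from_gaussian(1.0, 0.0, 0.6)
        Z = sum(p.norms)
        assert Z == pytest.approx(np.sqrt(1 - 0.36))

    def test_monte_carlo_law(self, rng):
        # r = (ac + bd)/2 under the Gaussian coefficient model follows the
        # asymmetric Laplacian: KS distance < 0.01 at n = 1e5
        r = cm.sample_coefficient_correlations(1.0, 0.5, 0.0, 100_000, rng)
        p = cm.alap_from_gaussian(1.0, 0.5, 0.0)
        ks = stats.ks_1samp(r, lambda x: p.cdf(x)).statistic
        assert ks < 0.01

    def test_rejects_degenerate_correlation(self):
        with pytest.raises(ValueError):
            cm.alap_from_gaussian(1.0, 1.0)


class TestSandwichDistributions:
    def test_symmetric_exponential_cdf_at_zero(self):
        p = cm.SandwichParams("exponential", (0.4,), (0.4,))
        assert p.cdf(0.0) == pytest.approx(0.5)

    def test_gamma_with_unit_shapes_reduces_to_exponential(self):
        pe = cm.SandwichParams("exponential", (0.3,), (0.15,))
        pg = cm.SandwichParams("gamma", (0.3, 1.0), (0.15, 1.0))
        x = np.linspace(-1.5, 1.5, 301)
        assert np.allclose(pe.pdf(x), pg.pdf(x), atol=1e-9)

    def test_gig_approaches_gamma_in_small_alpha_limit(self):
        # fixed mean scale 2 lam / alpha while alpha*lam -> 0
        scale, k = 0.4, 0.7
        alpha = 1e-3
        pg = cm.SandwichParams("gamma", (scale, k), (scale, k))
        pgig = cm.SandwichParams(
            "gig", (alpha * scale / 2, k, alpha), (alpha * scale / 2, k, alpha)
        )
        x = np.linspace(0.05, 2.0, 100)

        def quad_norm(p):
            z, _ = integrate.quad(lambda t: p.pdf(t), -np.inf, np.inf, limit=200)
            return z

        assert quad_norm(pg) == pytest.approx(1.0, abs=1e-6)
        dev = np.max(np.abs(pg.pdf(x) - pgig.pdf(x)))
        assert dev < 1e-3

    @pytest.mark.parametrize("family", ["exponential", "gamma", "gig"])
    def test_pdf_integrates_to_one(self, family, rng):
        # normalisation by quadrature over random in-bounds parameter draws
        for _ in range(33):
            scale = rng.uniform(0.05, 2.0)
            scale2 = rng.uniform(0.05, 2.0)
            if family == "exponential":
                p = cm.SandwichParams(family, (scale,), (scale2,))
            elif family == "gamma":
                p = cm.SandwichParams(
                    family,
                    (scale, rng.uniform(0.3, 3.0)),
                    (scale2, rng.uniform(0.3, 3.0)),
                )
            else:
                p = cm.SandwichParams(
                    family,
                    (scale, rng.uniform(0.3, 3.0), rng.uniform(0.2, 3.0)),
                    (scale2, rng.uniform(0.3, 3.0), rng.uniform(0.2, 3.0)),
                )
            z, _ = integrate.quad(
                lambda t: p.pdf(t), -np.inf, np.inf, limit=400
            )
            assert z == pytest.approx(1.0, abs=1e-6)

    def test_sampling_matches_cdf(self, rng):
        p = cm.SandwichParams("gamma", (0.3, 0.8), (0.2, 1.4))
        y = p.rvs(50_000, rng)
        ks = stats.ks_1samp(y, lambda x: p.cdf(x)).statistic
        assert ks < 0.01


class TestEMFit:
    def test_exponential_recovery(self, rng):
        p = cm.SandwichParams("exponential", (0.3,), (0.1,))
        y = p.rvs(10_000, rng)
        fit = cm.em_fit(y, family="exponential")
        assert fit.converged
        assert fit.params.pos[0] == pytest.approx(0.3, rel=0.05)
        assert fit.params.neg[0] == pytest.approx(0.1, rel=0.05)

    def test_intermittent_recovery(self, rng):
        p = cm.SandwichParams("exponential", (0.5,), (0.2,))
        n = 10_000
        z = rng.random(n) < 0.7
        y = np.where(z, p.rvs(n, rng), rng.normal(0.0, 0.01, n))
        # prior mean selected from the grid by fit quality (grid search)
        fits = {
            i0: cm.em_fit(y, family="exponential", intermittent=True, iota0=i0)
            for i0 in np.arange(0.1, 0.95, 0.1)
        }
        best = max(fits.values(), key=lambda f: cm.fit_quality(f, y).value)
        assert 0.6 <= best.iota <= 0.8
        assert best.params.pos[0] == pytest.approx(0.5, rel=0.1)
        assert best.params.neg[0] == pytest.approx(0.2, rel=0.1)

    def test_pure_noise_shrinks_iota_and_flags_noise(self, rng):
        y = rng.normal(0.0, 0.01, 2000)
        fit = cm.em_fit(y, family="exponential", intermittent=True, iota0=0.1)
        assert fit.iota < 0.2
        assert (~fit.z_hat).mean() > 0.5

    def test_all_zero_observations_gives_noise_only_fit(self):
        fit = cm.em_fit(np.zeros(100), family="exponential", intermittent=True)
        assert fit.noise_only
        assert fit.iota == 0.0

    def test_loglik_trace_non_decreasing_for_exponential(self, rng):
        p = cm.SandwichParams("exponential", (0.4,), (0.2,))
        n = 5000
        z = rng.random(n) < 0.6
        y = np.where(z, p.rvs(n, rng), rng.normal(0.0, 0.02, n))
        fit = cm.em_fit(y, family="exponential", intermittent=True, iota0=0.6)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs > -1e-8 * max(1.0, abs(fit.loglik_trace[-1]))).all()

    def test_gamma_recovery(self, rng):
        p = cm.SandwichParams("gamma", (0.3, 0.5), (0.1, 0.8))
        y = p.rvs(10_000, rng)
        fit = cm.em_fit(y, family="gamma")
        assert fit.params.pos[0] == pytest.approx(0.3, rel=0.2)
        assert fit.params.pos[1] == pytest.approx(0.5, rel=0.2)

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError):
            cm.em_fit(np.ones(5))

    def test_closed_form_matches_numerical_mle(self, rng):
        # the closed-form exponential update solves the sandwiched-
        # exponential score equations: compare with Nelder-Mead over 50 sets
        for _ in range(50):
            lam = rng.uniform(0.05, 1.0)
            mu = rng.uniform(0.05, 1.0)
            y = cm.SandwichParams("exponential", (lam,), (mu,)).rvs(400, rng)
            z = np.ones(len(y), dtype=bool)
            lam_c, mu_c = cm._closed_form_exponential(y, z)

            def nll(x):
                if np.any(x <= 0):
                    return 1e30
                p = cm.SandwichParams("exponential", (x[0],), (x[1],))
                return -np.sum(p.logpdf(y))

            res = optimize.minimize(
                nll, [0.5, 0.5], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            assert lam_c == pytest.approx(res.x[0], rel=1e-4)
            assert mu_c == pytest.approx(res.x[1], rel=1e-4)


class TestFitQuality:
    def test_self_fit_quality_high(self, rng):
        p = cm.SandwichParams("exponential", (0.4,), (0.2,))
        y = p.rvs(100_000, rng)
        fit = cm.em_fit(y, family="exponential")
        assert cm.fit_quality(fit, y).value > 0.99

    def test_disjoint_supports_give_near_zero_quality(self, rng):
        # a model with essentially all mass far above the data
        p = cm.SandwichParams("exponential", (10.0,), (1e-6,))
        fit = cm.CorrelationModelFit(
            params=p, interm=None, z_hat=np.ones(10, bool),
            loglik_trace=np.array([]), converged=True, n_iter=0,
        )
        y = rng.normal(0, 1e-4, 1000) - 1.0  # bounded, negative data
        assert cm.fit_quality(fit, y).value < 0.1

    def test_mismatched_family_scores_below_matched(self, rng):
        # gamma data with k = 0.3 has excess small values the asymmetric
        # Laplacian cannot capture
        p = cm.SandwichParams("gamma", (0.5, 0.3), (0.5, 0.3))
        y = p.rvs(20_000, rng)
        fit_exp = cm.em_fit(y, family="exponential")
        fit_gam = cm.em_fit(y, family="gamma")
        q_exp = cm.fit_quality(fit_exp, y).value
        q_gam = cm.fit_quality(fit_gam, y).value
        assert q_gam > q_exp + 0.01

    def test_no_valid_points_raises(self):
        with pytest.raises(ValueError):
            cm.fit_quality(
                cm.CorrelationModelFit(
                    params=cm.SandwichParams("exponential", (1.0,), (1.0,)),
                    interm=None, z_hat=np.ones(2, bool),
                    loglik_trace=np.array([]), converged=True, n_iter=0,
                ),
                np.array([1.0]),
            )


@pytest.fixture(scope="module")
def exp_data():
    rng = np.random.default_rng(7)
    return cm.SandwichParams("exponential", (0.4,), (0.15,)).rvs(800, rng)


class TestNestedCV:
    def test_generator_family_ranks_near_top(self, exp_data):
        grid = [
            {"family": "exponential", "intermittent": False, "iota0": None},
            {"family": "gamma", "intermittent": False, "iota0": None},
            {"family": "exponential", "intermittent": True, "iota0": 0.5},
        ]
        out = cm.nested_cv(exp_data, hyper_grid=grid, seed=3)
        top = out.iloc[0]
        assert top["family"] in ("exponential", "gamma")
        exp_perf = out[
            (out["family"] == "exponential") & (~out["intermittent"])
        ]["performance"].iloc[0]
        assert exp_perf >= out["performance"].max() - 0.02

    def test_duplicate_settings_receive_tied_ranks(self, exp_data):
        grid = [
            {"family": "exponential", "intermittent": False, "iota0": None},
            {"family": "exponential", "intermittent": False, "iota0": None},
        ]
        out = cm.nested_cv(exp_data, hyper_grid=grid, seed=0)
        assert out["rank"].iloc[0] == out["rank"].iloc[1] == 1.5

    def test_seeded_runs_are_reproducible(self, exp_data):
        grid = [
            {"family": "exponential", "intermittent": False, "iota0": None},
            {"family": "exponential", "intermittent": True, "iota0": 0.3},
        ]
        a = cm.nested_cv(exp_data, hyper_grid=grid, seed=42)
        b = cm.nested_cv(exp_data, hyper_grid=grid, seed=42)
        assert a.equals(b)

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError):
            cm.nested_cv(np.ones(10))
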