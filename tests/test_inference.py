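import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

import cjsclim as cc
from cjsclim.inference import ImpactResult, _Layout
from cjsclim.likelihood import interval_covariate


def make_fit(params, species, calendar, climate, spec, pointwise=None):
    """Assemble a PosteriorDraws by hand for derived-quantity tests."""
    n = 0 if pointwise is None else pointwise.shape[2]
    some = next(v for k, v in params.items() if not k.startswith("_"))
    C, D = some.shape[:2]
    params = dict(params)
    params.setdefault("_p_occ", np.arange(1, calendar.n_occasions))
    return cc.PosteriorDraws(
        spec=spec,
        species=list(species),
        params=params,
        pointwise=pointwise if pointwise is not None else np.zeros((C, D, 0)),
        individuals=np.arange(n),
        species_of_individual=np.array([species[0]] * n),
        calendar=calendar,
        climate=climate,
        seed=0,
    )


class TestLogPosterior:
    def test_matches_independent_reimplementation(self, small_matrix, small_climate):
        """Oracle: likelihood summed per history + explicit prior terms."""
        rng = np.random.default_rng(4)
        spec = cc.ModelSpec("temperature")
        state = {
            "alpha": rng.normal(0, 0.5, 2),
            "beta": rng.normal(0, 0.5, 2),
            "p": rng.uniform(0.2, 0.8, 2),
            "mu_alpha": 0.1,
            "sigma_alpha": 0.7,
            "mu_beta": -0.2,
            "sigma_beta": 0.4,
        }
        got = cc.log_posterior(state, small_matrix, spec, small_climate)
        # independent reimplementation with scalar history likelihoods
        x = interval_covariate(spec, small_climate, small_matrix.calendar)
        expected = 0.0
        for sp_idx, sp in enumerate(["A", "B"]):
            phi = expit(state["alpha"][sp_idx] + state["beta"][sp_idx] * x)
            p = np.full(4, state["p"][sp_idx])
            rows = np.flatnonzero(small_matrix.species == sp)
            for i in rows:
                expected += cc.history_loglik(
                    small_matrix.detections[i],
                    small_matrix.first_capture[i],
                    phi,
                    p,
                )
            expected += norm.logpdf(
                state["alpha"][sp_idx], state["mu_alpha"], state["sigma_alpha"]
            )
            expected += norm.logpdf(
                state["beta"][sp_idx], state["mu_beta"], state["sigma_beta"]
            )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_out_of_support_returns_neg_inf(self, small_matrix, small_climate):
        spec = cc.ModelSpec("constant")
        base = {
            "alpha": np.zeros(2),
            "p": np.full(2, 0.5),
            "mu_alpha": 0.0,
            "sigma_alpha": 1.0,
        }
        assert np.isfinite(cc.log_posterior(base, small_matrix, spec, small_climate))
        bad_p = dict(base, p=np.array([0.5, 1.4]))
        assert cc.log_posterior(bad_p, small_matrix, spec, small_climate) == -np.inf
        bad_sig = dict(base, sigma_alpha=-1.0)
        assert cc.log_posterior(bad_sig, small_matrix, spec, small_climate) == -np.inf

    def test_centered_uncentered_equivalence(self, small_matrix, small_climate):
        """The centered density equals the non-centered one divided by the
        reparameterization Jacobian sigma^S (alpha = mu + sigma z)."""
        spec = cc.ModelSpec("constant")
        z = np.array([0.7, -1.1])
        mu, sigma = 0.2, 0.8
        state = {
            "alpha": mu + sigma * z,
            "p": np.full(2, 0.5),
            "mu_alpha": mu,
            "sigma_alpha": sigma,
        }
        centered = cc.log_posterior(state, small_matrix, spec, small_climate)
        # non-centered target: likelihood(alpha(mu, sigma, z)) + N(z; 0, 1)
        lik_only = centered - norm.logpdf(state["alpha"], mu, sigma).sum()
        uncentered = lik_only + norm.logpdf(z).sum()
        assert centered == pytest.approx(uncentered - 2 * np.log(sigma), rel=1e-12)


class TestSampler:
    def test_same_seed_identical_draws(self, small_matrix, small_climate):
        kw = dict(chains=2, warmup=50, draws=50, seed=123)
        f1 = cc.sample_posterior(small_matrix, cc.ModelSpec("constant"), small_climate, **kw)
        f2 = cc.sample_posterior(small_matrix, cc.ModelSpec("constant"), small_climate, **kw)
        np.testing.assert_array_equal(f1.flat("alpha"), f2.flat("alpha"))
        np.testing.assert_array_equal(f1.pointwise, f2.pointwise)
        f3 = cc.sample_posterior(
            small_matrix, cc.ModelSpec("constant"), small_climate,
            chains=2, warmup=50, draws=50, seed=124,
        )
        assert not np.array_equal(f1.flat("alpha"), f3.flat("alpha"))

    def test_single_species_heavy_data_consistency(self):
        """Posterior means land on the simulation truth with n ~ 2000."""
        cfg = cc.SimulationConfig(
            n_species=1, n_occasions=10, start_year=2000,
            mean_releases_per_year=200.0, mu_alpha=0.4, sigma_alpha=0.0,
            mu_beta=0.0, sigma_beta=0.0, p_mean=0.5, p_logit_sd=0.0,
        )
        rng = np.random.default_rng(10)
        climate = cc.simulate_climate(cfg, rng)
        matrix, _ = cc.simulate_capture_histories(cfg, climate, rng)
        fit = cc.sample_posterior(
            matrix, cc.ModelSpec("constant"), climate,
            chains=2, warmup=400, draws=400, seed=11, pooling=False,
        )
        assert expit(fit.flat("alpha")).mean() == pytest.approx(expit(0.4), abs=0.02)
        assert expit(fit.flat("logit_p")).mean() == pytest.approx(0.5, abs=0.02)

    def test_uncentered_bookkeeping_reconstructs(self, paper_scale_bundle):
        fit = cc.sample_posterior(
            paper_scale_bundle.matrix, cc.ModelSpec("temperature"),
            paper_scale_bundle.climate, chains=2, warmup=100, draws=100, seed=42,
        )
        recon = (
            fit.params["mu_alpha"][..., None]
            + fit.params["sigma_alpha"][..., None] * fit.params["z_alpha"]
        )
        np.testing.assert_allclose(recon, fit.params["alpha"], rtol=1e-12)
        recon_b = (
            fit.params["mu_beta"][..., None]
            + fit.params["sigma_beta"][..., None] * fit.params["z_beta"]
        )
        np.testing.assert_allclose(recon_b, fit.params["beta"], rtol=1e-12)
        # all detection draws are probabilities
        assert (expit(fit.flat("logit_p")) <= 1).all()

    def test_shrinkage_toward_global_mean(self):
        """Sparsely captured species shrink toward the community mean under
        partial pooling, relative to their no-pooling estimates."""
        cfg = cc.SimulationConfig(
            n_species=12, n_occasions=12, start_year=2000,
            mean_releases_per_year=1.2, sigma_alpha=0.8,
        )
        rng = np.random.default_rng(5)
        climate = cc.simulate_climate(cfg, rng)
        matrix, _ = cc.simulate_capture_histories(cfg, climate, rng)
        kw = dict(chains=2, warmup=400, draws=400, seed=6)
        pooled = cc.sample_posterior(matrix, cc.ModelSpec("constant"), climate, **kw)
        unpooled = cc.sample_posterior(
            matrix, cc.ModelSpec("constant"), climate, pooling=False, **kw
        )
        mu = pooled.flat("mu_alpha").mean()
        d_pool = np.abs(pooled.flat("alpha").mean(axis=0) - mu)
        d_unpool = np.abs(unpooled.flat("alpha").mean(axis=0) - mu)
        assert (d_pool < d_unpool).mean() >= 0.75
        assert d_pool.mean() < d_unpool.mean()

    def test_recovery_coverage(self, recovery_experiment):
        """95% intervals for the global temperature effect cover the truth."""
        truth = recovery_experiment["truth"]
        covered = sum(lo <= truth <= hi for lo, hi in recovery_experiment["intervals"])
        assert covered >= 18  # >= 90% of 20 replicates


class TestDerivedQuantities:
    def _temperature_fit(self, alpha_draws, beta_draws):
        # climate z = (-1, 1, 0): survival intervals use x = (-1, 1)
        climate = cc.zscore_covariates(
            cc.ClimateSeries(
                years=np.array([0, 1, 2]),
                temp_c=np.array([26.0, 28.0, 27.0]),
                precip_mm=np.array([300.0, 280.0, 290.0]),
            )
        )
        calendar = cc.OccasionCalendar.all_sampled([0, 1, 2])
        K = len(alpha_draws)
        params = {
            "alpha": np.asarray(alpha_draws, dtype=float).reshape(1, K, 1),
            "beta": np.asarray(beta_draws, dtype=float).reshape(1, K, 1),
            "logit_p": np.zeros((1, K, 1)),
        }
        return make_fit(params, ["A"], calendar, climate, cc.ModelSpec("temperature"))

    def test_zero_slope_constant_across_years(self):
        fit = self._temperature_fit([0.3, 0.5], [0.0, 0.0])
        df = cc.derived_annual_survival(fit, "A")
        assert df["median"].nunique() == 1

    def test_single_draw_arithmetic(self):
        fit = self._temperature_fit([0.0], [1.0])
        df = cc.derived_annual_survival(fit, "A")
        np.testing.assert_allclose(df["median"], [expit(-1), expit(1)], atol=2e-4)
        np.testing.assert_allclose(df["median"], [0.2689, 0.7311], atol=1e-3)

    def test_negative_slope_monotone_in_covariate(self):
        fit = self._temperature_fit([0.1, 0.2, 0.0], [-0.8, -0.5, -1.2])
        df = cc.derived_annual_survival(fit, "A")
        # x = (-1, 1): survival must decrease with the covariate
        assert df["median"].iloc[0] > df["median"].iloc[1]

    def test_unknown_species_raises(self):
        fit = self._temperature_fit([0.0], [1.0])
        with pytest.raises(KeyError):
            cc.derived_annual_survival(fit, "nope")


class TestPercentReduction:
    def test_arithmetic(self):
        assert cc.percent_reduction(0.5, 0.25) == pytest.approx(50.0)
        assert cc.percent_reduction(0.66, 0.16) == pytest.approx(75.757575, rel=1e-6)
        assert cc.percent_reduction(0.42, 0.42) == 0.0

    def test_vectorized_over_draws(self):
        out = cc.percent_reduction(np.array([0.5, 0.4]), np.array([0.25, 0.1]))
        np.testing.assert_allclose(out, [50.0, 75.0])

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            cc.percent_reduction(0.0, 0.1)


class TestCommunityImpact:
    def _hier_fit(self, mu_alpha, mu_beta, climate):
        K = len(mu_alpha)
        calendar = cc.OccasionCalendar.all_sampled(climate.years.tolist())
        params = {
            "alpha": np.zeros((1, K, 1)),
            "beta": np.zeros((1, K, 1)),
            "logit_p": np.zeros((1, K, 1)),
            "mu_alpha": np.asarray(mu_alpha, dtype=float).reshape(1, K),
            "sigma_alpha": np.ones((1, K)),
            "mu_beta": np.asarray(mu_beta, dtype=float).reshape(1, K),
            "sigma_beta": np.ones((1, K)),
        }
        return make_fit(params, ["A"], calendar, climate, cc.ModelSpec("temperature"))

    def test_zero_effect_zero_impact(self, small_climate):
        fit = self._hier_fit([0.1, 0.4, -0.2], [0.0, 0.0, 0.0], small_climate)
        r = cc.community_climate_impact(fit, 1.0)
        assert r.percent == pytest.approx(0.0, abs=1e-12)

    def test_single_draw_one_sd_shift(self, small_climate):
        fit = self._hier_fit([0.0], [-1.0], small_climate)
        r = cc.community_climate_impact(fit, small_climate.temp_sd)
        # phi: 0.5 -> logistic(-1) = 0.2689, reduction 46.2%
        assert r.z_shift == pytest.approx(1.0)
        assert r.percent == pytest.approx(100 * (0.5 - expit(-1)) / 0.5, rel=1e-10)
        assert r.percent == pytest.approx(46.2, abs=0.1)

    def test_recovers_closed_form_at_truth(self, small_climate):
        """Degenerate posterior at the generating hyperparameters returns the
        closed-form impact exactly."""
        mu_a, mu_b = 0.3, -0.5
        fit = self._hier_fit([mu_a] * 50, [mu_b] * 50, small_climate)
        r = cc.community_climate_impact(fit, 1.0)
        z = 1.0 / small_climate.temp_sd
        expected = 100 * (expit(mu_a) - expit(mu_a + mu_b * z)) / expit(mu_a)
        assert r.percent == pytest.approx(expected, rel=1e-12)


class TestConvergence:
    def _fit_from_chains(self, arr):
        calendar = cc.OccasionCalendar.all_sampled([0, 1])
        params = {"mu_alpha": arr}
        C, D = arr.shape
        return cc.PosteriorDraws(
            spec=cc.ModelSpec("constant"),
            species=["A"],
            params={**params, "_p_occ": np.array([1])},
            pointwise=np.zeros((C, D, 0)),
            individuals=np.array([]),
            species_of_individual=np.array([]),
            calendar=calendar,
            climate=None,
            seed=0,
        )

    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        fit = self._fit_from_chains(rng.standard_normal((2, 2000)))
        rep = cc.convergence_check(fit, rhat_max=1.01, ess_min=400)
        assert rep.passed

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((2, 500))
        arr[0] -= 5
        arr[1] += 5
        rep = cc.convergence_check(self._fit_from_chains(arr))
        assert not rep.passed
        assert (rep.table["rhat"] > 1.1).any()

    def test_single_chain_partial_report(self):
        rng = np.random.default_rng(0)
        rep = cc.convergence_check(self._fit_from_chains(rng.standard_normal((1, 500))))
        assert not rep.rhat_available
        assert rep.table["rhat"].isna().all()

    def test_ar1_ess_matches_closed_form(self):
        rho, n = 0.6, 10_000
        rng = np.random.default_rng(3)
        draws = np.empty((2, n))
        for c in range(2):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = rho * x[t - 1] + np.sqrt(1 - rho**2) * e[t]
            draws[c] = x
        rep = cc.convergence_check(self._fit_from_chains(draws), ess_min=0)
        ess = rep.table["ess_bulk"].iloc[0]
        analytic = 2 * n * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(analytic, rel=0.2)
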