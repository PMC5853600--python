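"""Likelihood arithmetic, sampler correctness and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from lightresponse import (
    FitConfig,
    LightResponseRegressor,
    check_convergence,
    log_likelihood,
    log_posterior,
    run_chains,
    run_mcmc,
)
from lightresponse.bayes import PosteriorChain, initial_log_params

GRID = np.array([22.0, 46.0, 106.0, 170.0, 251.0, 356.0, 509.0, 679.0])


def curve(i, etr_max, i_k):
    return etr_max / (0.42 * i) * -np.expm1(-i / i_k)


class TestLogLikelihood:
    def test_single_observation_on_curve_unit_sigma(self):
        i = np.array([100.0])
        y = curve(i, 25.0, 140.0)
        lp = np.log([25.0, 140.0, 1.0])
        assert log_likelihood(lp, i, y, "phi_ii") == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12
        )

    def test_matches_scipy_normal_logpdf_sum(self):
        rng = np.random.default_rng(3)
        i = np.array([50.0, 200.0, 600.0])
        y = curve(i, 30.0, 150.0) + rng.normal(0, 0.05, 3)
        sigma = 0.07
        lp = np.log([30.0, 150.0, sigma])
        expected = stats.norm.logpdf(y, loc=curve(i, 30.0, 150.0), scale=sigma).sum()
        assert log_likelihood(lp, i, y, "phi_ii") == pytest.approx(expected, abs=1e-12)

    def test_doubling_sigma_with_zero_residuals_costs_n_log2(self):
        i = GRID
        y = curve(i, 25.0, 140.0)
        ll1 = log_likelihood(np.log([25.0, 140.0, 1.0]), i, y, "phi_ii")
        ll2 = log_likelihood(np.log([25.0, 140.0, 2.0]), i, y, "phi_ii")
        assert ll1 - ll2 == pytest.approx(len(i) * np.log(2), abs=1e-10)

    def test_nonfinite_parameters_give_minus_inf_not_exception(self):
        i, y = GRID, curve(GRID, 25.0, 140.0)
        assert log_likelihood([np.nan, 0.0, 0.0], i, y, "phi_ii") == -np.inf
        assert log_likelihood([1e308, 0.0, 0.0], i, y, "phi_ii") == -np.inf

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError, match="log-parameters"):
            log_likelihood([0.0, 0.0], GRID, curve(GRID, 25, 140), "phi_ii")


class TestFlatPrior:
    def test_posterior_equals_likelihood_everywhere(self):
        rng = np.random.default_rng(5)
        i, y = GRID, curve(GRID, 25.0, 140.0)
        for _ in range(20):
            lp = rng.normal(0, 2, 3)
            assert log_posterior(lp, i, y, "phi_ii") == log_likelihood(lp, i, y, "phi_ii")

    def test_mode_matches_generating_params_by_grid_search(self):
        # noiseless data: the posterior mode over the curve parameters sits
        # at the generating values; verified against a coarse lattice search
        y = curve(GRID, 25.0, 140.0)
        etr_grid = np.linspace(20, 30, 41)
        ik_grid = np.linspace(100, 180, 41)
        lls = np.array(
            [
                [
                    log_posterior(np.log([e, k, 0.01]), GRID, y, "phi_ii")
                    for k in ik_grid
                ]
                for e in etr_grid
            ]
        )
        ei, ki = np.unravel_index(np.argmax(lls), lls.shape)
        assert etr_grid[ei] == pytest.approx(25.0, rel=0.01)
        assert ik_grid[ki] == pytest.approx(140.0, rel=0.01)

    def test_mode_matches_independent_optimizer(self, small_dataset):
        i = small_dataset["intensity"].to_numpy()
        y = small_dataset["response"].to_numpy()
        x0 = initial_log_params(i, y, "phi_ii")
        res = optimize.minimize(
            lambda x: -log_posterior(x, i, y, "phi_ii"), x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        # independent route: plain least squares on the curve parameters
        popt, _ = optimize.curve_fit(curve, i, y, p0=[20.0, 100.0])
        assert np.exp(res.x[0]) == pytest.approx(popt[0], rel=1e-4)
        assert np.exp(res.x[1]) == pytest.approx(popt[1], rel=1e-4)


class TestSampler:
    def test_same_seed_bit_identical(self, small_dataset):
        cfg = FitConfig(n_samples=5_000, burn_in=500, seed=42)
        c1 = run_mcmc(small_dataset, "phi_ii", cfg)
        c2 = run_mcmc(small_dataset, "phi_ii", cfg)
        assert np.array_equal(c1.draws, c2.draws)
        assert c1.acceptance_rate == c2.acceptance_rate

    def test_chain_shape_and_finiteness(self, small_dataset):
        cfg = FitConfig(n_samples=5_000, burn_in=500, seed=0)
        chain = run_mcmc(small_dataset, "phi_ii", cfg)
        assert chain.draws.shape == (4_500, 3)
        assert np.all(np.isfinite(np.exp(chain.draws)))

    def test_near_noiseless_recovery_within_one_percent(self):
        rng = np.random.default_rng(11)
        i = np.tile(GRID, 6)
        y = curve(i, 25.0, 140.0) + rng.normal(0, 1e-4, i.size)
        data = pd.DataFrame({"intensity": i, "response": y})
        chain = run_mcmc(data, "phi_ii", FitConfig(n_samples=30_000, burn_in=2_000, seed=1))
        means = chain.natural().mean()
        assert means["etr_max"] == pytest.approx(25.0, rel=0.01)
        assert means["i_k"] == pytest.approx(140.0, rel=0.01)

    def test_posterior_mean_agrees_with_least_squares(self, wt_sl_air, wt_chain):
        i = wt_sl_air["intensity"].to_numpy()
        y = wt_sl_air["response"].to_numpy()
        popt, _ = optimize.curve_fit(curve, i, y, p0=[20.0, 100.0])
        nat = wt_chain.natural()
        for j, name in enumerate(["etr_max", "i_k"]):
            assert abs(nat[name].mean() - popt[j]) < nat[name].std()

    def test_posterior_matches_emcee_cross_check(self, small_dataset):
        # independent ensemble sampler on the identical log posterior
        emcee = pytest.importorskip("emcee")
        i = small_dataset["intensity"].to_numpy()
        y = small_dataset["response"].to_numpy()
        x0 = initial_log_params(i, y, "phi_ii")
        rng = np.random.default_rng(0)
        nwalkers = 16
        p0 = x0 + rng.normal(0, 0.01, (nwalkers, 3))
        sampler = emcee.EnsembleSampler(
            nwalkers, 3, lambda x: log_posterior(x, i, y, "phi_ii"),
        )
        sampler.run_mcmc(p0, 2_000, progress=False)
        ref = np.exp(sampler.get_chain(discard=500, flat=True))
        chain = run_mcmc(
            small_dataset, "phi_ii", FitConfig(n_samples=40_000, burn_in=2_000, seed=3)
        )
        nat = chain.natural().to_numpy()
        for j in range(2):  # curve parameters
            assert nat[:, j].mean() == pytest.approx(ref[:, j].mean(), rel=0.02)
            assert nat[:, j].std() == pytest.approx(ref[:, j].std(), rel=0.4)

    def test_too_few_intensities_rejected(self):
        data = pd.DataFrame({"intensity": [50.0, 50.0, 100.0], "response": [0.4, 0.41, 0.3]})
        with pytest.raises(ValueError, match="3 distinct intensities"):
            run_mcmc(data, "phi_ii", FitConfig(n_samples=1000, burn_in=100, seed=0))

    def test_oversized_fixed_step_warns(self, small_dataset):
        # step large enough to mix terribly but still accept occasionally
        cfg = FitConfig(n_samples=3_000, burn_in=300, seed=0, proposal_scale=3.0)
        with pytest.warns(RuntimeWarning, match="acceptance rate"):
            run_mcmc(small_dataset, "phi_ii", cfg)

    def test_never_accepting_chain_is_a_hard_error(self, small_dataset):
        from lightresponse.bayes import ChainError

        cfg = FitConfig(n_samples=3_000, burn_in=300, seed=0, proposal_scale=25.0)
        with pytest.raises(ChainError, match="never accepted"):
            run_mcmc(small_dataset, "phi_ii", cfg)


class TestConvergence:
    @staticmethod
    def _chain_from(draws):
        return PosteriorChain(
            kind="phi_ii",
            param_names=("log_etr_max", "log_i_k", "log_sigma"),
            draws=draws,
            acceptance_rate=0.3,
        )

    def test_identical_well_mixed_chains_have_unit_rhat(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0, 1, (4_000, 3))
        report = check_convergence([self._chain_from(draws)] * 2)
        assert np.allclose(report["rhat"], 1.0, atol=5e-3)
        assert report["converged"].all()

    def test_dispersed_starts_converge_on_identified_data(self, small_dataset):
        chains = run_chains(
            small_dataset, "phi_ii",
            FitConfig(n_samples=50_000, burn_in=5_000, n_chains=2, seed=0),
        )
        report = check_convergence(chains)
        assert (report["rhat"] < 1.05).all()

    def test_stuck_chain_flagged(self):
        rng = np.random.default_rng(1)
        mixing = rng.normal(0, 1, (2_000, 3))
        stuck = np.full((2_000, 3), 5.0) + rng.normal(0, 1e-6, (2_000, 3))
        report = check_convergence([self._chain_from(mixing), self._chain_from(stuck)])
        assert (report["rhat"] > 1.05).all()
        assert not report["converged"].any()

    def test_unequal_lengths_rejected(self):
        rng = np.random.default_rng(2)
        a = self._chain_from(rng.normal(size=(1_000, 3)))
        b = self._chain_from(rng.normal(size=(900, 3)))
        with pytest.raises(ValueError, match="equal length"):
            check_convergence([a, b])

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(2)
        a = self._chain_from(rng.normal(size=(1_000, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            check_convergence([a])


class TestEstimatorAPI:
    def test_fit_predict_roundtrip(self, wt_sl_air):
        reg = LightResponseRegressor(
            model="phi_ii", n_samples=10_000, burn_in=1_000, n_chains=2, seed=0
        )
        X = wt_sl_air["intensity"].to_numpy().reshape(-1, 1)
        y = wt_sl_air["response"].to_numpy()
        reg.fit(X, y)
        assert set(reg.params_) == {"etr_max", "i_k", "sigma"}
        assert reg.convergence_ is not None
        pred = reg.predict(X)
        assert pred.shape == y.shape
        assert reg.score(X, y) > 0.9

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        reg = LightResponseRegressor(model="npq", seed=5)
        cloned = clone(reg)
        assert cloned.get_params() == reg.get_params()
        reg.set_params(n_samples=1_234)
        assert reg.n_samples == 1_234

    def test_phi_range_validated(self):
        reg = LightResponseRegressor(n_samples=1_000, burn_in=100)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            reg.fit(np.array([[10.0], [20.0], [30.0]]), np.array([0.5, 1.4, 0.2]))
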