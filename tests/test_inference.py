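"""Likelihood, grid/MCMC posteriors, marginals and amplitude fractions."""

import numpy as np
import pytest
from scipy.integrate import quad

import flim_bayes as fb
from flim_bayes.inference import (
    McmcResult,
    ParameterGrid,
    PosteriorGrid,
    _logsumexp,
)

from conftest import PERIOD, TAU_LONG, TAU_SHORT


def tiny_binning(n=8, window=8.0):
    return fb.TimeBinning.uniform(n, window=window)


class TestLogLikelihood:
    def test_pure_background_single_occupied_bin(self, binning):
        theta = fb.DecayParameters(0.0, 0.0, TAU_SHORT, TAU_LONG, PERIOD)
        counts = np.zeros(binning.n_bins, dtype=int)
        counts[17] = 1234
        hist = fb.BinnedHistogram(counts, binning)
        expected = 1234 * np.log(1.0 / binning.n_masked)
        assert fb.log_likelihood(hist, theta, None) == pytest.approx(expected, rel=1e-12)

    def test_difference_matches_direct_product_oracle(self):
        # 8-bin toy instance small enough to form the products explicitly
        binning = tiny_binning()
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 6, size=8)
        hist = fb.BinnedHistogram(counts, binning)
        t1 = fb.DecayParameters(0.3, 0.5, 0.5, 3.0, PERIOD)
        t2 = fb.DecayParameters(0.6, 0.2, 0.5, 3.0, PERIOD)
        got = fb.log_likelihood(hist, t1, None) - fb.log_likelihood(hist, t2, None)
        p1 = fb.mixture_bin_probabilities(t1, None, binning).p
        p2 = fb.mixture_bin_probabilities(t2, None, binning).p
        oracle = np.log(np.prod(p1**counts) / np.prod(p2**counts))
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_linearity_in_counts(self, binning, irf, theta_mix):
        hist = fb.simulate_histogram(
            theta=theta_mix, irf=irf, binning=binning, n_photons=500, seed=9
        )
        scaled = fb.BinnedHistogram(hist.counts * 7, binning)
        assert fb.log_likelihood(scaled, theta_mix, irf) == pytest.approx(
            7 * fb.log_likelihood(hist, theta_mix, irf), rel=1e-12
        )

    def test_counts_in_masked_out_bins_are_ignored(self, irf, theta_mix):
        binning = fb.default_binning().mask_bin_range(17, 240)
        irf_m = fb.InstrumentResponse(irf.weights, binning)
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 50, size=binning.n_bins)
        base = fb.log_likelihood(fb.BinnedHistogram(counts, binning), theta_mix, irf_m)
        spiked = counts.copy()
        spiked[:16] += 10_000
        spiked[241:] += 5_000
        after = fb.log_likelihood(fb.BinnedHistogram(spiked, binning), theta_mix, irf_m)
        assert after == base


class TestGridPosterior:
    def test_zero_photons_returns_the_prior(self, binning, irf):
        hist = fb.BinnedHistogram(np.zeros(binning.n_bins, dtype=int), binning)
        grid = ParameterGrid(
            axes=(("f_short", np.linspace(0.0, 0.4, 21)),),
            fixed={"f_long": 0.5, "tau_short": TAU_SHORT, "tau_long": TAU_LONG,
                   "period": PERIOD},
        )
        post = fb.grid_posterior(hist, grid, irf)
        masses = post.masses
        assert np.abs(masses - masses[0]).max() < 1e-12

    def test_two_point_grid_odds_equal_likelihood_ratio(self, binning, irf, theta_mix):
        hist = fb.simulate_histogram(
            theta=theta_mix, irf=irf, binning=binning, n_photons=2000, seed=4
        )
        vals = np.array([0.25, 0.35])
        grid = ParameterGrid(
            axes=(("f_short", vals),),
            fixed={"f_long": 0.6, "tau_short": TAU_SHORT, "tau_long": TAU_LONG,
                   "period": PERIOD},
        )
        post = fb.grid_posterior(hist, grid, irf)
        masses = post.masses
        ll = [
            fb.log_likelihood(
                hist, fb.DecayParameters(v, 0.6, TAU_SHORT, TAU_LONG, PERIOD), irf
            )
            for v in vals
        ]
        assert masses[0] / masses[1] == pytest.approx(np.exp(ll[0] - ll[1]), rel=1e-10)

    def test_simplex_points_are_excluded(self, binning, irf, theta_mix):
        hist = fb.simulate_histogram(
            theta=theta_mix, irf=irf, binning=binning, n_photons=100, seed=5
        )
        grid = ParameterGrid(
            axes=(
                ("f_short", np.array([0.2, 0.9])),
                ("f_long", np.array([0.2, 0.9])),
            ),
            fixed={"tau_short": TAU_SHORT, "tau_long": TAU_LONG, "period": PERIOD},
        )
        post = fb.grid_posterior(hist, grid, irf)
        assert np.isneginf(post.log_density[1, 1])
        assert np.isfinite(post.log_density[0, 0])

    def test_generic_and_fast_paths_agree(self, binning, irf, theta_mix):
        # a lifetime axis forces the generic path; compare a fraction slice
        hist = fb.simulate_histogram(
            theta=theta_mix, irf=irf, binning=binning, n_photons=5000, seed=6
        )
        fs = np.linspace(0.1, 0.5, 5)
        fast = fb.grid_posterior(
            hist,
            ParameterGrid(
                axes=(("f_short", fs),),
                fixed={"f_long": 0.6, "tau_short": TAU_SHORT, "tau_long": TAU_LONG,
                       "period": PERIOD},
            ),
            irf,
        )
        generic = fb.grid_posterior(
            hist,
            ParameterGrid(
                axes=(("f_short", fs), ("tau_short", np.array([TAU_SHORT]))),
                fixed={"f_long": 0.6, "tau_long": TAU_LONG, "period": PERIOD},
            ),
            irf,
        )
        assert np.abs(fast.masses - generic.masses[:, 0]).max() < 1e-10

    def test_recovery_within_three_posterior_sd(self, binning, irf, fitter):
        theta = fb.DecayParameters(0.5, 0.4, TAU_SHORT, TAU_LONG, PERIOD)
        hist = fb.simulate_histogram(
            theta=theta, irf=irf, binning=binning, n_photons=1_000_000, seed=12
        )
        est = fitter.fit(hist)["f_short"]
        assert abs(est.mean[0] - 0.5) < 3 * est.sd[0]


class TestMarginalsAndEstimates:
    def _posterior(self, log_density, axes):
        grid = ParameterGrid(
            axes=axes,
            fixed={"tau_short": TAU_SHORT, "tau_long": TAU_LONG, "period": PERIOD,
                   **({} if any(n == "f_long" for n, _ in axes) else {"f_long": 0.0}),
                   **({} if any(n == "f_short" for n, _ in axes) else {"f_short": 0.0})},
        )
        return PosteriorGrid(grid, log_density, _logsumexp(log_density))

    def test_single_axis_marginal_is_identity(self):
        vals = np.linspace(0, 1, 11)
        ld = -((vals - 0.4) ** 2)
        post = self._posterior(ld, (("f_short", vals),))
        marg = fb.marginalize(post, "f_short")
        assert np.abs(marg.mass - post.masses).max() < 1e-15

    def test_separable_density_marginalizes_to_factor(self):
        x = np.linspace(0, 1, 9)
        y = np.linspace(0, 1, 7)
        g = np.exp(-3 * x)
        h = 1 + y**2
        ld = np.log(np.outer(g, h))
        post = self._posterior(ld, (("f_short", x), ("f_long", y)))
        marg = fb.marginalize(post, "f_short")
        assert np.abs(marg.mass - g / g.sum()).max() < 1e-12
        assert marg.mass.sum() == pytest.approx(1.0, abs=1e-10)

    def test_unknown_parameter_raises(self):
        vals = np.linspace(0, 1, 5)
        post = self._posterior(np.zeros(5), (("f_short", vals),))
        with pytest.raises(KeyError):
            fb.marginalize(post, "tau_short")

    def test_mean_and_mode_of_skewed_marginal(self):
        marg = fb.MarginalDistribution(
            "f_short", np.array([0.0, 0.5, 1.0]), np.array([0.5, 0.3, 0.2])
        )
        assert fb.estimate(marg, "mean") == pytest.approx(0.35)
        assert fb.estimate(marg, "mode") == 0.0

    def test_symmetric_marginal_mean_equals_mode(self):
        vals = np.linspace(0.2, 0.8, 31)
        mass = np.exp(-((vals - 0.5) ** 2) / 0.005)
        marg = fb.MarginalDistribution("f_short", vals, mass / mass.sum())
        assert fb.estimate(marg, "mean") == pytest.approx(0.5, abs=1e-12)
        assert fb.estimate(marg, "mode") == pytest.approx(0.5, abs=1e-12)

    def test_mode_tie_breaks_to_smallest_value(self):
        marg = fb.MarginalDistribution(
            "f_short", np.array([0.1, 0.2, 0.3, 0.4]), np.array([0.2, 0.3, 0.3, 0.2])
        )
        assert fb.estimate(marg, "mode") == 0.2

    def test_truncated_posterior_is_skewed_so_mode_and_mean_differ(self, binning, irf, fitter):
        # near-zero true fraction: the posterior is truncated at f = 0
        theta = fb.DecayParameters(0.0, 0.95, TAU_SHORT, TAU_LONG, PERIOD)
        hist = fb.simulate_histogram(
            theta=theta, irf=irf, binning=binning, n_photons=2000, seed=13
        )
        est = fitter.fit(hist)["f_short"]
        assert est.mean[0] > est.mode[0]  # mass piles against the boundary


class TestPosteriorConcentration:
    def test_posterior_sd_shrinks_with_photon_number(self, binning, irf, fitter, theta_mix):
        sds = []
        for n, seed in [(1_000, 21), (10_000, 22), (100_000, 23)]:
            hist = fb.simulate_histogram(
                theta=theta_mix, irf=irf, binning=binning, n_photons=n, seed=seed
            )
            sds.append(fitter.fit(hist)["f_short"].sd[0])
        assert sds[0] > sds[1] > sds[2]


class TestMcmc:
    FIXED = {"tau_short": TAU_SHORT, "tau_long": TAU_LONG, "period": PERIOD}

    def test_same_seed_gives_identical_samples(self, binning, irf, theta_mix):
        hist = fb.simulate_histogram(
            theta=theta_mix, irf=irf, binning=binning, n_photons=3000, seed=31
        )
        kw = dict(free_params=["f_short", "f_long"], fixed=self.FIXED,
                  n_samples=2000, seed=42, irf=irf)
        a = fb.mcmc_posterior(hist, **kw)
        b = fb.mcmc_posterior(hist, **kw)
        assert np.array_equal(a.samples["f_short"], b.samples["f_short"])
        assert np.array_equal(a.samples["f_long"], b.samples["f_long"])

    def test_single_parameter_chain_matches_grid_posterior_mean(self, binning, irf, theta_mix):
        hist = fb.simulate_histogram(
            theta=theta_mix, irf=irf, binning=binning, n_photons=5000, seed=32
        )
        res = fb.mcmc_posterior(
            hist, ["f_short"], {**self.FIXED, "f_long": 0.6},
            n_samples=20_000, seed=7, irf=irf,
        )
        chain = res.samples["f_short"]
        grid = ParameterGrid(
            axes=(("f_short", np.linspace(0.0, 1.0, 2001)),),
            fixed={**self.FIXED, "f_long": 0.6},
        )
        post = fb.grid_posterior(hist, grid, irf)
        target = fb.marginalize(post, "f_short").mean()
        # batch-means Monte Carlo standard error from the chain itself
        nb = 20
        bm = chain[: (len(chain) // nb) * nb].reshape(nb, -1).mean(axis=1)
        se = bm.std(ddof=1) / np.sqrt(nb)
        assert abs(chain.mean() - target) < 4 * se

    def test_free_lifetime_sampling_runs(self, binning, irf, theta_mix):
        hist = fb.simulate_histogram(
            theta=theta_mix, irf=irf, binning=binning, n_photons=2000, seed=33
        )
        res = fb.mcmc_posterior(
            hist, ["f_short", "tau_short"],
            {**self.FIXED, "f_long": 0.6},
            bounds={"tau_short": (0.05, 2.0)},
            n_samples=1500, seed=8, irf=irf,
        )
        assert 0.0 < res.acceptance_rate < 1.0
        assert np.all(res.samples["tau_short"] > 0.05)
        assert np.all(res.samples["tau_short"] < 2.0)


class TestAmplitudeFraction:
    def test_equal_lifetimes_reduce_to_photon_fraction(self):
        theta = fb.DecayParameters(0.3, 0.6, 2.0, 2.0, PERIOD)
        assert fb.amplitude_fraction(theta) == pytest.approx(0.3 / 0.9, abs=1e-12)

    def test_no_long_component_gives_unit_fraction(self):
        theta = fb.DecayParameters(0.4, 0.0, TAU_SHORT, TAU_LONG, PERIOD)
        assert fb.amplitude_fraction(theta) == 1.0

    def test_both_fractions_zero_is_an_error(self):
        theta = fb.DecayParameters(0.0, 0.0, TAU_SHORT, TAU_LONG, PERIOD)
        with pytest.raises(fb.decay_model.InvalidParameterError):
            fb.amplitude_fraction(theta)

    def test_full_window_long_period_matches_numeric_integration(self):
        # full recording window, T >> tau: a_S/(1-a_S) -> (f_S/tau_S)/(f_L/tau_L)
        tau_s, tau_l, T = 0.3, 1.1, 200.0
        binning = fb.TimeBinning.uniform(512, window=T)
        theta = fb.DecayParameters(0.35, 0.55, tau_s, tau_l, T)
        a_s = fb.amplitude_fraction(theta, binning)

        # oracle: photon yields are amplitudes times the numeric integral of
        # each wrapped decay over the window
        def yield_of(tau):
            return quad(lambda t: np.exp(-t / tau) / (1 - np.exp(-T / tau)), 0, T)[0]

        amp_s = 0.35 / yield_of(tau_s)
        amp_l = 0.55 / yield_of(tau_l)
        assert a_s == pytest.approx(amp_s / (amp_s + amp_l), rel=1e-6)
        ratio = a_s / (1 - a_s)
        assert ratio == pytest.approx((0.35 / tau_s) / (0.55 / tau_l), rel=1e-3)
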