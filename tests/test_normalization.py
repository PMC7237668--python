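"""Stochastic normalization model: drives, rates, gain variability, fits."""

import numpy as np
import pytest

import gainvar as gv
from gainvar.normalization import DEFAULT_POOL_GAIN, orientation_tuning_weight


class TestRaisedCosineWeight:
    def test_peak_value(self):
        assert gv.raised_cosine_weight(30.0, 30.0) == pytest.approx(np.exp(4.5))

    def test_orthogonal_zero(self):
        assert gv.raised_cosine_weight(120.0, 30.0) == pytest.approx(0.0, abs=1e-12)

    def test_even_symmetry(self):
        for delta in (5.0, 17.0, 40.0, 89.0):
            assert gv.raised_cosine_weight(50 + delta, 50.0) == pytest.approx(
                gv.raised_cosine_weight(50 - delta, 50.0)
            )

    def test_periodic_reduction(self):
        assert gv.raised_cosine_weight(10.0, 10.0 + 180.0) == pytest.approx(np.exp(4.5))


class TestStimulusDrive:
    def test_zero_dynamic_range_reduces_to_eta(self):
        g = gv.stimulus_drive(np.array([30.0]), np.array([0.5]), np.array([90.0]),
                              eta=2.0, upsilon=0.0)
        assert g[0] == pytest.approx(2.0)

    def test_single_component(self):
        theta0, pref, c = 40.0, 25.0, 0.3
        g = gv.stimulus_drive(np.array([theta0]), np.array([c]), np.array([pref]),
                              eta=1.5, upsilon=20.0)
        expected = 1.5 + 20.0 * c * orientation_tuning_weight(theta0, pref)
        assert g[0] == pytest.approx(expected)

    def test_additive_in_stimulus(self):
        pref = np.array([10.0, 80.0])
        a1, c1 = np.array([0.0, 20.0]), np.array([0.2, 0.1])
        a2, c2 = np.array([40.0, 60.0]), np.array([0.05, 0.3])
        g1 = gv.stimulus_drive(a1, c1, pref, 2.0, 50.0)
        g2 = gv.stimulus_drive(a2, c2, pref, 2.0, 50.0)
        g12 = gv.stimulus_drive(np.concatenate([a1, a2]), np.concatenate([c1, c2]),
                                pref, 2.0, 50.0)
        assert np.allclose(g12 - 2.0, (g1 - 2.0) + (g2 - 2.0))


class TestMeanRateAndGainVariability:
    def test_zero_drive(self):
        assert gv.mean_rate(0.0, 1.0) == 0.0

    def test_closed_form(self):
        assert gv.mean_rate(1.0, 1.0, beta=0.64, p=2.0) == pytest.approx(
            (1 / 1.64) ** 2
        )

    def test_monotone_in_drive(self):
        rates = gv.mean_rate(np.linspace(0, 5, 20), 2.0)
        assert np.all(np.diff(rates) > 0)

    def test_noiseless_pool(self):
        assert gv.gain_variability_from_normalization(1.0, sigma_N=0.0) == 0.0

    def test_empty_pool_closed_form(self):
        assert gv.gain_variability_from_normalization(
            0.0, beta=0.64, p=2.0, sigma_N=0.35
        ) == pytest.approx(1.09375)

    def test_inverse_proportionality(self):
        s1 = gv.gain_variability_from_normalization(1.36)  # beta + pool = 2
        s2 = gv.gain_variability_from_normalization(3.36)  # beta + pool = 4
        assert s1 == pytest.approx(2 * s2)

    def test_nonpositive_denominator(self):
        with pytest.raises(ValueError):
            gv.mean_rate(1.0, -1.0)


class TestSampleNoisyRate:
    def test_deterministic_limit(self):
        samples = gv.sample_noisy_rate(1.0, 1.0, sigma_N=0.0, n_samples=100)
        assert np.all(samples == gv.mean_rate(1.0, 1.0))

    def test_taylor_moments_small_noise(self):
        """Monte-Carlo CV and mean of the noisy rate match the first-order
        Taylor expressions at sigma_N / (beta + pool) = 0.05."""
        g, pool = 1.5, 4.36  # beta + pool = 5
        sigma_N = 0.25
        samples = gv.sample_noisy_rate(g, pool, sigma_N=sigma_N, n_samples=10**6, seed=41)
        f = gv.mean_rate(g, pool)
        sigma_g = gv.gain_variability_from_normalization(pool, sigma_N=sigma_N)
        assert samples.mean() == pytest.approx(f, rel=0.01)
        assert samples.std() / samples.mean() == pytest.approx(sigma_g, rel=0.02)

    def test_taylor_error_shrinks_with_noise(self):
        g, pool = 1.0, 4.36
        errs = []
        for sigma_N in (0.5, 0.25, 0.125):
            s = gv.sample_noisy_rate(g, pool, sigma_N=sigma_N, n_samples=4 * 10**5, seed=42)
            pred = gv.gain_variability_from_normalization(pool, sigma_N=sigma_N)
            errs.append(abs(s.std() / s.mean() - pred) / pred)
        assert errs[2] < errs[0]

    def test_excessive_noise_rejected(self):
        with pytest.raises(ValueError, match="acceptance rate"):
            gv.sample_noisy_rate(1.0, 0.0, beta=0.64, sigma_N=1.0, n_samples=10)


class TestFitSigmaN:
    def setup_method(self):
        self.pools = np.array([0.5, 1.0, 2.0, 4.0, 8.0])

    def test_self_consistency(self):
        obs = gv.gain_variability_from_normalization(self.pools, sigma_N=0.35)
        fit = gv.fit_sigma_N(obs, self.pools)
        assert fit.sigma_N == pytest.approx(0.35, abs=1e-12)

    def test_linearity_in_observations(self):
        obs = gv.gain_variability_from_normalization(self.pools, sigma_N=0.35)
        fit2 = gv.fit_sigma_N(2 * obs, self.pools)
        assert fit2.sigma_N == pytest.approx(0.70, abs=1e-12)

    def test_closed_form_matches_grid_search(self):
        rng = np.random.default_rng(43)
        obs = gv.gain_variability_from_normalization(self.pools, sigma_N=0.35)
        obs = obs + rng.normal(0, 0.02, size=obs.size)
        fit = gv.fit_sigma_N(obs, self.pools)
        grid = np.linspace(0.0, 2.0, 10**4)
        u = 2.0 / (0.64 + self.pools)
        mse = ((obs[None, :] - grid[:, None] * u[None, :]) ** 2).mean(axis=1)
        assert fit.sigma_N == pytest.approx(grid[np.argmin(mse)], abs=2.0 / 10**4)

    def test_held_out_predictions_returned(self):
        obs = gv.gain_variability_from_normalization(self.pools, sigma_N=0.35)
        fit = gv.fit_sigma_N(obs, self.pools, fit_index=[0, 1, 2])
        assert fit.predictions.shape == self.pools.shape
        assert np.allclose(fit.predictions, obs)


class TestUncertaintyReceptiveField:
    """End-to-end stimulus dependence of the pool signal and gain variability."""

    def test_pool_decreases_with_spread_sigma_g_increases(self, small_population):
        model = small_population
        sigmas, pools = [], []
        for spread in (1.0, 10.0, 25.0, 40.0, 55.0):
            stim = gv.OrientationStimulus(60.0, 0.4, spread)
            a, u = stim.energy_profile()
            pools.append(model.bank.pool(a, u))
            sigmas.append(model.gain_variability(stim))
        assert np.all(np.diff(pools) < 0)
        assert np.all(np.diff(sigmas) > 0)

    def test_sigma_g_decreases_with_contrast(self, small_population):
        model = small_population
        sigmas = [
            model.gain_variability(gv.OrientationStimulus(60.0, c, 5.0))
            for c in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert np.all(np.diff(sigmas) < 0)

    def test_rate_and_gainvar_share_denominator(self, small_population):
        model = small_population
        stim = gv.OrientationStimulus(33.0, 0.3, 12.0)
        a, u = stim.energy_profile()
        rates, sigma_g = model.evaluate(stim)
        g = model.bank.drives(a, u)
        P = model.bank.pool(a, u)
        denom_from_rates = g[g > 0] / rates[g > 0] ** (1.0 / model.bank.p)
        denom_from_sigma = model.sigma_N * model.bank.p / sigma_g
        assert np.allclose(denom_from_rates, model.bank.beta + P)
        assert denom_from_sigma == pytest.approx(model.bank.beta + P)


class TestOrientationStimulus:
    def test_component_structure(self):
        stim = gv.OrientationStimulus(30.0, 0.4, 20.0)
        assert len(stim.component_angles) == 9
        offs = stim.component_offsets
        assert np.allclose(np.diff(offs), 20.0)
        assert stim.component_contrasts.max() == pytest.approx(0.4)

    def test_energy_profile_sums_to_contrast(self):
        for spread in (0.0, 1.0, 30.0, 55.0):
            stim = gv.OrientationStimulus(10.0, 0.25, spread)
            _, u = stim.energy_profile()
            assert u.sum() == pytest.approx(0.25)
            assert np.all(u >= 0)

    def test_invalid_contrast(self):
        with pytest.raises(ValueError):
            gv.OrientationStimulus(0.0, 1.2, 5.0)
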