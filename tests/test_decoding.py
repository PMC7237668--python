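"""Population likelihood, ML decoding, heuristic estimator, evaluation."""

import numpy as np
import pytest

import gainvar as gv
from gainvar.decoding import _PopulationLikelihood

from test_modulated_poisson import gamma_poisson_quadrature_log_pmf


class TestPopulationLogLikelihood:
    def test_equals_sum_of_single_neuron_terms(self, small_population):
        model = small_population
        stim = gv.OrientationStimulus(45.0, 0.3, 10.0)
        rng = np.random.default_rng(51)
        counts = rng.poisson(3.0, size=model.bank.n_units)
        ll = gv.population_log_likelihood(counts, stim, model, dt_ms=1000.0)
        rates, sigma_g = model.evaluate(stim)
        singles = gv.nb_log_pmf(counts, rates, sigma_g)
        assert ll == pytest.approx(float(np.sum(singles)), abs=1e-8)

    def test_matches_quadrature_oracle(self, small_population):
        model = small_population
        stim = gv.OrientationStimulus(45.0, 0.3, 10.0)
        rates, sigma_g = model.evaluate(stim)
        counts = np.zeros(model.bank.n_units, dtype=int)
        counts[:3] = [2, 5, 1]
        ll = gv.population_log_likelihood(counts, stim, model, dt_ms=1000.0)
        oracle = sum(
            gamma_poisson_quadrature_log_pmf(int(k), lam, sigma_g)
            for k, lam in zip(counts, rates)
        )
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_impossible_stimulus(self, small_population):
        """A zero-rate unit with a positive count makes the likelihood the
        impossible sentinel."""
        model = small_population
        like = _PopulationLikelihood(np.ones(model.bank.n_units), model, 1000.0)
        rates, _ = like.rates_and_sigma(0.0, 0.0, 1.0)
        if np.all(rates > 0):  # blank stimulus: eta keeps rates positive
            assert like.log_likelihood(0.0, 0.0, 1.0) > -np.inf


class TestMlDecode:
    def test_noiseless_recovery(self, standard_population):
        model = standard_population
        stim = gv.OrientationStimulus(77.0, 0.5, 1.0)
        rates, _ = model.evaluate(stim)
        counts = np.round(rates).astype(int)  # expected counts at dt = 1 s
        dec = gv.ml_decode(counts, model, dt_ms=1000.0, seed=52)
        assert abs(gv.circular_error_deg(dec.theta_hat, 77.0)) < 2.0

    def test_argmax_dominates_truth(self, standard_population):
        model = standard_population
        stim = gv.OrientationStimulus(120.0, 0.2, 20.0)
        trial = gv.generate_population_trial(stim, model, seed=53)
        dec = gv.ml_decode(trial.counts, model, seed=54)
        ll_truth = gv.population_log_likelihood(trial.counts, stim, model, 1000.0)
        assert dec.log_likelihood >= ll_truth - 1e-6

    def test_error_grows_with_uncertainty(self, standard_population):
        """Scaled contrast of the decoding simulation: high-contrast narrow
        stimuli are decoded nearly perfectly; low-contrast dispersed stimuli
        are not."""
        model = standard_population
        rng = np.random.default_rng(55)
        errs = {}
        for label, (c, sp) in {"easy": (0.5, 1.0), "hard": (0.05, 55.0)}.items():
            e = []
            for t in range(12):
                th = float(rng.uniform(0, 180))
                trial = gv.generate_population_trial(
                    gv.OrientationStimulus(th, c, sp), model, seed=rng
                )
                dec = gv.ml_decode(trial.counts, model, rng=rng)
                e.append(gv.circular_error_deg(dec.theta_hat, th))
            errs[label] = gv.axial_circular_variance(e)
        assert errs["easy"] < 0.01
        assert errs["hard"] > 5 * errs["easy"]

    def test_bounds_respected(self, standard_population):
        model = standard_population
        trial = gv.generate_population_trial(
            gv.OrientationStimulus(5.0, 0.1, 40.0), model, seed=56
        )
        dec = gv.ml_decode(trial.counts, model, seed=57)
        assert 0.0 <= dec.theta_hat < 180.0
        assert 0.0 <= dec.c_hat <= 1.0
        assert 0.0 <= dec.sigma_s_hat <= 70.0


class TestDecodedGainVariability:
    def test_matches_uncertainty_receptive_field(self, standard_population):
        model = standard_population
        dec = gv.DecodeResult(30.0, 0.2, 15.0, np.nan, 0.0, 1)
        val = gv.decoded_gain_variability(dec, model)
        assert val == pytest.approx(
            model.gain_variability(gv.OrientationStimulus(30.0, 0.2, 15.0))
        )

    def test_blank_stimulus_limit(self, standard_population):
        model = standard_population
        dec = gv.DecodeResult(0.0, 0.0, 1.0, np.nan, 0.0, 1)
        assert gv.decoded_gain_variability(dec, model) == pytest.approx(
            model.sigma_N * model.bank.p / model.bank.beta
        )

    def test_decreasing_in_contrast(self, standard_population):
        model = standard_population
        vals = [
            gv.decoded_gain_variability(gv.DecodeResult(0.0, c, 10.0, np.nan, 0.0, 1), model)
            for c in (0.1, 0.2, 0.4)
        ]
        assert vals[0] > vals[1] > vals[2]


class TestHeuristicSigmaG:
    def test_hand_computed_fixture(self):
        res = gv.heuristic_sigma_g(np.array([2, 4, 6]), np.zeros(3))
        assert res.sigma_g_sq_raw == pytest.approx((4.0 - 4.0) / 16.0)
        assert res.sigma_g == 0.0

    def test_poisson_null_near_zero(self):
        rng = np.random.default_rng(61)
        labels = np.repeat(np.arange(5), 200)
        lam = np.array([5.0, 10.0, 20.0, 35.0, 50.0])[labels]
        ests = [
            gv.heuristic_sigma_g(rng.poisson(lam), labels).sigma_g for _ in range(100)
        ]
        assert np.mean(ests) < 0.05

    def test_permutation_invariance(self):
        rng = np.random.default_rng(62)
        labels = np.repeat(np.arange(5), 50)
        counts = rng.poisson(10.0, size=250)
        base = gv.heuristic_sigma_g(counts, labels).sigma_g
        perm = rng.permutation(250)
        assert gv.heuristic_sigma_g(counts[perm], labels[perm]).sigma_g == pytest.approx(base)

    def test_small_column_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            gv.heuristic_sigma_g(np.array([1, 2, 3]), np.array([0, 0, 1]))

    def test_negative_raw_clamped(self):
        res = gv.heuristic_sigma_g(np.array([10, 10, 10, 11]), np.zeros(4))
        assert res.sigma_g_sq_raw < 0 and res.clamped and res.sigma_g == 0.0


class TestEvaluateDecoding:
    def test_all_zero_errors_undefined_correlation(self):
        res = gv.evaluate_decoding(np.linspace(0.1, 1.0, 50), np.zeros(50))
        assert np.isnan(res["spearman_r"])
        assert np.all(res["bin_error_circular_variance"] == 0.0)

    def test_uniform_errors_have_unit_circular_variance(self):
        errors = np.linspace(-90.0, 90.0, 36, endpoint=False)
        assert gv.axial_circular_variance(errors) == pytest.approx(1.0, abs=1e-12)

    def test_rank_perfect_relation(self):
        # dispersion strictly increasing with sigma_g_hat, bin by bin
        sigma = np.repeat(np.linspace(0.1, 1.0, 10), 30)
        spread = np.repeat(2.0 + 4.0 * np.arange(10), 30)
        errors = spread * np.tile([-1.0, 0.0, 1.0], 100)
        res = gv.evaluate_decoding(sigma, errors, n_bins=10)
        assert res["spearman_r"] == pytest.approx(1.0)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            gv.evaluate_decoding(np.ones(5), np.ones(5))


def test_association_degrades_with_short_readout():
    """Scaled-down sweep of the read-out window: the gain-variability /
    decoding-error association is weaker for a 62.5 ms window than for the
    full 1000 ms window."""
    from gainvar.decoding import default_stimulus_grid

    grid = default_stimulus_grid(n_contrasts=4, n_spreads=4, n_orientations=3)
    out = gv.run_decoding_sweep(
        seed=99, dt_ladder=(62.5, 1000.0), gamma_values=(0.0,),
        n_neurons=80, stimulus_grid=grid,
    )
    r = {c["dt_ms"]: c["spearman_r"] for c in out["cells"]}
    assert r[1000.0] > r[62.5]


class TestGainMixing:
    def test_shared_limit_identical_gains(self):
        g = gv.sample_gains(0.3, n_trials=4, gamma_mix=1.0, n_neurons=10, seed=71)
        assert np.allclose(g, g[:1])

    def test_mixing_correlation_matches_formula(self):
        gamma = 0.33
        g = gv.sample_gains(0.3, n_trials=10**5, gamma_mix=gamma, n_neurons=2, seed=72)
        r = np.corrcoef(g[0, :, 0], g[1, :, 0])[0, 1]
        expected = gamma**2 / (gamma**2 + (1 - gamma) ** 2)
        assert r == pytest.approx(expected, abs=3.0 / np.sqrt(10**5))

    def test_marginal_moments_preserved_under_mixing(self, small_population):
        """gamma = 0 and gamma = 0.67 with matched sigma_G leave per-neuron
        marginal count mean unchanged (mixing preserves unit mean)."""
        model = small_population
        stim = gv.OrientationStimulus(90.0, 0.3, 5.0)
        means = {}
        for gamma in (0.0, 0.67):
            rng = np.random.default_rng(73)
            tot = np.zeros(model.bank.n_units)
            for t in range(400):
                trial = gv.generate_population_trial(stim, model, gamma_mix=gamma, seed=rng)
                tot += trial.counts
            means[gamma] = tot / 400
        assert np.allclose(means[0.0].mean(), means[0.67].mean(), rtol=0.05)
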