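"""Joint maximum-likelihood decoding of stimulus features and uncertainty.

A population of independent modulated-Poisson neurons, with rates and a
single shared gain variability supplied by the stochastic normalization
model, defines the population log-likelihood

    log p({K_i} | S) = sum_i log NB(K_i; lambda_i(S), sigma_G(S)),

with lambda_i = f_i(S) * dt. The decoder maximizes this over the stimulus
parameters (orientation, contrast, spread) with a bound-constrained
multi-start optimizer; evaluating the uncertainty receptive field at the
decoded stimulus yields the decoded gain variability. A neurally plausible
heuristic estimator of gain variability from columnar sub-populations and
the decoding-quality evaluation (binned circular error variance vs decoded
gain variability) are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .modulated_poisson import SIGMA_G_FLOOR, nb_log_pmf
from .normalization import NormalizationModel, OrientationStimulus
from .synthetic import _rng_from, generate_population_trial, make_population

__all__ = [
    "DecodeResult",
    "HeuristicGainVariability",
    "STIMULUS_BOUNDS",
    "population_log_likelihood",
    "ml_decode",
    "decoded_gain_variability",
    "heuristic_sigma_g",
    "circular_error_deg",
    "axial_circular_variance",
    "evaluate_decoding",
    "run_decoding_experiment",
    "run_decoding_sweep",
]

#: Decoder box constraints: contrast in [0, 1], orientation in [0, 180] deg,
#: spread in [0, 70] deg.
STIMULUS_BOUNDS = {"theta": (0.0, 180.0), "contrast": (0.0, 1.0), "spread": (0.0, 70.0)}

IMPOSSIBLE_LOG_LIKELIHOOD = -1e300


@dataclass
class DecodeResult:
    """Maximum-likelihood stimulus estimate and decoded gain variability."""

    theta_hat: float
    c_hat: float
    sigma_s_hat: float
    sigma_g_hat: float
    log_likelihood: float
    n_starts: int


class _PopulationLikelihood:
    """Vectorized population log-likelihood over (theta, contrast, spread).

    Precomputes the component-offset grid and population parameters so a
    single evaluation is one small matrix product plus the NB terms.
    """

    def __init__(self, counts, model: NormalizationModel, dt_ms: float):
        self.counts = np.asarray(counts, dtype=float)
        bank = model.bank
        if self.counts.shape != (bank.n_units,):
            raise ValueError("counts must have one entry per population unit")
        self.prefs = bank.preferred_deg
        self.eta = np.broadcast_to(np.asarray(bank.eta, dtype=float), self.prefs.shape)
        self.ups = np.broadcast_to(np.asarray(bank.upsilon, dtype=float), self.prefs.shape)
        self.pool_prefs = bank.pool_preferred_deg
        self.pool_gain = bank.pool_gain
        self.beta = bank.beta
        self.p = bank.p
        self.sigma_N = model.sigma_N
        self.dt_s = dt_ms / 1000.0
        self.offsets = OrientationStimulus(0.0, 0.0, 1.0).component_offsets
        self.gammaln_k1 = special.gammaln(self.counts + 1.0)

    def _profile(self, theta, c, spread):
        prof = np.exp(-(self.offsets**2) / (2.0 * max(spread, 1e-12) ** 2))
        if spread == 0:
            prof = (self.offsets == 0).astype(float)
        total = prof.sum()
        u = c * prof / total
        angles = theta + self.offsets
        return angles, u

    def rates_and_sigma(self, theta, c, spread):
        angles, u = self._profile(theta, c, spread)
        d = np.deg2rad((self.prefs[:, None] - angles[None, :] + 90.0) % 180.0 - 90.0)
        cc = np.cos(d)
        w = cc**3 * np.exp(4.5 * (cc**2 - 1.0))  # peak-normalized weights
        T = w @ u
        # pool units are the bank's own filters (default) or a dedicated set
        if self.pool_prefs is self.prefs:
            P = self.pool_gain * float(np.mean(T**2))
        else:
            dp = np.deg2rad((self.pool_prefs[:, None] - angles[None, :] + 90.0) % 180.0 - 90.0)
            cp = np.cos(dp)
            wp = cp**3 * np.exp(4.5 * (cp**2 - 1.0))
            P = self.pool_gain * float(np.mean((wp @ u) ** 2))
        denom = self.beta + P
        rates = ((self.eta + self.ups * T) / denom) ** self.p
        sigma_g = self.sigma_N * self.p / denom
        return rates, sigma_g

    def log_likelihood(self, theta, c, spread):
        rates, sigma_g = self.rates_and_sigma(theta, c, spread)
        lam = rates * self.dt_s
        k = self.counts
        if np.any((lam == 0) & (k > 0)):
            return IMPOSSIBLE_LOG_LIKELIHOOD
        if sigma_g < SIGMA_G_FLOOR:
            ll = special.xlogy(k, lam) - lam - self.gammaln_k1
        else:
            r = 1.0 / sigma_g**2
            s2lam = sigma_g**2 * lam
            ll = (
                special.gammaln(k + r)
                - self.gammaln_k1
                - special.gammaln(r)
                + special.xlogy(k, s2lam)
                - (k + r) * np.log1p(s2lam)
            )
        return float(np.sum(ll))

    def nll(self, x):
        return -self.log_likelihood(x[0], x[1], x[2])


def population_log_likelihood(counts, stimulus: OrientationStimulus, model, dt_ms=1000.0):
    """Log-likelihood of a pattern of spike counts given a stimulus.

    Sum over neurons of the negative-binomial log-pmf with rates and shared
    gain variability from the normalization model. A zero-rate neuron with a
    positive count makes the stimulus impossible (a large negative sentinel
    is returned rather than -inf, so optimizers remain well behaved).
    """
    like = _PopulationLikelihood(counts, model, dt_ms)
    return like.log_likelihood(stimulus.theta_deg, stimulus.contrast, stimulus.spread_deg)


def _moment_theta_init(counts, prefs_deg):
    """Population-vector orientation guess on the doubled-angle circle."""
    z = np.sum(counts * np.exp(2j * np.deg2rad(prefs_deg)))
    if np.abs(z) == 0:
        return 90.0
    return float(np.rad2deg(np.angle(z)) / 2.0 % 180.0)


def ml_decode(
    counts,
    model: NormalizationModel,
    dt_ms: float = 1000.0,
    n_starts: int = 8,
    seed=None,
    rng=None,
) -> DecodeResult:
    """Multi-start bound-constrained ML decode of (theta, contrast, spread).

    Starts are stratified over orientation (plus one moment-based
    population-vector start); each start runs L-BFGS-B within the stimulus
    bounds, with the orientation box centered on the start (the likelihood is
    180-degree periodic, so the union of starts covers the circle). The
    returned log-likelihood is the best over starts and never below the
    likelihood at any start's initialization.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if rng is None:
        rng = _rng_from(seed)
    like = _PopulationLikelihood(counts, model, dt_ms)
    c_lo, c_hi = 1e-4, STIMULUS_BOUNDS["contrast"][1]
    s_lo, s_hi = STIMULUS_BOUNDS["spread"]

    theta0s = [_moment_theta_init(like.counts, like.prefs)]
    offset = rng.uniform(0.0, 180.0)
    theta0s += list((offset + np.arange(n_starts) * 180.0 / n_starts) % 180.0)

    best = None
    n_fail = 0
    for i, th0 in enumerate(theta0s):
        if i == 0:
            c0, sp0 = 0.2, 10.0
        else:
            c0 = float(np.exp(rng.uniform(np.log(0.02), np.log(0.8))))
            sp0 = float(rng.uniform(1.0, 55.0))
        x0 = np.array([th0, c0, sp0])
        ll0 = -like.nll(x0)
        if best is None or ll0 > best[0]:
            best = (ll0, x0)
        try:
            res = optimize.minimize(
                like.nll,
                x0,
                method="L-BFGS-B",
                bounds=[(th0 - 90.0, th0 + 90.0), (c_lo, c_hi), (s_lo, s_hi)],
                options={"maxiter": 200, "ftol": 1e-12},
            )
        except Exception:  # pragma: no cover - optimizer failure path
            n_fail += 1
            continue
        if -res.fun > best[0]:
            best = (-res.fun, res.x)
    if best is None or best[0] <= IMPOSSIBLE_LOG_LIKELIHOOD:
        raise RuntimeError(f"decoder failed on all {len(theta0s)} starts ({n_fail} raised)")
    ll, x = best
    _, sigma_g_hat = like.rates_and_sigma(x[0] % 180.0, x[1], x[2])
    return DecodeResult(
        theta_hat=float(x[0] % 180.0),
        c_hat=float(x[1]),
        sigma_s_hat=float(x[2]),
        sigma_g_hat=float(sigma_g_hat),
        log_likelihood=float(ll),
        n_starts=len(theta0s),
    )


def decoded_gain_variability(result: DecodeResult, model: NormalizationModel) -> float:
    """Uncertainty receptive field evaluated at the decoded stimulus."""
    stim = OrientationStimulus(result.theta_hat, result.c_hat, result.sigma_s_hat)
    return float(model.gain_variability(stim))


# ---------------------------------------------------------------------------
# Heuristic columnar estimator
# ---------------------------------------------------------------------------

@dataclass
class HeuristicGainVariability:
    """Cross-neuron gain-variability estimate from columnar sub-populations.

    ``sigma_g_sq_raw`` may be negative through sampling noise; ``sigma_g`` is
    computed from the value clamped at zero (``clamped`` flags this)."""

    sigma_g: float
    sigma_g_sq_raw: float
    clamped: bool
    column_means: np.ndarray
    column_variances: np.ndarray


def heuristic_sigma_g(counts, column_labels) -> HeuristicGainVariability:
    """Pooled within-column estimator of gain variability.

    Within each column of identically tuned neurons, the sample mean
    estimates lambda_i and the unbiased sample variance estimates
    lambda_i + sigma_G^2 lambda_i^2; pooling across columns gives

        sigma_G^2 ~= sum_i (var_i - mean_i) / sum_i mean_i**2.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(column_labels)
    if counts.shape != labels.shape:
        raise ValueError("counts and column_labels must have the same shape")
    means, variances = [], []
    for lab in np.unique(labels):
        c = counts[labels == lab]
        if len(c) < 2:
            raise ValueError(f"column {lab!r} has fewer than 2 neurons")
        means.append(c.mean())
        variances.append(c.var(ddof=1))
    means = np.array(means)
    variances = np.array(variances)
    denom = np.sum(means**2)
    if denom == 0:
        raise ValueError("all column means are zero; heuristic undefined")
    raw = float(np.sum(variances - means) / denom)
    clamped = raw < 0
    return HeuristicGainVariability(
        sigma_g=float(np.sqrt(max(raw, 0.0))),
        sigma_g_sq_raw=raw,
        clamped=clamped,
        column_means=means,
        column_variances=variances,
    )


# ---------------------------------------------------------------------------
# Decoding-quality evaluation
# ---------------------------------------------------------------------------

def circular_error_deg(theta_hat_deg, theta_true_deg):
    """Signed orientation error on the 180-degree (axial) domain."""
    return (np.asarray(theta_hat_deg, dtype=float) - theta_true_deg + 90.0) % 180.0 - 90.0


def axial_circular_variance(errors_deg):
    """Circular variance of axial errors, computed on doubled angles.

    0 for perfectly concentrated errors, 1 for errors uniform on the
    180-degree domain.
    """
    ang = 2.0 * np.deg2rad(np.asarray(errors_deg, dtype=float))
    if ang.size == 0:
        return np.nan
    return float(1.0 - np.abs(np.mean(np.exp(1j * ang))))


def evaluate_decoding(sigma_g_hats, errors_deg, n_bins: int = 10) -> dict:
    """Binned association between decoded gain variability and error spread.

    Trials are sorted into ``sigma_g_hat`` percentile bins (deciles by
    default); within each bin the circular variance of the orientation error
    is computed and the Spearman rank correlation between bin-mean
    ``sigma_g_hat`` and bin error variance is reported. With constant inputs
    the correlation is undefined and returned as NaN.
    """
    sigma_g_hats = np.asarray(sigma_g_hats, dtype=float)
    errors_deg = np.asarray(errors_deg, dtype=float)
    n = len(sigma_g_hats)
    if n < 10:
        raise ValueError("need at least 10 trials")
    if n < n_bins:
        warnings.warn(f"fewer trials ({n}) than bins ({n_bins}); reducing bin count")
        n_bins = n
    order = np.argsort(sigma_g_hats, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_sigma = np.array([sigma_g_hats[b].mean() for b in bins])
    bin_var = np.array([axial_circular_variance(errors_deg[b]) for b in bins])
    if np.all(bin_var == bin_var[0]) or np.all(bin_sigma == bin_sigma[0]):
        r = np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = float(stats.spearmanr(bin_sigma, bin_var).statistic)
    return {
        "spearman_r": r,
        "bin_mean_sigma_g_hat": bin_sigma,
        "bin_error_circular_variance": bin_var,
        "n_trials": n,
        "n_bins": n_bins,
    }


# ---------------------------------------------------------------------------
# Full simulate -> decode -> evaluate experiment
# ---------------------------------------------------------------------------

def default_stimulus_grid(
    n_contrasts: int = 10,
    n_spreads: int = 10,
    n_orientations: int = 10,
    contrast_range=(0.05, 0.5),
    spread_range=(1.0, 55.0),
):
    """The decoding stimulus set: ``n_contrasts * n_spreads`` unique
    contrast-spread stimuli crossed with ``n_orientations`` orientations."""
    contrasts = np.linspace(*contrast_range, n_contrasts)
    spreads = np.linspace(*spread_range, n_spreads)
    thetas = (np.arange(n_orientations) + 0.5) * 180.0 / n_orientations
    grid = [
        (th, c, sp)
        for c in contrasts
        for sp in spreads
        for th in thetas
    ]
    return grid


def run_decoding_experiment(
    seed: int,
    n_neurons: int = 250,
    dt_ms: float = 1000.0,
    gamma_mix: float = 0.0,
    n_repeats: int = 1,
    n_starts: int = 8,
    stimulus_grid=None,
    sigma_N: float = 0.35,
    n_bins: int = 10,
    return_trials: bool = False,
) -> dict:
    """Simulate, decode and evaluate the full population experiment.

    Per repeat, a fresh heterogeneous population of ``n_neurons`` units is
    drawn (eta ~ N(2, 0.2^2) ips, upsilon ~ N(50, 7^2) ips, uniform preferred
    orientations; sigma_N = 0.35, p = 2, beta = 0.64); each stimulus of the
    grid (default 100 contrast-spread combinations at 10 orientations, 1000
    trials) is simulated with gain-mixing coefficient ``gamma_mix``, ML
    decoded, and its gain variability read off the uncertainty receptive
    field at the decoded stimulus. Trials are binned into deciles of decoded
    gain variability and the Spearman correlation between bin error variance
    and bin-mean decoded gain variability is averaged across repeats.
    """
    if stimulus_grid is None:
        stimulus_grid = default_stimulus_grid()
    seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    per_repeat = []
    trials_out = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(seeds[rep])
        bank = make_population(n_neurons=n_neurons, seed=rng)
        model = NormalizationModel(bank=bank, sigma_N=sigma_N)
        sg_hats = np.empty(len(stimulus_grid))
        errors = np.empty(len(stimulus_grid))
        for t, (th, c, sp) in enumerate(stimulus_grid):
            stim = OrientationStimulus(th, c, sp)
            trial = generate_population_trial(
                stim, model, dt_ms=dt_ms, gamma_mix=gamma_mix, seed=rng
            )
            dec = ml_decode(trial.counts, model, dt_ms=dt_ms, n_starts=n_starts, rng=rng)
            sg_hats[t] = dec.sigma_g_hat
            errors[t] = circular_error_deg(dec.theta_hat, th)
            if return_trials:
                trials_out.append(
                    {
                        "repeat": rep,
                        "theta": th,
                        "contrast": c,
                        "spread": sp,
                        "sigma_g_true": trial.sigma_g,
                        "theta_hat": dec.theta_hat,
                        "c_hat": dec.c_hat,
                        "spread_hat": dec.sigma_s_hat,
                        "sigma_g_hat": dec.sigma_g_hat,
                        "error_deg": errors[t],
                    }
                )
        per_repeat.append(evaluate_decoding(sg_hats, errors, n_bins=n_bins))
    rs = np.array([e["spearman_r"] for e in per_repeat])
    out = {
        "spearman_r": float(np.nanmean(rs)),
        "spearman_r_per_repeat": rs,
        "per_repeat": per_repeat,
        "n_trials": len(stimulus_grid),
        "n_repeats": n_repeats,
        "dt_ms": dt_ms,
        "gamma_mix": gamma_mix,
    }
    if return_trials:
        out["trials"] = trials_out
    return out


def run_decoding_sweep(
    seed: int,
    dt_ladder=(125.0, 250.0, 500.0, 1000.0),
    gamma_values=(0.0, 0.33, 0.67),
    **experiment_kwargs,
) -> dict:
    """Association-vs-readout-time table over (dt, gamma) cells.

    Runs :func:`run_decoding_experiment` for every combination of read-out
    window and shared-gain fraction, with independent sub-seeds per cell.
    Returns ``{"cells": [{"dt_ms", "gamma", "spearman_r"}, ...]}`` plus the
    full per-cell results.
    """
    cells = []
    results = []
    seeds = np.random.SeedSequence(seed).generate_state(len(dt_ladder) * len(gamma_values))
    i = 0
    for gamma in gamma_values:
        for dt in dt_ladder:
            res = run_decoding_experiment(
                seed=int(seeds[i] % (2**31)), dt_ms=dt, gamma_mix=gamma, **experiment_kwargs
            )
            cells.append({"dt_ms": dt, "gamma": gamma, "spearman_r": res["spearman_r"]})
            results.append(res)
            i += 1
    return {"cells": cells, "results": results}
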