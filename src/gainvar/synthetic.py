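"""Seeded generators for every input of the pipeline, with ground truth.

Gamma-distributed multiplicative gains (slow or fast dynamics, optionally
correlated across neurons), gamma-Poisson spike-count tables over nested
counting windows, parametric tuning curves with attached reference Fisher
information, and full population trials driven by the stochastic
normalization model.

Counts are always generated once at the finest window and summed into the
larger windows, so the "same set of spikes" is counted at every window size
and nested window sums are exactly consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalization import FilterBank, NormalizationModel, OrientationStimulus

__all__ = [
    "GeneratorConfig",
    "PopulationTrial",
    "TuningCurve",
    "sample_gains",
    "generate_spike_table",
    "make_population",
    "make_columnar_population",
    "generate_population_trial",
    "generate_tuning_curve",
]


def _rng_from(seed):
    """Accept an int seed, a SeedSequence, or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_gains(
    sigma_g: float,
    regime: str = "slow",
    n_trials: int = 1,
    n_intervals_per_trial: int = 1,
    gamma_mix: float = 0.0,
    n_neurons: int = 1,
    seed=None,
    preserve_variance: bool = False,
):
    """Unit-mean gamma gains of shape (n_neurons, n_trials, n_intervals).

    Gamma parameterization: shape ``1/sigma_g**2``, scale ``sigma_g**2`` (mean
    1, variance ``sigma_g**2``); ``sigma_g = 0`` is the degenerate point mass
    at 1. Slow dynamics draw one gain per (neuron, trial) and repeat it across
    intervals; fast dynamics draw one gain per (neuron, trial, interval).

    ``gamma_mix`` mixes a shared and a private gain per the printed rule
    ``G = gamma*G_s + (1-gamma)*G_p`` (both unit mean, variance sigma_g**2;
    the mixture variance is ``(gamma**2 + (1-gamma)**2) * sigma_g**2``).
    ``preserve_variance=True`` instead rescales the zero-mean fluctuations by
    ``1/sqrt(gamma**2 + (1-gamma)**2)`` so the mixture keeps variance
    ``sigma_g**2`` exactly (values are clipped at 0 to remain valid gains).
    """
    if sigma_g < 0:
        raise ValueError("sigma_g must be non-negative")
    if regime not in ("slow", "fast"):
        raise ValueError("regime must be 'slow' or 'fast'")
    if not 0.0 <= gamma_mix <= 1.0:
        raise ValueError("gamma_mix must lie in [0, 1]")
    rng = _rng_from(seed)
    n_int = n_intervals_per_trial if regime == "fast" else 1
    shape_out = (n_neurons, n_trials, n_int)
    if sigma_g == 0:
        g = np.ones(shape_out)
    else:
        a = 1.0 / sigma_g**2
        scale = sigma_g**2
        g_shared = rng.gamma(a, scale, size=(1, n_trials, n_int))
        g_private = rng.gamma(a, scale, size=shape_out)
        if gamma_mix == 0.0:
            g = g_private
        elif gamma_mix == 1.0:
            g = np.broadcast_to(g_shared, shape_out).copy()
        else:
            g = gamma_mix * g_shared + (1.0 - gamma_mix) * g_private
            if preserve_variance:
                norm = np.sqrt(gamma_mix**2 + (1.0 - gamma_mix) ** 2)
                g = np.clip(1.0 + (g - 1.0) / norm, 0.0, None)
    if regime == "slow" and n_intervals_per_trial > 1:
        g = np.broadcast_to(g, (n_neurons, n_trials, n_intervals_per_trial)).copy()
    return g


@dataclass
class GeneratorConfig:
    """Design of a synthetic spike-count table for one neuron and family.

    ``mean_counts_finest`` gives the per-condition mean count at the smallest
    window; window sizes must tile the largest window.
    """

    seed: object
    mean_counts_finest: np.ndarray = field(default_factory=lambda: np.full(16, 3.125))
    sigma_g: float = 0.25
    regime: str = "slow"
    n_trials: int = 100
    windows_ms: tuple = (62.5, 125.0, 250.0, 500.0, 1000.0)
    gamma_mix: float = 0.0
    neuron_id: str = "sim0"
    family_id: str = "fam0"

    def __post_init__(self):
        self.mean_counts_finest = np.asarray(self.mean_counts_finest, dtype=float)
        w = np.sort(np.asarray(self.windows_ms, dtype=float))
        if np.any(w <= 0):
            raise ValueError("window sizes must be positive")
        longest, finest = w[-1], w[0]
        for wi in w:
            if not np.isclose((longest / wi) % 1.0, 0.0) and not np.isclose(
                (longest / wi) % 1.0, 1.0
            ):
                raise ValueError(f"window {wi} ms does not tile the longest window {longest} ms")
            if not np.isclose((wi / finest) % 1.0, 0.0) and not np.isclose(
                (wi / finest) % 1.0, 1.0
            ):
                raise ValueError(f"window {wi} ms is not a multiple of the finest window")
        self.windows_ms = tuple(w)


def generate_spike_table(config: GeneratorConfig) -> pd.DataFrame:
    """Gamma-Poisson spike-count table over nested counting windows.

    Counts are Poisson at rate ``mean * gain`` per finest window; larger
    windows are contiguous sums of the finest counts, tiling each trial's
    longest window from response onset. The returned frame carries a
    ``ground_truth`` entry in ``DataFrame.attrs`` (gains, means, parameters).
    """
    rng = _rng_from(config.seed)
    windows = config.windows_ms
    finest, longest = windows[0], windows[-1]
    n_fine = int(round(longest / finest))
    means = config.mean_counts_finest
    n_cond = means.size

    gains = sample_gains(
        config.sigma_g,
        regime=config.regime,
        n_trials=n_cond * config.n_trials,
        n_intervals_per_trial=n_fine,
        gamma_mix=config.gamma_mix,
        n_neurons=1,
        seed=rng,
    )[0].reshape(n_cond, config.n_trials, n_fine)
    lam_fine = means[:, None, None] * gains
    counts_fine = rng.poisson(lam_fine)

    rows = []
    for w in windows:
        step = int(round(w / finest))
        n_seg = n_fine // step
        # (cond, trial, segment) counts for this window
        cw = counts_fine[:, :, : n_seg * step].reshape(n_cond, config.n_trials, n_seg, step).sum(axis=3)
        cond_idx, trial_idx, seg_idx = np.meshgrid(
            np.arange(n_cond), np.arange(config.n_trials), np.arange(n_seg), indexing="ij"
        )
        rows.append(
            pd.DataFrame(
                {
                    "neuron_id": config.neuron_id,
                    "family_id": config.family_id,
                    "condition_id": cond_idx.ravel(),
                    "trial": trial_idx.ravel(),
                    "window_ms": float(w),
                    "segment": seg_idx.ravel(),
                    "count": cw.ravel(),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table.attrs["ground_truth"] = {
        "sigma_g": config.sigma_g,
        "regime": config.regime,
        "gamma_mix": config.gamma_mix,
        "mean_counts_finest": means.copy(),
        "gains": gains,
        "counts_finest": counts_fine,
        "windows_ms": windows,
    }
    return table


# ---------------------------------------------------------------------------
# Populations and population trials
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, size):
    """Normal draws truncated at zero (redraw negatives)."""
    x = rng.normal(mean, sd, size=size)
    while np.any(x <= 0):
        bad = x <= 0
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return x


def make_population(
    n_neurons: int = 250,
    seed=None,
    eta_mean: float = 2.0,
    eta_sd: float = 0.2,
    upsilon_mean: float = 50.0,
    upsilon_sd: float = 7.0,
    **bank_kwargs,
) -> FilterBank:
    """Heterogeneous population: uniform preferred orientations on [0, 180),
    spontaneous discharge and dynamic range drawn from Gaussians truncated at
    zero (eta ~ N(2, 0.2^2) ips, upsilon ~ N(50, 7^2) ips by default)."""
    rng = _rng_from(seed)
    prefs = rng.uniform(0.0, 180.0, size=n_neurons)
    eta = _truncated_normal(rng, eta_mean, eta_sd, n_neurons)
    ups = _truncated_normal(rng, upsilon_mean, upsilon_sd, n_neurons)
    return FilterBank(preferred_deg=prefs, eta=eta, upsilon=ups, **bank_kwargs)


def make_columnar_population(
    n_columns: int = 5,
    neurons_per_column: int = 50,
    seed=None,
    eta_mean: float = 2.0,
    eta_sd: float = 0.2,
    upsilon_mean: float = 50.0,
    upsilon_sd: float = 7.0,
    **bank_kwargs,
) -> tuple[FilterBank, np.ndarray]:
    """Columnar population: ``n_columns`` sub-populations of identically tuned
    neurons (shared preference, eta and upsilon within a column). Returns the
    bank and the per-neuron column label array."""
    rng = _rng_from(seed)
    col_prefs = (np.arange(n_columns) + rng.uniform()) * 180.0 / n_columns
    eta_c = _truncated_normal(rng, eta_mean, eta_sd, n_columns)
    ups_c = _truncated_normal(rng, upsilon_mean, upsilon_sd, n_columns)
    labels = np.repeat(np.arange(n_columns), neurons_per_column)
    bank = FilterBank(
        preferred_deg=col_prefs[labels],
        eta=eta_c[labels],
        upsilon=ups_c[labels],
        **bank_kwargs,
    )
    return bank, labels


@dataclass
class PopulationTrial:
    """One simulated population response with full ground truth."""

    counts: np.ndarray
    dt_ms: float
    stimulus: OrientationStimulus
    rates: np.ndarray
    sigma_g: float
    gains: np.ndarray
    gamma_mix: float
    column_labels: np.ndarray | None = None


def generate_population_trial(
    stimulus: OrientationStimulus,
    model: NormalizationModel,
    dt_ms: float = 1000.0,
    gamma_mix: float = 0.0,
    seed=None,
    column_labels=None,
    preserve_variance: bool = False,
) -> PopulationTrial:
    """Simulate one trial of the normalization-model population.

    Rates and the shared gain variability come from the stochastic
    normalization model; each neuron's count is Poisson with mean
    ``f_i * G_i * dt``, with gains drawn once per trial (slow dynamics).
    """
    rng = _rng_from(seed)
    rates, sigma_g = model.evaluate(stimulus)
    gains = sample_gains(
        sigma_g,
        regime="slow",
        n_trials=1,
        gamma_mix=gamma_mix,
        n_neurons=rates.size,
        seed=rng,
        preserve_variance=preserve_variance,
    )[:, 0, 0]
    lam = rates * gains * (dt_ms / 1000.0)
    counts = rng.poisson(lam)
    return PopulationTrial(
        counts=counts,
        dt_ms=dt_ms,
        stimulus=stimulus,
        rates=rates,
        sigma_g=float(sigma_g),
        gains=gains,
        gamma_mix=gamma_mix,
        column_labels=None if column_labels is None else np.asarray(column_labels),
    )


# ---------------------------------------------------------------------------
# Tuning-curve fixtures
# ---------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Mean rate on an equispaced periodic orientation grid."""

    angles_deg: np.ndarray
    mean_rates: np.ndarray
    n_trials: np.ndarray | None = None
    period_deg: float = 360.0
    reference_fisher_information: float | None = None

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        if self.angles_deg.shape != self.mean_rates.shape:
            raise ValueError("angles and rates must have matching shapes")
        d = np.diff(self.angles_deg)
        if len(d) and not np.allclose(d, d[0]):
            raise ValueError("tuning-curve grid must be equispaced")
        if np.any(self.mean_rates < 0):
            raise ValueError("mean rates must be non-negative")


def generate_tuning_curve(
    kind: str = "sinusoid",
    n_points: int = 16,
    period_deg: float = 360.0,
    baseline: float = 10.0,
    amplitude: float = 5.0,
    theta_pref_deg: float = 0.0,
    noise_sd: float = 0.0,
    seed=None,
    reference_grid: int = 4096,
) -> TuningCurve:
    """Parametric tuning-curve fixture with a dense-grid reference value.

    ``kind``: "flat" (constant rate, zero information), "sinusoid"
    (baseline + amplitude*cos), or "von_mises" (baseline + amplitude *
    exp(kappa*(cos - 1)), a smooth periodic orientation-tuning bump with
    concentration kappa = 4.5). The attached reference Fisher information is
    computed by uniform quadrature of ``h'^2/h`` with the analytic derivative
    on ``reference_grid`` points (trapezoid on the periodic domain), in
    information per radian^2.
    """
    rng = _rng_from(seed)
    angles = np.arange(n_points) * period_deg / n_points
    period_rad = np.deg2rad(period_deg)

    def h_and_dh(a_deg):
        a = np.deg2rad(np.asarray(a_deg, dtype=float) - theta_pref_deg)
        w = 2.0 * np.pi / period_rad  # angular frequency of one full cycle
        if kind == "flat":
            return baseline * np.ones_like(a), np.zeros_like(a)
        if kind == "sinusoid":
            return baseline + amplitude * np.cos(w * a), -amplitude * w * np.sin(w * a)
        if kind == "von_mises":
            kappa = 4.5
            wgt = np.exp(kappa * (np.cos(w * a) - 1.0))
            dwgt = -kappa * w * np.sin(w * a) * wgt
            return baseline + amplitude * wgt, amplitude * dwgt
        raise ValueError(f"unknown tuning-curve kind {kind!r}")

    dense = np.arange(reference_grid) * period_deg / reference_grid
    h, dh = h_and_dh(dense)
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.where(h > 0, dh**2 / h, 0.0)
    ref_info = float(np.mean(integrand))

    rates, _ = h_and_dh(angles)
    if noise_sd > 0:
        rates = np.clip(rates + rng.normal(0.0, noise_sd, size=n_points), 0.0, None)
    return TuningCurve(
        angles_deg=angles,
        mean_rates=rates,
        period_deg=period_deg,
        reference_fisher_information=ref_info,
    )
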