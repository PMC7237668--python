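"""Stimulus-uncertainty metrics and gain-variability selectivity.

Orientation uncertainty is quantified as the inverse Fisher information of a
measured tuning curve under a Poisson spiking assumption,

    1 / I_theta = E_theta[ h'(theta)**2 / h(theta) ]**-1,

which depends only on mean responses and is therefore independent of the
level of gain fluctuations. Selectivity of gain variability for an
uncertainty-inducing stimulus manipulation is the common logarithm of the
ratio of two sigma_G estimates, with a simulation-based null test built from
datasets regenerated at the pooled sigma_G estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modulated_poisson import _fit_sigma_from_counts
from .synthetic import TuningCurve

__all__ = [
    "TuningCurve",
    "FisherInfoResult",
    "SelectivityIndex",
    "fisher_information",
    "selectivity_index",
    "selectivity_null_test",
    "uncertainty_gainvar_association",
]

SIGMA_RATIO_FLOOR = 1e-4


@dataclass
class FisherInfoResult:
    """Fisher information (per radian^2) and its inverse, the orientation
    uncertainty; a flat tuning curve carries zero information and infinite
    uncertainty (represented as ``np.inf``)."""

    fisher_information: float
    orientation_uncertainty: float


def _circular_derivative(h, spacing_rad, method="spectral"):
    n = len(h)
    if method == "central":
        return (np.roll(h, -1) - np.roll(h, 1)) / (2.0 * spacing_rad)
    if method == "spectral":
        # trigonometric differentiation on the periodic grid; exact for
        # band-limited curves, no smoothing applied
        period = n * spacing_rad
        omega = 2.0 * np.pi * np.fft.fftfreq(n, d=spacing_rad)
        hk = np.fft.fft(h)
        if n % 2 == 0:
            hk[n // 2] = 0.0  # drop the Nyquist mode for a real derivative
        return np.real(np.fft.ifft(1j * omega * hk))
    raise ValueError(f"unknown derivative method {method!r}")


def fisher_information(curve: TuningCurve, derivative: str = "spectral") -> FisherInfoResult:
    """Poisson-assumption Fisher information of a measured tuning curve.

    The derivative is estimated on the periodic grid (angles converted to
    radians; trigonometric differentiation by default, circular central
    differences via ``derivative="central"``) and the expectation is the
    uniform average over grid points. Zero-rate grid points contribute zero
    when the local derivative is also zero; a zero rate with a nonzero
    derivative makes the information undefined and raises an error.
    """
    h = np.asarray(curve.mean_rates, dtype=float)
    if len(h) < 4:
        raise ValueError("need at least 4 grid points")
    if not np.any(h > 0):
        raise ValueError("tuning curve must have at least one positive rate")
    spacing_rad = np.deg2rad(curve.period_deg) / len(h)
    dh = _circular_derivative(h, spacing_rad, method=derivative)
    zero = h == 0
    tol = 1e-9 * max(np.max(np.abs(dh)), 1.0)
    if np.any(zero & (np.abs(dh) > tol)):
        raise ValueError("zero mean rate with nonzero tuning slope: information undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.where(zero, 0.0, dh**2 / np.where(zero, 1.0, h))
    info = float(np.mean(integrand))
    unc = np.inf if info == 0 else 1.0 / info
    return FisherInfoResult(fisher_information=info, orientation_uncertainty=unc)


@dataclass
class SelectivityIndex:
    """log10 ratio of gain-variability estimates (manipulation / baseline).

    1.0 means the manipulation increased gain variability tenfold, 0 no
    change; negative values are decreases. ``significant`` is "untested"
    unless a null test has been run.
    """

    value: float
    sigma_num: float
    sigma_den: float
    significant: str = "untested"
    floored: bool = False
    null_median: float | None = None
    null_interval: tuple | None = None


def selectivity_index(sigma_manip: float, sigma_base: float) -> SelectivityIndex:
    """Common logarithm of the ratio of two sigma_G estimates.

    Zero estimates are floored at 1e-4 (the fitting floor) with a flag, so
    the index stays finite.
    """
    if sigma_manip < 0 or sigma_base < 0:
        raise ValueError("sigma_G estimates must be non-negative")
    floored = sigma_manip < SIGMA_RATIO_FLOOR or sigma_base < SIGMA_RATIO_FLOOR
    num = max(sigma_manip, SIGMA_RATIO_FLOOR)
    den = max(sigma_base, SIGMA_RATIO_FLOOR)
    return SelectivityIndex(
        value=float(np.log10(num / den)),
        sigma_num=sigma_manip,
        sigma_den=sigma_base,
        floored=floored,
    )


def _fit_sigma_counts(counts_by_cond):
    """Profile sigma_G fit from a list of per-condition count arrays.

    Same estimator as :func:`~gainvar.modulated_poisson.fit_gain_variability`
    (per-condition sample means, shared sigma_G profile likelihood), skipping
    the table plumbing; used for the many refits of the null simulation.
    """
    sigma, _ = _fit_sigma_from_counts(counts_by_cond)
    return sigma


def selectivity_null_test(
    table: pd.DataFrame,
    conditions_manip,
    conditions_base,
    n_sim: int = 100,
    seed: int = 0,
    window_ms: float = 1000.0,
    alpha: float = 0.05,
) -> SelectivityIndex:
    """Selectivity index with a simulation-based two-sided significance test.

    Gain variability is first estimated from the pooled set of conditions;
    ``n_sim`` synthetic datasets are then simulated from the pooled sigma_G
    and the empirical per-condition means, each refit separately for the
    manipulation and baseline condition sets. The null selectivity
    distribution is formed from all ``n_sim**2`` ordered pairs; because
    sigma_G is positive-valued its estimation bias depends on response
    magnitude, so the null need not be centered at zero (its median is
    reported). The observed index is significant if it falls outside the
    central ``1 - alpha`` interval (empirical percentiles, linear
    interpolation).
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2 for a meaningful null distribution")
    rng = np.random.default_rng(seed)
    sub = table[np.isclose(table["window_ms"].to_numpy(dtype=float), window_ms)]

    def cond_counts(cond_ids):
        out = []
        for c in cond_ids:
            counts = sub.loc[sub["condition_id"] == c, "count"].to_numpy(dtype=int)
            if len(counts) == 0:
                raise ValueError(f"condition {c!r} has no trials")
            out.append(counts)
        return out

    counts_a = cond_counts(conditions_manip)
    counts_b = cond_counts(conditions_base)

    sigma_a = _fit_sigma_counts(counts_a)
    sigma_b = _fit_sigma_counts(counts_b)
    observed = selectivity_index(sigma_a, sigma_b)

    sigma0 = _fit_sigma_counts(counts_a + counts_b)
    means_a = [c.mean() for c in counts_a]
    means_b = [c.mean() for c in counts_b]

    def simulate_and_fit(means, sizes):
        sims = []
        for _ in range(n_sim):
            counts = []
            for m, n in zip(means, sizes):
                if sigma0 > 0:
                    gains = rng.gamma(1.0 / sigma0**2, sigma0**2, size=n)
                else:
                    gains = np.ones(n)
                counts.append(rng.poisson(m * gains))
            sims.append(_fit_sigma_counts(counts))
        return np.array(sims)

    sims_a = simulate_and_fit(means_a, [len(c) for c in counts_a])
    sims_b = simulate_and_fit(means_b, [len(c) for c in counts_b])
    num = np.maximum(sims_a, SIGMA_RATIO_FLOOR)
    den = np.maximum(sims_b, SIGMA_RATIO_FLOOR)
    null = np.log10(num[:, None] / den[None, :]).ravel()
    lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    observed.null_median = float(np.median(null))
    observed.null_interval = (float(lo), float(hi))
    observed.significant = "yes" if (observed.value < lo or observed.value > hi) else "no"
    return observed


def uncertainty_gainvar_association(pairs: pd.DataFrame, min_families: int = 3) -> dict:
    """Per-neuron association between orientation uncertainty and sigma_G.

    ``pairs`` must have columns ``neuron_id``, ``uncertainty`` and
    ``sigma_g`` with one row per (neuron, stimulus family). Returns the
    per-neuron Pearson correlations, their median, and a Wilcoxon signed-rank
    test of the correlations against zero (the headline population
    statistic). Neurons with a constant vector have no defined correlation
    and are excluded (their number is reported).
    """
    per_neuron = {}
    n_excluded = 0
    for nid, grp in pairs.groupby("neuron_id"):
        x = grp["uncertainty"].to_numpy(dtype=float)
        y = grp["sigma_g"].to_numpy(dtype=float)
        if len(x) < min_families:
            raise ValueError(f"neuron {nid!r} has fewer than {min_families} families")
        if np.all(x == x[0]) or np.all(y == y[0]):
            n_excluded += 1
            continue
        per_neuron[nid] = float(stats.pearsonr(x, y).statistic)
    rs = np.array(list(per_neuron.values()))
    out = {
        "per_neuron_r": per_neuron,
        "n_excluded_constant": n_excluded,
        "median_r": float(np.median(rs)) if len(rs) else np.nan,
    }
    if len(rs) >= 5 and np.any(rs != 0):
        wil = stats.wilcoxon(rs)
        out["wilcoxon_p"] = float(wil.pvalue)
    else:
        out["wilcoxon_p"] = np.nan
    return out
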