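"""Stochastic divisive normalization and the uncertainty receptive field.

A unit's firing rate is its stimulus drive divided by pooled drive plus a
constant, passed through a power nonlinearity:

    f_i(S) = ( g_i(S) / (beta + P(S)) )**p,

where ``P(S)`` is the normalization pool signal. Making the denominator noisy
(additive Gaussian noise epsilon ~ N(0, sigma_N**2)) turns the rate into a
stochastic quantity mu_i whose first-order Taylor moments are

    E[mu_i]   = f_i(S),
    Std[mu_i] = sigma_N * p / (beta + P(S)) * f_i(S),

so the coefficient of variation of the rate -- the gain variability of the
modulated Poisson model -- is

    sigma_G(S) = sigma_N * p / (beta + P(S)).

The noise is stimulus independent, yet normalization makes gain variability
stimulus dependent: strong, concentrated stimuli drive the pool hard and
quench gain fluctuations; weak or dispersed stimuli leave them large. This
mapping from stimulus to gain variance is the uncertainty receptive field.

Conventions
-----------
Orientation-selective filters follow the raised-cosine profile
``cos^3(d) * exp(4.5 * cos^2(d))`` of a third-order Gaussian-derivative
filter; angular differences are reduced to [-90, +90] degrees so weights are
non-negative. Inside the population model, drives use peak-normalized weights
(so ``upsilon`` is the dynamic range between spontaneous and preferred-
stimulus response) and a total-contrast-normalized component profile (the
component contrasts are rescaled to sum to the stimulus contrast), so the
total stimulus energy is set by contrast alone, not by spread. The default
pool is an energy pool over the bank's own raised-cosine units,

    P(S) = pool_gain * mean_j (w_j . u)**2,

which increases with contrast and decreases with stimulus spread, as required
for a pool of narrowly tuned units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_BETA",
    "DEFAULT_P",
    "DEFAULT_SIGMA_N",
    "DEFAULT_POOL_GAIN",
    "OrientationStimulus",
    "FilterBank",
    "NormalizationModel",
    "SigmaNFit",
    "raised_cosine_weight",
    "orientation_tuning_weight",
    "stimulus_drive",
    "pool_drive",
    "mean_rate",
    "gain_variability_from_normalization",
    "sample_noisy_rate",
    "fit_sigma_N",
]

#: Semisaturation constant and transduction exponent of the normalization
#: model, fixed from mean-response fits to V1 data (p = 2.001 approximated
#: by the canonical p = 2).
DEFAULT_BETA = 0.64
DEFAULT_P = 2.0

#: Normalization-noise s.d. fitted to the measured population-average gain
#: variability of high-contrast stimuli.
DEFAULT_SIGMA_N = 0.35

#: Scale of the default energy pool, chosen once so that gain variability
#: spans roughly 0.08-1.05 over the decoding stimulus set (contrast 0.05-0.5,
#: spread 1-55 deg), bracketing the values measured in cortex.
DEFAULT_POOL_GAIN = 200.0

_W_PEAK = float(np.exp(4.5))  # raised-cosine weight at the preferred angle


def _wrap_half(delta_deg):
    """Reduce an orientation difference to [-90, +90) degrees."""
    return (np.asarray(delta_deg, dtype=float) + 90.0) % 180.0 - 90.0


def raised_cosine_weight(theta_deg, theta_pref_deg):
    """Raised-cosine orientation selectivity ``cos^3(d) exp(4.5 cos^2 d)``.

    ``d`` is the orientation difference reduced to [-90, +90] degrees, so the
    weight is non-negative, even-symmetric, and peaks at ``exp(4.5)`` for the
    preferred orientation.
    """
    d = np.deg2rad(_wrap_half(np.asarray(theta_deg, dtype=float) - theta_pref_deg))
    c = np.cos(d)
    return c**3 * np.exp(4.5 * c**2)


def orientation_tuning_weight(theta_deg, theta_pref_deg):
    """Raised-cosine weight normalized to peak 1 at the preferred angle."""
    return raised_cosine_weight(theta_deg, theta_pref_deg) / _W_PEAK


@dataclass
class OrientationStimulus:
    """Gaussian orientation mixture on the 180-degree domain.

    Up to ``n_components`` grating components at ``spacing_deg`` intervals
    around the center orientation ``theta_deg``; component contrasts follow a
    circular-Gaussian profile with peak ``contrast`` and s.d. ``spread_deg``.
    ``energy_profile`` rescales the components to sum to ``contrast`` (fixed
    total stimulus energy); the population model consumes that profile.
    """

    theta_deg: float
    contrast: float
    spread_deg: float
    spacing_deg: float = 20.0
    n_components: int = 9

    def __post_init__(self):
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.spread_deg < 0:
            raise ValueError("spread must be non-negative")
        if self.n_components > 9:
            raise ValueError("at most 9 components")

    @property
    def component_offsets(self) -> np.ndarray:
        half = (self.n_components - 1) // 2
        return self.spacing_deg * np.arange(-half, half + 1)

    @property
    def component_angles(self) -> np.ndarray:
        return (self.theta_deg + self.component_offsets) % 180.0

    @property
    def component_contrasts(self) -> np.ndarray:
        """Raw profile: circular Gaussian with peak equal to ``contrast``."""
        d = self.component_offsets
        denom = 2.0 * max(self.spread_deg, 1e-12) ** 2
        prof = np.exp(-(d**2) / denom)
        if self.spread_deg == 0:
            prof = (d == 0).astype(float)
        return self.contrast * prof

    def energy_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(angles, contrasts) with contrasts rescaled to sum to ``contrast``."""
        raw = self.component_contrasts
        total = raw.sum()
        if total == 0:
            return self.component_angles, np.zeros_like(raw)
        return self.component_angles, self.contrast * raw / total


def stimulus_drive(angles_deg, contrasts, theta_pref_deg, eta, upsilon):
    """Affine stimulus drive ``g = eta + upsilon * sum_k w(theta_k) c_k``.

    Uses peak-normalized weights so ``upsilon`` is the dynamic range: a unit-
    contrast component at the preferred orientation yields ``eta + upsilon``.
    Broadcasts over arrays of preferred orientations / eta / upsilon.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    if np.any(contrasts < 0):
        raise ValueError("stimulus contrasts must be non-negative")
    theta_pref_deg = np.asarray(theta_pref_deg, dtype=float)
    w = orientation_tuning_weight(
        np.asarray(angles_deg, dtype=float)[None, :], theta_pref_deg[..., None]
    )
    dot = w @ contrasts
    return np.asarray(eta, dtype=float) + np.asarray(upsilon, dtype=float) * dot


def pool_drive(angles_deg, contrasts, pool_preferred_deg, pool_gain=DEFAULT_POOL_GAIN):
    """Energy-pool normalization signal over raised-cosine units.

    ``P = pool_gain * mean_j (w_j . c)**2`` with peak-normalized weights and
    uniform pool weights. Quadratic in contrast, decreasing in stimulus spread
    (energy concentrated on few units yields a larger sum of squares than the
    same energy dispersed), and zero for a blank stimulus.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    pool_preferred_deg = np.asarray(pool_preferred_deg, dtype=float)
    w = orientation_tuning_weight(
        np.asarray(angles_deg, dtype=float)[None, :], pool_preferred_deg[:, None]
    )
    e = w @ contrasts
    return float(pool_gain) * float(np.mean(e**2))


def mean_rate(g, pool_drive_value, beta=DEFAULT_BETA, p=DEFAULT_P):
    """Deterministic normalized rate ``(g / (beta + P))**p``."""
    denom = beta + pool_drive_value
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("normalization denominator beta + pool_drive must be positive")
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("stimulus drive must be non-negative")
    return (g / denom) ** p


def gain_variability_from_normalization(
    pool_drive_value, beta=DEFAULT_BETA, p=DEFAULT_P, sigma_N=DEFAULT_SIGMA_N
):
    """Taylor-approximation gain variability ``sigma_N * p / (beta + P)``."""
    denom = beta + pool_drive_value
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("normalization denominator beta + pool_drive must be positive")
    if sigma_N < 0:
        raise ValueError("sigma_N must be non-negative")
    return sigma_N * p / denom


def sample_noisy_rate(
    g,
    pool_drive_value,
    beta=DEFAULT_BETA,
    p=DEFAULT_P,
    sigma_N=DEFAULT_SIGMA_N,
    n_samples=10000,
    seed=None,
    rng=None,
):
    """Monte-Carlo samples of the stochastic rate ``(g / (beta+P+eps))**p``.

    ``eps ~ N(0, sigma_N**2)``. Samples whose denominator falls below a
    positivity floor of ``1e-6 * (beta + P)`` are rejected and redrawn; if the
    expected acceptance rate is below 99% the noise is too large for the
    Taylor regime and an error naming the noise/denominator ratio is raised.
    """
    from scipy import stats as _stats

    denom0 = beta + pool_drive_value
    if denom0 <= 0:
        raise ValueError("normalization denominator beta + pool_drive must be positive")
    if sigma_N == 0:
        return np.full(n_samples, mean_rate(g, pool_drive_value, beta, p))
    floor = 1e-6 * denom0
    p_accept = 1.0 - _stats.norm.cdf((floor - denom0) / sigma_N)
    if p_accept < 0.99:
        raise ValueError(
            f"normalization noise too large: sigma_N/(beta+pool) = {sigma_N / denom0:.3g} "
            f"gives acceptance rate {p_accept:.4f} < 0.99"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.empty(n_samples, dtype=float)
    filled = 0
    while filled < n_samples:
        eps = rng.normal(0.0, sigma_N, size=n_samples - filled)
        d = denom0 + eps
        d = d[d > floor]
        out[filled : filled + len(d)] = (g / d) ** p
        filled += len(d)
    return out


@dataclass
class FilterBank:
    """A population of raised-cosine orientation filters with a shared pool.

    ``eta`` (spontaneous discharge, ips) and ``upsilon`` (dynamic range, ips)
    may be scalars or per-unit arrays. The normalization pool defaults to the
    bank's own units with uniform weights.
    """

    preferred_deg: np.ndarray
    eta: np.ndarray | float = 2.0
    upsilon: np.ndarray | float = 50.0
    beta: float = DEFAULT_BETA
    p: float = DEFAULT_P
    pool_gain: float = DEFAULT_POOL_GAIN
    pool_preferred_deg: np.ndarray | None = None

    def __post_init__(self):
        self.preferred_deg = np.atleast_1d(np.asarray(self.preferred_deg, dtype=float))
        if self.preferred_deg.size == 0:
            raise ValueError("filter bank must contain at least one unit")
        if self.beta <= 0 or self.p <= 0:
            raise ValueError("beta and p must be positive")
        if np.any(np.atleast_1d(self.upsilon) <= 0):
            raise ValueError("dynamic range upsilon must be positive")
        if self.pool_preferred_deg is None:
            self.pool_preferred_deg = self.preferred_deg
        self.pool_preferred_deg = np.asarray(self.pool_preferred_deg, dtype=float)
        if self.pool_preferred_deg.size == 0:
            raise ValueError("normalization pool must be non-empty")

    @property
    def n_units(self) -> int:
        return self.preferred_deg.size

    def drives(self, angles_deg, contrasts) -> np.ndarray:
        return stimulus_drive(angles_deg, contrasts, self.preferred_deg, self.eta, self.upsilon)

    def pool(self, angles_deg, contrasts) -> float:
        return pool_drive(angles_deg, contrasts, self.pool_preferred_deg, self.pool_gain)


@dataclass
class NormalizationModel:
    """Filter bank plus normalization noise: the full stochastic model.

    ``evaluate`` maps a stimulus to per-unit mean rates and the single
    population gain variability; both share the identical denominator
    ``beta + P(S)`` (computed once).
    """

    bank: FilterBank
    sigma_N: float = DEFAULT_SIGMA_N

    def __post_init__(self):
        if self.sigma_N < 0:
            raise ValueError("sigma_N must be non-negative")

    def evaluate_profile(self, angles_deg, contrasts) -> tuple[np.ndarray, float]:
        g = self.bank.drives(angles_deg, contrasts)
        P = self.bank.pool(angles_deg, contrasts)
        denom = self.bank.beta + P
        rates = (g / denom) ** self.bank.p
        sigma_g = self.sigma_N * self.bank.p / denom
        return rates, sigma_g

    def evaluate(self, stimulus: OrientationStimulus) -> tuple[np.ndarray, float]:
        angles, contrasts = stimulus.energy_profile()
        return self.evaluate_profile(angles, contrasts)

    def gain_variability(self, stimulus: OrientationStimulus) -> float:
        angles, contrasts = stimulus.energy_profile()
        P = self.bank.pool(angles, contrasts)
        return gain_variability_from_normalization(P, self.bank.beta, self.bank.p, self.sigma_N)

    def to_config(self) -> dict:
        """Round-trippable JSON/YAML-compatible parameter block."""
        b = self.bank
        return {
            "sigma_N": float(self.sigma_N),
            "beta": float(b.beta),
            "p": float(b.p),
            "pool_gain": float(b.pool_gain),
            "preferred_deg": np.asarray(b.preferred_deg, dtype=float).tolist(),
            "eta": np.asarray(b.eta, dtype=float).tolist(),
            "upsilon": np.asarray(b.upsilon, dtype=float).tolist(),
            "pool_preferred_deg": np.asarray(b.pool_preferred_deg, dtype=float).tolist(),
        }

    @classmethod
    def from_config(cls, config: dict) -> "NormalizationModel":
        bank = FilterBank(
            preferred_deg=np.asarray(config["preferred_deg"], dtype=float),
            eta=np.asarray(config.get("eta", 2.0), dtype=float),
            upsilon=np.asarray(config.get("upsilon", 50.0), dtype=float),
            beta=config.get("beta", DEFAULT_BETA),
            p=config.get("p", DEFAULT_P),
            pool_gain=config.get("pool_gain", DEFAULT_POOL_GAIN),
            pool_preferred_deg=(
                np.asarray(config["pool_preferred_deg"], dtype=float)
                if "pool_preferred_deg" in config
                else None
            ),
        )
        return cls(bank=bank, sigma_N=config.get("sigma_N", DEFAULT_SIGMA_N))


@dataclass
class SigmaNFit:
    sigma_N: float
    predictions: np.ndarray
    fit_index: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False


def fit_sigma_N(
    observed_sigma_g,
    pool_drives,
    beta=DEFAULT_BETA,
    p=DEFAULT_P,
    fit_index=None,
) -> SigmaNFit:
    """Least-squares fit of the normalization-noise s.d.

    ``sigma_G = sigma_N * p / (beta + P_f)`` is linear in ``sigma_N``, so the
    MSE-minimizing value over the fit subset has the closed form
    ``sum(obs * u) / sum(u**2)`` with ``u_f = p / (beta + P_f)``. Predictions
    are returned for every family, including held-out ones.
    """
    observed = np.asarray(observed_sigma_g, dtype=float)
    pool_drives = np.asarray(pool_drives, dtype=float)
    if observed.shape != pool_drives.shape:
        raise ValueError("observed_sigma_g and pool_drives must have the same shape")
    u = p / (beta + pool_drives)
    if np.any(beta + pool_drives <= 0):
        raise ValueError("beta + pool_drive must be positive for every family")
    if fit_index is None:
        fit_index = np.arange(observed.size)
    fit_index = np.asarray(fit_index, dtype=int)
    if fit_index.size < 1:
        raise ValueError("need at least one family in the fit subset")
    uu = u[fit_index]
    degenerate = False
    if np.allclose(uu, uu[0]) and not np.allclose(observed[fit_index], observed[fit_index][0]):
        degenerate = True
    sigma_N = float(np.sum(observed[fit_index] * uu) / np.sum(uu**2))
    sigma_N = max(sigma_N, 0.0)
    return SigmaNFit(sigma_N=sigma_N, predictions=sigma_N * u, fit_index=fit_index, degenerate=degenerate)
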