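# gainvar

Tools for studying how sensory cortex could encode *stimulus uncertainty*
through variability in neural response gain, and for testing whether that
code can actually be read out from population activity.

## The scientific problem

Perception is inference under uncertainty: the same V1 population response is
compatible with many stimulus interpretations, and downstream circuits need
to know not just *what* the stimulus most likely was, but *how reliable* that
report is. `gainvar` implements a coding model in which these two messages
travel through separate channels of the same spike train:

- **mean spike count** encodes stimulus features (the classical receptive
  field, `f(S)`), and
- **variance of a multiplicative response gain** encodes the uncertainty of
  those features (an *uncertainty receptive field*, `u(S)`).

Spikes are modeled as a doubly stochastic Poisson process: counts `K` over a
window `Δt` are Poisson with rate `f(S)·G·Δt`, where the gain `G` is gamma
distributed with mean 1 and variance `σ_G²`. Marginally the counts are
negative binomial, and when the gain is constant within a trial ("slow"
dynamics):

    Var[K | S, Δt] = λ + σ_G² λ²,          λ = f(S) Δt.

If instead the gain refreshes every `ΔT < Δt` ("fast" dynamics) the quadratic
term is damped by `ΔT/Δt`, which makes the two regimes distinguishable by
counting the same spikes with nested windows (62.5–1000 ms).

Gain variability is tied to the stimulus through a **stochastic divisive
normalization** model: a unit's rate is `f_i(S) = (g_i(S)/(β + Σ_j g_j(S)))^p`
and additive Gaussian noise `ε ~ N(0, σ_N²)` on the normalization signal
makes the rate fluctuate with coefficient of variation

    σ_G(S) = σ_N · p / (β + Σ_j g_j(S)).

Strong, concentrated stimuli drive the pool hard and quench gain
fluctuations; weak or orientation-dispersed stimuli leave them large — so a
single stimulus-independent noise source yields stimulus-*dependent*
uncertainty coding.

The package provides, as separately usable modules:

| module | contents |
| --- | --- |
| `gainvar.modulated_poisson` | NB likelihood, ML estimation of `σ_G`, Fano factor, slow-vs-fast dynamics comparison and recovery analysis |
| `gainvar.uncertainty` | Fisher-information orientation uncertainty `1/I_θ`, selectivity indices of gain variability, simulation-based null test |
| `gainvar.normalization` | raised-cosine filter bank, stochastic normalization model, `σ_N` fitting |
| `gainvar.decoding` | joint ML decoding of (orientation, contrast, spread) + decoded `σ_G`, columnar heuristic estimator, decoding-quality evaluation |
| `gainvar.synthetic` | seeded generators for all of the above, with ground truth |
| `gainvar.io`, `gainvar.cli` | CSV/JSON round-trips and the `gainvar` command line |

## Worked example

Estimate gain variability from a synthetic spike-count table with known
ground truth, then compare slow and fast gain dynamics:

```python
import numpy as np
import gainvar as gv

cfg = gv.GeneratorConfig(
    seed=1,
    mean_counts_finest=np.linspace(5, 50, 16) / 16,  # 16 conditions, 62.5 ms means
    sigma_g=0.25, regime="slow", n_trials=100,
)
table = gv.generate_spike_table(cfg)

fit = gv.fit_gain_variability(table, window_ms=1000.0)
comp = gv.compare_dynamics(table)
print(f"sigma_G = {fit.sigma_g:.3f}")
print(f"delta LL (slow - fast) = {comp.delta_ll:.1f}, preferred: {comp.preferred}")
```

prints

```
sigma_G = 0.246
delta LL (slow - fast) = 530.9, preferred: slow
```

The estimate recovers the generating `σ_G = 0.25`, and the log-likelihood
difference of the multi-window fit correctly identifies the slow-dynamics
generator. The same pipeline is available from the shell:

```bash
gainvar simulate --seed 1 --sigma-g 0.25 --n-trials 100 --out counts.csv
gainvar fit-gain counts.csv --out fit.json
gainvar fit-dynamics counts.csv --out dynamics.json
```

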