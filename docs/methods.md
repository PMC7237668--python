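# Methods

This note documents the models implemented in `gainvar`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## 1. The modulated Poisson model

Spike counts `K` in a window `Δt` arise from a Poisson process whose rate is
the product of a deterministic stimulus drive `f(S)` and a stochastic,
unit-mean gain `G`. The gain is gamma distributed with shape `1/σ_G²` and
scale `σ_G²` (mean 1, variance `σ_G²`), so the marginal count distribution
is negative binomial with mean `λ = f(S)Δt` and shape `1/σ_G²`, and

    Var[K] = λ + σ_G² λ²          (slow dynamics, gain constant per trial).

If the gain instead refreshes independently every `ΔT ≤ Δt` (fast dynamics),
a window spans `n = Δt/ΔT` i.i.d. gain intervals. Each interval's count is
NB with shape `1/σ_G²` and mean `λ/n`; because the intervals share a common
NB success probability, their sum is exactly NB with shape `n/σ_G²` — the
sum-of-NB closure we rely on when fitting the fast model — which damps the
quadratic variance term by `ΔT/Δt`. This closure is unit-tested against
direct sub-interval simulation.

**Likelihood.** `nb_log_pmf` evaluates the gamma-Poisson mixture through the
explicit log-gamma expansion, which yields correct limits for degenerate
inputs (`λ = 0` gives 0 at `k = 0` and `-inf` otherwise). Below
`σ_G = 1e-4` the implementation switches to the Poisson log-pmf: the NB
shape exceeds 1e8 there and the paired `gammaln` terms cancel
catastrophically, while the two distributions are numerically
indistinguishable. The same threshold is the lower edge of the `σ_G` search
range (`[1e-4, 10]`).

**Estimating σ_G.** For a single counting window the joint MLE of
per-condition means and a shared `σ_G` profiles exactly onto the
per-condition *sample* means: for any fixed NB shape the score in the mean
vanishes at the sample mean. The remaining 1-D problem in `log σ_G` is
solved by a 31-point log-spaced grid followed by bounded golden-section
refinement (tolerance 1e-6 in `log σ_G`). If the Poisson boundary achieves a
log-likelihood within 1e-6 (relative) of the NB optimum, `σ_G = 0` is
reported — the tolerance absorbs the log-gamma cancellation noise near the
shape ceiling. All-zero tables carry no dispersion information and return 0
with a warning flag.

**Dynamics comparison.** The multi-window fit shares one count rate `f_c`
per condition across windows (`λ_w = f_c · w`) plus one `σ_G`, with the NB
shape `1/σ_G²` at every window (slow) or `(w/ΔT)/σ_G²` (fast, `ΔT` = the
smallest window, 62.5 ms by default). All observations are treated as
statistically independent even though each spike is counted once per window
size — the multiple-counting caveat is accepted deliberately, and the
recovery analysis quantifies how well the comparison discriminates the
regimes despite it. The joint optimization (17 parameters for 16 conditions)
runs L-BFGS-B in log-parameters with an analytic gradient (digamma terms for
the shape). Ties in the log-likelihood comparison prefer slow and are
flagged. The recovery analysis synthesizes per-regime datasets (one gain per
trial vs one gain per 62.5 ms), fits both models to each, and also reports
the slow-preference rate of the pooled collection as the equal-prior null.

**Fano factor** is the per-condition `variance/mean` (unbiased variance),
averaged across a family's conditions; zero-mean conditions are excluded and
counted, and a family in which every condition is silent has no defined
Fano factor.

## 2. Fisher-information orientation uncertainty

Under a Poisson spiking assumption the Fisher information of a tuning curve
`h(θ)` is `I_θ = E_θ[h'(θ)² / h(θ)]`, with the expectation a uniform average
over the measurement grid and angles in radians (so `I_θ` is information per
radian²; the inverse is the orientation-uncertainty measure, `∞` for a flat
curve). The statistic depends only on mean responses, never on measured
variance, so associations between it and gain variability cannot arise
trivially.

The derivative on the periodic grid is computed by trigonometric (FFT)
differentiation by default. Plain circular central differences attenuate the
m-th harmonic by `sin(mΔ)/(mΔ)`; on a 16-point grid this biases `E[h'²/h]`
down by ~5% already for a pure sinusoid, whereas spectral differentiation is
exact for band-limited curves and involves no smoothing of the measured
values. Central differences remain available (`derivative="central"`) for
sensitivity checks, as does an explicitly smoothed route via fitting before
calling. Grid points with `h = 0` contribute zero only if the local
derivative is also zero; a zero rate with nonzero slope would send the
integrand to infinity and raises an error instead of silently inflating the
information.

**Selectivity and its null test.** Selectivity of gain variability for an
uncertainty-inducing manipulation is `log10(σ_G^manip / σ_G^base)` (1 = a
tenfold increase); zero estimates are floored at 1e-4 with a flag. The
significance test re-estimates `σ_G` from the pooled condition sets,
simulates `n_sim = 100` synthetic datasets from the pooled estimate and the
empirical per-condition means, refits each half, and forms the null from all
`n_sim²` ordered pairs. Because `σ_G` is positive-valued its estimation bias
depends on response magnitude, so the null need not be centered at zero; its
median is reported and the observed index is called significant outside the
empirical central 95% interval (linear-interpolation percentiles). On
matched-`σ_G` simulations the measured type-I error is close to, and
slightly below, the nominal 5% (the plug-in pooled estimate makes the test
mildly conservative).

## 3. Stochastic divisive normalization

A unit's mean rate is `f_i(S) = (g_i(S)/(β + P(S)))^p`; additive Gaussian
noise `ε ~ N(0, σ_N²)` on the denominator gives the stochastic rate
`μ_i = (g_i/(β + P + ε))^p`, whose first-order Taylor moments are
`E[μ_i] = f_i(S)` and `Std[μ_i]/E[μ_i] = σ_N·p/(β + P)` — identified with
the gain variability `σ_G(S)` of the modulated Poisson model. The Taylor
expressions are validated against Monte-Carlo sampling of `μ_i` (rejection
of non-positive denominators with a floor of `1e-6·(β+P)`; noise levels with
expected acceptance below 99% are refused because the Taylor regime no
longer applies). All fitting uses the Taylor expression, never sampling.
Mean rate and gain variability are computed from the one shared denominator.

Defaults `β = 0.64` and `p = 2` are the population-average values obtained
from mean-response fits in the orientation experiment this model targets
(`p = 2.001` rounded to the canonical exponent); `σ_N = 0.35` is the value
fitted to population-average gain variability at high contrast. All are
overridable. Since `σ_G` is linear in `σ_N`, fitting `σ_N` to observed
per-family gain variability is closed-form least squares (cross-checked
against grid search); predictions are returned for held-out families.

**Filters, drives and the pool.** Orientation selectivity follows the
raised-cosine profile `W(d) = cos³(d)·exp(4.5·cos²(d))` of a third-order
Gaussian-derivative filter, with the angular difference `d` reduced to
[-90°, +90°] on the 180°-periodic orientation domain so weights are
non-negative (a sign-indefinite drive would be meaningless as a rate input).
Inside the population model the weights are normalized to peak 1, so that
the dynamic range `υ` is literally the response difference between blank and
preferred stimulus, and the stimulus drive is the affine dot-product
`g_i = η + υ · Σ_k W̃_i(θ_k)·c_k`.

Two conventions needed choosing where the source material leaves them open:

- *Stimulus energy.* A Gaussian orientation mixture is parameterized by its
  peak component contrast `c_S`; with the peak fixed, widening the spread
  adds components and hence total energy. The population model instead
  consumes an energy-normalized profile whose component contrasts sum to
  `c_S`, i.e. total stimulus contrast is set by `c_S` alone and spread only
  redistributes it — matching the experimental convention in which contrast
  levels denote overall stimulus contrast. Both profiles are exposed on
  `OrientationStimulus`.
- *The normalization pool.* The exact empirical pool model is out of scope
  here; the default is an energy pool over the bank's own raised-cosine
  units, `P(S) = pool_gain · mean_j (W̃_j · u)²` with uniform pool weights.
  Summing squared filter outputs makes `P` grow with contrast and *shrink*
  as fixed energy is dispersed over orientation, which is what produces the
  uncertainty receptive field's signature: `σ_G` falls with contrast and
  rises with spread. A linear pool cannot do this (it tracks total energy
  regardless of dispersion). `pool_gain = 200` was chosen once so `σ_G`
  spans ≈ 0.08–1.05 over the decoding stimulus set (contrast 0.05–0.5,
  spread 1–55°), bracketing values measured in cortex; pool membership and
  gain are configuration knobs. Because the pool is a stand-in, quantitative
  agreement with any particular empirical pool is not asserted — only the
  qualitative contrast/spread trends and the exact closed forms downstream
  of `P`.

## 4. Population decoding

The decoder assumes `n` independent modulated-Poisson neurons with rates
`λ_i = f_i(S)Δt` and one shared `σ_G(S)`, both from the normalization model,
and maximizes `Σ_i log NB(K_i; λ_i, σ_G)` over `(θ_S, c_S, σ_S)` within the
boxes orientation [0°, 180°], contrast [0, 1], spread [0°, 70°]. The
likelihood is 180°-periodic in `θ_S`; the multi-start procedure (default 8
stratified orientation starts plus one moment-based population-vector start
on the doubled-angle circle; contrast and spread initialized randomly) runs
L-BFGS-B with the orientation box centered on each start, so boundary traps
cannot exclude the optimum. Convergence tolerance is 1e-12 in the scaled
objective; the reported optimum is the best across starts and never falls
below any start's initial likelihood. Decoded gain variability is the
uncertainty receptive field evaluated at the decoded stimulus — identical by
construction to `gain_variability_from_normalization` on that stimulus.

**Heuristic estimator.** With the population organized into `n = 5` columns
of `m = 50` identically tuned neurons, within-column sample means `λ̂_i` and
unbiased variances `σ̂_i²` give the pooled estimator
`σ̂_G² = Σ(σ̂_i² − λ̂_i) / Σ λ̂_i²`. Sampling noise can drive the numerator
negative; the raw value is retained and the reported `σ̂_G` clamps at zero
with a flag.

**Evaluation.** Orientation errors live on the axial 180° domain; circular
statistics use doubled angles (the standard axial convention, which the
source leaves unstated), so the circular variance is 0 for concentrated and
1 for uniform errors. Trials are sorted into deciles of decoded `σ̂_G`, the
error circular variance is computed per bin, and the association is the
Spearman rank correlation between bin-mean `σ̂_G` and bin error variance,
averaged over independent simulation repeats. Degenerate inputs (all errors
identical) make the correlation undefined and are reported as NaN rather
than coerced.

**Gain correlations.** Shared gain fluctuations mix a common and a private
unit-mean gamma gain, `G = γG_s + (1−γ)G_p`, implemented exactly as printed;
note this gives `Var(G) = (γ² + (1−γ)²)σ_G²`, which is below `σ_G²` for
intermediate `γ`. A variance-preserving alternative (rescaled zero-mean
fluctuations, clipped at zero) is available behind `preserve_variance=True`;
the printed rule is the default because it is the stated one. The
cross-neuron gain correlation under the printed rule is
`γ²/(γ² + (1−γ)²)`, verified by simulation.

## 5. Synthetic data: what it does and does not emulate

All generators are seeded (`numpy` `SeedSequence` spawning for replicate
sub-seeds; identical seeds give bit-identical outputs) and return ground
truth sufficient to score any estimator without re-simulation. Spike-count
tables are generated once at the finest window and summed into coarser
windows, so nested windows count literally the same spikes and child counts
sum exactly to parent counts. Population parameters follow the simulation
conditions of the decoding study: 250 units, preferred orientations uniform
on [0°, 180°), `η ~ N(2, 0.2²)` ips and `υ ~ N(50, 7²)` ips truncated at
zero, `σ_N = 0.35`, `p = 2`, `β = 0.64`, read-out 1000 ms, 100
contrast-spread combinations (contrast 0.05–0.5, spread 1–55°) at ten
orientations.

The generators emulate the *statistical structure* the models assume:
gamma gains, Poisson spiking given the rate, exact window nesting,
independent neurons (up to the explicit shared-gain mixture). They do not
emulate real recordings' deviations from that structure — non-Poisson
refractoriness, stimulus-dependent normalization noise, heterogeneous
uncertainty receptive fields, adaptation, or correlated Poisson noise.
Passing tests therefore demonstrate internal consistency and estimator
correctness under the model, not that cortical data satisfy the model; the
empirical quantities reported for real recordings (example-neuron
information values, population medians, the empirical slow-dynamics
percentage) are outside what desk-scale simulation can reproduce and are
not asserted anywhere.

## 6. Problem sizes used by the shipped analyses

The quantitative checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use: 100 replicates per condition for `σ_G`
recovery (16 conditions × 100 trials); 100 synthetic datasets per regime for
dynamics model selection (16 conditions × 10 trials, five windows); 500
replicates for the null-test calibration (two sets of 8 conditions × 20
trials, `n_sim = 100`); 500 trials per `σ_G` level for the columnar
heuristic; 1e5–1e6 draws for moment and Taylor-oracle checks; and the full
1000-trial decoding simulation averaged over two independent repeats. These
sizes were chosen so each analysis resolves its target quantity well inside
the tolerance being checked while remaining runnable on a single desktop
core.

## 7. Known limitations

- The normalization pool is a configurable idealization; absolute `σ_G`
  scales depend on `pool_gain` and are meaningful relative to one another,
  not as predictions for specific neurons.
- The decoder's likelihood assumes exactly the generative model (shared
  `σ_G`, independent neurons); under `γ > 0` it is deliberately mismatched,
  which is the point of the robustness sweep, but its estimates are then no
  longer ML in the strict sense.
- The multi-window dynamics likelihood double-counts spikes across window
  sizes (treated as independent observations); model-comparison rates should
  be interpreted through the recovery analysis, which shows a modest bias
  toward the slow regime at these problem sizes.
- `fit_dynamics_model` profiles a 17-parameter likelihood; with very sparse
  data (few trials, near-zero counts) the moment-based initialization can
  sit far from the optimum and the fit, while convergent, is slow to
  certify global optimality.
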