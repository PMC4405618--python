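# Methods

`spikinghm` implements a Helmholtz machine — a paired generative
(top-down) and recognition (bottom-up) probabilistic model trained by
the wake-sleep algorithm — twice: once as a small rate-based
("computational") model, and once as a network of conductance-based
Izhikevich spiking neurons in which the delta rule of wake-sleep
learning emerges from a BCM-type synaptic plasticity rule acting inside
a dedicated microcircuit.  This note records the models, the parameter
choices and their rationale, the numerical conventions, and what the
shipped tests do and do not establish.

## 1. Rate-based Helmholtz machine

Two observed units `y` and two hidden units `x`, both non-negative
(firing rates, Hz).  Conditionals are truncated Gaussians:

    y | x ~ TruncNorm(W_G x + B_G β, Σ)        (generative)
    x | y ~ TruncNorm(W_R y + B_R β, Σ)        (recognition)

with support restricted to the non-negative orthant.  `β` (bias
activity) and `Σ` are fixed; `W_G, W_R` (unconstrained) and
`B_G, B_R ≥ 0` are learned online, one sample per phase:

* wake: `ΔW_G = η (y − ŷ) xᵀ`, `ΔB_G = η_b (y − ŷ)` with
  `ŷ = W_G x + B_G β`, `x` inferred by the recognition model;
* sleep: the mirror update of `W_R, B_R` on a prior fantasy.

The *approximate* rule replaces the error `e` with
`M (M + θ)`, `M = max(e, −θ)` — the quadratic, clipped form that the
spiking plasticity realises.  It preserves the sign of the exact update
whenever `e > −θ` and is zero below; `θ` defaults to 10 Hz.

Defaults: `β = 25` Hz (matching the spiking bias-stream rate),
`Σ = 25·I` Hz².  With `Σ = 25·I` the recognition-sample noise places a
floor of ≈ 0.24 position units on the linear-decoding error
(`Ĉ = ((x₁−15)+(x₂−15))/30`, so the floor is `√(2·25)/30`); a sharper
`Σ = 9·I` puts the floor at ≈ 0.14.  Both are config values; analyses
that need a low decoding floor (the prolonged-sleep experiment) pass
`Σ = 9·I` explicitly.

Sampling of truncated Gaussians is by batch rejection for general `Σ`
and by exact inverse-CDF per component when `Σ` is diagonal (the
training hot path); the truncated normaliser is never computed.

**Wake-sleep bias.** Wake-sleep does not descend a single objective;
its fixed point differs from the maximum-likelihood solution.  For
this linear family the deterministic two-regression fixed-point map
predicts the converged `W_G`, and the discrepancy grows with the
ratio of recognition noise to prior signal and with the off-diagonal
(mixing) weight.  The parameter-recovery test therefore uses a
diagonally-dominant ground truth (`W_G = [[0.5, 0.05], [0.05, 0.6]]`,
prior spread 6 Hz), for which the predicted asymptotic bias is ≈ 6 %,
and anneals the learning rate (5e-5 → 1e-5 → 5e-6 over 2.5×10⁵
phases).  A small diagonal initialisation of `W_R` (0.3·I) anchors the
hidden-unit labelling, which is otherwise unidentifiable (permutation
symmetry).

## 2. Neuron and synapse model

Izhikevich point neurons,

    dV/dt = 0.04 V² + 5 V + 140 − u + I_e + I_i + I_r
    du/dt = a (bV − u);   spike and reset (V←c, u←u+d) when V > 0 mV,

with presets RS (a=0.02, b=0.2, c=−65, d=8; excitatory) and FS
(a=0.1, b=0.2, c=−65, d=2; inhibitory).  Currents are conductance
based: AMPA `g_e1` and NMDA `g_e2` (gated by the Jahr–Stevens magnesium
factor `1/(1 + [Mg]/3.57 · e^(−0.062V))`, [Mg] = 1 mM) reverse at
0 mV, GABA_A `g_i` at −70 mV; an external AMPA-like channel `g_r`
carries per-neuron independent Poisson drive.  Decay constants:
τ_e1 = 5 ms, τ_e2 = 100 ms, τ_i = 10 ms; `g_r` shares τ_e1.  Each
delivered spike releases `max(f, 0)` vesicles with
`f ~ N(N_v P_v, N_v P_v (1−P_v))`, `N_v = 10`, `P_v = 0.5`, scaling the
weight; excitatory events increment `g_e1` by `w·f` and `g_e2` by
`0.5·w·f` (the NMDA fraction is a config value).  All transmission is
delayed by Δ = 1 ms.

**Integration.**  Fixed step dt = 0.1 ms, forward Euler, with the
membrane update split into two half-steps: summed inhibitory
conductances beyond ≈ 10 nS otherwise leave the Euler stability region
and produce spurious spikes.  Spike detection (V > 0) and reset are
applied per half-step.  Conductances and plasticity traces decay by
exact exponential factors per step.  Poisson generators and external
drives are Bernoulli-approximated per step (event probability
rate·dt), valid for rates ≪ 10 kHz.

**Event ordering per step** (the "just before" convention): delayed
spike deliveries (with pre-synaptic plasticity), external/generator
events, membrane integration, post-synaptic plasticity, trace
increments, decays.  A trace read during an event therefore never
includes any spike of the current step, so a spike cannot interact
with its own kernel contribution.

## 3. Plasticity rules and their equivalence

Both rules act on non-negative inhibitory weights and estimate rates by
kernel-filtered spike trains (kernels integrate to one over seconds, so
traces are unbiased rate estimates in Hz):

* **Spiking BCM** (exponential kernel, τ = 50 ms): at each
  pre-synaptic spike, `w += A · r̂_post (r̂_post − r_θ)`.
* **STDPi** (difference-of-exponentials kernel, τ₁ = 50 ms,
  τ₂ = 20 ms): at pre spikes `w −= A_m r̂_post`; at post spikes
  `w += A_p r̂_pre r̂_post`.

For independent Poisson trains the expected drifts are

    BCM:   A  · r_pre · r_post · (r_post + κ₂ − r_θ),   κ₂ = ∫κ² = 1/(2τ)
    STDPi: r_pre · r_post · (A_p r_post − A_m),

the `κ₂` term (10 Hz at τ = 50 ms) being the variance of the squared
single trace; STDPi has no such term because its quadratic is a product
of *independent* pre and post traces.  `match_amplitudes(η, r_θ)`
therefore returns BCM parameters `(A = η, r_θ^param = r_θ + 1/(2τ))`
and STDPi parameters `(A_p = η, A_m = η r_θ)`, under which both rules
realise the same effective BCM drift `η r_pre r_post (r_post − r_θ)` —
verified against long-run event-driven simulation rather than assumed.
Artificial-train experiments (drift surfaces, nullclines, correlated
trains) are computed event-exactly from sampled spike times; the
inhomogeneous post train of the correlated-train generator is drawn on
a 0.1 ms Bernoulli grid from the exponentially filtered pre train.
Drift measurements accumulate raw rule increments without the zero
floor (the floor is a property of a synapse, not of the drift).

Negative pre→post correlation (each pre spike suppresses the post
intensity) makes post spikes coincide with low pre traces, weakening
STDPi potentiation and shifting its zero-drift nullcline to higher post
rates; widening the kernel's initial dip (larger τ₂) discounts the
most recent pre spikes and shrinks the shift.  Default correlated-train
parameters: r_pre = 30 Hz, Δr = −30 Hz, τ_r = 10 ms.

## 4. The delta-rule microcircuit

Pools: `E`, `T` (20 Poisson generators each), `O`, `M` (20 RS each,
nonspecific drives of 100 Hz at 0.6 nS and 0.42 nS respectively — the
two published drive values), `D`, `I` (10 FS each); sparsity 0.3
everywhere.  `T` excites `O` and `M`; `M` excites `D`, which inhibits
`O`; `E` excites `M` and `I`; `I` makes the plastic inhibitory synapses
onto `M`.

Writing the linearised rates as `r_M = a_T r_T + s(r_E, w)` and
`r_O = o₀ + o_T r_T − G r_M`, the circuit approximates the delta rule
when three conditions hold: `o_T = G a_T` (output insensitive to the
target on short timescales), `G = 1/a_T`, and `r_θ = a_T o₀` — then
`sign(r_M − r_θ) = sign(r_T − r_O)`, so BCM potentiation/depression of
the plastic inhibition has the sign of the delta-rule update, and the
BCM fixed point `r_M = r_θ` maps to `r_O = r_T`.  The shipped fixed
conductances (per-source totals, nS: T→O 0.18, T→M 0.09, E→M 0.15,
E→I 0.05, M→D 0.04, D→O 1.8) were produced by the package's
calibration routine (probe-grid sign score plus coordinate refinement)
around those gain conditions, with r_θ = 30 Hz.  Trained tracking
deviation |r_T − r_O| averages ≈ 5–7 Hz for Spiking BCM and ≈ 10 Hz
for STDPi (largest at high targets, where the correlation-induced
threshold shift bites).  Learning amplitude defaults
to η = 2×10⁻⁶ nS/Hz² per event, giving convergence well inside 50 s of
training.

Deviations from perfect tracking come from neuron nonlinearity near
threshold (D falls silent when M is strongly suppressed), inhibition
saturating as V approaches the GABA_A reversal, and the heterogeneity
of per-synapse fixed points across the random connectivity.

## 5. The spiking Helmholtz machine

Four units (two sensory, two hidden) built from the delta circuit with
`E` removed and two pools added: an *output* pool (20 RS, relay
conductance 0.13 giving a ≈ unit-gain readout of its driver) that can
be driven either by `T` (external input) or by `O` (the unit's own
conditional sample) through gated projections, and a bias pool (10
Poisson generators at r_b = 25 Hz) making plastic inhibitory synapses
onto the unit's own `M`.  Pool `I` belongs to the unit as a *source*:
it is driven by the unit's output pool and provides the presynaptic
partner for the plastic inhibitory synapses this unit makes onto the
other layer's `M` pools, alongside fixed excitation from the output
pool (0.10 nS).  The excitation/plastic-inhibition balance of each
pathway encodes the signed weight of the rate model; a speculative
pass-through relay pool between `O` and the output pool can be enabled
by a config flag but is off by default.

Wake: sensory outputs are T-driven (data, one sample per 500 ms, 10
samples per phase), hidden outputs are O-driven (recognition samples),
and only the plastic synapses onto sensory `M` pools (generative side,
including the sensory bias streams) are eligible to learn.  Sleep: the
mirror image, with hidden `T` pools carrying prior draws.  The
non-driven layer's `T` pools are held at a steady 40 Hz.  Switching is
implemented as synaptic gating (conductance multiplier 0/1), never
rewiring, and gating of learning is exact: ineligible weights are
bit-identical across a phase.

**Stability.**  The two phases train each side of the machine under
the *other* side's output statistics.  If those statistics differ
between phases (e.g. recognition samples much lower than prior draws),
each side equilibrates against conditions the other phase never
produces, and the mismatch is amplified around the loop — weights grow
until `M` pools are silenced, where BCM has a dead zone (a silent post
trace produces no depression) and the degenerate state is absorbing.
Three measures keep the machine in the consistent regime:

1. *Balance-point initialisation* (`equilibrate`, the default 50 s
   warm-up of `train_wake_sleep`): both layers' outputs are temporarily
   driven externally at data/prior rates while all plastic synapses
   learn, so every `M` pool starts at its BCM fixed point under
   realistic stream rates.
2. *Moderate coupling gains*: the output→I drive (0.015 nS) keeps I
   rates comparable to output rates, and the inter-layer excitation is
   0.10 nS, limiting how strongly a phase-to-phase output discrepancy
   is amplified.
3. *A per-synapse weight cap* (0.4 nS) that prevents the plastic
   inhibition from silencing an `M` pool outright; equilibrium
   per-synapse weights sit around 0.05–0.3 nS.

With these defaults, η = 10⁻⁷ and 500 s of training (50 s warm-up +
450 s wake-sleep) on the isotropic unimodal dataset, the generative
divergence to the training data falls from ≈ 0.7–1.0 to ≈ 0.5
(base-2 Jensen–Shannon on 40×40 histograms), with generative moments
matching the data; the residual divergence is dominated by the
machine's limited spread and the biases of random connectivity.
STDPi networks conventionally receive prior rates scaled ×3 (the
`scale` argument of the prior constructors) to compensate for their
difficulty reaching high weights.

## 6. Datasets, priors and evaluation

Named datasets (all ≥ 15 Hz in mean, where the plasticity rules are
accurate; N = 2000 by default): `a`–`e` unimodal truncated Gaussians
(rotated covariance `R(θ) diag(ρ₁², ρ₂²) R(θ)ᵀ`; `e` is
anti-correlated — the hard case for purely-inhibitory plasticity),
`f`–`i` bimodal mixtures of unskewed truncated Gaussians (modes ≥ 15 Hz
apart), `o` a uniform line from (15, 15) to (30, 30) with isotropic
truncated-Gaussian noise (ρ = 3 Hz), labelled by the position
C ∈ [0, 1], and `r` the noise-free reward line
`(25, 25) + C·(−10, 10)`, C ∈ [−1, 1].  Priors: unimodal (mean
(25, 25), ρ = 8), bimodal (modes (15, 35)/(35, 15), ρ = 4), uniform
line matching the decoding geometry, and the reward prior with modes at
(10, 35)/(35, 10) (the ends of the reward decode line) mixed in
proportion r₁ : r₂.

Evaluation: 40×40 histograms on [0, 60] Hz per axis (out-of-range
samples clipped into edge bins so mass is conserved), base-2
Jensen–Shannon divergence via `scipy.spatial.distance.jensenshannon`;
best-match and confusion analyses against per-dataset population-average
distributions (ties broken toward the lowest dataset index); linear
decoders `Ĉ = ((x₁−15)+(x₂−15))/30` and `Ĉ = (−x₁+x₂)/25`;
root-mean-square deviation; per-trial maximum-likelihood logistic fits
(Nelder–Mead on the exact binomial log-likelihood, with explicit
separation detection); expected-reward quadrature
(`scipy.integrate.quad`, relative tolerance 1e-8) and bounded scalar
maximisation of the threshold on [−1, 1]; Tukey-fence (1.5·IQR)
discarding of non-converged thresholds before population statistics.

The prolonged-sleep experiment trains the rate model slowly on the
decoding task and, at chosen checkpoints, clones the state and runs
sleep-only updates with the learning rate annealed (halved per block)
until the recognition weights settle; the deviation change of the
slept clone is the improvement.  Decoding for this diagnostic uses the
recognition conditional *mean* (variance-reduced readout of weight
quality); the behavioural tests use samples.  The improvement peaks
mid-training and decays to ≈ 0 once training has converged; the effect
size (~0.01–0.02 position units) is close to evaluation noise, so the
shipped test checks it at a fixed seed.

## 7. Reproducibility and problem sizes

Every stochastic component draws from named substreams of a master
seed (`numpy` `SeedSequence`); network construction and simulation are
deterministic given the seed, and experiment outputs embed the
resolved configuration.  The test suite runs the full battery at
reduced scale chosen to keep statistical power: plasticity surfaces on
a 5×5 grid (0–60 Hz, 100 s per cell, 6 repetitions), the delta
experiment on a 5×5 target/initial-weight grid with 3 connectivity
instantiations and 20 s training, parameter recovery at 2.5×10⁵
phases, and spiking wake-sleep runs of 500 s on dataset `a` with 3
seeds and 120 generative samples per divergence estimate.  These sizes
are the package's reference configuration; all are arguments.

## 8. What the synthetic setting does and does not show

All data are drawn from the model families above: low-dimensional,
stationary, with rates kept away from 0 Hz.  Passing tests show that
the spiking machinery implements the intended algorithm under those
conditions — that the plasticity rules realise the BCM drift, that the
microcircuit turns it into error-correcting learning, and that
wake-sleep training of the assembled machine improves its generative
model.  They do not show robustness to non-stationary input statistics,
to rates near the rules' inaccurate low-rate regime, to richer stimulus
dimensionality, or to pathological connectivity draws (across-network
variability is large, and anti-correlated datasets remain hard).
Known limitations:
negative weights are representable only weakly (purely inhibitory
plasticity), the wake-sleep fixed point is intrinsically biased away
from maximum likelihood, and the spiking machine requires the
balance-point warm-up to avoid the degenerate silent-`M` attractor.
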