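# Methods

## Model

A stimulus at t = 0 launches a neural process (a single neuron or, more
plausibly, an ensemble) whose firing rate r(t) changes monotonically.
Elapsed time is read out by counting spikes in a boxcar window of width τ,
R(t) ≈ τ·r(t), and declaring the interval over at the first time R(t)
crosses a threshold R₀ — from above when r falls, from below when r rises.
Trial-to-trial spike-count variability makes the crossing time t_est a
random variable; the theory asks which r(t) makes its dispersion obey the
scalar law σ_t(t) = α·t.

Linear error propagation gives σ_t(t) ≈ σ_R(t)/|τ·r′(t)|. With power-law
count noise σ_R = β·(τr)^ρ this becomes the ODE
dr/dt = ±(β·τ^(ρ−1)/α)·r^ρ/t, solved in closed form by the log-power curve

    r(t) = K·(±log(t/t₀))ⁿ,  n = 1/(1−ρ),  K = (1/τ)·(β(1−ρ)/α)ⁿ.

All parameters are measurable spike/behaviour statistics; none are free.
The integration constant t₀ is the shortest (increasing) or longest
(decreasing) representable time, with r(t₀) = 0 exactly.

### Assumptions

- Spike counts in disjoint windows are conditionally independent given the
  rate (no refractoriness, adaptation, or cross-neuron correlations).
- The count noise follows σ_R = β·R^ρ with 0 ≤ ρ ≤ 1; ρ = 1/2, β = 1
  matches Poisson statistics, the case used throughout the simulations.
- The derivation is first-order (local linearisation of R(t) at the
  target); simulations quantify where it is only approximate.

## Parameters

| symbol | meaning | default | rationale |
|---|---|---|---|
| α | Weber fraction, σ_t/t | 0.05 | middle of the behaviourally reported range for interval timing |
| β, ρ | count-noise multiplier/exponent | 1, 1/2 | Poisson-like variability, the experimentally common case |
| τ | count window (s) | 0.1 | the canonical simulation protocol value |
| t₀ | integration constant (s) | 10 | decreasing-branch scenario value |
| dt | simulation step (s) | 0.001 | ≥ 100 steps per window; per-step Poisson mean stays O(1) |
| targets | 6 log-spaced in [0.5, 6] s | — | spans >1 decade inside the decreasing domain |
| n_trials | trials per target | 200 | the protocol's ensemble size |
| η | learning rate (dimensionless) | 0.01 | see below |

## Numerical choices

**Spike generation.** Per-step Poisson draws with mean r(t_mid)·dt. This is
exact for an inhomogeneous Poisson process at any rate magnitude; thinning
would be equivalent but needs a rate bound and is slower when the
decreasing branch reaches thousands of Hz.

**Windowing and crossing.** Counts are emitted only where the full window
fits inside the trial (first centre t_start + τ/2): a partial window at the
start of a decreasing trial would read artificially low and fire spurious
crossings. A count exactly equal to R₀ counts as a crossing; learned
(non-integer) thresholds are compared to integer counts directly. Trials
that never cross are *censored*: excluded from statistics, counted, and
logged when they exceed 1% of an ensemble.

**Trial span.** The decreasing branch diverges as t → 0⁺, so trials start
at max(t_tar/2, t_min) − τ/2, where t_min is the time at which the expected
window count reaches 10× the count at the target — a practical floor, since
the theory itself gives no lower bound — and end at 2·t_tar (capped just
below t₀). At α = 0.05 this leaves ≥ 8 standard deviations of headroom on
both sides of the crossing region; censoring is absent in practice.

**Seeding.** Trial i of an ensemble uses `default_rng(seed + i)`; experiment
targets are spaced 10⁶ seeds apart and evaluation ensembles are offset from
learning streams, so no two pipelines share a stream. Identical inputs give
bit-identical outputs.

**Domain edges.** `rate` returns exactly 0 at t = t₀ and raises a domain
error beyond it rather than clamping, which keeps the monotonicity
invariants strict. ODE residuals are computed with the *analytic* derivative
of the closed form, so they measure solution error, not discretisation
error.

**General solver.** For non-power-law noise maps σ_R(R) or tabulated
non-linear scaling σ_t(t), `solve_rate_numeric` integrates
dr/dt = ±σ_R(τr)/(τ·σ_t(t)) with DOP853 at rtol 1e−8 (configurable) from a
boundary point, with a terminal event guarding against the rate crossing
zero inside the grid. Under power-law noise and a linear law it reproduces
the closed form to better than 1e−5 relative, which the tests assert.

## Discrete first-crossing model

Time is split into non-overlapping bins of width τ with expected counts
R_i = τ·r((i−0.5)·τ). Independent per-bin Poisson counts give the per-bin
crossing probability P_c(i|R₀) (lower Poisson CDF at floor(R₀) for a
falling rate, upper tail from ceil(R₀) for a rising one) and the first
crossing lands in bin j with probability
P_FC(j|R₀) = P_c(j)·∏_{i<j}(1−P_c(i)). Normalisation Σp + residual = 1
holds to 1e−12 by construction and is property-tested; moments are
conditional on crossing and an error is raised if the truncation residual
exceeds 1e−6, so truncation can never bias moments silently.

**Bin representative time.** The distribution indexes bins, not times. The
default maps bin j to its *midpoint* (j−0.5)·τ — the time at which R_j
samples the rate, and the convention with the smaller noiseless offset
(bias in [0, τ) versus [τ/2, 3τ/2) for the bin end). The end convention
j·τ remains available.

**Fidelity.** A coarse-grained Monte-Carlo twin (crossings permitted only
at bin points) matches the distribution exactly in law; the tests verify
its moments at 10⁵ trials and a χ² fit of bin frequencies. Against the
*fine* simulator the discrete model is an approximation with a known,
systematic gap: the sliding window is tested at every dt step, so its first
passage comes earlier (and spreads slightly less) than the once-per-τ
discrete checks — at α = 0.05 the mean gap grows from ≈ 0.03 s at a 0.5 s
target to ≈ 0.2 s at 6 s, several standard errors of a 200-trial mean, and
part of the std gap is the bin-quantisation variance τ²/12. The discrete
model does capture the scalar-law *slope* well (within ≈ 6% of the fine
simulation's here), which is the quantity it is used for.

## Threshold learning

Setting R₀ = τ·r(t_tar) underestimates every target: among many noisy
looks at a falling count, the first dip below threshold precedes the mean
crossing. The threshold is therefore treated as learned. After each trial,

    R₀ ← R₀ + s·η·|τ·r′(t_tar)|·(t_est − t_tar),   s = +1 falling, −1 rising.

The error sign is chosen so the rule is stable: for a falling rate t_est
decreases as R₀ rises, so short estimates must *lower* the threshold. The
raw error is seconds while R₀ is a count; scaling by the local count slope
|τ·r′(t_tar)| makes η dimensionless and, to first order, the per-trial
contraction rate of the error — one default (η = 0.01, ≈ 100-trial
convergence horizon) then works across all targets, and convergence is
robust over at least η ∈ [0.003, 0.03] (tested). Convergence is declared on
a trailing 50-iteration window of estimates (single trials are too noisy to
judge), and the reported threshold is the window-averaged R₀, which damps
the stochastic-approximation jitter. Updates run one trial at a time by
default (mini-batches optional); a threshold escaping
[0, max expected count] raises a divergence error. Evaluation always uses a
fresh ensemble on an independent stream.

## What the simulations do and do not show

The generator *is* the model under test — inhomogeneous Poisson trains
from the derived rate curve — so passing tests show internal consistency
of derivation, simulation, discrete theory and learning, plus the emergent
properties (linear σ_T vs ⟨t_est⟩ with R² ≥ 0.95; KS-indistinguishable
mean-rescaled distributions; unbiased learned estimates). They do not show
that real neurons have log-power dynamics, that count noise is exactly
power-law, or that behaviourally measured Weber fractions are reproduced:
no biological data enters the package, by design. Known limitations:
no refractoriness or count correlations; only the Poisson count model is
implemented behind the `spike_model` abstraction point; the fitted scalar
slope sits systematically below the configured α (the linear approximation
overestimates the error, as the simulations quantify), so α should not be
read off a simulated slope without that correction in mind.

## Problem sizes

Default experiments use 6 targets × 200 trials at dt = 1 ms (seconds of
runtime); discrete-model cross-checks use 10⁵ coarse-grained trials; the
noise-recovery regression uses 20 mean-count levels × 5000 windowed counts.
These sizes give Monte-Carlo standard errors comfortably below the effects
being measured while keeping any run interactive.
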