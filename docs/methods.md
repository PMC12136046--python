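# Methods

## Model

Each of n cortical parcels is a reduced Wong-Wang dynamic mean-field
node: an excitatory pool with NMDA-gated synaptic variable S_E and an
inhibitory pool with GABA-gated S_I. Input currents (nA)

    I_E,i = W_E + w_EE,i S_E,i + G J Σ_j C_ij S_E,j − w_IE,i S_I,i
    I_I,i = W_I + w_EI,i S_E,i − w_II S_I,i

are converted to firing rates through the sigmoidal transfer
H(I) = x / (1 − e^(−d x)) with x = a (I − b), and the gating variables
follow

    dS_E/dt = −S_E/τ_E + (1 − S_E) γ H_E(I_E) + σ ν(t)
    dS_I/dt = −S_I/τ_I + H_I(I_I) + σ ν(t)

integrated by Euler-Maruyama at dt = 0.1 ms with S clamped to [0, 1]
after every step. The transfer threshold is applied in current units
(x = a(I − b)); applying the printed threshold value after the slope
multiplication would be dimensionally inconsistent and does not
reproduce the balanced working point (H_E(0.37738 nA) ≈ 3.08 Hz,
S_E ≈ 0.165). The noise term uses independent standard-normal draws for
the E and I equations of each node (draw order per step: node-major,
E before I), discretized as σ√dt ν. Excitatory gating drives a
Balloon-Windkessel model (Euler, dt = 1 ms, 3-T read-out coefficients)
whose BOLD output is sampled every TR; the first 30 s of a 450 s
simulation are discarded everywhere (states and volumes).

Fixed constants are the published set for this model family
(W_E = 0.382 nA, W_I = 0.267 nA, J = 0.15 nA, a_E = 310 nC⁻¹,
b_E = 0.403 nA, d_E = 0.16, a_I = 615 nC⁻¹, b_I = 0.288 nA, d_I = 0.087,
τ_E = 0.1 s, τ_I = 0.01 s, γ = 0.641, w_II = 1, σ = 0.01 nA; κ = 10.65 s⁻¹,
γ_h = 10.41 s⁻¹, τ_h = 0.98 s, α = 0.32, ρ = 0.34, V0 = 0.02, k1 = 3.72,
k2 = 0.527, k3 = 0.53).

### Free parameters

Regional w_EE and w_EI are bias × (1 + Σ_k c_k M_k) over k z-scored
heterogeneity maps, shifted upward if needed so min ≥ 0.001. With k = 6
the fit vector is 15-dimensional: G ∈ [0.5, 4], biases ∈ [0.05, 0.75],
and per-map coefficient bounds [−1/max(M), −1/min(M)] (which keep
1 + c·M positive at the extreme nodes). Variants: `homogeneous`
(3 parameters, uniform weights) and `node_based` (1 + 2n parameters).

### Conduction delays

Optionally, node j's contribution to node i is delayed by
length_ij/velocity, rounded to the global-input update interval (1 ms in
delayed runs; zero-interval delays allowed). With zero delays the
delayed code path is bit-identical to the plain integrator at the same
interval, which makes the large-velocity limit an exact test rather than
an approximate one.

## Feedback inhibition control

w_IE is set per node in two stages targeting ⟨r_E⟩ ≈ 3 Hz
(⟨S_E⟩ ≈ 0.164757, ⟨I_E⟩ ≈ 0.37738 nA):

1. **Analytic.** Assuming all nodes share that steady state, the
   inhibitory self-consistency equation
   W_I + w_EI⟨S_E⟩ − H_I(I_I)τ_I − I_I = 0 is solved per node by
   bracketed root-finding (Brent, bracket [0, 2] nA, xtol 1e-12) — the
   left side is strictly decreasing in the physical range — and w_IE
   follows algebraically from the excitatory current equation with the
   network term G·J·(Σ_j C_ij)·⟨S_E⟩.
2. **Numeric.** Up to 10 noisy 10-s trial simulations measure ⟨I_E⟩ per
   node against the target b_E − 0.026 nA (tolerance 0.005 nA). Nodes
   above target get more inhibition, nodes below less. The step is
   proportional to the deviation (gain 5 nA⁻¹) but capped by a per-node
   trust radius (initial 0.1) that halves whenever the deviation changes
   sign: the current-to-weight sensitivity varies severalfold between
   the balanced and high-rate regimes, so a pure fixed-gain update
   oscillates between dynamical branches. Trials start at the analytic
   steady state so the short average is not dominated by the onset
   transient, and use per-trial seeds derived from the simulation's
   noise seed (deterministic end to end).

FIC success is a soft constraint: parameter regions where the per-node
w_EE/w_EI ratio is large at high G make the 3 Hz state bistable or
unstable, no w_IE attains the target, and the numeric stage reports
non-convergence. Such candidate fits are charged the rate penalty below
rather than rejected.

## Model evaluation

Static FC is the Pearson correlation matrix of the BOLD time series
(scrubbed volumes excluded). FCD tiles sliding windows (defaults 30 s
window, 6 s step, converted to integer TR counts by rounding), drops
the first and last window and windows with ≥ 50% flagged volumes, and
correlates the vectorized lower-triangular window-FC patterns. Fit of
simulation to data is

    gof = FC_corr − FC_diff − FCD_KS ≤ 1

with FC_corr/FC_diff computed on lower-triangle edges (interhemispheric
edges excluded by default; also excluded from window-FC vectors for
consistency, both switchable) and FCD_KS the two-sample
Kolmogorov-Smirnov distance between lower-triangular FCD value sets.

## Optimization

CMA-ES (population Λ = 210, ≤ 80 generations, early stop when the
best-ever cost improves ≤ 0.005 over the trailing 30 generations; at
most 16,800 evaluations per run and two runs per subject, best
goodness-of-fit wins). The optimizer is the standard (µ/µ_w, λ)
formulation — log-linear recombination weights over the best ⌊Λ/2⌋
particles, cumulative step-size adaptation, rank-one plus rank-µ
covariance update — run in the unit cube with per-dimension scaling to
the parameter bounds, initial mean at the box center and σ0 = 0.25. A
degenerate covariance triggers one restart from the current mean, then
aborts. Out-of-bounds components are corrected to the boundary and
charged quadratically in range-normalized units (a 10%-of-range
violation costs 0.01). Nodes with post-FIC rates outside 2-4 Hz add

    penalty = (2/n) Σ_i (1 − e^(−0.05 |⟨r_E,i⟩ − 3|))

summed over out-of-band nodes only. Cost = −gof + both penalties;
particles whose simulation blows up get a sentinel cost and drop out.

## E-I markers and validation

The primary regional marker is ⟨I_E⟩ (nA) averaged after burn-in; the
alternative is the ratio of time averages ⟨S_E⟩/⟨S_I⟩ (ratio of means,
not mean of ratios). Validation harnesses: (i) single-parameter ±10%
perturbations with w_IE frozen (no FIC re-run), paired t statistics
across nodes — expected signs are + for G and w_EE, − for w_IE, − for
w_EI; (ii) ground-truth recovery — fit the model to the FC/FCD of a
synthetic subject generated by the package's own forward model and
compare recovered vs. true ⟨I_E⟩ maps by Pearson r and ICC, with the
particle simulations using either the ground truth's noise seed or a
different one; (iii) noise-seed sensitivity — re-simulate an optimal
configuration under alternative seeds and summarize per-seed ICC
(median across seeds; the per-seed ICC is computed across nodes between
the default-seed and alternative-seed maps). ICC is the two-way
single-measure form computed from the ANOVA mean squares; both absolute
agreement ICC(2,1) and consistency ICC(3,1) are available (bands:
poor < 0.5, moderate 0.5-0.75, good ≥ 0.75).

## Synthetic data

The generator emulates the pipeline's three inputs so everything is
testable without imaging data. Connectomes: nodes on two hemispheric
rings (radius 40 mm, 30 mm gap), log-normal weights (σ = 0.6) with
exponential distance decay (75 mm), 2× intrahemispheric boost,
Bernoulli edge density 0.7 (regenerated if disconnected), normalized to
mean weight 0.01; Euclidean distances serve as streamline lengths.
Maps: first/second harmonics of ring angle per hemisphere plus Gaussian
noise (sd 0.3), z-scored — smooth and independent across k, unlike real
heterogeneity maps, which are mutually correlated (a documented
limitation: passing tests do not certify behavior under collinear
maps). Scrub masks are Bernoulli. Ground truths run the package's own
expansion → FIC → simulation chain and store BOLD plus the true E-I map
(closure property: a fit of the truth against its own features with the
same noise seed attains gof = 1 exactly).

The default ground-truth parameters sit in the dynamically balanced
regime (G = 1.2, wb_EE = 0.40, wb_EI = 0.45, the two coefficient
vectors sharing one spatial pattern with 10% jitter so per-node weight
ratios stay uniform and FIC converges quickly). Because FIC pins every
node's ⟨I_E⟩ to a common target, the E-I map's spatial variance *is*
the pattern of sub-tolerance residuals — set by the regional weights,
the network input, and the specific noise realization. At 10 nodes with
mean weight 0.01 the network term is an order of magnitude weaker than
at 100 nodes and these residuals are small (1e-5 to 1e-3 nA depending
on regime) but fully structured and reproducible given the seed.

## Problem sizes

Desk-scale defaults used throughout the tests: 10-node connectomes,
120 s simulations (60 s for unit-level checks), TR 3 s, FCD windows of
10 TR stepping 2 TR, recovery fits with Λ = 16 and ≤ 12 generations of
a single run, fitting the homogeneous three-parameter variant. The
model dimension is scaled down along with the population and network
size deliberately: the FC/FCD of a 10-node, 30-volume target does not
identify the twelve map coefficients (the optimizer reaches the flat
rim of the fit landscape with coefficient errors of a third of their
range or more), and since the E-I residual map tracks the coefficient
pattern, map-based recovery at this scale measures only that
degeneracy. In the homogeneous variant everything that shapes the E-I
map — global coupling acting through the connectome's row sums, the
uniform weights, and the shared noise realization — is recoverable,
and the experiment cleanly reproduces the full protocol's seed
phenomenology (near-perfect same-seed recovery; a collapse of both the
achievable fit and the recovery correlation under a different seed).
These sizes let a complete recovery experiment (two full fits) run in
about ten minutes on one CPU core while exercising every code path of
the full-scale protocol; the full-scale settings (Λ = 210, 80
generations, 450 s, two runs, 15-parameter map-based layout) remain
the configuration defaults.

## Numerical choices and edge cases

- Transfer-function singularity at x = 0 returns 1/d (guard |x| < 1e-8);
  continuous to < 1e-6.
- Gating clamped to [0, 1] after each Euler step, before the next
  hemodynamic sample is read.
- v^(1/α) and (1−ρ)^(1/f) evaluated in log space; hemodynamic
  integration aborts if flow or volume becomes non-positive.
- Connectome diagonals are forced to zero (self-excitation lives in
  w_EE only); SC normalization divides by mean × 100 over all n²
  entries (off-diagonal variant available).
- Zero-variance BOLD nodes get FC rows of 0 with a warning; fewer than
  two surviving FCD windows is an error naming the cause.
- All randomness flows from explicit integer seeds; every simulation
  re-seeds its own generator, so any stage re-run with the same inputs
  is bit-identical.

## Known limitations

- The synthetic connectome has no streamline-count noise model and its
  distance geometry is planar; delays are exercised but not validated
  against tract anatomy.
- Recovery at 10 nodes probes far fewer effective degrees of freedom
  than the 100-parcel protocol; the same-seed recovery correlation is a
  scaled-down analogue, not a reproduction of the full-scale value.
- Group-level statistics (age effects, FDR, spin tests, meta-analysis)
  are out of scope; the package ends at per-subject markers.
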