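# Methods

This note documents the model's assumptions, the numerical choices behind
the implementation, and the places where the underlying description left a
genuine design decision open.

## Circuit composition and parameters

The circuit holds N point neurons split 0.8 / 0.07 / 0.13 into E, I1 and I2
classes (largest-remainder rounding at reduced scale, so every class is
nonempty for any sensible N). All physiological and synaptic parameters are
carried by `microhet.params`: per-class homogeneous values and
heterogeneous distribution descriptors for the neurons, per-class receptor
kinetics, and per-connection-type densities, weight/delay statistics and
structural-bias parameters. Lognormal descriptors are given as the
*distribution* mean and standard deviation and converted internally to
shape parameters via `σ² = ln(1+s²/m²)`, `μ = ln m − σ²/2`.

Two table-reading decisions deserve emphasis:

- **Redundant rows.** The single-neuron table lists C_m, g_leak and also
  τ_m and R_m. The dynamical model is parameterized by (C_m, g_leak); in
  the heterogeneous condition these two are sampled directly from their
  stated distributions and τ_m = C_m/g_leak is implied. Deriving g_leak
  from sampled τ_m instead (available as `g_leak_mode='from_tau_m'`)
  produces g_leak spreads several times wider than the stated ones (I1:
  7.6±4.3 nS against the stated 9.09±0.75), so the direct reading is the
  default.
- **Adaptation timescale.** No measured value constrains τ_w directly.
  The default is 144 ms, the conventional value for this
  adaptation-current model family; it is a config parameter, and the I1
  class (a=b=0) is unaffected by it. The choice shifts the slow tail of E
  and I2 voltage responses but none of the class relations.

Rejection resampling enforces V_reset < V_thresh and positivity of g_leak,
C_m and t_ref on heterogeneous draws; no other truncation is applied.

## Receptor model and the amplitude convention

A spike elicits `g(t) = ḡ·n(V)·(1−e^{−t/τ_rise})(r e^{−t/τ_f} +
(1−r) e^{−t/τ_s})`, which expands into at most four pure exponentials.
The engine therefore keeps, per neuron, 16 exponential state variables
(4 slots per receptor family) advanced by their exact per-step decay
factors; spike arrival adds weight-scaled jumps. Superposition over spike
trains is exact on the grid, and the single-spike trace matches the closed
form to 10⁻⁶ nS (property-tested).

The product shape does not peak at 1, so ḡ can be read either as a raw
multiplier or as the realized peak conductance. Measuring all six reference
single-spike PSPs under both conventions settles it: the raw-multiplier
reading (default) reproduces the excitatory PSP on E cells at 0.83 mV
versus the reference 0.82 mV and is closer on most rows, whereas peak
normalization overshoots every excitatory amplitude by 30–55%.
`normalize_peak=True` retains the normalized variant. Residual
discrepancies remain under the default convention (I1 GABA amplitude
−0.29 vs −0.25 mV; fitted decay constants of mixed-kinetics PSPs run
~13% above the reference values for any fit window we tested); they are
reported by the test suite rather than hidden, and no parameter is tuned to
close them.

NMDA gating is evaluated once per time step at the current membrane
potential and multiplies the summed NMDA conductance; GABA_A/GABA_B
reversal potentials are per class, AMPA/NMDA reverse at 0 mV.

PSP protocols start the neuron at its sub-threshold fixed point (rest, or a
holding potential imposed by a constant current with the adaptation current
at its fixed-point value) and fit `A(e^{−t/τ_d} − e^{−t/τ_r})` from spike
arrival over the full window, initialized from the 20–80% rise time and the
post-peak log-slope.

## Connectivity

Homogeneous blocks are independent-Bernoulli digraphs at the stated
densities (autapses excluded; realized density lands within binomial
bounds). Structurally heterogeneous blocks carry exactly
⌊p·n_pre·n_post⌋ edges whose endpoints are drawn from normalized truncated
exponentials `P(j) ∝ e^{−jk/N}`; duplicates and autapses are resampled,
with adaptive oversampling because the densest biased blocks (e.g. E→I1 at
57.5% density with k_in=5) saturate their favoured targets — top I1
neurons end up receiving input from nearly every E cell, which is the
intended extreme of the degree distribution. Resampling conditions the
index marginals only where pair occupancy is high; at low occupancy the
marginals pass a χ² test against the analytic pmf. Index 0 is the
most-connected end by convention.

Weight correlations (only when structural and synaptic heterogeneity are
both active) multiply each weight by per-presynaptic and per-postsynaptic
factors ζ ~ logN(−c²/2, c); E[ζ]=1 preserves the marginal mean while
inducing common-factor correlations of c²/(c²+σ₀²) among log-weights
sharing an endpoint.

Condition isolation: a single master seed is split into a fixed layout of
seed-sequence children (3 classes, 9 adjacency, 9 weight/delay, 9
correlation blocks), so conditions sharing a component realize it
identically — Hom and Neu share adjacency and weights bit-for-bit, Hom and
Syn share adjacency and neuron parameters.

## Integration scheme

Fixed 0.1 ms grid. Per step: delayed arrivals fold into the receptor
states; conductances are summed (NMDA gated at the step's opening
potential) and held across one classical RK4 step of the coupled
(V, I_adapt) system; threshold crossings are registered at the end of the
step, V is clamped at V_reset for ⌈t_ref/dt⌉ steps (adaptation continues
to relax exactly during refractoriness), b is added to I_adapt, and
outgoing spikes enter per-delay ring buffers. Background input collapses
the K_in independent Poisson sources into one Poisson count process of rate
K_in·ν_in·dt per neuron — exactly equivalent because background synapses
share one weight (the class's mean excitatory weight) and delay. Spike
times are grid times (no sub-step interpolation). Halving the step to
0.05 ms changes quiet-state spike counts by <2% (tested), which guards the
fixed-grid choice against the adaptive-stepping alternative.

The loop is numba-compiled; identical inputs and seed reproduce spike
trains bit-for-bit. Full-scale (N=2500) 10-s runs take ~45 s on one core.

## Activity statistics

- CC: Pearson correlation of 2-ms binned spike counts over 500 random
  disjoint pairs of neurons with ≥2 spikes (bin size is a config knob and
  is reported with results, since CC depends on it).
- CV_ISI, ISI_5%, H_ISI: computed per neuron with ≥10 ISIs; exclusion
  counts are surfaced. H_ISI bins ln-ISI by Freedman–Diaconis; entropy is
  bin-sensitive, so the rule is fixed here.
- E/I balance: signed summed receptor currents (excitatory negative below
  0 mV), per-neuron zero-lag Pearson correlation.
- τ_eff = C_m/⟨G_total⟩ with the leak included; τ_eff ≤ τ₀ always.
- τ_int: per-neuron fit of `a(e^{−lag/τ}+b)` to the V_m autocorrelation
  over lags up to one tenth of the trace (the largest window the estimate's
  own precondition admits for a 10-s recording); the decay constant is
  initialized at the first 1/e crossing, which keeps the fit identifiable
  for white-noise-like traces. The V_m autocorrelation in the quiet state
  mixes a fast (milliseconds) component from AMPA/GABA_A filtering with
  slow NMDA/GABA_B components, so the single-exponential τ_int is a
  protocol-dependent compromise: the window rule above is fixed once and
  used everywhere. Population summaries average the E class, whose
  membrane potentials are the state variables of the processing analysis;
  tonically firing interneurons yield reset-dominated autocorrelations
  (τ ≈ 2 ms for I1).

## Capacity analysis

States are the E-population membrane potentials sampled at the end of each
input step after discarding 100 washout steps; initial potentials are
randomized uniformly between rest and threshold. Targets remap u∈[0,1] to
s=2u−1 before evaluating Legendre polynomials — without the remap the
product family is not orthogonal under the input measure — and are scaled
by √(2d+1) (orthonormality affects only diagnostics; capacity is invariant
to target scale). Scoring mean-centers states and targets and uses
ordinary least squares through a thin SVD of the state matrix, so
thousands of targets reuse one decomposition; the result matches an
explicit regression oracle to 10⁻⁸.

Finite samples inflate small capacities by ≈N_state/T; capacities below
2·N_state/T are zeroed before aggregation (threshold recorded in the
result, and with the threshold disabled the measured bias on pure-noise
targets matches N_state/T). Total capacity enumerates degree partitions
with at most 3 simultaneous factors, sweeping delay shells in increasing
maximal delay with early stopping once a shell contributes <10⁻³, plus a
hard evaluation budget; truncation is recorded. The capacity space is
necessarily under-sampled — C_T values are lower bounds.

Desk-scale protocol: the condition-level capacity figures this model is
known for (C_M ≈ 2.67–3.65, C_T ≈ 14–17, Δt* ≈ 4–20 ms) require N=2500
with T=10⁵ input steps; the same code paths support those
runs but they take hours, so the packaged tests and the acceptance script
work at reduced problem sizes (N=250 fixtures, T≈10³–10⁴; 10-s full-scale
runs only for the quiet-state statistics) where the qualitative ordering
across conditions, not the printed capacity values, is the reproducible
quantity.

## What the synthetic inputs do and do not emulate

Background activity is homogeneous Poisson; real ongoing cortical input has
spatiotemporal structure (up/down states, correlated afferents), so
quiet-state statistics here characterize the circuit, not cortex. The
active-state signal is deliberately structure-free (i.i.d. uniform steps)
so that measured capacity reflects the circuit rather than input
statistics. Active-state input amplitudes are tuned per condition against
realistic population-rate bounds (E ∈ [0.5,5], I1 ∈ [10,25], I2 ∈ [3,15]
spikes/s) by a grid scan that picks the lowest admissible drive.

## Known limitations

- No synaptic plasticity, receptor desensitization or spillover; weight
  shuffling controls (`Shuffled_1..3`) probe non-random weight placement
  instead. Under `Shuffled_3` the designated set spans three connection
  types; ranks are reassigned within each type so per-type weight multisets
  are preserved exactly.
- The reference PSP table is reproduced to ~1% on the E-class excitatory
  amplitude but only to ~10–20% on some other rows and decay constants (see
  the receptor section); the E-class inhibitory PSP at rest (−0.1 mV) is
  unreachable because rest sits ~1.4 mV above the GABA_A reversal.
- Degree-biased blocks at the stated densities saturate their favoured
  nodes; duplicate-edge resampling (rather than keeping multigraph edges)
  flattens the extreme tail slightly.
- Heterogeneous t_ref values are used as drawn and rounded up to the
  integration grid per spike (⌈t_ref/dt⌉ steps).
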