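# Methods

This note documents the modelling choices behind swnforce: what each
stage computes, which parameters matter, where the design was genuinely
open and what we chose, and what the synthetic fixtures do and do not
establish about real recordings.

## Network construction

Each excitatory module is a Watts–Strogatz graph: a ring lattice with
every node joined to K/2 neighbours per side, each lattice edge rewired
with probability β₀ to a uniform non-duplicate target. Rewiring
preserves the edge count, so a module always has N_m·K/2 edges. Defaults
are M = 8 modules of N_m = 100 neurons, K = 6, β₀ = 0.1 — the operating
point at which the ensemble-mean Small-Worldness Index of a 500-node
graph peaks (≈ 24) while global efficiency ≈ 0.2.

Inter-module coupling is implemented as a second rewiring pass: each
intra-module edge is independently moved, with probability β₁ (default
0.1), to a uniformly chosen neuron of a *different* excitatory module.
This preserves total edge count and produces the sparse long-range
connections between modules; the exact mechanism is a design choice, as
only the probability is fixed by the model description.

The inhibitory pool is wired in the convention of modular small-world
spiking models: the pool itself is an Erdős–Rényi graph with mean degree
K (II block); every inhibitory neuron receives *focal* excitation from
n_ei = 4 excitatory neurons of one randomly chosen module (EI block) and
projects *diffuse* inhibition to every neuron outside the pool (IE
block). Focal excitation plus diffuse inhibition is what lets a single
module's burst recruit pool inhibition that damps the whole network.

Synaptic weights are uniform(0, 1) magnitudes scaled per block:
EE +17, EI +50, IE −2, II −1. Dale's law is enforced structurally — the
sign of a weight column is fixed by the presynaptic neuron's type — and
configurations whose block scales contradict it are rejected. Conduction
delays are integers: uniform on {1, …, 20} ms for EE axons (modelling
varying axon lengths), 1 ms for all synapses involving inhibitory
neurons (local circuitry). Delays of 0 are disallowed so causality is
strict: a spike can never influence the step it occurs in.

*Directed vs undirected.* A directed network draws both orientations of
every pair independently. An undirected network mirrors magnitudes and
delays within the same-type blocks (EE, II). Full value symmetry across
the mixed E–I blocks is impossible — an EI weight must be positive and
an IE weight negative — so the mixed blocks are treated as structural
projections unaffected by the flag. One seeded generator threads through
all draws; construction is bit-reproducible per seed.

## Graph metrics

Metrics operate on the binarized undirected skeleton, since the
small-world baselines are defined for unweighted graphs. Clustering is
node-averaged local clustering (the Watts–Strogatz convention, which the
SWI formula assumes); path lengths are BFS hop counts. On a disconnected
graph the characteristic path length falls back to the largest component
with a warning, while the efficiencies use the zero-for-unreachable rule
and need no fallback. The SWI baselines are analytic: λ_rand =
ln N / ln K and γ_rand = K/N. Local efficiency averages the global
efficiency of each node's *open* neighbourhood subgraph; nodes with
fewer than two neighbours contribute zero (hence a star graph scores 0,
a complete graph 1). Under this definition the β = 0.1 ensemble scores
E_L ≈ 0.60; the ring-lattice limit of the same metric is 0.756, and
closed-neighbourhood or full-graph-distance variants score 0.80 / 0.72 —
worth knowing when comparing against published values whose convention
is not stated.

## Neuron integration

Izhikevich dynamics are integrated by forward Euler at 1 ms resolution
with two 0.5 ms substeps for the stiff voltage equation and one full
step for the recovery variable — the standard published network scheme.
The threshold test (v ≥ 30 mV) runs once per ms after both substeps;
flagged neurons are reset v ← c, u ← u + d. As in the reference scheme,
the voltage overshoot of the crossing step enters the recovery update,
which adds small step-quantisation jitter to inter-spike intervals; the
first-spike time under constant drive agrees with a dt = 0.01 ms
reference integration to within 2 ms. Initial conditions are rest:
v = −65 mV, u = b·v. Stored voltage traces keep the unclipped spike
peaks (they are diagnostics only). Non-finite states abort with the
offending step named rather than propagating NaNs.

Synaptic transmission is event-based through a ring buffer of
max_delay + 1 slots: a spike of neuron j at step t deposits w_ij into
slot t + d_ij for every postsynaptic i (one sparse matrix–vector product
per distinct delay value); the current slot is consumed and cleared
before integration. Delay d ≥ 1 and buffer length max_delay + 1
guarantee a deposit never lands in the slot being consumed.

Background drive for the complexity experiments is per-step Gaussian
current with σ = 5 pA on excitatory and 2 pA on inhibitory neurons — the
canonical cortical-network noise input, chosen once as the default; the
drive amplitude has no standard value, so this is the package's own
operating condition. Under it the default network fires at ≈ 4–5 Hz per
neuron.

## Synapse kernels

The three kernels (single exponential, double exponential, alpha) are
linear ODEs, so the per-step update uses their exact solution operator
(matrix exponential of the two-state rise/decay system) rather than
Euler stepping: a single-spike response matches the closed-form
difference of exponentials to machine precision at any dt, and
filtering is exactly linear in the spike train. Impulses inject
1/(τ_s·τ_d) into r (single) or 1/(τ_r·τ_d) into h (double/alpha) at the
start of the spike step. The alpha kernel is the double kernel with
τ_r = τ_d, handled by its degenerate-eigenvalue solution t·e^(−t/τ).
Defaults are τ_r = 2 ms, τ_d = 20 ms — typical AMPA-rise/NMDA-decay
scales — and both are config-exposed. Excitatory readout features use the double kernel.

## Dynamical complexity

Per-module mean firing rates use 50 ms windows sliding by 20 ms. The
window is deliberately at least as long as the maximum conduction delay
so each window sees complete synaptic interactions; the 20 ms slide is
the sampling period of the rate series. The windows therefore overlap:
a truly non-overlapping 50 ms window could not be sampled every 20 ms,
so the estimator is a sliding window by construction. A
5000 ms run yields ⌊(5000−50)/20⌋+1 = 248 windows. Only the M = 8
excitatory modules enter C(S); the inhibitory pool is excluded.

Rate series are detrended by exact second-order differencing
(y_t − 2y_{t−1} + y_{t−2}), which removes linear trends before
covariance estimation. Entropies are Gaussian differential entropies in
nats. A covariance whose smallest eigenvalue is at or below the ridge
level gets εI added, ε = 1e−9·trace/M, with a warning and a flag in the
report; this keeps degenerate systems (e.g. a silent module) finite
without materially shifting well-conditioned values.

C(S) at the default operating point is ≈ 0.13 nats with a seed-to-seed
standard deviation of ≈ 0.02. That spread matters when comparing
operating points: differences of the same order as the spread (as
between rewiring probabilities 0.1 and 0.2) are not resolvable from
single runs, and 5-seed means of nearby conditions can order either
way. Intra-module rewiring β₀ alone barely changes inter-module
coupling, and measured C(S) is correspondingly flat in β₀.

## Training and replay

The readout is trained online by RLS with P(0) = I/α. With λ_f = 1
(growing window, the default) the update sequence is algebraically
identical to batch ridge regression, which the tests exploit as an
oracle. Updates run every 2 steps (the finest non-overlapping window);
φ is snapshotted per update window. Defaults α = 2200 for directed
networks and α = 2 for undirected ones — empirically, undirected
networks need α ≪ N or RLS diverges, and the trainer warns when that
ratio is violated. The chaos warm-up length (default 500 ms) has no
canonical value and is config-exposed.

Each epoch restores the post-warm-up state (membrane potentials,
recovery variables, synaptic traces, pending delayed currents) and
replays the identical pink-noise stimulus, so the feature sequence is
the same every epoch and φ converges with repeated presentation. The chaos
warm-up brings the network into its high-dimensional regime before any
learning takes place.

In the modified (default) mode the readout never enters any neuron's
input, so the task network's raster is identical whether or not the
readout is computed — asserted bit-for-bit in the tests. "Only spiking
neurons inform the update" needs no extra masking: a silent neuron's
trace is identically zero, so it contributes nothing to the RLS
correlation. The feedback mode injects Q·η·z(t) into every neuron (the
rank-one term of the classical decomposition ξ = G·ξ⁰ + Q·η·φᵀ). The
two-network objective retains a u·z_target term whose role is ambiguous
in the feedback-free setting; we expose it behind
``use_target_network`` (a second, identically structured network driven
by η·u·y(t) with a fixed random readout) and default it off, where the
learning signal reduces to y(t) itself.

Replay restores the same post-warm-up snapshot and stimulus and
free-runs with the stored per-window weights and no optimisation; over
the training horizon the output is bit-for-bit the training-phase
output, and beyond it the final window's weights are reused with a
freshly seeded stimulus extension (both behaviours are tested).

## Synthetic targets and what the tests show

``synth_eeg`` generates one seeded sinusoid per EEG band (theta/alpha/
beta, tens of µV) plus pink 1/f noise — the spectral shape and amplitude
scale of resting scalp EEG. It has none of the nonstationarity,
artifacts, or cross-channel structure of real recordings, so passing
tests establish that the pipeline's mechanics are correct (learning
reduces RMSE, replay is exact, interpolation is transparent), not that
any particular RMSE on real EEG would be attained. Fitting real
recordings additionally depends on the dataset, channel and epoch count,
which are outside the package's scope.

Lowpass interpolation upsamples a target by integer factor l using a
symmetric windowed-sinc FIR filter of length 2pl+1 (Kaiser window,
β = 8), after reflecting the signal p samples outward at the edges. The
sinc's zeros at multiples of l guarantee the original samples pass
through exactly; p (default 8) controls the truncation error of the new
points (a 5 Hz sine at 128 Hz upsampled 4× is reproduced to better than
1e−3 of its amplitude away from the edges).

## Problem sizes

Default experiment sizes are the model's native ones: 1000 neurons,
5000 ms at 1 ms steps for complexity scoring; 100-trial ensembles at
N = 500 for the graph-metric sweeps. The test suite exercises the same
code paths on smaller fixtures (125–250 neurons, hundreds of steps) so
the full suite stays fast; the acceptance script runs the native sizes.

## Known limitations

- Graph metrics are binary and undirected; weighted or directed
  efficiency variants are out of scope.
- The Gaussian-entropy complexity assumes approximately Gaussian,
  stationary detrended rate series; it is a parametric estimate, not a
  general entropy estimator.
- The readout is scalar; multichannel targets are independent runs.
- Recurrent weights are static during learning (no STDP); only the
  readout adapts.
- The forgetting factor λ_f < 1 is supported but the batch-ridge
  equivalence (and the associated convergence guarantees) hold only at
  λ_f = 1.
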